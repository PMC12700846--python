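"""Volume/mask I/O, preprocessing and augmentation.

Arrays are indexed ``(slice, row, col)`` = (d, h, w), 0-based; crops are
half-open ``[start, start + extent)``.  NIfTI files written by this package
store the array in that order (axis 0 = slice); slice-last files from other
tools are detected by their strictly smallest trailing axis and rolled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import FormatError, SizeError, ValidationError

__all__ = [
    "ImageVolume",
    "ZoneMask",
    "VALID_LABELS",
    "load_volume",
    "save_volume",
    "preprocess",
    "augment_pair",
    "augment_dataset",
    "export_metrics",
    "load_dataset",
]

VALID_LABELS = frozenset({0, 1, 2})


@dataclass
class ImageVolume:
    """Single-channel volume; intensities in [0, 255] after preprocessing."""

    voxels: np.ndarray  # (d, h, w) float
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (dz, dy, dx) mm
    subject_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValidationError(f"volume must be 3D, got shape {self.voxels.shape}")

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class ZoneMask:
    """Integer labels over (d, h, w): 0=background, 1=TZ, 2=PZ."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValidationError(f"mask must be 3D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded, atol=1e-6):
                raise ValidationError("mask contains non-integer values")
            arr = rounded.astype(np.int16)
        bad = sorted(set(np.unique(arr)) - VALID_LABELS)
        if bad:
            raise ValidationError(f"mask contains labels outside {{0,1,2}}: {set(bad)}")
        self.labels = arr.astype(np.int16)

    @property
    def shape(self):
        return self.labels.shape


def _normalize_axes(arr: np.ndarray, zooms) -> tuple[np.ndarray, tuple]:
    """Return (d, h, w)-ordered data; roll slice-last layouts to slice-first."""
    if arr.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {arr.shape}")
    zooms = tuple(float(z) for z in zooms[:3]) if zooms is not None else (1.0, 1.0, 1.0)
    if arr.shape[2] < arr.shape[0] and arr.shape[2] < arr.shape[1]:
        # slice axis last (e.g. (320, 320, 20)) -> move to front
        return arr.transpose(2, 0, 1), (zooms[2], zooms[0], zooms[1])
    return arr, zooms


def _read_nifti(path: Path):
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    return _normalize_axes(data, zooms)


def _read_dicom_series(path: Path):
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError("reading DICOM series requires the optional 'pydicom' package") from exc
    files = sorted(path.glob("*.dcm")) or sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise FormatError(f"no DICOM files found in {path}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda s: int(getattr(s, "InstanceNumber", 0)))
    data = np.stack([s.pixel_array for s in slices], axis=0)
    first = slices[0]
    dy, dx = (float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0]))
    dz = float(getattr(first, "SliceThickness", 1.0))
    return data, (dz, dy, dx)


def load_volume(path, kind: str = "image"):
    """Read a NIfTI file or DICOM series directory as an ImageVolume/ZoneMask."""
    if kind not in {"image", "mask"}:
        raise ValueError(f"kind must be 'image' or 'mask', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    if path.is_dir():
        data, spacing = _read_dicom_series(path)
    else:
        data, spacing = _read_nifti(path)
    subject_id = path.name.split(".")[0]
    if kind == "mask":
        return ZoneMask(data, spacing, subject_id)
    return ImageVolume(data.astype(np.float32), spacing, subject_id)


def save_volume(obj: ImageVolume | ZoneMask, path) -> None:
    """Write as NIfTI with the (d, h, w) array order and spacing in the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, ZoneMask):
        data = obj.labels.astype(np.int16)
    else:
        data = obj.voxels.astype(np.float32)
    img = nib.Nifti1Image(data, affine=np.diag(list(obj.spacing) + [1.0]))
    img.header.set_zooms(obj.spacing)
    nib.save(img, str(path))


def preprocess(vol: ImageVolume, mask: ZoneMask, crop_hw: int = 128,
               target: tuple[int, int, int] = (20, 128, 128)):
    """Center-crop in-plane, resample to ``target`` and rescale to [0, 255].

    The crop start is the image center minus half the crop extent; depth is
    resampled linearly for the image and nearest-neighbor for the mask; a
    constant-intensity volume maps to all zeros.
    """
    if vol.shape != mask.shape:
        raise ValidationError(f"image/mask shape mismatch: {vol.shape} vs {mask.shape}")
    d, h, w = vol.shape
    if crop_hw > h or crop_hw > w:
        raise SizeError(f"crop {crop_hw} exceeds in-plane extent {(h, w)}")
    r0 = h // 2 - crop_hw // 2
    c0 = w // 2 - crop_hw // 2
    img = vol.voxels[:, r0:r0 + crop_hw, c0:c0 + crop_hw].astype(np.float64)
    lab = mask.labels[:, r0:r0 + crop_hw, c0:c0 + crop_hw]

    factors = tuple(t / s for t, s in zip(target, img.shape))
    if any(abs(f - 1.0) > 1e-12 for f in factors):
        img = ndimage.zoom(img, factors, order=1, mode="nearest", grid_mode=True)
        lab = ndimage.zoom(lab, factors, order=0, mode="nearest", grid_mode=True)
    if img.shape != tuple(target) or lab.shape != tuple(target):
        raise SizeError(f"resampling produced {img.shape}, expected {tuple(target)}")

    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        img = np.zeros_like(img)
    else:
        img = (img - lo) / (hi - lo) * 255.0
    new_spacing = tuple(sp * s / t for sp, s, t in zip(vol.spacing, (d, crop_hw, crop_hw), target))
    return (ImageVolume(img.astype(np.float32), new_spacing, vol.subject_id),
            ZoneMask(lab, new_spacing, mask.subject_id))


def augment_pair(vol: ImageVolume, mask: ZoneMask, seed: int):
    """One random in-plane flip (h/v/none) and right-angle rotation, applied
    identically to image and mask; deterministic given ``seed``.

    Rotation by 90 degrees maps pixel (r, c) to (c, h-1-r) (clockwise).
    """
    if vol.shape != mask.shape:
        raise ValidationError("image/mask shape mismatch")
    rng = np.random.default_rng(seed)
    flip = int(rng.integers(3))  # 0 none, 1 horizontal (width), 2 vertical (height)
    rot = int(rng.integers(4))
    img, lab = vol.voxels, mask.labels
    if flip == 1:
        img, lab = np.flip(img, axis=2), np.flip(lab, axis=2)
    elif flip == 2:
        img, lab = np.flip(img, axis=1), np.flip(lab, axis=1)
    if rot:
        img = np.rot90(img, k=-rot, axes=(1, 2))
        lab = np.rot90(lab, k=-rot, axes=(1, 2))
    return (ImageVolume(np.ascontiguousarray(img), vol.spacing, vol.subject_id),
            ZoneMask(np.ascontiguousarray(lab), mask.spacing, mask.subject_id))


def augment_dataset(pairs, seed: int):
    """Double the dataset: one augmented copy per pair, per-sample seeds
    spawned from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    out = list(pairs)
    for (vol, mask), ss in zip(pairs, children):
        sub_seed = int(ss.generate_state(1)[0])
        av, am = augment_pair(vol, mask, sub_seed)
        av.subject_id = f"{vol.subject_id}_aug"
        am.subject_id = f"{mask.subject_id}_aug"
        out.append((av, am))
    return out


def export_metrics(records, path) -> pd.DataFrame:
    """Write per-(subject, class) DSC/IoU/MSD rows plus mean/SD/worst summary
    rows per class.  SD is the population standard deviation."""
    records = list(records)
    if not records:
        raise ValidationError("no metric records to export")
    rows = [{
        "subject_id": r.subject_id,
        "class": r.cls,
        "dsc": r.dsc,
        "iou": r.iou,
        "msd": r.msd,
        "flags": ";".join(r.flags) if r.flags else "",
    } for r in records]
    df = pd.DataFrame(rows, columns=["subject_id", "class", "dsc", "iou", "msd", "flags"])
    summary = []
    for cls, grp in df.groupby("class", sort=True):
        stats = {
            "summary_mean": (grp["dsc"].mean(), grp["iou"].mean(), grp["msd"].mean()),
            "summary_sd": (grp["dsc"].std(ddof=0), grp["iou"].std(ddof=0), grp["msd"].std(ddof=0)),
            "summary_worst": (grp["dsc"].min(), grp["iou"].min(), grp["msd"].max()),
        }
        for name, (dsc_v, iou_v, msd_v) in stats.items():
            summary.append({"subject_id": name, "class": cls, "dsc": dsc_v,
                            "iou": iou_v, "msd": msd_v, "flags": ""})
    out = pd.concat([df, pd.DataFrame(summary)], ignore_index=True)
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        out.to_csv(path, index=False)
    return out


def load_dataset(directory, split: str | None = None):
    """Load (ImageVolume, ZoneMask) pairs listed in ``manifest.json``."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    pairs = []
    for entry in manifest["subjects"]:
        if split is not None and entry["split"] != split:
            continue
        vol = load_volume(directory / entry["image"], "image")
        mask = load_volume(directory / entry["mask"], "mask")
        vol.subject_id = mask.subject_id = entry["id"]
        if vol.shape != mask.shape:
            raise ValidationError(f"{entry['id']}: image/mask shape mismatch")
        pairs.append((vol, mask))
    return pairs
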