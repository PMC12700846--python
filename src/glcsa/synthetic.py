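"""Prostate-like phantom volumes and random tensor fixtures.

A phantom is a bright inner ellipsoid (TZ, label 1) inside a larger prostate
ellipsoid whose remaining shell is the PZ (label 2), thicker posteriorly
(crescent-like) because the TZ center is displaced anteriorly.  Intensities
are per-zone means plus Gaussian noise, clipped to [0, 255].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import ImageVolume, ZoneMask, save_volume
from .errors import ConfigError, ValidationError
from .nn import Tensor

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "feature_fixture"]


@dataclass
class PhantomSpec:
    """Geometry and intensity description of one phantom family.

    Semiaxes and offsets are fractions of the half-extent per axis (d, h, w);
    the TZ ellipsoid must fit strictly inside the prostate ellipsoid.
    """

    shape: tuple[int, int, int] = (20, 128, 128)
    prostate_semiaxes: tuple[float, float, float] = (0.70, 0.55, 0.55)
    tz_semiaxes: tuple[float, float, float] = (0.45, 0.32, 0.34)
    tz_offset: tuple[float, float, float] = (0.0, -0.12, 0.0)  # anterior shift
    intensity_means: tuple[float, float, float] = (40.0, 190.0, 110.0)  # bg, TZ, PZ
    noise_sigma: float = 8.0
    jitter: float = 0.03
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if len(self.shape) != 3 or min(self.shape) < 4:
            raise ConfigError(f"phantom shape must be 3D with extents >= 4, got {self.shape}")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        margin = self.jitter  # worst-case jitter of center and axes
        for pa, ta, off in zip(self.prostate_semiaxes, self.tz_semiaxes, self.tz_offset):
            if not (0 < ta < pa <= 1.0):
                raise ConfigError(
                    f"TZ semiaxis {ta} must be strictly inside prostate semiaxis {pa}")
            if abs(off) + ta + 2 * margin >= pa:
                raise ConfigError(
                    f"TZ offset {off} + semiaxis {ta} (+jitter) does not fit inside {pa}")
        if self.noise_sigma == 0 and len(set(self.intensity_means)) != 3:
            raise ConfigError("intensity means must be pairwise distinct when noise_sigma=0")
        return self


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / max(a, 1e-9)) ** 2
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec, seed: int | None = None):
    """Render one (ImageVolume, ZoneMask) pair; deterministic given the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shape = tuple(spec.shape)
    half = np.array(shape, dtype=np.float64) / 2.0

    jit = spec.jitter
    center = half - 0.5 + rng.uniform(-jit, jit, size=3) * half
    pro_ax = (np.array(spec.prostate_semiaxes) + rng.uniform(-jit, jit, size=3)) * half
    tz_ax = (np.array(spec.tz_semiaxes) + rng.uniform(-jit, jit, size=3)) * half
    tz_center = center + np.array(spec.tz_offset) * half

    prostate = _ellipsoid(shape, center, pro_ax)
    tz = _ellipsoid(shape, tz_center, tz_ax)
    if not np.all(prostate[tz]):
        raise ValidationError("TZ ellipsoid escaped the prostate ellipsoid")
    labels = np.zeros(shape, dtype=np.int16)
    labels[prostate] = 2  # PZ shell ...
    labels[tz] = 1  # ... minus the inner TZ

    bg, tz_mean, pz_mean = spec.intensity_means
    img = np.full(shape, bg, dtype=np.float64)
    img[labels == 1] = tz_mean
    img[labels == 2] = pz_mean
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=shape)
        img = np.clip(img, 0.0, 255.0)
    return (ImageVolume(img.astype(np.float32)), ZoneMask(labels))


def generate_dataset(n: int, spec: PhantomSpec, split: tuple[float, float] = (0.8, 0.2),
                     out_dir=None):
    """Generate ``n`` phantom subjects with a deterministic train/test split.

    When ``out_dir`` is given, NIfTI pairs plus ``manifest.json`` are written;
    the in-memory pairs and manifest are returned either way.
    """
    if n < 2:
        raise ConfigError("need at least 2 subjects")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ConfigError(f"split fractions must sum to 1, got {split}")
    spec.validate()
    seeds = [int(ss.generate_state(1)[0]) for ss in np.random.SeedSequence(spec.seed).spawn(n)]
    rng = np.random.default_rng(spec.seed)
    n_train = int(round(split[0] * n))
    assignment = np.array(["train"] * n, dtype=object)
    assignment[rng.permutation(n)[n_train:]] = "test"

    pairs, entries = [], []
    for i in range(n):
        sid = f"sub-{i:03d}"
        vol, mask = generate_phantom(spec, seed=seeds[i])
        vol.subject_id = mask.subject_id = sid
        pairs.append((vol, mask))
        entries.append({"id": sid, "image": f"{sid}_image.nii.gz",
                        "mask": f"{sid}_mask.nii.gz", "split": str(assignment[i])})
    manifest = {"seed": spec.seed, "n": n, "shape": list(spec.shape),
                "noise_sigma": spec.noise_sigma, "subjects": entries}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for (vol, mask), entry in zip(pairs, entries):
            save_volume(vol, out_dir / entry["image"])
            save_volume(mask, out_dir / entry["mask"])
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return pairs, manifest


def feature_fixture(b: int, c: int, h: int, w: int, seed: int = 0,
                    dist: str = "normal", dtype=np.float64) -> Tensor:
    """Reproducible random (b, c, h, w) tensor for oracle tests."""
    if min(b, c, h, w) < 1:
        raise ConfigError("all dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    if dist == "normal":
        data = rng.standard_normal((b, c, h, w))
    elif dist == "uniform":
        data = rng.random((b, c, h, w))
    else:
        raise ConfigError(f"unknown distribution {dist!r}")
    return Tensor(data.astype(dtype))
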