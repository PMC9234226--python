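"""Cropping, intensity normalization and augmented 2D patch sampling.

The training pipeline mirrors the clinical one: crop the volume to the
contoured structures with a minimum field of view (256 x 256 x 128 voxels by
default, clamped to the grid), window the intensities to [0, 1], then feed
the network random in-plane patches with light elastic/noise/contrast
augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .io import N_CLASSES, LabelMap, Volume3D


@dataclass
class CropRegion:
    """Axis-aligned box in voxel indices, axes (LR, AP, FH), half-open."""

    start: tuple[int, int, int]
    size: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.start = tuple(int(s) for s in self.start)
        self.size = tuple(int(s) for s in self.size)
        if any(s < 0 for s in self.start) or any(s <= 0 for s in self.size):
            raise ValueError(f"invalid crop region {self}")

    @property
    def stop(self) -> tuple[int, int, int]:
        return tuple(a + b for a, b in zip(self.start, self.size))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, a + b) for a, b in zip(self.start, self.size))

    def to_json(self) -> dict:
        return {"start": list(self.start), "size": list(self.size)}

    @classmethod
    def from_json(cls, d: dict) -> "CropRegion":
        return cls(tuple(d["start"]), tuple(d["size"]))


@dataclass
class AugmentConfig:
    """Patch augmentation: shared elastic deformation, then image-only
    additive Gaussian noise and a contrast-gamma transform."""

    deformation_sd: float = 2.0         # control-point displacement sd, px
    deformation_spacing: float = 32.0   # control grid spacing, px
    noise_sigma_range: tuple[float, float] = (0.0, 0.05)
    contrast_gamma_range: tuple[float, float] = (0.8, 1.25)


@dataclass
class TrainConfig:
    """Every training hyperparameter in one place.

    Defaults are the full-scale recipe: 128 x 128 patches, batch 4, Adam at
    1e-4, 1000 epochs with a checkpoint every 100, focal-loss gamma 2, alpha
    dropout 0.4 at the bottom level, crop minimum 256 x 256 x 128.  One
    "epoch" consumes ``patches_per_epoch`` random patches.
    """

    patch_size: int = 128
    batch_size: int = 4
    learning_rate: float = 1e-4
    epochs: int = 1000
    checkpoint_interval: int = 100
    ensemble_size: int = 3
    gamma: float = 2.0
    dropout_rate: float = 0.4
    crop_min_size: tuple[int, int, int] = (256, 256, 128)
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    patches_per_epoch: int = 64
    normalize_percentiles: tuple[float, float] = (1.0, 99.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.epochs <= 0 or self.checkpoint_interval <= 0:
            raise ValueError("epochs and checkpoint_interval must be positive")
        if self.epochs % self.checkpoint_interval != 0:
            raise ValueError(
                f"epochs ({self.epochs}) not divisible by checkpoint_interval "
                f"({self.checkpoint_interval})")
        n_ckpt = self.epochs // self.checkpoint_interval
        if n_ckpt < self.ensemble_size:
            raise ValueError(
                f"only {n_ckpt} checkpoints but ensemble_size={self.ensemble_size}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.patch_size <= 0 or self.batch_size <= 0 or self.patches_per_epoch <= 0:
            raise ValueError("patch/batch sizes must be positive")
        lo, hi = self.normalize_percentiles
        if not 0 <= lo < hi <= 100:
            raise ValueError("normalize_percentiles must satisfy 0 <= lo < hi <= 100")


@dataclass
class PatchBatch:
    """A batch of congruent image / integer-label patches."""

    images: np.ndarray   # (N, ps, ps) float32
    labels: np.ndarray   # (N, ps, ps) int
    coords: np.ndarray   # (N, 3) top-left corner (LR, AP) and slice index

    def __len__(self) -> int:
        return self.images.shape[0]


def compute_crop(labels: LabelMap, min_size: tuple[int, int, int] = (256, 256, 128)
                 ) -> CropRegion:
    """Smallest box containing all foreground, expanded to ``min_size``.

    Per axis the size is ``max(bbox extent, min(min_size, grid extent))``;
    expansion is centered on the bounding-box center, then shifted minimally
    to stay inside the grid.
    """
    fg = labels.data != 0
    if not fg.any():
        raise ValueError("no structures to crop to")
    shape = labels.shape
    start, size = [], []
    for ax in range(3):
        proj = fg.any(axis=tuple(i for i in range(3) if i != ax))
        idx = np.flatnonzero(proj)
        lo, hi = int(idx[0]), int(idx[-1]) + 1
        extent = hi - lo
        sz = max(extent, min(min_size[ax], shape[ax]))
        center = (lo + hi) // 2
        st = center - sz // 2
        st = min(max(st, 0), shape[ax] - sz)
        start.append(st)
        size.append(sz)
    return CropRegion(tuple(start), tuple(size))


def apply_crop(obj: Volume3D | LabelMap, region: CropRegion):
    """Extract the region; origin advances by start x spacing."""
    if any(region.stop[ax] > obj.shape[ax] for ax in range(3)):
        raise ValueError(f"crop region {region} out of bounds for shape {obj.shape}")
    data = obj.data[region.slices()].copy()
    origin = tuple(o + s * sp for o, s, sp in
                   zip(obj.origin_mm, region.start, obj.spacing_mm))
    return replace(obj, data=data, origin_mm=origin)


def uncrop(data: np.ndarray, region: CropRegion, full_shape, fill=0) -> np.ndarray:
    out = np.full(full_shape, fill, dtype=data.dtype)
    out[region.slices()] = data
    return out


@dataclass(frozen=True)
class NormStats:
    """Intensity window from training: values clipped to [lo, hi] then
    affinely mapped to [0, 1]."""

    lo: float
    hi: float

    def to_json(self) -> dict:
        return {"lo": self.lo, "hi": self.hi}

    @classmethod
    def from_json(cls, d: dict) -> "NormStats":
        return cls(float(d["lo"]), float(d["hi"]))


def compute_normalization(vol: Volume3D, lo_pct: float = 1.0, hi_pct: float = 99.0
                          ) -> NormStats:
    lo, hi = np.percentile(vol.data, [lo_pct, hi_pct])
    return NormStats(float(lo), float(hi))


def apply_normalization(vol: Volume3D, stats: NormStats) -> Volume3D:
    if stats.hi <= stats.lo:  # constant (or degenerate) window -> all zeros
        return replace(vol, data=np.zeros_like(vol.data, dtype=np.float32))
    data = np.clip(vol.data, stats.lo, stats.hi)
    data = (data - stats.lo) / (stats.hi - stats.lo)
    return replace(vol, data=data.astype(np.float32))


def normalize_intensity(vol: Volume3D, lo_pct: float = 1.0, hi_pct: float = 99.0
                        ) -> Volume3D:
    """Percentile-window the volume to [0, 1] (constant input maps to zeros)."""
    return apply_normalization(vol, compute_normalization(vol, lo_pct, hi_pct))


def sample_patches(vol: Volume3D, labels: LabelMap, cfg: TrainConfig,
                   rng: np.random.Generator, n: int | None = None) -> PatchBatch:
    """Cut ``n`` random axis-aligned in-plane patches (uniform slice, uniform
    top-left corner); image and label patches are congruent."""
    ps = cfg.patch_size
    nx, ny, nz = vol.shape
    if ps > nx or ps > ny:
        raise ValueError(f"patch_size {ps} exceeds in-plane size ({nx}, {ny})")
    if labels.shape != vol.shape:
        raise ValueError("image/label shape mismatch")
    n = cfg.batch_size if n is None else n
    imgs = np.empty((n, ps, ps), dtype=np.float32)
    labs = np.empty((n, ps, ps), dtype=np.int16)
    coords = np.empty((n, 3), dtype=np.int64)
    for i in range(n):
        k = int(rng.integers(0, nz))
        x0 = int(rng.integers(0, nx - ps + 1))
        y0 = int(rng.integers(0, ny - ps + 1))
        imgs[i] = vol.data[x0:x0 + ps, y0:y0 + ps, k]
        labs[i] = labels.data[x0:x0 + ps, y0:y0 + ps, k]
        coords[i] = (x0, y0, k)
    return PatchBatch(imgs, labs, coords)


def augment_patch(img: np.ndarray, lab: np.ndarray, cfg: AugmentConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Augment one congruent (image, label) patch pair.

    Order: shared smooth elastic deformation (linear interp for the image,
    nearest-neighbour for labels), additive Gaussian noise (image only),
    contrast-gamma transform (image only).  Label values stay in {0..3}.
    """
    if img.shape != lab.shape:
        raise ValueError("image/label patch shapes differ")
    img = np.asarray(img, dtype=np.float32)
    lab = np.asarray(lab)

    if cfg.deformation_sd > 0:
        nc = tuple(int(np.ceil((s - 1) / cfg.deformation_spacing)) + 1 for s in img.shape)
        ctrl = rng.normal(0.0, cfg.deformation_sd, size=(2,) + nc)
        base = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in img.shape],
                           indexing="ij")
        coarse = [b / cfg.deformation_spacing for b in base]
        warped = [base[ax] + map_coordinates(ctrl[ax], coarse, order=1, mode="nearest")
                  for ax in range(2)]
        img = map_coordinates(img, warped, order=1, mode="reflect").astype(np.float32)
        lab = map_coordinates(lab, warped, order=0, mode="reflect")

    lo, hi = cfg.noise_sigma_range
    sigma = rng.uniform(lo, hi)
    if sigma > 0:
        img = img + rng.normal(0.0, sigma, size=img.shape).astype(np.float32)

    glo, ghi = cfg.contrast_gamma_range
    gamma = rng.uniform(glo, ghi)
    if gamma != 1.0:
        img = np.sign(img) * np.abs(img) ** gamma  # sign-safe for noise-negative values

    return img.astype(np.float32), lab


def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """(...,) int -> (..., n_classes) float32 one-hot, channel order
    (background, CTV, bladder, rectum)."""
    out = np.zeros(labels.shape + (n_classes,), dtype=np.float32)
    for c in range(n_classes):
        out[..., c][labels == c] = 1.0
    return out


def background_fraction(labels: LabelMap) -> float:
    """Fraction of voxels labelled background."""
    return float((labels.data == 0).mean())
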