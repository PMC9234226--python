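"""Synthetic longitudinal pelvic phantom.

Generates per-patient fraction series (image + ground-truth labels) that mimic
the statistical structure of daily T2-weighted pelvic MR on an MR-Linac:

* three organs — CTV (prostate-like ellipsoid), bladder (larger ellipsoid,
  superior-anterior of the CTV), rectum (curved tube posterior to the CTV,
  running feet-head through the volume);
* T2-like contrast: bright bladder fluid, intermediate CTV, darker rectum,
  with optional very bright "gas pocket" segments in the rectum;
* interfractional variation: per-organ volume changes (small for the CTV,
  large for bladder/rectum) applied as isotropic scaling about the organ
  centroid, followed by a shared smooth random deformation;
* a low-frequency multiplicative bias field and additive Gaussian noise.

Organ shapes are analytic, so organ volumes are exactly controllable and the
generator needs nothing beyond numpy/scipy.  Intensities live on an arbitrary
[0, 1000] scale; downstream normalization makes the scale irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .io import LabelMap, PatientSeries, Volume3D

BG, CTV, BLADDER, RECTUM = 0, 1, 2, 3
# overlap priority: CTV > rectum > bladder (target integrity first)
_PRIORITY = (CTV, RECTUM, BLADDER)

_MAX_RETRIES = 25


@dataclass
class OrganGeometry:
    """Base organ shapes in voxel units on the default 96x96x32 grid.

    Centers are fractions of the grid shape so the layout survives moderate
    grid-size changes; semi-axes and radii are absolute voxels.
    """

    ctv_center: tuple[float, float, float] = (0.50, 0.55, 0.45)
    ctv_semiaxes: tuple[float, float, float] = (11.0, 9.0, 7.5)
    bladder_center: tuple[float, float, float] = (0.50, 0.36, 0.60)
    bladder_semiaxes: tuple[float, float, float] = (15.0, 13.0, 8.0)
    rectum_center_ap: float = 0.72          # centerline AP position (fraction)
    rectum_curvature: float = 4.0           # AP bow amplitude over FH, voxels
    rectum_radius: float = 5.0              # tube radius, voxels


@dataclass
class VariationConfig:
    """Per-fraction interfractional variation.

    ``*_volume_range`` is the maximum relative organ-volume change versus
    fraction 1 (0.4 = up to +-40%); ``deformation_magnitude`` bounds the
    per-voxel displacement (voxels) of the shared smooth field, sampled on a
    control grid with ``deformation_spacing`` voxel spacing.
    """

    ctv_volume_range: float = 0.05
    bladder_volume_range: float = 0.40
    rectum_volume_range: float = 0.25
    deformation_magnitude: float = 1.5
    deformation_spacing: float = 16.0


@dataclass
class ContrastConfig:
    """Per-organ mean intensity (arbitrary [0, 1000] scale) and noise sigma."""

    means: tuple[float, float, float, float] = (150.0, 450.0, 900.0, 300.0)
    noise_sigma: float = 25.0
    bias_field_amplitude: float = 0.10
    bias_field_spacing: float = 32.0


@dataclass
class PocketConfig:
    """Bright rectal gas pockets — the contrast-mismatch failure mode.

    With probability ``probability`` per fraction, a feet-head segment of the
    rectum renders at ``intensity`` (above the bladder mean).  ``in_training``
    controls whether the training fraction may receive pockets; off by
    default, so pockets model contrast *unseen* at training time.
    """

    probability: float = 0.0
    intensity: float = 1000.0
    min_length_frac: float = 0.25
    max_length_frac: float = 0.50
    in_training: bool = False


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (96, 96, 32)
    spacing_mm: tuple[float, float, float] = (0.86, 0.86, 1.0)
    n_fractions: int = 4
    organ_geometry: OrganGeometry = field(default_factory=OrganGeometry)
    variation: VariationConfig = field(default_factory=VariationConfig)
    contrast: ContrastConfig = field(default_factory=ContrastConfig)
    rectum_bright_pocket: PocketConfig = field(default_factory=PocketConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_fractions < 2:
            raise ValueError("n_fractions must be >= 2")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid too small")
        g = self.organ_geometry
        if min(g.ctv_semiaxes) <= 0 or min(g.bladder_semiaxes) <= 0 or g.rectum_radius <= 0:
            raise ValueError("organ semi-axes/radius must be positive")
        v = self.variation
        for name, r in (("ctv", v.ctv_volume_range), ("bladder", v.bladder_volume_range),
                        ("rectum", v.rectum_volume_range)):
            if r < 0:
                raise ValueError(f"{name} volume range must be >= 0")
        if v.deformation_magnitude < 0:
            raise ValueError("deformation magnitude must be >= 0")
        if v.deformation_magnitude >= v.deformation_spacing / 2:
            raise ValueError(
                "deformation magnitude must stay below half the control spacing "
                f"({v.deformation_magnitude} >= {v.deformation_spacing / 2}) "
                "to keep the field invertible")
        m = self.contrast.means
        if not (m[BLADDER] > m[CTV] > m[BG]):
            raise ValueError("contrast must satisfy bladder > CTV > background")
        if not 0 <= self.rectum_bright_pocket.probability <= 1:
            raise ValueError("pocket probability must be in [0, 1]")

    def volume_ranges(self) -> dict[int, float]:
        v = self.variation
        return {CTV: v.ctv_volume_range, BLADDER: v.bladder_volume_range,
                RECTUM: v.rectum_volume_range}


@dataclass
class DeformationSpec:
    """One fraction's interfractional change: a smooth displacement field on a
    coarse control grid plus per-organ volume-scale factors."""

    control_disp: np.ndarray        # (3, nc_lr, nc_ap, nc_fh) control-point displacements
    control_spacing: float
    scale_ratios: dict[int, float]  # organ label -> target volume ratio vs fraction 1

    def displacement(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Trilinearly upsample control displacements to a (3, *shape) field.

        Linear interpolation keeps every per-voxel displacement within the
        control-point range, so the configured magnitude bound is exact.
        """
        coords = np.meshgrid(*[np.arange(n) / self.control_spacing for n in shape],
                             indexing="ij")
        out = np.empty((3,) + tuple(shape), dtype=np.float64)
        for ax in range(3):
            out[ax] = map_coordinates(self.control_disp[ax], coords, order=1, mode="nearest")
        return out


def _control_grid_shape(shape, spacing) -> tuple[int, ...]:
    return tuple(int(np.ceil((n - 1) / spacing)) + 1 for n in shape)


def sample_interfraction_change(config: PhantomConfig, fraction_index: int,
                                rng: np.random.Generator) -> DeformationSpec:
    """Draw the deformation + per-organ scale factors for one test fraction.

    ``fraction_index`` is 1-based; the training fraction (1) has no change,
    so only indices >= 2 are valid here.
    """
    if fraction_index < 2:
        raise ValueError("fraction_index must be >= 2 (fraction 1 is the reference)")
    v = config.variation
    nc = _control_grid_shape(config.grid_shape, v.deformation_spacing)
    m = v.deformation_magnitude
    disp = rng.uniform(-m, m, size=(3,) + nc) if m > 0 else np.zeros((3,) + nc)
    # target ratios drawn from the inner 85% of the band: leaves headroom for
    # voxelization and deformation effects while the count check enforces the
    # full band exactly
    ratios = {}
    for organ, r in config.volume_ranges().items():
        ratios[organ] = 1.0 + 0.85 * r * rng.uniform(-1, 1) if r > 0 else 1.0
    return DeformationSpec(disp, v.deformation_spacing, ratios)


def _organ_memberships(config: PhantomConfig, coords: np.ndarray,
                       scales: dict[int, float] | None = None) -> dict[int, np.ndarray]:
    """Evaluate analytic organ membership at (possibly warped) coordinates.

    ``coords`` is (3, ...) in voxel units.  ``scales`` maps organ -> volume
    ratio; ellipsoids scale isotropically about their centroid, the rectum
    scales its cross-sectional radius (its centerline spans the whole
    feet-head extent, so axial scaling is meaningless).
    """
    g = config.organ_geometry
    shape = np.asarray(config.grid_shape, dtype=np.float64)
    scales = scales or {}
    x, y, z = coords
    out = {}

    for organ, center_frac, semi in ((CTV, g.ctv_center, g.ctv_semiaxes),
                                     (BLADDER, g.bladder_center, g.bladder_semiaxes)):
        lin = scales.get(organ, 1.0) ** (1.0 / 3.0)
        c = np.asarray(center_frac) * (shape - 1)
        q = (((x - c[0]) / (semi[0] * lin)) ** 2
             + ((y - c[1]) / (semi[1] * lin)) ** 2
             + ((z - c[2]) / (semi[2] * lin)) ** 2)
        out[organ] = q <= 1.0

    rad = g.rectum_radius * scales.get(RECTUM, 1.0) ** 0.5
    cx = 0.5 * (shape[0] - 1)
    cy = g.rectum_center_ap * (shape[1] - 1) + g.rectum_curvature * np.sin(
        np.pi * z / max(shape[2] - 1, 1))
    out[RECTUM] = (x - cx) ** 2 + (y - cy) ** 2 <= rad ** 2
    return out


def _compose_labels(memberships: dict[int, np.ndarray], shape) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int16)
    for organ in reversed(_PRIORITY):  # lowest priority painted first
        labels[memberships[organ]] = organ
    return labels


def _check_fit(labels: np.ndarray) -> int | None:
    """Return the first organ touching a forbidden grid face, else None.

    The rectum legitimately spans the feet-head extent, so only its LR/AP
    faces are checked.
    """
    for organ in (CTV, BLADDER, RECTUM):
        m = labels == organ
        if not m.any():
            return organ
        faces = [m[0], m[-1], m[:, 0], m[:, -1]]
        if organ != RECTUM:
            faces += [m[:, :, 0], m[:, :, -1]]
        if any(f.any() for f in faces):
            return organ
    return None


def render_intensity(labels: LabelMap, config: PhantomConfig,
                     rng: np.random.Generator,
                     pocket_mask: np.ndarray | None = None) -> Volume3D:
    """Render a T2-like image: per-organ mean x low-frequency bias + noise."""
    c = config.contrast
    mean_map = np.asarray(c.means, dtype=np.float64)
    img = mean_map[labels.data]
    if pocket_mask is not None:
        img[pocket_mask] = config.rectum_bright_pocket.intensity
    if c.bias_field_amplitude > 0:
        nc = _control_grid_shape(labels.shape, c.bias_field_spacing)
        ctrl = rng.uniform(-1, 1, size=nc)
        coords = np.meshgrid(*[np.arange(n) / c.bias_field_spacing for n in labels.shape],
                             indexing="ij")
        img = img * (1.0 + c.bias_field_amplitude * map_coordinates(
            ctrl, coords, order=1, mode="nearest"))
    if c.noise_sigma > 0:
        img = img + rng.normal(0.0, c.noise_sigma, size=img.shape)
    return Volume3D(img.astype(np.float32), labels.spacing_mm, labels.origin_mm)


def _sample_pocket(labels: np.ndarray, cfg: PocketConfig,
                   rng: np.random.Generator) -> np.ndarray | None:
    if rng.uniform() >= cfg.probability:
        return None
    nz = labels.shape[2]
    length = int(round(nz * rng.uniform(cfg.min_length_frac, cfg.max_length_frac)))
    length = max(length, 1)
    z0 = int(rng.integers(0, max(nz - length, 0) + 1))
    mask = np.zeros_like(labels, dtype=bool)
    mask[:, :, z0:z0 + length] = labels[:, :, z0:z0 + length] == RECTUM
    return mask if mask.any() else None


def generate_patient(config: PhantomConfig, patient_id: str = "phantom01") -> PatientSeries:
    """Generate one patient's longitudinal series.

    Fraction 1 is the undeformed reference (the training fraction); each
    later fraction applies freshly sampled per-organ volume scaling and a
    shared smooth deformation, then is re-rendered with fresh noise.  Organ
    voxel counts are verified against fraction 1 and the configured ranges;
    a draw that breaks a range or pushes an organ out of the grid is
    rejected and resampled (bounded retries).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    frac_seeds = root.spawn(config.n_fractions)
    shape = config.grid_shape
    base_coords = np.array(np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape],
                                       indexing="ij"))

    # fraction 1: no scaling, no deformation
    labels1 = _compose_labels(_organ_memberships(config, base_coords), shape)
    bad = _check_fit(labels1)
    if bad is not None:
        raise ValueError(f"base geometry: organ {bad} empty or touching grid boundary")
    ref_counts = {o: int((labels1 == o).sum()) for o in (CTV, BLADDER, RECTUM)}
    ranges = config.volume_ranges()

    fractions = []
    for i in range(config.n_fractions):
        rng = np.random.default_rng(frac_seeds[i])
        if i == 0:
            labels = labels1
        else:
            labels = None
            for _ in range(_MAX_RETRIES):
                spec = sample_interfraction_change(config, i + 1, rng)
                disp = spec.displacement(shape)
                warped = base_coords + disp  # backward map: sample shapes at x+u(x)
                cand = _compose_labels(
                    _organ_memberships(config, warped, spec.scale_ratios), shape)
                if _check_fit(cand) is not None:
                    continue
                ok = all(abs((cand == o).sum() / ref_counts[o] - 1.0) <= ranges[o] + 1e-12
                         for o in (CTV, BLADDER, RECTUM))
                if ok:
                    labels = cand
                    break
            if labels is None:
                raise RuntimeError(
                    f"fraction {i + 1}: could not keep organs in grid and within "
                    f"volume ranges after {_MAX_RETRIES} draws")
        lab = LabelMap(labels, config.spacing_mm)
        pocket_cfg = config.rectum_bright_pocket
        pocket = None
        if i > 0 or pocket_cfg.in_training:
            pocket = _sample_pocket(labels, pocket_cfg, rng)
        vol = render_intensity(lab, config, rng, pocket)
        fractions.append((vol, lab))

    return PatientSeries(patient_id=patient_id, fractions=fractions, training_index=0)
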