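"""Volumes, label maps and patient series, with NIfTI round-trip.

The package fixes a single internal axis convention: arrays are indexed
``(LR, AP, FH)`` — left-right, anterior-posterior, feet-head — so that a
transversal (axial) slice is ``data[:, :, k]``.  Files are reoriented to the
closest RAS-canonical orientation on load; spacing is carried as metadata and
never resampled.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

CLASS_NAMES = ("background", "ctv", "bladder", "rectum")
N_CLASSES = 4


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (LR, AP, FH)
        Finite scalar intensities.
    spacing_mm : tuple of 3 floats
        Voxel size along each axis, strictly positive.
    origin_mm : tuple of 3 floats
        World coordinate of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.86, 0.86, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume3D":
        return replace(self, data=self.data.copy())


@dataclass
class LabelMap:
    """An integer segmentation grid aligned to a :class:`Volume3D`.

    Values are restricted to ``{0, 1, 2, 3}`` = (background, CTV, bladder,
    rectum).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.86, 0.86, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D label map, got {arr.ndim}D")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded, atol=1e-3):
                raise ValueError("label map contains non-integer voxel values")
            arr = rounded.astype(np.int16)
        bad = np.setdiff1d(np.unique(arr), np.arange(N_CLASSES))
        if bad.size:
            raise ValueError(f"label values outside {{0..3}}: {bad.tolist()}")
        self.data = arr.astype(np.int16, copy=False)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask(self, cls: int) -> np.ndarray:
        return self.data == cls

    def copy(self) -> "LabelMap":
        return replace(self, data=self.data.copy())


@dataclass
class PatientSeries:
    """One patient's ordered fraction images with (optional) label maps.

    ``training_index`` points at the fraction whose labels train the
    patient-specific model (0-based; clinically this is fraction 1, index 0).
    """

    patient_id: str
    fractions: list[tuple[Volume3D, LabelMap | None]]
    training_index: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) < 1:
            raise ValueError("series needs at least one fraction")
        if not (0 <= self.training_index < len(self.fractions)):
            raise ValueError("training_index out of range")
        if self.fractions[self.training_index][1] is None:
            raise ValueError("training fraction requires labels")
        spacings = {f[0].spacing_mm for f in self.fractions}
        if len(spacings) != 1:
            raise ValueError(f"spacing mismatch across fractions: {sorted(spacings)}")
        for i, (vol, lab) in enumerate(self.fractions):
            if lab is not None and lab.shape != vol.shape:
                raise ValueError(f"fraction {i}: label shape {lab.shape} != image shape {vol.shape}")

    @property
    def training_fraction(self) -> tuple[Volume3D, LabelMap]:
        vol, lab = self.fractions[self.training_index]
        assert lab is not None
        return vol, lab

    def test_indices(self) -> list[int]:
        return [i for i in range(len(self.fractions)) if i != self.training_index]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _load_canonical(path):
    img = nib.load(os.fspath(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected 3D volume, got {len(img.shape)}D: {path}")
    img = nib.as_closest_canonical(img)  # RAS+ == (LR, AP, FH)
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return data, tuple(float(z) for z in zooms), tuple(float(o) for o in origin)


def read_volume(path) -> Volume3D:
    """Read a 3D NIfTI image, reoriented to the internal (LR, AP, FH) axes."""
    data, spacing, origin = _load_canonical(path)
    return Volume3D(np.asarray(data, dtype=np.float32), spacing, origin)


def write_volume(vol: Volume3D, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32),
                          _affine(vol.spacing_mm, vol.origin_mm))
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, os.fspath(path))


def read_labelmap(path) -> LabelMap:
    """Read a 3D NIfTI label map; values must round to integers in {0..3}."""
    data, spacing, origin = _load_canonical(path)
    return LabelMap(data, spacing, origin)


def write_labelmap(lab: LabelMap, path) -> None:
    img = nib.Nifti1Image(lab.data.astype(np.int16),
                          _affine(lab.spacing_mm, lab.origin_mm))
    img.header.set_zooms(lab.spacing_mm)
    nib.save(img, os.fspath(path))


def load_series(manifest_path) -> PatientSeries:
    """Assemble a :class:`PatientSeries` from a JSON manifest.

    The manifest lists, per fraction, an ``image`` path and optionally a
    ``labels`` path (relative paths resolve against the manifest's directory),
    plus ``patient_id`` and 0-based ``training_index`` (default 0).  Geometry
    consistency is enforced on load; nothing is resampled silently.
    """
    manifest_path = os.fspath(manifest_path)
    with open(manifest_path) as fh:
        man = json.load(fh)
    base = os.path.dirname(os.path.abspath(manifest_path))

    def _resolve(p):
        return p if os.path.isabs(p) else os.path.join(base, p)

    fractions: list[tuple[Volume3D, LabelMap | None]] = []
    for entry in man["fractions"]:
        vol = read_volume(_resolve(entry["image"]))
        lab = read_labelmap(_resolve(entry["labels"])) if entry.get("labels") else None
        fractions.append((vol, lab))
    return PatientSeries(
        patient_id=str(man.get("patient_id", "patient")),
        fractions=fractions,
        training_index=int(man.get("training_index", 0)),
    )


def save_series(series: PatientSeries, out_dir, compress: bool = True) -> str:
    """Write every fraction as NIfTI plus a ``manifest.json``; returns its path."""
    os.makedirs(out_dir, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    entries = []
    for i, (vol, lab) in enumerate(series.fractions):
        img_name = f"frac{i + 1:02d}_img{ext}"
        write_volume(vol, os.path.join(out_dir, img_name))
        entry = {"image": img_name}
        if lab is not None:
            lab_name = f"frac{i + 1:02d}_lab{ext}"
            write_labelmap(lab, os.path.join(out_dir, lab_name))
            entry["labels"] = lab_name
        entries.append(entry)
    manifest = {
        "patient_id": series.patient_id,
        "training_index": series.training_index,
        "fractions": entries,
    }
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
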