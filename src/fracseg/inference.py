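"""Ensemble inference: soft-voting over late checkpoints, then keeping only
the largest coherent 3D structure per class."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import N_CLASSES, LabelMap, Volume3D
from .model import ModelCheckpoint, pad_to_multiple
from .preprocess import apply_crop, apply_normalization, uncrop


@dataclass
class EnsemblePrediction:
    """Soft-voted per-voxel probabilities over the crop region, plus the
    full-grid argmax label map (background outside the crop)."""

    prob: np.ndarray          # (n_classes, *crop.size)
    labels: LabelMap          # full grid
    member_epochs: list[int]


def select_ensemble(checkpoints: list[ModelCheckpoint], k: int
                    ) -> list[ModelCheckpoint]:
    """The ``k`` highest-epoch checkpoints, in ascending epoch order."""
    if k < 1:
        raise ValueError("ensemble size must be >= 1")
    if len(checkpoints) < k:
        raise ValueError(
            f"need {k} checkpoints for the ensemble, have {len(checkpoints)}")
    return sorted(checkpoints, key=lambda c: c.epoch)[-k:]


def soft_vote(prob_maps: list[np.ndarray]) -> np.ndarray:
    """Voxel-wise arithmetic mean of congruent probability grids."""
    if not prob_maps:
        raise ValueError("no probability maps to vote over")
    shape = prob_maps[0].shape
    for p in prob_maps[1:]:
        if p.shape != shape:
            raise ValueError(f"shape mismatch in soft vote: {p.shape} vs {shape}")
    return np.mean(prob_maps, axis=0)


def _member_prob(ck: ModelCheckpoint, data: np.ndarray,
                 chunk: int = 8) -> np.ndarray:
    """Run one member over all transversal slices of a cropped, normalized
    volume -> (n_classes, X, Y, Z).  Full slices, no patch tiling."""
    model = ck.build()
    mult = 2 ** ck.spec.depth
    nx, ny, nz = data.shape
    padded0, pads = pad_to_multiple(data[:, :, 0], mult)
    stack = np.empty((nz,) + padded0.shape + (1,), dtype=np.float32)
    stack[0, :, :, 0] = padded0
    for k in range(1, nz):
        stack[k, :, :, 0] = pad_to_multiple(data[:, :, k], mult)[0]
    out = np.empty((ck.spec.n_classes, nx, ny, nz), dtype=np.float32)
    t, b, l, r = pads
    h, w = padded0.shape
    for k0 in range(0, nz, chunk):
        prob = model.forward(stack[k0:k0 + chunk], train=False)
        out[:, :, :, k0:k0 + chunk] = prob[:, t:h - b, l:w - r, :].transpose(3, 1, 2, 0)
    return out


def predict_volume(checkpoints: list[ModelCheckpoint], volume: Volume3D
                   ) -> EnsemblePrediction:
    """Segment a full volume with a checkpoint ensemble.

    The crop and intensity window stored at training time are applied (a
    test fraction has no labels to crop to); each member runs
    slice-by-slice over the transversal axis; members are soft-voted and the
    argmax (ties toward the lowest class index) is un-cropped to the full
    grid with background outside.
    """
    if not checkpoints:
        raise ValueError("empty checkpoint list")
    ref = checkpoints[0]
    for ck in checkpoints[1:]:
        if ck.spec != ref.spec or ck.crop != ref.crop or ck.norm_stats != ref.norm_stats:
            raise ValueError("ensemble members disagree on spec/crop/normalization")
    if any(ref.crop.stop[ax] > volume.shape[ax] for ax in range(3)):
        raise ValueError(
            f"volume shape {volume.shape} smaller than stored crop {ref.crop}")
    cvol = apply_normalization(apply_crop(volume, ref.crop), ref.norm_stats)
    probs = [_member_prob(ck, cvol.data) for ck in checkpoints]
    vote = soft_vote(probs)
    # np.argmax returns the first maximum -> ties break toward lowest class
    labels_crop = vote.argmax(axis=0).astype(np.int16)
    full = uncrop(labels_crop, ref.crop, volume.shape)
    return EnsemblePrediction(
        prob=vote,
        labels=LabelMap(full, volume.spacing_mm, volume.origin_mm),
        member_epochs=[ck.epoch for ck in checkpoints])


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def largest_component_filter(labels: LabelMap) -> LabelMap:
    """Keep, per foreground class, only the largest 26-connected 3D component.

    Removed voxels become background.  Size ties break toward the component
    containing the lexicographically smallest voxel coordinate (which is the
    first-labelled component in scan order).
    """
    out = labels.data.copy()
    for cls in range(1, N_CLASSES):
        mask = out == cls
        if not mask.any():
            continue
        comp, n = ndimage.label(mask, structure=_CONN26)
        if n <= 1:
            continue
        sizes = np.bincount(comp.ravel())[1:]  # component ids are 1..n
        keep = int(np.argmax(sizes)) + 1       # argmax -> lowest id among ties
        out[mask & (comp != keep)] = 0
    return LabelMap(out, labels.spacing_mm, labels.origin_mm, labels.class_names)
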