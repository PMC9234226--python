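"""Patient-specific segmentation as a scikit-learn style estimator.

``PatientSegmenter`` owns the whole per-patient recipe: crop to the labelled
anatomy, window intensities, train a 2D U-net on augmented random patches of
the single labelled training fraction, snapshot the model at fixed epoch
intervals, and segment unseen fractions with a soft-voting ensemble of the
last snapshots followed by largest-component filtering.

The class follows sklearn conventions (``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with trailing underscores)
so it composes with sklearn tooling; the module-level
:func:`train_patient_model` is a thin functional wrapper.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .io import LabelMap, PatientSeries, Volume3D
from .model import (ModelCheckpoint, UNetSpec, build_model, config_hash,
                    focal_loss, forward_slice)
from .preprocess import (AugmentConfig, TrainConfig, apply_crop,
                         apply_normalization, compute_crop,
                         compute_normalization, one_hot, sample_patches)


class PatientSegmenter(BaseEstimator):
    """Train on one labelled fraction; segment the rest.

    Parameters mirror :class:`~fracseg.preprocess.TrainConfig` and
    :class:`~fracseg.model.UNetSpec`; defaults are the full-scale recipe
    (1000 epochs, checkpoint every 100, ensemble of the 3 last snapshots,
    focal-loss gamma 2, Adam at 1e-4, 128x128 patches, batch 4).
    """

    def __init__(self, depth: int = 4, base_filters: int = 32,
                 dropout_rate: float = 0.4, patch_size: int = 128,
                 batch_size: int = 4, learning_rate: float = 1e-4,
                 epochs: int = 1000, checkpoint_interval: int = 100,
                 ensemble_size: int = 3, gamma: float = 2.0,
                 crop_min_size: tuple[int, int, int] = (256, 256, 128),
                 patches_per_epoch: int = 64,
                 augmentation: AugmentConfig | None = None,
                 normalize_percentiles: tuple[float, float] = (1.0, 99.0),
                 seed: int = 0):
        self.depth = depth
        self.base_filters = base_filters
        self.dropout_rate = dropout_rate
        self.patch_size = patch_size
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.checkpoint_interval = checkpoint_interval
        self.ensemble_size = ensemble_size
        self.gamma = gamma
        self.crop_min_size = crop_min_size
        self.patches_per_epoch = patches_per_epoch
        self.augmentation = augmentation
        self.normalize_percentiles = normalize_percentiles
        self.seed = seed

    # -- config assembly ---------------------------------------------------
    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            patch_size=self.patch_size, batch_size=self.batch_size,
            learning_rate=self.learning_rate, epochs=self.epochs,
            checkpoint_interval=self.checkpoint_interval,
            ensemble_size=self.ensemble_size, gamma=self.gamma,
            dropout_rate=self.dropout_rate, crop_min_size=tuple(self.crop_min_size),
            augmentation=self.augmentation or AugmentConfig(),
            patches_per_epoch=self.patches_per_epoch,
            normalize_percentiles=tuple(self.normalize_percentiles),
            seed=self.seed)

    def _unet_spec(self) -> UNetSpec:
        return UNetSpec(depth=self.depth, base_filters=self.base_filters,
                        bottom_dropout_rate=self.dropout_rate)

    # -- training ----------------------------------------------------------
    def fit(self, X: PatientSeries, y=None,
            validation: tuple[Volume3D, LabelMap] | None = None
            ) -> "PatientSegmenter":
        """Train on the series' designated training fraction.

        ``validation``, if given, is an (image, labels) pair evaluated (focal
        loss + per-class Dice) at every checkpoint and logged to
        ``history_``; it never influences the weights.
        """
        cfg = self._train_config()
        spec = self._unet_spec()
        vol, lab = X.training_fraction
        if self.patch_size % 2 ** self.depth:
            raise ValueError("patch_size must be divisible by 2^depth")

        min_size = tuple(min(m, s) for m, s in zip(cfg.crop_min_size, vol.shape))
        crop = compute_crop(lab, min_size)
        cvol = apply_crop(vol, crop)
        clab = apply_crop(lab, crop)
        stats = compute_normalization(cvol, *cfg.normalize_percentiles)
        cvol = apply_normalization(cvol, stats)

        ss = np.random.SeedSequence(cfg.seed)
        init_seed, drop_seed, patch_seed = ss.spawn(3)
        model = build_model(spec, np.random.default_rng(init_seed))
        # dropout draws must not perturb the patch stream
        for layer in model.bottom:
            if hasattr(layer, "rate"):
                layer.rng = np.random.default_rng(drop_seed)
        rng = np.random.default_rng(patch_seed)
        opt = model.make_optimizer(cfg.learning_rate)
        cfg_hash = config_hash(cfg, spec)

        val = None
        if validation is not None:
            vvol, vlab = validation
            vvol = apply_normalization(apply_crop(vvol, crop), stats)
            val = (vvol, apply_crop(vlab, crop))

        self.checkpoints_ = []
        self.history_ = []
        n_batches = -(-cfg.patches_per_epoch // cfg.batch_size)
        for epoch in range(1, cfg.epochs + 1):
            epoch_loss = 0.0
            for _ in range(n_batches):
                batch = sample_patches(cvol, clab, cfg, rng)
                imgs, labs = [], []
                for img, lb in zip(batch.images, batch.labels):
                    img, lb = _augment(img, lb, cfg.augmentation, rng)
                    imgs.append(img)
                    labs.append(one_hot(lb))
                x = np.stack(imgs)[..., None]
                t = np.stack(labs)
                prob = model.forward(x, train=True)
                loss, dlog = focal_loss(prob, t, cfg.gamma, return_dlogits=True)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} (lr={cfg.learning_rate}); "
                        "training aborted")
                model.backward(dlog)
                opt.step()
                epoch_loss += loss
            rec = {"epoch": epoch, "train_loss": epoch_loss / n_batches}
            if epoch % cfg.checkpoint_interval == 0:
                self.checkpoints_.append(ModelCheckpoint(
                    epoch=epoch, weights=model.get_weights(), spec=spec,
                    crop=crop, norm_stats=stats, train_config_hash=cfg_hash))
                if val is not None:
                    rec.update(_validate(model, val, cfg.gamma))
            self.history_.append(rec)

        self.crop_ = crop
        self.norm_stats_ = stats
        self.spec_ = spec
        return self

    # -- inference ---------------------------------------------------------
    def predict(self, X: Volume3D, postprocess: bool = True) -> LabelMap:
        """Segment a test-fraction volume with the checkpoint ensemble."""
        from .inference import largest_component_filter, predict_volume, select_ensemble
        self._check_fitted()
        members = select_ensemble(self.checkpoints_, self.ensemble_size)
        pred = predict_volume(members, X)
        return largest_component_filter(pred.labels) if postprocess else pred.labels

    def predict_proba(self, X: Volume3D):
        from .inference import predict_volume, select_ensemble
        self._check_fitted()
        members = select_ensemble(self.checkpoints_, self.ensemble_size)
        return predict_volume(members, X)

    def _check_fitted(self) -> None:
        if not hasattr(self, "checkpoints_"):
            raise RuntimeError("estimator is not fitted; call fit() first")


def _augment(img, lab, aug_cfg, rng):
    from .preprocess import augment_patch
    return augment_patch(img, lab, aug_cfg, rng)


def _validate(model, val, gamma: float) -> dict:
    """Slice-wise loss + per-class Dice of one model on a validation pair."""
    vvol, vlab = val
    losses, inter, sizes = [], np.zeros(4), np.zeros(4)
    for k in range(vvol.shape[2]):
        prob = np.moveaxis(forward_slice(model, vvol.data[:, :, k]), 0, -1)
        truth = one_hot(vlab.data[:, :, k])
        losses.append(focal_loss(prob, truth, gamma))
        pred = prob.argmax(axis=-1)
        for c in range(4):
            inter[c] += 2 * np.sum((pred == c) & (vlab.data[:, :, k] == c))
            sizes[c] += np.sum(pred == c) + np.sum(vlab.data[:, :, k] == c)
    dice = np.where(sizes > 0, inter / np.maximum(sizes, 1), 1.0)
    return {"val_loss": float(np.mean(losses)),
            "val_dice": {c: float(dice[c]) for c in range(4)}}


def train_patient_model(series: PatientSeries, cfg: TrainConfig,
                        spec: UNetSpec,
                        validation: tuple[Volume3D, LabelMap] | None = None
                        ) -> list[ModelCheckpoint]:
    """Functional wrapper: train and return the ordered checkpoint list."""
    est = PatientSegmenter(
        depth=spec.depth, base_filters=spec.base_filters,
        dropout_rate=spec.bottom_dropout_rate, patch_size=cfg.patch_size,
        batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
        epochs=cfg.epochs, checkpoint_interval=cfg.checkpoint_interval,
        ensemble_size=cfg.ensemble_size, gamma=cfg.gamma,
        crop_min_size=cfg.crop_min_size, patches_per_epoch=cfg.patches_per_epoch,
        augmentation=cfg.augmentation,
        normalize_percentiles=cfg.normalize_percentiles, seed=cfg.seed)
    est.fit(series, validation=validation)
    return est.checkpoints_
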