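"""End-to-end orchestration: simulate -> train -> predict -> evaluate.

Every run leaves a self-describing tree under ``output_dir``::

    patient01/frac01_img.nii.gz, frac01_lab.nii.gz, ..., manifest.json
    patient01/model/ckpt_epoch0100/ ...
    patient01/pred/frac02_pred.nii.gz ...
    report.csv
    run.json          # config echo, seed, versions, per-stage wall time

Re-running with the same config and seed reproduces the report bit-for-bit
(the whole stack is seeded numpy; there is no other source of randomness).
"""

from __future__ import annotations

import json
import logging
import os
import re
import sys
import time

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .config import RunConfig, config_to_dict
from .estimator import PatientSegmenter
from .io import PatientSeries, load_series, read_labelmap, save_series, write_labelmap
from .metrics import MetricsReport, ToleranceSpec, evaluate_series
from .model import config_hash, load_bundle, save_bundle
from .phantom import generate_patient

log = logging.getLogger("fracseg")


def _setup_logging(output_dir: str) -> None:
    if log.handlers:
        return
    log.setLevel(logging.INFO)
    fmt = logging.Formatter("%(asctime)s [%(stage)s] %(message)s", "%H:%M:%S")
    for h in (logging.StreamHandler(sys.stderr),
              logging.FileHandler(os.path.join(output_dir, "run.log"))):
        h.setFormatter(fmt)
        log.addHandler(h)


def _log(stage: str, msg: str) -> None:
    log.info(msg, extra={"stage": stage})


def estimator_from_config(cfg: RunConfig) -> PatientSegmenter:
    t, m = cfg.train, cfg.model
    return PatientSegmenter(
        depth=m.depth, base_filters=m.base_filters, dropout_rate=t.dropout_rate,
        patch_size=t.patch_size, batch_size=t.batch_size,
        learning_rate=t.learning_rate, epochs=t.epochs,
        checkpoint_interval=t.checkpoint_interval, ensemble_size=t.ensemble_size,
        gamma=t.gamma, crop_min_size=t.crop_min_size,
        patches_per_epoch=t.patches_per_epoch, augmentation=t.augmentation,
        normalize_percentiles=t.normalize_percentiles, seed=t.seed)


def predict_fractions(checkpoints, series: PatientSeries, ensemble_size: int,
                      fractions: list[int] | None = None):
    """Segment the requested (1-based) fractions; default: all but training."""
    from .inference import largest_component_filter, predict_volume, select_ensemble
    members = select_ensemble(checkpoints, ensemble_size)
    if fractions is None:
        fractions = [i + 1 for i in series.test_indices()]
    preds = {}
    for frac in fractions:
        vol = series.fractions[frac - 1][0]
        pred = predict_volume(members, vol)
        preds[frac] = largest_component_filter(pred.labels)
    return preds


def load_predictions(pred_dir) -> dict[int, "LabelMap"]:
    """Read ``fracNN_pred.nii[.gz]`` label maps from a directory."""
    preds = {}
    for name in sorted(os.listdir(pred_dir)):
        m = re.match(r"frac(\d+)_pred\.nii(\.gz)?$", name)
        if m:
            preds[int(m.group(1))] = read_labelmap(os.path.join(pred_dir, name))
    if not preds:
        raise FileNotFoundError(f"no fracNN_pred.nii[.gz] files in {pred_dir}")
    return preds


def run_pipeline(cfg: RunConfig) -> MetricsReport:
    """Execute the enabled stages in order; returns the metrics report
    (empty when the evaluate stage is disabled)."""
    out = cfg.output_dir
    os.makedirs(out, exist_ok=True)
    _setup_logging(out)
    manifest = {"config": config_to_dict(cfg), "seed": cfg.seed,
                "config_hash": config_hash(config_to_dict(cfg)),
                "versions": {"python": sys.version.split()[0],
                             "numpy": np.__version__, "scipy": scipy.__version__,
                             "fracseg": __version__},
                "nondeterminism": [],  # pure seeded numpy: nothing to declare
                "stages": {}}
    pdir = os.path.join(out, "patient01")
    series = None
    report = MetricsReport(rows=pd.DataFrame(
        columns=["patient_id", "fraction", "structure", "method", "dice", "apl"]))

    def _stage(name, enabled, fn):
        nonlocal report
        if not enabled:
            _log(name, "skipped")
            return
        t0 = time.time()
        try:
            fn()
        except Exception:
            manifest["stages"][name] = {"status": "failed",
                                        "wall_s": round(time.time() - t0, 2)}
            _write_manifest(out, manifest)
            _log(name, "FAILED")
            raise
        manifest["stages"][name] = {"status": "ok",
                                    "wall_s": round(time.time() - t0, 2)}
        _log(name, f"done in {manifest['stages'][name]['wall_s']} s")

    def do_simulate():
        nonlocal series
        series = generate_patient(cfg.phantom, patient_id="patient01")
        save_series(series, pdir)

    def do_train():
        nonlocal series
        if series is None:
            series = load_series(os.path.join(pdir, "manifest.json"))
        est = estimator_from_config(cfg)
        est.fit(series)
        save_bundle(est.checkpoints_, os.path.join(pdir, "model"))

    def do_predict():
        nonlocal series
        if series is None:
            series = load_series(os.path.join(pdir, "manifest.json"))
        checkpoints = load_bundle(os.path.join(pdir, "model"))
        preds = predict_fractions(checkpoints, series, cfg.train.ensemble_size)
        os.makedirs(os.path.join(pdir, "pred"), exist_ok=True)
        for frac, lab in preds.items():
            write_labelmap(lab, os.path.join(pdir, "pred", f"frac{frac:02d}_pred.nii.gz"))

    def do_evaluate():
        nonlocal series, report
        if series is None:
            series = load_series(os.path.join(pdir, "manifest.json"))
        preds = load_predictions(os.path.join(pdir, "pred"))
        refs = {f: series.fractions[f - 1][1] for f in preds}
        if any(r is None for r in refs.values()):
            raise ValueError("evaluate: reference labels missing for some fractions")
        report = evaluate_series(preds, refs, method_name="ann", tol=cfg.eval,
                                 patient_id=series.patient_id)
        report.to_csv(os.path.join(out, "report.csv"))

    _stage("simulate", cfg.stages.simulate, do_simulate)
    _stage("train", cfg.stages.train, do_train)
    _stage("predict", cfg.stages.predict, do_predict)
    _stage("evaluate", cfg.stages.evaluate, do_evaluate)
    _write_manifest(out, manifest)
    return report


def _write_manifest(out, manifest) -> None:
    with open(os.path.join(out, "run.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
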