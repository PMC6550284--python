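"""End-to-end run: simulate (or load) -> extract -> classify/regress -> report.

A single YAML config drives the whole run; every random draw derives from the
master seed, so identical configs produce identical ``metrics.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import Cohort
from .features import FeatureMatrix, build_matrix
from .io import load_cohort, truncate_to_common_length, write_cohort
from .predict import (ModelConfig, classification_metrics, loocv_predict,
                      permutation_test, regression_metrics)
from .synth import SynthConfig, generate_cohort

log = logging.getLogger("actibiomark")


@dataclass
class RunConfig:
    """Exactly one input source: a synthetic cohort spec or a data directory."""

    synth: Optional[SynthConfig] = None
    input_dir: Optional[Path] = None
    scores: Optional[Path] = None
    model: ModelConfig = field(default_factory=ModelConfig)
    output_dir: Path = Path("actibiomark_run")
    log_level: str = "INFO"
    write_cohort_csvs: bool = True
    permutation_b: int = 0        # 0 disables the permutation test

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.input_dir is None):
            raise ValueError("specify exactly one of synth / input_dir")
        self.output_dir = Path(self.output_dir)
        if self.input_dir is not None:
            self.input_dir = Path(self.input_dir)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synth", None)
        model = raw.pop("model", None) or {}
        if synth is not None:
            for key in ("sleep_window", "madrs_pre_range"):
                if key in synth:
                    synth[key] = tuple(synth[key])
            synth = SynthConfig(**synth)
        return cls(synth=synth, model=ModelConfig(**model), **raw)


def _metrics_payload(matrix: FeatureMatrix, config: RunConfig) -> dict:
    model = config.model
    payload: dict = {"n_subjects": len(matrix),
                     "n_features": matrix.X.shape[1]}

    clf_cfg = dataclasses.replace(model, task="classify")
    labels_pred = loocv_predict(matrix, clf_cfg)
    cm, metrics = classification_metrics(labels_pred, matrix.labels)
    payload["classification"] = {
        "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn,
                      "positive_class": cm.positive_class},
        "accuracy": metrics.accuracy, "kappa": metrics.kappa,
        "sensitivity": metrics.sensitivity, "specificity": metrics.specificity,
        "nir": metrics.nir, "nir_pvalue": metrics.nir_pvalue,
        "predictions": {s: str(p) for s, p in zip(matrix.subjects, labels_pred)},
    }

    out = np.asarray(matrix.outcomes, dtype=float)
    has = np.isfinite(out)
    if has.sum() >= 3:
        reg_cfg = dataclasses.replace(model, task="regress")
        change_pred = loocv_predict(matrix, reg_cfg)
        reg = regression_metrics(change_pred, out[has])
        subj = [s for s, h in zip(matrix.subjects, has) if h]
        payload["regression"] = {
            "r": reg.r, "pvalue": reg.pvalue, "n": reg.n,
            "predictions": {s: float(p) for s, p in zip(subj, change_pred)},
            "predicted_z": [float(v) for v in reg.predicted_z],
            "observed_z": [float(v) for v in reg.observed_z],
        }

    if config.permutation_b > 0:
        perm = permutation_test(matrix, clf_cfg, "kappa",
                                b=config.permutation_b, seed=model.seed)
        payload["permutation"] = {
            "statistic": "kappa", "observed": perm.observed, "b": perm.b,
            "p_empirical": perm.p_empirical,
            "null_draws": [float(v) for v in perm.null_draws],
        }
    return payload


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the metrics payload it writes."""
    out_dir = config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level.upper())
    try:
        log.info("actibiomark %s on python %s", __version__, platform.python_version())
        log.info("config: %s", config)

        stage = "simulate/load"
        try:
            if config.synth is not None:
                cohort = generate_cohort(config.synth)
                if config.write_cohort_csvs:
                    write_cohort(cohort, out_dir / "cohort")
            else:
                cohort = load_cohort(config.input_dir, config.scores)
            cohort = truncate_to_common_length(cohort)
            log.info("cohort: %d subjects, common length %d minutes",
                     len(cohort), cohort.common_length)

            stage = "extract"
            matrix = build_matrix(cohort)
            matrix.to_frame().to_csv(out_dir / "features.tsv", sep="\t", index=False)
            log.info("features: %d x %d", len(matrix), matrix.X.shape[1])

            stage = "predict"
            payload = _metrics_payload(matrix, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

        (out_dir / "metrics.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
        log.info("metrics written to %s", out_dir / "metrics.json")
        return payload
    finally:
        log.removeHandler(handler)
        handler.close()
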