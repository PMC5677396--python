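"""End-to-end experiments: soil-type classification and TN calibration.

Two experiments run over one cohort (real or synthetic):

1. Classification.  Stratified 2:1 split -> SNV + calibration-fitted
   z-score -> SPA with the 1/2/3 category code as reference -> GLCM texture
   features at the selected effective wavelengths -> four RBF-SVM models,
   one per input-variable set (full spectrum, effective wavelengths,
   texture, fused spectral+texture), each reported with confusion matrices
   and accuracies on both sets.

2. TN prediction.  For the *general* scope one pooled unstratified 2:1
   split; for the *local* scope an independent 2:1 split within each soil
   type.  Per scope: SNV + z-score, SPA with TN as reference, then PLSR on
   the full spectrum and on the effective wavelengths, evaluated by
   RMSEP / R^2 / RPD on the held-out set.

Nothing fitted on held-out samples leaks into selection or preprocessing:
SPA, z-score statistics, the SVM grid search and the PLSR latent-dimension
choice all see the calibration set only.

One master seed fans out to stage-specific seeds (synthesis, splits, SVM
CV folds) so stages are independently reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modeling import (
    SVMConfig,
    fit_plsr,
    fit_svm,
    fuse_features,
    regression_metrics,
    stratified_split,
)
from .spa import SPAConfig, select_effective_wavelengths
from .spectra import SpectraMatrix, mean_roi_spectrum, snv, trim_bands, zscore_fit_apply
from .synthetic_data import SoilType, SyntheticConfig, SyntheticDataset, generate_dataset
from .texture import GLCMConfig, texture_features

__all__ = [
    "ExperimentConfig",
    "build_spectra_matrix",
    "run_classification_experiment",
    "run_tn_experiment",
    "run_experiment",
    "report_render",
    "report_to_json",
]

logger = logging.getLogger("soilhsi")

INPUT_SETS = ("full_spectrum", "effective_wavelengths", "texture", "fused")


def configure_logging(level: int = logging.INFO, logfile: str | None = None) -> None:
    """Stderr (and optional file) logging with stage timings."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything the two experiments need, with study-design defaults."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0
    trim_nm: tuple[float, float] = (975.0, 1645.0)
    spa: SPAConfig = field(default_factory=SPAConfig)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    plsr_max_components: int = 20
    split_ratio: float = 2.0 / 3.0


def stage_seeds(master: int, n: int) -> list[int]:
    """Fan one master seed out to n independent stage seeds (< 2^31)."""
    ss = np.random.SeedSequence(master)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def build_spectra_matrix(dataset: SyntheticDataset, trim_nm=(975.0, 1645.0)) -> SpectraMatrix:
    """Mean ROI spectrum per sample, trimmed to the working window."""
    X = np.array([mean_roi_spectrum(dataset.roi_stack(i)) for i in range(len(dataset.sample_ids))])
    matrix = SpectraMatrix(
        X=X,
        wavelengths=dataset.wavelengths,
        sample_ids=dataset.sample_ids,
        labels=dataset.labels,
        tn=dataset.tn,
    )
    return trim_bands(matrix, *trim_nm)


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage %s: done in %.2fs", stage, dt)
            else:
                logger.error("stage %s: failed after %.2fs", stage, dt)
            return False

    return _Timer()


class StageError(RuntimeError):
    """Raised when an experiment stage fails; names the stage."""


def _run_stage(stage: str, fn, *args, **kwargs):
    with _timed(stage):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc


def run_classification_experiment(
    dataset: SyntheticDataset, config: ExperimentConfig
) -> dict:
    """Soil-type classification over the four input-variable sets."""
    seed_split, seed_svm = stage_seeds(config.seed, 2)

    sm = _run_stage("spectra", build_spectra_matrix, dataset, config.trim_nm)
    split = _run_stage(
        "split", stratified_split, sm.labels, ratio=config.split_ratio, seed=seed_split
    )
    cal, pred = split.calibration_idx, split.prediction_idx

    def _preprocess():
        Xs = snv(sm.X, sm.sample_ids)
        Z_cal, Z_pred, state = zscore_fit_apply(Xs[cal], Xs[pred], sm.wavelengths)
        Z = np.empty_like(Xs)
        Z[cal] = Z_cal
        Z[pred] = Z_pred
        return Z

    Z = _run_stage("preprocess", _preprocess)

    spa_res = _run_stage(
        "spa",
        select_effective_wavelengths,
        Z[cal],
        sm.labels[cal].astype(float),
        config.spa,
        sm.wavelengths,
    )
    ew_idx = spa_res.selected_indices
    ews = spa_res.selected_wavelengths_nm

    def _texture_table():
        rows = [
            texture_features(dataset.roi_stack(i), dataset.wavelengths, ews, config.glcm)
            for i in range(len(sm.sample_ids))
        ]
        return pd.DataFrame(rows, index=sm.sample_ids)

    T = _run_stage("texture", _texture_table)

    ids = np.array(sm.sample_ids)
    spectral_ew = pd.DataFrame(
        Z[:, ew_idx], index=ids, columns=[f"wl_{w:.1f}" for w in ews]
    )
    fused = fuse_features(spectral_ew, T)

    blocks = {
        "full_spectrum": Z,
        "effective_wavelengths": Z[:, ew_idx],
        "texture": T.to_numpy(),
        "fused": fused.to_numpy(),
    }

    svm_cfg = SVMConfig(
        log2c=config.svm.log2c,
        log2g=config.svm.log2g,
        cv_folds=config.svm.cv_folds,
        standardize=config.svm.standardize,
        seed=seed_svm,
    )
    models = {}
    for name, X in blocks.items():
        _, rep_cal, rep_pred = _run_stage(
            f"svm:{name}",
            fit_svm,
            X[cal],
            sm.labels[cal],
            X[pred],
            sm.labels[pred],
            svm_cfg,
        )
        models[name] = {
            "n_variables": int(X.shape[1]),
            "c": rep_cal.c,
            "g": rep_cal.g,
            "calibration": rep_cal.to_dict(),
            "prediction": rep_pred.to_dict(),
        }

    return {
        "seed": config.seed,
        "split": {
            "calibration_ids": [sm.sample_ids[i] for i in cal],
            "prediction_ids": [sm.sample_ids[i] for i in pred],
        },
        "effective_wavelengths": spa_res.to_dict(),
        "models": models,
    }


def _tn_models_for_pool(
    X: np.ndarray,
    wavelengths: np.ndarray,
    tn: np.ndarray,
    seed: int,
    config: ExperimentConfig,
) -> dict:
    """Split, select and calibrate TN models for one sample pool."""
    if len(tn) < 6:
        raise ValueError(f"pool of {len(tn)} samples is too small for a 2:1 TN calibration")
    split = stratified_split(None, n_samples=len(tn), ratio=config.split_ratio, seed=seed)
    cal, pred = split.calibration_idx, split.prediction_idx

    Xs = snv(X)
    Z_cal, Z_pred, _ = zscore_fit_apply(Xs[cal], Xs[pred], wavelengths)

    spa_res = select_effective_wavelengths(Z_cal, tn[cal], config.spa, wavelengths)
    ew_idx = spa_res.selected_indices

    out = {
        "n_calibration": int(len(cal)),
        "n_prediction": int(len(pred)),
        "effective_wavelengths": spa_res.to_dict(),
        "models": {},
    }
    for name, cols in (
        ("full_spectrum", slice(None)),
        ("effective_wavelengths", ew_idx),
    ):
        plsr = fit_plsr(Z_cal[:, cols], tn[cal], config.plsr_max_components)
        metrics = regression_metrics(tn[pred], plsr.predict(Z_pred[:, cols]))
        out["models"][name] = {
            "n_variables": int(Z_cal[:, cols].shape[1]),
            "n_components": plsr.n_components,
            **metrics.to_dict(),
        }
    return out


def run_tn_experiment(dataset: SyntheticDataset, config: ExperimentConfig) -> dict:
    """Local (per-soil-type) vs general (pooled) TN calibration."""
    seeds = stage_seeds(config.seed + 1, 1 + len(SoilType))
    sm = _run_stage("spectra", build_spectra_matrix, dataset, config.trim_nm)

    report: dict = {"seed": config.seed, "scopes": {"local": {}, "general": None}}
    for soil, seed in zip(SoilType, seeds[1:]):
        idx = np.flatnonzero(sm.labels == int(soil))
        report["scopes"]["local"][soil.name] = _run_stage(
            f"tn:local:{soil.name}",
            _tn_models_for_pool,
            sm.X[idx],
            sm.wavelengths,
            sm.tn[idx],
            seed,
            config,
        )
    report["scopes"]["general"] = _run_stage(
        "tn:general", _tn_models_for_pool, sm.X, sm.wavelengths, sm.tn, seeds[0], config
    )

    # headline comparison: mean local RMSEP vs general RMSEP per input set
    summary = {}
    for name in ("full_spectrum", "effective_wavelengths"):
        local_rmseps = [
            report["scopes"]["local"][s.name]["models"][name]["rmsep"] for s in SoilType
        ]
        summary[name] = {
            "local_mean_rmsep": float(np.mean(local_rmseps)),
            "general_rmsep": report["scopes"]["general"]["models"][name]["rmsep"],
        }
    report["summary"] = summary
    return report


def run_experiment(config: ExperimentConfig) -> dict:
    """Synthesize a cohort and run both experiments."""
    (seed_synth,) = stage_seeds(config.seed + 2, 1)
    dataset = _run_stage("synthesize", generate_dataset, config.synthetic, seed_synth)
    return {
        "provenance": {"seed": config.seed, "synthesis_seed": seed_synth},
        "classification": run_classification_experiment(dataset, config),
        "tn": run_tn_experiment(dataset, config),
    }


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def report_to_json(report: dict, indent: int = 2) -> str:
    """Deterministic, lossless JSON rendering of a report."""
    return json.dumps(_jsonify(report), indent=indent, sort_keys=True)


def _fmt_pct(x: float) -> str:
    return f"{100 * x:.1f}%"


def report_render(report: dict) -> str:
    """Human-readable tables for a (possibly partial) experiment report."""
    lines: list[str] = []
    cls = report.get("classification") or (
        report if "models" in report and "scopes" not in report else None
    )
    if cls and "models" in cls:
        lines.append("Soil-type classification (SVM, RBF kernel)")
        lines.append(f"{'input set':<26}{'vars':>6}{'(c, g)':>22}{'cal acc':>10}{'pred acc':>10}")
        for name in INPUT_SETS:
            if name not in cls["models"]:
                continue
            m = cls["models"][name]
            cg = "({:.4g}, {:.4g})".format(m["c"], m["g"])
            lines.append(
                f"{name:<26}{m['n_variables']:>6}"
                f"{cg:>22}"
                f"{_fmt_pct(m['calibration']['overall_accuracy']):>10}"
                f"{_fmt_pct(m['prediction']['overall_accuracy']):>10}"
            )
        ews = cls.get("effective_wavelengths", {}).get("selected_wavelengths_nm")
        if ews:
            lines.append(
                "effective wavelengths (nm): " + ", ".join(f"{w:.1f}" for w in ews)
            )
        lines.append("")

    tn = report.get("tn") or (report if "scopes" in report else None)
    if tn and "scopes" in tn:
        lines.append("Soil TN prediction (PLSR)")
        lines.append(
            f"{'scope':<24}{'input set':<24}{'NV':>5}{'LV':>4}{'RMSEP':>9}{'R2':>7}{'RPD':>6}"
        )
        rows = [(name, block) for name, block in tn["scopes"]["local"].items()]
        rows.append(("general", tn["scopes"]["general"]))
        for scope_name, block in rows:
            for name in ("full_spectrum", "effective_wavelengths"):
                m = block["models"][name]
                lines.append(
                    f"{scope_name:<24}{name:<24}{m['n_variables']:>5}{m['n_components']:>4}"
                    f"{m['rmsep']:>9.4f}{m['r2']:>7.2f}{m['rpd']:>6.1f}"
                )
        s = tn.get("summary", {})
        for name, vals in s.items():
            lines.append(
                f"summary[{name}]: mean local RMSEP {vals['local_mean_rmsep']:.4f} "
                f"vs general RMSEP {vals['general_rmsep']:.4f}"
            )
        lines.append("")
    if not lines:
        lines.append("(empty report)")
    return "\n".join(lines)
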