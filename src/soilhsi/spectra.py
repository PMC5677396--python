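"""Spectral matrix construction and preprocessing.

Each sample contributes one mean spectrum, the per-band average over all ROI
pixels.  The noisy detector edges are trimmed to the 975-1645 nm window
(closed interval) and two chemometric transforms are applied in order:

1. SNV (standard normal variate): per spectrum, subtract the row mean and
   divide by the row standard deviation.  Removes additive baseline offsets
   and multiplicative scatter.
2. z-score: per band, centre and scale by column statistics estimated on the
   calibration subset only, then applied unchanged to the prediction subset
   (no information leaks from held-out samples into the scaling).

Sample standard deviations (n-1 denominator) are used throughout, the
chemometrics convention; flip ``ddof`` if the population form is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpectraMatrix",
    "PreprocessState",
    "mean_roi_spectrum",
    "trim_bands",
    "snv",
    "zscore_fit",
    "zscore_apply",
    "zscore_fit_apply",
]

DDOF = 1  # sample SD convention for both SNV and z-score


@dataclass
class SpectraMatrix:
    """n_samples x n_bands spectra with ids, soil-type labels and TN."""

    X: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray | None = None  # integer category codes 1/2/3
    tn: np.ndarray | None = None      # % dry mass

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x bands)")
        if self.X.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match sample id count")
        if self.X.shape[1] != len(self.wavelengths):
            raise ValueError("column count does not match wavelength count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "SpectraMatrix":
        """Row subset (e.g. a calibration or prediction split)."""
        idx = np.asarray(idx)
        return SpectraMatrix(
            X=self.X[idx],
            wavelengths=self.wavelengths,
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=None if self.labels is None else np.asarray(self.labels)[idx],
            tn=None if self.tn is None else np.asarray(self.tn)[idx],
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=[f"wl_{w:06.1f}" for w in self.wavelengths])
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "soil_type", self.labels if self.labels is not None else np.nan)
        df.insert(2, "tn_percent", self.tn if self.tn is not None else np.nan)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraMatrix":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if c.startswith("wl_")]
        wavelengths = np.array([float(c[3:]) for c in wl_cols])
        labels = df["soil_type"].to_numpy()
        tn = df["tn_percent"].to_numpy()
        return cls(
            X=df[wl_cols].to_numpy(dtype=float),
            wavelengths=wavelengths,
            sample_ids=df["sample_id"].astype(str).tolist(),
            labels=None if np.all(pd.isna(labels)) else labels.astype(int),
            tn=None if np.all(pd.isna(tn)) else tn.astype(float),
        )


@dataclass(frozen=True)
class PreprocessState:
    """Column means/SDs estimated on the calibration subset (z-score)."""

    mean: np.ndarray
    sd: np.ndarray


def mean_roi_spectrum(stack: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean over all pixels of a ROI stack.

    ``stack`` is height x width x bands; the result has one value per band.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] * stack.shape[1] == 0:
        raise ValueError("ROI stack must be a non-empty height x width x bands array")
    return stack.mean(axis=(0, 1))


def trim_bands(matrix: SpectraMatrix, lo_nm: float, hi_nm: float) -> SpectraMatrix:
    """Keep bands with lo <= wavelength <= hi (closed interval)."""
    if not lo_nm < hi_nm:
        raise ValueError(f"need lo < hi, got {lo_nm} >= {hi_nm}")
    keep = (matrix.wavelengths >= lo_nm) & (matrix.wavelengths <= hi_nm)
    if not np.any(keep):
        raise ValueError(f"no bands in [{lo_nm}, {hi_nm}] nm")
    return replace(matrix, X=matrix.X[:, keep], wavelengths=matrix.wavelengths[keep])


def snv(X: np.ndarray, sample_ids: list[str] | None = None) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum (row).

    A constant row has no scatter to normalise and raises, naming the sample.
    """
    X = np.asarray(X, dtype=float)
    one_d = X.ndim == 1
    if one_d:
        X = X[None, :]
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=DDOF, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        ident = sample_ids[bad[0]] if sample_ids is not None else f"row {bad[0]}"
        raise ValueError(f"constant spectrum (zero SD) for sample {ident}; SNV undefined")
    out = (X - mean) / sd
    return out[0] if one_d else out


def snv_matrix(matrix: SpectraMatrix) -> SpectraMatrix:
    return replace(matrix, X=snv(matrix.X, matrix.sample_ids))


def zscore_fit(X_cal: np.ndarray, wavelengths: np.ndarray | None = None) -> PreprocessState:
    """Estimate per-band mean/SD on the calibration matrix."""
    X_cal = np.asarray(X_cal, dtype=float)
    mean = X_cal.mean(axis=0)
    sd = X_cal.std(axis=0, ddof=DDOF)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        band = f"{wavelengths[bad[0]]:.1f} nm" if wavelengths is not None else f"index {bad[0]}"
        raise ValueError(f"zero-variance band at {band}; z-score undefined")
    return PreprocessState(mean=mean, sd=sd)


def zscore_apply(X: np.ndarray, state: PreprocessState) -> np.ndarray:
    return (np.asarray(X, dtype=float) - state.mean) / state.sd


def zscore_fit_apply(
    X_cal: np.ndarray,
    X_other: np.ndarray | None = None,
    wavelengths: np.ndarray | None = None,
):
    """Fit z-score statistics on calibration data and apply to both sets.

    Returns ``(Z_cal, Z_other, state)``; ``Z_other`` is None when no second
    matrix is given.
    """
    state = zscore_fit(X_cal, wavelengths)
    Z_cal = zscore_apply(X_cal, state)
    Z_other = None if X_other is None else zscore_apply(X_other, state)
    return Z_cal, Z_other, state
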