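"""Splitting, classification (SVM, PCA+LDA), PLSR regression and metrics.

Model evaluation follows standard chemometric practice: the cohort is split
2:1 into calibration and prediction sets (stratified by soil type where
classes are present), models are fitted on the calibration set only and
judged on the held-out prediction set by

* classification: 3x3 confusion matrix, per-class and overall accuracy;
* regression: RMSEP (root mean squared error of prediction), R^2
  (1 - SSres/SStot on the prediction set), and RPD, the prediction-set
  reference SD divided by RMSEP (RPD > 2 is conventionally usable).

The SVM uses an RBF kernel with (C, gamma) chosen by grid search over
log2 C in [-5, 15] and log2 gamma in [-15, 5] (step 2) with 5-fold
cross-validated accuracy on the calibration set.  PLSR picks its latent
dimension by leave-one-out RMSECV up to a ceiling of 20 components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .spectra import PreprocessState, zscore_apply, zscore_fit

__all__ = [
    "SplitSpec",
    "SVMConfig",
    "ClassificationReport",
    "PLSRModel",
    "RegressionMetrics",
    "stratified_split",
    "fit_svm",
    "fuse_features",
    "pca_lda_explore",
    "fit_plsr",
    "regression_metrics",
]


@dataclass(frozen=True)
class SplitSpec:
    """Calibration/prediction partition of sample indices."""

    calibration_idx: np.ndarray
    prediction_idx: np.ndarray
    ratio: float
    seed: int
    stratified: bool

    def __post_init__(self) -> None:
        cal = set(self.calibration_idx.tolist())
        pred = set(self.prediction_idx.tolist())
        if cal & pred:
            raise ValueError("calibration and prediction sets overlap")


def stratified_split(
    labels: np.ndarray | None,
    n_samples: int | None = None,
    ratio: float = 2.0 / 3.0,
    seed: int = 0,
) -> SplitSpec:
    """Random 2:1 split, stratified per class when labels are given.

    Per class, floor(ratio * n) samples go to calibration: for the
    (84, 57, 42) cohort this yields 56/38/28 calibration and 28/19/14
    prediction samples; an unstratified pool of 183 gives 122/61.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be a fraction in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    if labels is None:
        if n_samples is None:
            raise ValueError("need labels or n_samples")
        groups = [np.arange(n_samples)]
        stratified = False
    else:
        labels = np.asarray(labels)
        groups = [np.flatnonzero(labels == c) for c in np.unique(labels)]
        stratified = True

    cal_parts, pred_parts = [], []
    for idx in groups:
        n = len(idx)
        if n < 3:
            raise ValueError(f"class with {n} samples cannot be split 2:1")
        n_cal = int(np.floor(ratio * n))
        perm = rng.permutation(idx)
        cal_parts.append(np.sort(perm[:n_cal]))
        pred_parts.append(np.sort(perm[n_cal:]))

    return SplitSpec(
        calibration_idx=np.sort(np.concatenate(cal_parts)),
        prediction_idx=np.sort(np.concatenate(pred_parts)),
        ratio=ratio,
        seed=seed,
        stratified=stratified,
    )


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM grid-search settings.

    c is the penalty coefficient, g the RBF kernel width parameter.
    """

    log2c: tuple[float, float, float] = (-5, 15, 2)   # start, stop (incl.), step
    log2g: tuple[float, float, float] = (-15, 5, 2)
    cv_folds: int = 5
    standardize: bool = True
    seed: int = 0

    def c_grid(self) -> np.ndarray:
        a, b, s = self.log2c
        return 2.0 ** np.arange(a, b + 1e-9, s)

    def g_grid(self) -> np.ndarray:
        a, b, s = self.log2g
        return 2.0 ** np.arange(a, b + 1e-9, s)


@dataclass
class ClassificationReport:
    """Confusion matrix (rows = true class code order) plus accuracies."""

    confusion: np.ndarray
    classes: np.ndarray
    c: float
    g: float

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)

    @property
    def per_class_accuracy(self) -> np.ndarray:
        totals = self.confusion.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, np.diag(self.confusion) / totals, np.nan)

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "classes": [int(c) for c in self.classes],
            "per_class_accuracy": [float(a) for a in self.per_class_accuracy],
            "overall_accuracy": self.overall_accuracy,
            "c": float(self.c),
            "g": float(self.g),
        }


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    M = np.zeros((len(classes), len(classes)), dtype=int)
    pos = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        M[pos[t], pos[p]] += 1
    return M


def fit_svm(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray | None = None,
    y_pred: np.ndarray | None = None,
    config: SVMConfig = SVMConfig(),
):
    """Grid-searched RBF-SVM with calibration/prediction reports.

    Features are z-scored with calibration statistics first (so spectral and
    texture blocks are commensurate after fusion); disable via the config.
    Returns ``(model, report_cal, report_pred)``; the prediction report is
    None when no held-out set is passed.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal).astype(int)
    classes = np.unique(y_cal)
    if len(classes) < 2:
        raise ValueError("calibration set holds a single class; SVM needs at least two")

    state: PreprocessState | None = None
    if config.standardize:
        state = zscore_fit(X_cal)
        X_cal = zscore_apply(X_cal, state)

    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    search = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": config.c_grid(), "gamma": config.g_grid()},
        scoring="accuracy",
        cv=cv,
        n_jobs=1,
    )
    search.fit(X_cal, y_cal)
    model = search.best_estimator_
    c, g = float(model.C), float(model.gamma)

    report_cal = ClassificationReport(
        confusion=_confusion(y_cal, model.predict(X_cal), classes), classes=classes, c=c, g=g
    )
    report_pred = None
    if X_pred is not None:
        X_pred = np.asarray(X_pred, dtype=float)
        if state is not None:
            X_pred = zscore_apply(X_pred, state)
        y_hat = model.predict(X_pred)
        if y_pred is not None:
            report_pred = ClassificationReport(
                confusion=_confusion(np.asarray(y_pred).astype(int), y_hat, classes),
                classes=classes,
                c=c,
                g=g,
            )
    return model, report_cal, report_pred


def fuse_features(spectral: pd.DataFrame, texture: pd.DataFrame) -> pd.DataFrame:
    """Column-wise concatenation of spectral and texture blocks.

    Both frames must be indexed by sample id in identical order; provenance
    is preserved in the column names.
    """
    if texture.shape[1] == 0:
        return spectral.copy()
    if list(spectral.index) != list(texture.index):
        raise ValueError("sample ids of spectral and texture blocks do not match")
    return pd.concat([spectral, texture], axis=1)


def pca_lda_explore(X: np.ndarray, labels: np.ndarray, n_pcs: int = 4):
    """Exploratory PCA then Fisher LDA on the first principal components.

    Returns ``(discriminant_scores, accuracy, explained_variance_ratio)``
    where scores are the first two discriminant coordinates and accuracy is
    the resubstitution correct-classification fraction.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if n_pcs >= X.shape[0]:
        raise ValueError("n_pcs must be smaller than the sample count")
    pca = PCA(n_components=n_pcs)
    scores = pca.fit_transform(X)
    lda = LinearDiscriminantAnalysis()
    lda.fit(scores, labels)
    disc = lda.transform(scores)[:, : min(2, len(np.unique(labels)) - 1)]
    accuracy = float(np.mean(lda.predict(scores) == labels))
    return disc, accuracy, pca.explained_variance_ratio_


@dataclass
class PLSRModel:
    """Fitted PLSR with LOOCV-chosen latent dimension.

    ``coef``/``intercept`` act on the training preprocessing scale:
    prediction is ``X @ coef + intercept``.
    """

    coef: np.ndarray
    intercept: float
    n_components: int
    rmsecv_curve: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


def _pls_truncated_coefs(X: np.ndarray, y: np.ndarray, max_k: int):
    """Fit one PLS with max_k components; return per-k coefficient vectors.

    PLS components are extracted sequentially, so truncating the rotation
    and loading matrices of a single fit reproduces the smaller models.
    """
    pls = PLSRegression(n_components=max_k, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(X, y)
    rot = pls.x_rotations_          # p x K
    q = pls.y_loadings_             # 1 x K
    # scale=False: the only preprocessing PLS applies is mean centring
    x_mean = X.mean(axis=0)
    y_mean = float(np.mean(y))
    coefs = []
    for k in range(1, max_k + 1):
        B = rot[:, :k] @ q[:, :k].T  # p x 1
        coefs.append((B.ravel(), y_mean - float(x_mean @ B.ravel())))
    return coefs


def fit_plsr(X: np.ndarray, y: np.ndarray, max_components: int = 20) -> PLSRModel:
    """PLSR with the latent dimension chosen by leave-one-out RMSECV.

    The ceiling is clipped (with a warning) to the data rank bound
    min(n-2, p).  The final model is refitted on all calibration samples at
    the chosen dimension.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= 2:
        raise ValueError("need more than 2 calibration samples")
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    cap = max(min(n - 2, p, rank), 1)
    if max_components > cap:
        warnings.warn(f"max_components clipped from {max_components} to rank bound {cap}")
        max_components = cap
    max_components = max(max_components, 1)

    press = np.zeros(max_components)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        coefs = _pls_truncated_coefs(X[mask], y[mask], max_components)
        for k, (B, b0) in enumerate(coefs):
            err = y[i] - (X[i] @ B + b0)
            press[k] += err * err
    rmsecv = np.sqrt(press / n)
    best_k = int(np.argmin(rmsecv)) + 1

    B, b0 = _pls_truncated_coefs(X, y, max_components)[best_k - 1]
    return PLSRModel(coef=B, intercept=b0, n_components=best_k, rmsecv_curve=rmsecv)


@dataclass(frozen=True)
class RegressionMetrics:
    """Prediction-set metrics: RMSEP (% TN), R^2, RPD."""

    rmsep: float
    r2: float
    rpd: float

    def to_dict(self) -> dict:
        return {"rmsep": self.rmsep, "r2": self.r2, "rpd": self.rpd}


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> RegressionMetrics:
    """RMSEP, R^2 = 1 - SSres/SStot and RPD = SD(y_true, n-1)/RMSEP.

    Perfect prediction gives RMSEP 0 and RPD +inf; a constant reference
    vector leaves R^2/RPD undefined and raises.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_true) != len(y_pred) or len(y_true) < 2:
        raise ValueError("need equal-length vectors with at least 2 samples")
    sd = float(np.std(y_true, ddof=1))
    if sd == 0:
        raise ValueError("constant reference values: R^2 and RPD are undefined")
    rmsep = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rpd = float(np.inf) if rmsep == 0 else sd / rmsep
    return RegressionMetrics(rmsep=rmsep, r2=r2, rpd=rpd)
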