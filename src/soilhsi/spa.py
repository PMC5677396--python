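"""Successive projections algorithm (SPA) for effective-wavelength selection.

SPA is a greedy forward selector built to minimise collinearity among the
chosen spectral variables.  It runs in two phases:

Phase 1 (projections).  Starting from a candidate band, repeatedly project
every unselected column onto the orthogonal complement of the span of the
already-selected columns and append the column with the largest projected
norm.  One such run is a *chain*; chains are grown from every candidate
start band.

Phase 2 (scoring).  Each chain prefix of size m defines a candidate subset.
Subsets are scored by the RMSECV of a multiple linear regression fitted with
leave-one-out cross-validation on the calibration set; for each size m the
best subset over all chains is kept, giving an RMSECV-vs-size curve.

The final size is the smallest m whose RMSECV is not significantly larger
than the curve minimum under an F-test at significance level alpha
(default 0.25): accept m when RMSECV(m)^2 <= F_crit(alpha; n, n) *
RMSECV_min^2, with n the number of calibration samples.  Relaxing alpha
(larger critical value) can only shrink the accepted size.

Selection must run on preprocessed calibration data only; held-out samples
never influence the choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SPAConfig",
    "SPAResult",
    "spa_chain",
    "mlr_loocv_rmsecv",
    "select_effective_wavelengths",
]

# Projected norms at or below this fraction of the largest initial column
# norm are treated as numerically zero (exhausted column space).
_NORM_TOL = 1e-10


@dataclass(frozen=True)
class SPAConfig:
    """Knobs for SPA selection.

    max_vars defaults to min(30, n_cal // 2): selections in this problem
    class run 7-18 variables, comfortably inside, and LOOCV-scored subsets
    approaching n_cal variables are degenerate (few residual degrees of
    freedom), which lets the minimum-over-starts curve collapse at the
    largest sizes and breaks the F-criterion.  An explicit max_vars is
    honoured up to the hard bound min(n_cal - 2, n_bands).  alpha is the
    F-test significance level for sizing the subset.  starts restricts the
    chain start bands (default: every band).
    """

    max_vars: int | None = None
    alpha: float = 0.25
    starts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.max_vars is not None and self.max_vars < 1:
            raise ValueError("max_vars must be >= 1")

    def resolve_max_vars(self, n_cal: int, n_bands: int) -> int:
        cap = min(n_cal - 2, n_bands)
        m = min(30, max(n_cal // 2, 1), cap) if self.max_vars is None else min(self.max_vars, cap)
        if m < 1:
            raise ValueError(f"too few calibration samples (n={n_cal}) for SPA")
        return m


@dataclass
class SPAResult:
    """Outcome of one SPA run."""

    rmsecv_curve: np.ndarray          # RMSECV per size, index 0 -> size 1
    best_size: int
    selected_indices: np.ndarray
    selected_wavelengths_nm: np.ndarray | None
    rmsecv_min: float
    subsets_per_size: list[np.ndarray] = field(default_factory=list)

    @property
    def rmsecv_best(self) -> float:
        return float(self.rmsecv_curve[self.best_size - 1])

    def to_dict(self) -> dict:
        return {
            "best_size": int(self.best_size),
            "selected_indices": [int(i) for i in self.selected_indices],
            "selected_wavelengths_nm": (
                None
                if self.selected_wavelengths_nm is None
                else [float(w) for w in self.selected_wavelengths_nm]
            ),
            "rmsecv_curve": [float(v) for v in self.rmsecv_curve],
            "rmsecv_min": float(self.rmsecv_min),
        }


def spa_chain(X: np.ndarray, start: int, k: int) -> np.ndarray:
    """One projection chain of up to ``k`` band indices starting at ``start``.

    Deflation form: after appending a column, every remaining column is
    replaced by its residual orthogonal to it, so projected norms accumulate
    the full orthogonal-complement projection.  Ties in the maximal norm
    break to the lowest band index; the chain stops early (with a warning)
    once the residual space is numerically exhausted.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 0 <= start < p:
        raise IndexError(f"start index {start} out of range for {p} bands")
    if k < 1:
        raise ValueError("chain length must be >= 1")

    work = X.copy()
    scale = float(np.max(np.einsum("ij,ij->j", work, work)))
    tol = _NORM_TOL * max(scale, 1.0)

    chain = [start]
    available = np.ones(p, dtype=bool)
    available[start] = False
    v = work[:, start].copy()

    while len(chain) < k:
        vv = float(v @ v)
        if vv <= tol:
            warnings.warn("SPA chain stopped early: selected column numerically null")
            break
        work -= np.outer(v, (v @ work) / vv)
        norms = np.einsum("ij,ij->j", work, work)
        norms[~available] = -np.inf
        j = int(np.argmax(norms))  # argmax takes the first (lowest) index on ties
        if norms[j] <= tol:
            warnings.warn(
                f"SPA chain stopped early at length {len(chain)}: residual space exhausted"
            )
            break
        chain.append(j)
        available[j] = False
        v = work[:, j].copy()
    return np.array(chain, dtype=int)


def mlr_loocv_rmsecv(X_subset: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out RMSECV of an intercept MLR on the given columns.

    Uses the exact hat-matrix identity for OLS leave-one-out residuals,
    e_i / (1 - h_ii), equivalent to refitting n separate models.
    """
    X_subset = np.atleast_2d(np.asarray(X_subset, dtype=float))
    if X_subset.shape[0] == 1:
        X_subset = X_subset.T
    y = np.asarray(y, dtype=float)
    n, m = X_subset.shape
    if len(y) != n:
        raise ValueError("X and y sample counts differ")
    if n <= m + 1:
        raise ValueError(f"need n > m + 1 samples for LOOCV, got n={n}, m={m}")

    A = np.column_stack([np.ones(n), X_subset])
    q, r = np.linalg.qr(A)
    diag = np.abs(np.diag(r))
    if np.any(diag <= 1e-10 * diag.max()):
        raise np.linalg.LinAlgError("rank-deficient variable subset in MLR")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - A @ beta
    h = np.einsum("ij,ij->i", q, q)
    h = np.minimum(h, 1 - 1e-12)  # guard exact-leverage pathologies
    loo = resid / (1.0 - h)
    return float(np.sqrt(np.mean(loo**2)))


def _f_critical(alpha: float, n_cal: int) -> float:
    """Critical value of the F-test used to size the subset.

    Degrees of freedom (n_cal, n_cal): each RMSECV in the ratio is built
    from n_cal cross-validation residuals.  Isolated here so the convention
    can be changed in one place.
    """
    return float(stats.f.ppf(1.0 - alpha, n_cal, n_cal))


def select_effective_wavelengths(
    X: np.ndarray,
    y: np.ndarray,
    config: SPAConfig = SPAConfig(),
    wavelengths: np.ndarray | None = None,
) -> SPAResult:
    """Full SPA selection: chains from every start, RMSECV curve, F-test size.

    ``y`` is the reference variable — total nitrogen (%) for regression
    or the 1/2/3 soil-category code treated as a single continuous response
    for classification-mode selection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y sample counts differ")
    col_sd = X.std(axis=0)
    if np.all(col_sd == 0):
        raise ValueError("all spectral variables are constant; SPA cannot select")

    max_vars = config.resolve_max_vars(n, p)
    starts = range(p) if config.starts is None else config.starts

    chains = [spa_chain(X, s, max_vars) for s in starts]

    curve = np.full(max_vars, np.inf)
    best_subsets: list[np.ndarray | None] = [None] * max_vars
    cache: dict[frozenset, float] = {}
    for chain in chains:
        for m in range(1, len(chain) + 1):
            subset = chain[:m]
            key = frozenset(int(i) for i in subset)
            rmsecv = cache.get(key)
            if rmsecv is None:
                try:
                    rmsecv = mlr_loocv_rmsecv(X[:, subset], y)
                except np.linalg.LinAlgError:
                    rmsecv = np.inf
                cache[key] = rmsecv
            if rmsecv < curve[m - 1]:
                curve[m - 1] = rmsecv
                best_subsets[m - 1] = subset

    finite = np.isfinite(curve)
    if not np.any(finite):
        raise ValueError("no scorable SPA subset (all candidate regressions failed)")
    rmsecv_min = float(np.min(curve[finite]))

    f_crit = _f_critical(config.alpha, n)
    # Absolute floor for the noiseless case: RMSECV values at machine-zero
    # scale are all "equal to the minimum".
    floor = 1e-8 * max(float(np.ptp(y)), 1.0)
    threshold_sq = f_crit * max(rmsecv_min, floor) ** 2
    accept = np.flatnonzero(finite & (curve**2 <= threshold_sq))
    best_size = int(accept[0]) + 1

    selected = np.sort(best_subsets[best_size - 1])
    return SPAResult(
        rmsecv_curve=curve,
        best_size=best_size,
        selected_indices=selected,
        selected_wavelengths_nm=None if wavelengths is None else np.asarray(wavelengths)[selected],
        rmsecv_min=rmsecv_min,
        subsets_per_size=[s if s is None else np.sort(s) for s in best_subsets],
    )
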