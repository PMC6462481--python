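"""Connectome-based predictive modeling (CPM).

Edges are filtered by the significance of their Pearson correlation with the
phenotype (two-tailed p from the exact t transform, default p < .01), split
into a positively and a negatively correlated set, and summarized per subject
as the sum over each set. Three linear models are then available: positive
sum only, negative sum only, and the combined model (ordinary least squares
on both sums jointly). Cross-validation re-runs selection and fitting inside
every fold; the Spearman correlation between predicted and observed scores is
the effect size, reported alongside rho^2 as "% variance explained".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CPMRegressor",
    "CPMResult",
    "select_edges",
    "edgewise_correlations",
    "fit_cpm",
    "loocv_cpm",
    "transfer_cpm",
    "steiger_z",
    "fdr_bh",
    "bootstrap_ci",
]

MODELS = ("positive", "negative", "combined")


def edgewise_correlations(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of every edge (column of ``x``) with ``y`` and the
    two-tailed p-value from the exact t transform t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if y.std() == 0:
        raise ValueError("phenotype has zero variance")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = math.sqrt(float((yc**2).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r = np.clip(np.where(np.isfinite(r), r, 0.0), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return r, p


def select_edges(
    x: np.ndarray, y: np.ndarray, p_thresh: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (positive, negative) edge masks at the selection threshold."""
    r, p = edgewise_correlations(x, y)
    sig = p < p_thresh
    return sig & (r > 0), sig & (r < 0)


class CPMRegressor(RegressorMixin, BaseEstimator):
    """Connectome-based predictive model as a scikit-learn regressor.

    Parameters
    ----------
    p_thresh : float
        Two-tailed selection threshold on the edge-phenotype correlation.
    model : {"positive", "negative", "combined"}
        Which summary-sum model to use for prediction.

    Attributes
    ----------
    pos_mask_, neg_mask_ : boolean arrays over edges (disjoint by
        construction).
    coef_, intercept_ : coefficients of the requested model on its summary
        sums.
    fallback_ : True when no edge survived selection for the requested model
        and the estimator predicts the training mean.
    """

    def __init__(self, p_thresh: float = 0.01, model: str = "combined"):
        self.p_thresh = p_thresh
        self.model = model

    def _sums(self, x: np.ndarray) -> np.ndarray:
        cols = []
        if self.model in ("positive", "combined"):
            cols.append(x[:, self.pos_mask_].sum(axis=1))
        if self.model in ("negative", "combined"):
            cols.append(x[:, self.neg_mask_].sum(axis=1))
        return np.column_stack(cols)

    def fit(self, X, y):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        x = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 2 or x.shape[0] != y.shape[0]:
            raise ValueError("X must be subjects x edges aligned with y")
        self.n_features_in_ = x.shape[1]
        self.pos_mask_, self.neg_mask_ = select_edges(x, y, self.p_thresh)
        sums = self._sums(x)
        used = sums.std(axis=0) > 0
        self.fallback_ = not bool(used.any())
        if self.fallback_:
            self.coef_ = np.zeros(sums.shape[1])
            self.intercept_ = float(y.mean())
            return self
        design = np.column_stack([np.ones(len(y)), sums[:, used]])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        coef = np.zeros(sums.shape[1])
        coef[used] = beta[1:]
        self.coef_ = coef
        self.intercept_ = float(beta[0])
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        x = np.asarray(X, dtype=float)
        if x.shape[1] != self.n_features_in_:
            raise ValueError(
                f"edge count mismatch: model has {self.n_features_in_}, got {x.shape[1]}"
            )
        return self.intercept_ + self._sums(x) @ self.coef_


def fit_cpm(X, y, p_thresh: float = 0.01, model: str = "combined") -> CPMRegressor:
    """Fit a CPM on the full sample (thin wrapper over CPMRegressor)."""
    return CPMRegressor(p_thresh=p_thresh, model=model).fit(X, y)


@dataclass
class CPMResult:
    """Predictions with the Spearman effect size."""

    predictions: np.ndarray
    rho: float
    rho2: float
    p: float
    n: int
    n_fallback_folds: int = 0


def _spearman(pred: np.ndarray, true: np.ndarray) -> tuple[float, float]:
    if np.std(pred) == 0 or np.std(true) == 0:
        return 0.0, 1.0
    rho, p = stats.spearmanr(pred, true)
    return float(rho), float(p)


def loocv_cpm(X, y, p_thresh: float = 0.01, model: str = "combined") -> CPMResult:
    """Leave-one-out cross-validation with selection and fitting re-done
    inside every fold (no leakage). Folds whose masks come up empty predict
    the training mean and are counted in ``n_fallback_folds``."""
    x = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 subjects for LOO-CV")
    preds = np.empty(n)
    n_fallback = 0
    est = CPMRegressor(p_thresh=p_thresh, model=model)
    for i in range(n):
        rows = np.ones(n, dtype=bool)
        rows[i] = False
        est.fit(x[rows], y[rows])
        n_fallback += int(est.fallback_)
        preds[i] = est.predict(x[i : i + 1])[0]
    rho, p = _spearman(preds, y)
    return CPMResult(preds, rho, rho * rho, p, n, n_fallback)


def transfer_cpm(model: CPMRegressor, X_new, y_new) -> CPMResult:
    """Apply a frozen CPM (masks + coefficients) to an independent dataset."""
    preds = model.predict(np.asarray(X_new, dtype=float))
    y_new = np.asarray(y_new, dtype=float)
    rho, p = _spearman(preds, y_new)
    return CPMResult(preds, rho, rho * rho, p, len(y_new))


def steiger_z(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Steiger's test for two dependent correlations sharing one variable.

    ``r1`` and ``r2`` correlate two predictors with the same outcome and
    ``r12`` is the inter-predictor correlation. Uses the Z1*-type statistic:
    Fisher transforms of r1 and r2, with their covariance evaluated at the
    averaged correlation. z > 0 iff r1 > r2; two-tailed normal p.
    """
    for r in (r1, r2, r12):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must be strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    z1, z2 = math.atanh(r1), math.atanh(r2)
    rbar = 0.5 * (r1 + r2)
    rb2 = rbar * rbar
    psi = r12 * (1.0 - 2.0 * rb2) - 0.5 * rb2 * (1.0 - 2.0 * rb2 - r12 * r12)
    c = psi / ((1.0 - rb2) ** 2)
    z = math.sqrt((n - 3) / (2.0 * (1.0 - c))) * (z1 - z2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def bootstrap_ci(
    predicted,
    true,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Seeded paired-percentile bootstrap CIs for the Spearman rho and rho^2
    of predictions against observations."""
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    n = len(true)
    if n < 10:
        raise ValueError("need at least 10 pairs")
    rng = np.random.default_rng(seed)
    rhos = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.std(predicted[idx]) == 0 or np.std(true[idx]) == 0:
            rhos[b] = 0.0
        else:
            rhos[b] = stats.spearmanr(predicted[idx], true[idx]).statistic
    alpha = (1.0 - level) / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ci_rho = (float(np.quantile(rhos, alpha)), float(np.quantile(rhos, 1 - alpha)))
        r2 = rhos**2
        ci_rho2 = (float(np.quantile(r2, alpha)), float(np.quantile(r2, 1 - alpha)))
    return {"rho": ci_rho, "rho2": ci_rho2}
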