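"""Univariable two-sample MR estimators and sensitivity analyses.

The workhorses are scikit-learn-style estimator classes — fit on an
instrument-effect matrix ``X`` (n_snp, k) and outcome-effect vector ``y``
with per-variant outcome standard errors — exposing fitted attributes with
trailing underscores.  Module-level functions (:func:`ivw`, :func:`mr_egger`,
:func:`weighted_median`, ...) are thin wrappers that accept a
:class:`~mrmediate.summary.HarmonizedSet` and return an :class:`MREstimate`.

Inference conventions: two-sided p-values and 95% CIs use the standard
normal reference (GWAS sample sizes are large); the default inverse-variance
weighted (IVW) model is multiplicative random effects — the fixed-effect
standard error is inflated by sqrt(Q / df) whenever Cochran's Q exceeds its
degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    UnitError,
)
from .summary import HarmonizedSet

__all__ = [
    "MREstimate",
    "OddsRatio",
    "IVWRegressor",
    "EggerRegressor",
    "WeightedMedianEstimator",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "cochran_q",
    "to_odds_ratio",
]

Z95 = 1.96  # conventional 95% normal quantile, kept explicit for reporting


@dataclass
class MREstimate:
    """One method's causal estimate with heterogeneity diagnostics."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    outcome_binary: bool = False

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class OddsRatio:
    odds_ratio: float
    ci_low: float
    ci_high: float
    pval: float


def _normal_p(z: float | np.ndarray) -> float | np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(z))


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares via the normal equations on whitened data.

    Returns (coef, unscaled covariance, weighted residual sum of squares).
    """
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    xtx = Xw.T @ Xw
    coef = np.linalg.solve(xtx, Xw.T @ yw)
    resid = yw - Xw @ coef
    rss = float(resid @ resid)
    cov = np.linalg.inv(xtx)
    return coef, cov, rss


class IVWRegressor(BaseEstimator):
    """Inverse-variance weighted regression through the origin.

    Weighted least squares of the outcome effects on the exposure effects
    with weights 1/se_outcome^2 and no intercept; with a single exposure this
    is algebraically the precision-weighted mean of per-variant Wald ratios.

    Parameters
    ----------
    mode : {"multiplicative_random", "fixed"}
        Fixed effects uses the model-based standard error; multiplicative
        random effects scales it by sqrt(max(Q/df, 1)).

    Attributes
    ----------
    coef_ : (k,) causal effect per exposure
    se_, pval_, ci_low_, ci_high_ : per-exposure inference
    q_stat_, q_df_, q_pval_ : Cochran's Q heterogeneity test
    scale_ : multiplicative SE inflation actually applied
    """

    def __init__(self, mode: str = "multiplicative_random"):
        self.mode = mode

    _min_df = 1  # require at least one heterogeneity df

    def _design(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return X, y

    def fit(self, X, y, outcome_se):
        if self.mode not in ("multiplicative_random", "fixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and np.ndim(y) == 1 and len(np.ravel(y)) == X.shape[1]:
            X = X.T
        y = np.asarray(y, dtype=float).ravel()
        outcome_se = np.asarray(outcome_se, dtype=float).ravel()
        n = X.shape[0]
        D, y_ = self._design(X, y)
        k = D.shape[1]
        if n - k < self._min_df:
            raise InsufficientInstrumentsError(
                f"{type(self).__name__} needs at least {k + self._min_df} instruments, got {n}"
            )
        w = 1.0 / outcome_se**2
        coef, cov, rss = _wls(D, y_, w)
        df = n - k
        scale = 1.0
        if self.mode == "multiplicative_random" and df > 0:
            scale = max(rss / df, 1.0)
        se = np.sqrt(np.diag(cov) * scale)
        self.n_snp_ = n
        self.coef_ = coef
        self.se_ = se
        self.pval_ = _normal_p(coef / se)
        self.ci_low_ = coef - Z95 * se
        self.ci_high_ = coef + Z95 * se
        self.q_stat_ = rss
        self.q_df_ = df
        self.q_pval_ = float(stats.chi2.sf(rss, df)) if df > 0 else float("nan")
        self.scale_ = scale
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        D, _ = self._design(X, np.zeros(X.shape[0]))
        return D @ self.coef_


class EggerRegressor(IVWRegressor):
    """MR-Egger: weighted regression with an unconstrained intercept.

    Variants are oriented so the (first) exposure effect is non-negative
    before fitting; the intercept estimates average directional pleiotropy
    and its two-sided p-value is the pleiotropy test.  The slope is the
    pleiotropy-adjusted causal estimate, consistent under the InSIDE
    assumption (instrument strength independent of direct effects).
    """

    _min_df = 1

    def _design(self, X, y):
        flip = np.sign(X[:, 0])
        flip[flip == 0] = 1.0
        Xo = X * flip[:, None]
        yo = y * flip
        return np.column_stack([np.ones(len(yo)), Xo]), yo

    def fit(self, X, y, outcome_se):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        if n < X.shape[1] + 2:
            raise InsufficientInstrumentsError(
                f"MR-Egger needs at least {X.shape[1] + 2} instruments, got {n}"
            )
        super().fit(X, y, outcome_se)
        # split intercept out of the augmented solution
        self.intercept_ = float(self.coef_[0])
        self.intercept_se_ = float(self.se_[0])
        self.intercept_pval_ = float(self.pval_[0])
        self.coef_ = self.coef_[1:]
        self.se_ = self.se_[1:]
        self.pval_ = self.pval_[1:]
        self.ci_low_ = self.ci_low_[1:]
        self.ci_high_ = self.ci_high_[1:]
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept_ + X @ self.coef_


class WeightedMedianEstimator(BaseEstimator):
    """Weighted median of per-variant Wald ratios.

    Consistent when instruments contributing more than half the total weight
    are valid.  The point estimate interpolates the inverse-variance-weighted
    empirical quantile function of the sorted ratio estimates at probability
    0.5; the standard error is the standard deviation of the estimate over
    seeded parametric-bootstrap resamples of the instrument effects.
    """

    def __init__(self, n_boot: int = 1000, seed: int | None = 0):
        self.n_boot = n_boot
        self.seed = seed

    @staticmethod
    def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
        order = np.argsort(ratios, kind="mergesort")
        r = ratios[order]
        w = weights[order] / weights.sum()
        p = np.cumsum(w) - 0.5 * w
        return float(np.interp(0.5, p, r))

    def fit(self, X, y, outcome_se, exposure_se):
        bx = np.asarray(X, dtype=float).ravel()
        by = np.asarray(y, dtype=float).ravel()
        sy = np.asarray(outcome_se, dtype=float).ravel()
        sx = np.asarray(exposure_se, dtype=float).ravel()
        n = len(bx)
        if n < 3:
            raise InsufficientInstrumentsError(
                f"weighted median needs at least 3 instruments, got {n}"
            )
        if np.any(bx == 0):
            raise DegenerateInstrumentError("zero exposure effect in ratio estimate")
        ratios = by / bx
        weights = bx**2 / sy**2  # 1 / first-order ratio variance
        est = self._weighted_median(ratios, weights)
        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bxb = rng.normal(bx, sx)
            byb = rng.normal(by, sy)
            bxb[bxb == 0] = np.finfo(float).tiny
            boots[b] = self._weighted_median(byb / bxb, bxb**2 / sy**2)
        se = float(np.std(boots, ddof=1))
        self.n_snp_ = n
        self.coef_ = np.array([est])
        self.se_ = np.array([se])
        self.pval_ = np.array([_normal_p(est / se)]) if se > 0 else np.array([np.nan])
        self.ci_low_ = self.coef_ - Z95 * self.se_
        self.ci_high_ = self.coef_ + Z95 * self.se_
        return self


# ---------------------------------------------------------------------------
# functional wrappers over HarmonizedSet


def _single_exposure(h: HarmonizedSet) -> None:
    if h.n_exposures != 1:
        raise UnitError(
            "univariable estimator called on a multi-exposure set; use mrmediate.mvmr"
        )


def _estimate_from(est, method: str, h: HarmonizedSet, **extra) -> MREstimate:
    return MREstimate(
        method=method,
        beta=float(est.coef_[0]),
        se=float(est.se_[0]),
        ci_low=float(est.ci_low_[0]),
        ci_high=float(est.ci_high_[0]),
        pval=float(est.pval_[0]),
        n_snp=est.n_snp_,
        outcome_binary=h.outcome_binary,
        **extra,
    )


def wald_ratio(
    bx: float, sx: float, by: float, sy: float, second_order: bool = False
) -> tuple[float, float]:
    """Single-variant Wald ratio by/bx and its delta-method standard error.

    First order: sqrt(sy^2/bx^2 + by^2 sx^2 / bx^4); ``second_order`` adds
    the sx^2 sy^2 / bx^4 cross term.
    """
    if bx == 0:
        raise DegenerateInstrumentError("Wald ratio undefined for bx = 0")
    est = by / bx
    var = sy**2 / bx**2 + by**2 * sx**2 / bx**4
    if second_order:
        var += sx**2 * sy**2 / bx**4
    return est, math.sqrt(var)


def ivw(h: HarmonizedSet, mode: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance weighted estimate over all instruments."""
    _single_exposure(h)
    est = IVWRegressor(mode=mode).fit(h.beta_exposure, h.beta_outcome, h.se_outcome)
    label = "ivw_mre" if mode == "multiplicative_random" else "ivw_fixed"
    return _estimate_from(
        est, label, h, q_stat=est.q_stat_, q_df=est.q_df_, q_pval=est.q_pval_
    )


def mr_egger(h: HarmonizedSet, mode: str = "multiplicative_random") -> MREstimate:
    """MR-Egger slope and directional-pleiotropy intercept test."""
    _single_exposure(h)
    est = EggerRegressor(mode=mode).fit(h.beta_exposure, h.beta_outcome, h.se_outcome)
    return _estimate_from(
        est,
        "egger",
        h,
        q_stat=est.q_stat_,
        q_df=est.q_df_,
        q_pval=est.q_pval_,
        egger_intercept=est.intercept_,
        egger_intercept_se=est.intercept_se_,
        egger_intercept_pval=est.intercept_pval_,
    )


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap standard error."""
    _single_exposure(h)
    est = WeightedMedianEstimator(n_boot=n_boot, seed=seed).fit(
        h.beta_exposure, h.beta_outcome, h.se_outcome, h.se_exposure
    )
    return _estimate_from(est, "weighted_median", h)


def cochran_q(h: HarmonizedSet, center: float) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity of per-variant ratios around ``center``.

    Q = sum_j w_j (ratio_j - center)^2 with IVW weights w_j = bx_j^2/sy_j^2;
    df = n_snp - 1; upper-tail chi-square p-value.
    """
    _single_exposure(h)
    bx = h.beta_exposure[:, 0]
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 instruments")
    if np.any(bx == 0):
        raise DegenerateInstrumentError("zero exposure effect in ratio estimate")
    ratios = h.beta_outcome / bx
    w = bx**2 / h.se_outcome**2
    q = float(np.sum(w * (ratios - center) ** 2))
    df = h.n_snp - 1
    return q, df, float(stats.chi2.sf(q, df))


def to_odds_ratio(e: MREstimate) -> OddsRatio:
    """Express a log-odds causal estimate as an odds ratio with 95% CI."""
    if not e.outcome_binary:
        raise UnitError("odds ratios are defined only for binary (log-odds) outcomes")
    return OddsRatio(
        odds_ratio=math.exp(e.beta),
        ci_low=math.exp(e.beta - Z95 * e.se),
        ci_high=math.exp(e.beta + Z95 * e.se),
        pval=e.pval,
    )
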