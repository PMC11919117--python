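"""Multivariable MR: joint direct effects, MVMR-Egger, conditional instrument
strength and instrument-validity heterogeneity.

Estimation reuses the weighted-regression estimators of
:mod:`mrmediate.estimators` on the (n_snp, k) exposure-effect matrix.  The
first-order weighting convention is used throughout: weights are the inverse
outcome-effect variances, ignoring measurement error in the exposure effects
(the NOME approximation standard in MVMR-IVW practice; see the methods note
for the resulting limitation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CollinearityError, ConfigurationError, InsufficientInstrumentsError
from .estimators import EggerRegressor, IVWRegressor, Z95, _normal_p, _wls
from .summary import HarmonizedSet

__all__ = ["MvmrResult", "mvmr_ivw", "mvmr_egger", "conditional_f", "q_validity"]


@dataclass
class MvmrResult:
    """Joint direct effects of k exposures on one outcome."""

    exposures: list[str]
    direct_beta: np.ndarray
    direct_se: np.ndarray
    direct_pval: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_snp: int
    conditional_f: np.ndarray | None = None
    q_validity: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    outcome_binary: bool = False
    method: str = "mvmr_ivw"


def _check_rank(h: HarmonizedSet) -> None:
    X = h.beta_exposure / h.se_outcome[:, None]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(
            f"exposure-effect matrix is rank deficient for exposures {h.exposures}"
        )


def mvmr_ivw(h: HarmonizedSet, with_conditional_f: bool = True) -> MvmrResult:
    """MVMR-IVW: weighted regression of outcome effects on all exposure effects.

    No intercept; weights 1/se_outcome^2; standard errors scaled by
    sqrt(max(Q/(n_snp - k), 1)) (multiplicative random effects).  With a
    single exposure this reduces exactly to the univariable IVW estimate.
    """
    n, k = h.beta_exposure.shape
    if n <= k:
        raise InsufficientInstrumentsError(
            f"MVMR needs more instruments than exposures (n={n}, k={k})"
        )
    _check_rank(h)
    est = IVWRegressor(mode="multiplicative_random").fit(
        h.beta_exposure, h.beta_outcome, h.se_outcome
    )
    cond_f = None
    if with_conditional_f and k >= 2:
        cond_f = np.array([conditional_f(h, i) for i in range(k)])
    return MvmrResult(
        exposures=list(h.exposures),
        direct_beta=est.coef_,
        direct_se=est.se_,
        direct_pval=est.pval_,
        ci_low=est.ci_low_,
        ci_high=est.ci_high_,
        n_snp=n,
        conditional_f=cond_f,
        q_validity=est.q_stat_,
        q_df=est.q_df_,
        q_pval=est.q_pval_,
        outcome_binary=h.outcome_binary,
        method="mvmr_ivw",
    )


def mvmr_egger(h: HarmonizedSet) -> MvmrResult:
    """MVMR-Egger: as :func:`mvmr_ivw` with an intercept column, after
    orienting every variant so the first exposure's effect is non-negative."""
    n, k = h.beta_exposure.shape
    if n <= k + 1:
        raise InsufficientInstrumentsError(
            f"MVMR-Egger needs n_snp > k + 1 (n={n}, k={k})"
        )
    _check_rank(h)
    est = EggerRegressor(mode="multiplicative_random").fit(
        h.beta_exposure, h.beta_outcome, h.se_outcome
    )
    return MvmrResult(
        exposures=list(h.exposures),
        direct_beta=est.coef_,
        direct_se=est.se_,
        direct_pval=est.pval_,
        ci_low=est.ci_low_,
        ci_high=est.ci_high_,
        n_snp=n,
        q_validity=est.q_stat_,
        q_df=est.q_df_,
        q_pval=est.q_pval_,
        egger_intercept=est.intercept_,
        egger_intercept_se=est.intercept_se_,
        egger_intercept_pval=est.intercept_pval_,
        outcome_binary=h.outcome_binary,
        method="mvmr_egger",
    )


def conditional_f(h: HarmonizedSet, exposure_index: int) -> float:
    """Sanderson–Windmeijer style conditional F-statistic (first order).

    The target exposure's instrument effects are regressed on the other
    exposures' instrument effects (weights 1/se_outcome^2); the residuals,
    scaled by the target exposure's instrument-effect variances, give the
    conditional heterogeneity statistic Q_x, and

        conditional F = Q_x / (n_snp - k + 1).

    F > 10 is the conventional adequate-strength threshold.  With perfectly
    collinear exposures the residuals vanish and F ~ 0.
    """
    n, k = h.beta_exposure.shape
    if k < 2:
        raise ConfigurationError(
            "conditional F requires k >= 2 exposures; use univariable f_statistics"
        )
    if not 0 <= exposure_index < k:
        raise ConfigurationError(f"exposure_index {exposure_index} out of range")
    target = h.beta_exposure[:, exposure_index]
    others = np.delete(h.beta_exposure, exposure_index, axis=1)
    w = 1.0 / h.se_outcome**2
    coef, _, _ = _wls(others, target, w)
    resid = target - others @ coef
    q_x = float(np.sum(resid**2 / h.se_exposure[:, exposure_index] ** 2))
    return q_x / (n - k + 1)


def q_validity(h: HarmonizedSet, fit: MvmrResult) -> tuple[float, int, float]:
    """Instrument-validity heterogeneity of an MVMR fit.

    Q = sum_j w_j (by_j - sum_e bx_je beta_e)^2 with w_j = 1/sy_j^2,
    df = n_snp - k, chi-square upper-tail p-value.
    """
    w = 1.0 / h.se_outcome**2
    resid = h.beta_outcome - h.beta_exposure @ fit.direct_beta
    if fit.egger_intercept is not None:
        # Egger fits on sign-oriented data; orient the residual identically.
        flip = np.sign(h.beta_exposure[:, 0])
        flip[flip == 0] = 1.0
        resid = h.beta_outcome * flip - (h.beta_exposure * flip[:, None]) @ fit.direct_beta
        resid = resid - fit.egger_intercept
    q = float(np.sum(w * resid**2))
    df = h.n_snp - len(fit.exposures) - (1 if fit.egger_intercept is not None else 0)
    return q, df, float(stats.chi2.sf(q, df))
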