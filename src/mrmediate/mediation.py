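"""Two-step MR mediation: product-of-coefficients effect decomposition.

Step 1 estimates the exposure->mediator effect (beta1) by univariable IVW on
the exposure's instruments; step 2 estimates the mediator->outcome effect
adjusted for the exposure (beta2) by MVMR-IVW on the union of both traits'
instruments.  The indirect effect is beta1 * beta2 with

* a first-order delta-method standard error
  sqrt(beta2^2 se1^2 + beta1^2 se2^2)   (zero covariance: the two steps use
  non-overlapping samples in a two-sample design),
* a symmetric 95% CI from that SE,
* an asymmetric CI from the exact distribution of the product of two
  independent normals (numerical integration of the product CDF, with a
  seeded Monte-Carlo alternative), and
* a two-sided normal p-value on indirect / se_indirect.

The proportion mediated indirect/total is reported only when the indirect
and total effects share a sign ("inconsistent mediation" otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError
from .estimators import Z95, ivw
from .mvmr import mvmr_ivw
from .summary import (
    GwasSummary,
    InstrumentCriteria,
    LDMatrix,
    harmonize,
    select_instruments,
)

__all__ = [
    "MediationResult",
    "product_effect",
    "delta_se",
    "prodnormal_ci",
    "two_step_mediation",
    "mediation_table",
]


def product_effect(beta1: float, beta2: float) -> float:
    """Product-method indirect effect beta1 * beta2."""
    return beta1 * beta2


def delta_se(
    beta1: float, se1: float, beta2: float, se2: float, second_order: bool = False
) -> float:
    """Delta-method SE of the product of two independent estimates.

    First order: sqrt(beta2^2 se1^2 + beta1^2 se2^2); the optional exact
    second-order term adds se1^2 se2^2 (off by default, matching the common
    reporting convention).
    """
    if se1 < 0 or se2 < 0:
        raise ConfigurationError("standard errors must be non-negative")
    var = beta2**2 * se1**2 + beta1**2 * se2**2
    if second_order:
        var += se1**2 * se2**2
    return math.sqrt(var)


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(160)


def _panel(t, b1, s1, b2, s2, lo, hi, upper_tail):
    """Gauss-Legendre integral of f1(x) * P(X2 {<=,>} t/x) over [lo, hi]."""
    if hi <= lo:
        return 0.0
    x = 0.5 * (hi - lo) * _GL_NODES + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * _GL_WEIGHTS
    f1 = stats.norm.pdf(x, b1, s1)
    inner = stats.norm.sf(t / x, b2, s2) if upper_tail else stats.norm.cdf(t / x, b2, s2)
    return float(np.sum(w * f1 * inner))


def _prod_cdf(t: float, b1: float, s1: float, b2: float, s2: float) -> float:
    """CDF of X1*X2 for independent X1 ~ N(b1, s1^2), X2 ~ N(b2, s2^2).

    The x-integral is split at 0, where the conditional tail switches sides;
    each half uses a fixed high-order Gauss-Legendre rule over the +/- 10
    sigma support of X1 (the integrand is smooth on each side).
    """
    lo, hi = b1 - 10 * s1, b1 + 10 * s1
    total = _panel(t, b1, s1, b2, s2, max(lo, 0.0), max(hi, 0.0), upper_tail=False)
    total += _panel(t, b1, s1, b2, s2, min(lo, 0.0), min(hi, 0.0), upper_tail=True)
    if lo < 0 < hi and t >= 0:
        total += 0.0  # the atom at x = 0 has measure zero
    return float(np.clip(total, 0.0, 1.0))


def prodnormal_ci(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    level: float = 0.95,
    method: str = "integration",
    n_mc: int = 1_000_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval from the distribution of a product of two
    independent normals (asymmetric in general).

    ``method="integration"`` inverts the numerically integrated product CDF
    (Meeker–Escobar approach); ``method="mc"`` uses quantiles of ``n_mc``
    seeded Monte-Carlo draws.  The two agree to three decimals at the scales
    used here and converge to the symmetric delta interval as both z-scores
    grow.
    """
    if not 0 < level < 1:
        raise ConfigurationError("level must be in (0, 1)")
    if se1 < 0 or se2 < 0:
        raise ConfigurationError("standard errors must be non-negative")
    point = beta1 * beta2
    if se1 == 0 and se2 == 0:
        return point, point
    if se1 == 0 or se2 == 0:
        # product of a constant and a normal is normal
        sd = abs(beta1) * se2 if se1 == 0 else abs(beta2) * se1
        z = stats.norm.ppf(0.5 + level / 2)
        return point - z * sd, point + z * sd

    alpha = (1 - level) / 2
    if method == "mc":
        rng = np.random.default_rng(seed)
        draws = rng.normal(beta1, se1, n_mc) * rng.normal(beta2, se2, n_mc)
        lo, hi = np.quantile(draws, [alpha, 1 - alpha])
        return float(lo), float(hi)
    if method != "integration":
        raise ConfigurationError(f"unknown method {method!r}")

    spread = delta_se(beta1, se1, beta2, se2, second_order=True)

    def quantile(q: float) -> float:
        f = lambda t: _prod_cdf(t, beta1, se1, beta2, se2) - q
        lo_b, hi_b = point - 12 * spread, point + 12 * spread
        f_lo, f_hi = f(lo_b), f(hi_b)
        tries = 0
        while f_lo > 0 and tries < 5:
            lo_b -= 12 * spread
            f_lo = f(lo_b)
            tries += 1
        tries = 0
        while f_hi < 0 and tries < 5:
            hi_b += 12 * spread
            f_hi = f(hi_b)
            tries += 1
        if f_lo > 0 or f_hi < 0:
            # fall back to Monte Carlo if bracketing failed
            return None
        return float(optimize.brentq(f, lo_b, hi_b, xtol=1e-8))

    lo = quantile(alpha)
    hi = quantile(1 - alpha)
    if lo is None or hi is None:
        import warnings

        warnings.warn("product-CDF inversion failed; falling back to Monte Carlo")
        return prodnormal_ci(beta1, se1, beta2, se2, level, "mc", n_mc, seed)
    return lo, hi


@dataclass
class MediationResult:
    """Effect decomposition for one mediator."""

    mediator: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    indirect: float
    se_indirect: float
    ci_delta: tuple[float, float]
    ci_prodnormal: tuple[float, float]
    pval: float
    total: float
    total_se: float
    total_ci: tuple[float, float]
    direct: float
    direct_se: float
    direct_ci: tuple[float, float]
    proportion_mediated: float | None
    classification: str
    n_snp_step1: int
    n_snp_step2: int


def _classify(
    direct_ci: tuple[float, float], indirect_ci: tuple[float, float]
) -> str:
    direct_null = direct_ci[0] <= 0 <= direct_ci[1]
    indirect_sig = not (indirect_ci[0] <= 0 <= indirect_ci[1])
    if direct_null and indirect_sig:
        return "complete mediation"
    if not direct_null and indirect_sig:
        return "partial mediation"
    return "none"


def assemble_mediation(
    mediator: str,
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    total,
    direct,
    n_snp_step1: int = 0,
    n_snp_step2: int = 0,
    ci_seed: int = 0,
) -> MediationResult:
    """Build a :class:`MediationResult` from step estimates.

    ``total`` / ``direct`` may be MREstimate-like objects (beta, se, ci_low,
    ci_high) or (beta, se) tuples.
    """

    def _unpack(e):
        if hasattr(e, "beta"):
            return e.beta, e.se, (e.ci_low, e.ci_high)
        b, s = e
        return b, s, (b - Z95 * s, b + Z95 * s)

    tot_b, tot_se, tot_ci = _unpack(total)
    dir_b, dir_se, dir_ci = _unpack(direct)
    indirect = product_effect(beta1, beta2)
    se_ind = delta_se(beta1, se1, beta2, se2)
    if se_ind == 0.0 and (se1 > 0 or se2 > 0):
        # first-order variance vanishes at beta1 = beta2 = 0; fall back to
        # the exact product variance so inference stays defined
        se_ind = delta_se(beta1, se1, beta2, se2, second_order=True)
    ci_delta = (indirect - Z95 * se_ind, indirect + Z95 * se_ind)
    ci_pn = prodnormal_ci(beta1, se1, beta2, se2, seed=ci_seed)
    pval = 2.0 * stats.norm.sf(abs(indirect / se_ind)) if se_ind > 0 else float("nan")
    if tot_b != 0 and np.sign(indirect) == np.sign(tot_b):
        prop = indirect / tot_b
    else:
        prop = None
    return MediationResult(
        mediator=mediator,
        beta1=beta1,
        se1=se1,
        beta2=beta2,
        se2=se2,
        indirect=indirect,
        se_indirect=se_ind,
        ci_delta=ci_delta,
        ci_prodnormal=ci_pn,
        pval=pval,
        total=tot_b,
        total_se=tot_se,
        total_ci=tot_ci,
        direct=dir_b,
        direct_se=dir_se,
        direct_ci=dir_ci,
        proportion_mediated=prop,
        classification=_classify(dir_ci, ci_pn),
        n_snp_step1=n_snp_step1,
        n_snp_step2=n_snp_step2,
    )


def two_step_mediation(
    exposure: GwasSummary,
    mediator: GwasSummary,
    outcome: GwasSummary,
    criteria: InstrumentCriteria | None = None,
    ld: LDMatrix | None = None,
    seed: int = 0,
    palindromic_eaf_tol: float = 0.08,
) -> MediationResult:
    """Full two-step MR mediation of exposure -> mediator -> outcome.

    Step 1: univariable IVW of the mediator on the exposure's instruments
    (beta1).  Step 2: MVMR-IVW of the outcome on exposure and mediator
    jointly, over the union of both traits' instruments; the mediator's
    direct effect is beta2 and the exposure's is the direct (mediator-
    adjusted) effect.  The total effect is univariable IVW of the outcome on
    the exposure's instruments.
    """
    criteria = criteria or InstrumentCriteria()
    inst_x = select_instruments(exposure, criteria, ld)
    inst_m = select_instruments(mediator, criteria, ld)

    h1 = harmonize([exposure], mediator, palindromic_eaf_tol, variant_ids=inst_x)
    step1 = ivw(h1)

    h_total = harmonize([exposure], outcome, palindromic_eaf_tol, variant_ids=inst_x)
    total = ivw(h_total)

    union = list(dict.fromkeys(inst_x + inst_m))
    # MVMR candidates come from the exposure summary; restrict to the union
    h2 = harmonize([exposure, mediator], outcome, palindromic_eaf_tol, variant_ids=union)
    fit2 = mvmr_ivw(h2)
    i_x = h2.exposures.index(exposure.trait)
    i_m = h2.exposures.index(mediator.trait)
    beta2 = float(fit2.direct_beta[i_m])
    se2 = float(fit2.direct_se[i_m])
    direct = (
        float(fit2.direct_beta[i_x]),
        float(fit2.direct_se[i_x]),
    )
    return assemble_mediation(
        mediator=mediator.trait,
        beta1=step1.beta,
        se1=step1.se,
        beta2=beta2,
        se2=se2,
        total=total,
        direct=direct,
        n_snp_step1=h1.n_snp,
        n_snp_step2=h2.n_snp,
        ci_seed=seed,
    )


# ---------------------------------------------------------------------------
# tabular reporting


def _fmt_p(p: float) -> str:
    """Two significant figures; scientific notation below 1e-2."""
    if not np.isfinite(p):
        return "NA"
    if p < 1e-2:
        return f"{p:.1E}"
    return f"{p:.3g}"


def mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    """Publication-style mediation table.

    Effects and SEs are rounded to three decimals.  The displayed p-value is
    recomputed from the *displayed* (rounded) indirect effect and SE so the
    printed row is internally consistent — the convention used in the kind of
    summary tables this mirrors.  Full-precision values belong in the JSON
    serialization, not here.
    """
    rows = []
    for r in results:
        ind = round(r.indirect, 3)
        se = round(r.se_indirect, 3)
        p_shown = 2.0 * stats.norm.sf(abs(ind / se)) if se > 0 else float("nan")
        rows.append(
            {
                "mediator": r.mediator,
                "beta1": round(r.beta1, 3),
                "se_beta1": round(r.se1, 3),
                "beta2": round(r.beta2, 3),
                "se_beta2": round(r.se2, 3),
                "indirect": ind,
                "ci_low": round(r.ci_prodnormal[0], 3),
                "ci_high": round(r.ci_prodnormal[1], 3),
                "se_indirect": se,
                "pval": _fmt_p(p_shown),
                "classification": r.classification,
            }
        )
    return pd.DataFrame(rows)
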