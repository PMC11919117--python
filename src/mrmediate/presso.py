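"""MR-PRESSO: simulation-based global heterogeneity, per-variant outlier and
distortion tests for horizontal pleiotropy.

The observed statistic is a leave-one-out weighted residual sum of squares
(RSS): each variant's outcome effect is compared with the prediction of the
IVW estimate computed *without* that variant, weighted by its inverse outcome
variance.  The null distribution is generated parametrically — instrument
effects are redrawn from normal distributions centred on the leave-one-out
model — and p-values are Monte-Carlo tail probabilities with the add-one
correction, so the smallest attainable p is 1/(n_sim + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CannotCorrectError, ConfigurationError, InsufficientInstrumentsError
from .estimators import MREstimate, ivw
from .summary import HarmonizedSet

__all__ = ["PressoResult", "MRPresso", "presso_global", "presso_outliers", "presso_distortion"]


@dataclass
class PressoResult:
    """Global, outlier and distortion test results."""

    global_rss: float
    global_pval: float
    n_sim: int
    seed: int
    outlier_pvals: np.ndarray
    variant_ids: list[str]
    outlier_ids: list[str] = field(default_factory=list)
    corrected: MREstimate | None = None
    distortion_pval: float | None = None
    # simulated per-variant RSS distribution, kept for the outlier test
    _sim_rss: np.ndarray | None = None


def _loo_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized over the left-out index.

    Supports batched inputs of shape (..., n).
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def _rss_terms(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    beta_loo = _loo_ivw(bx, by, w)
    return w * (by - bx * beta_loo) ** 2


def presso_global(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0) -> PressoResult:
    """Global pleiotropy test: observed leave-one-out RSS versus its
    parametric null distribution.

    For each of ``n_sim`` replicates, per-variant effects are redrawn as
    bx* ~ N(bx_j, sx_j) and by* ~ N(bx_j * beta_loo_j, sy_j) and the RSS is
    recomputed; global_pval = (1 + #{RSS* >= RSS_obs}) / (n_sim + 1).
    """
    if h.n_exposures != 1:
        raise ConfigurationError("MR-PRESSO is defined for a single exposure")
    n = h.n_snp
    if n < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs at least 4 instruments, got {n}")
    bx = h.beta_exposure[:, 0]
    sx = h.se_exposure[:, 0]
    by = h.beta_outcome
    sy = h.se_outcome
    w = 1.0 / sy**2

    obs_terms = _rss_terms(bx, by, w)
    obs_rss = float(obs_terms.sum())

    rng = np.random.default_rng(seed)
    beta_loo = _loo_ivw(bx, by, w)
    bx_sim = rng.normal(bx, sx, size=(n_sim, n))
    by_sim = rng.normal(bx * beta_loo, sy, size=(n_sim, n))
    sim_terms = _rss_terms(bx_sim, by_sim, w)
    sim_rss = sim_terms.sum(axis=1)

    global_pval = (1.0 + np.sum(sim_rss >= obs_rss)) / (n_sim + 1.0)
    outlier_pvals = (1.0 + np.sum(sim_terms >= obs_terms, axis=0)) / (n_sim + 1.0)
    return PressoResult(
        global_rss=obs_rss,
        global_pval=float(global_pval),
        n_sim=n_sim,
        seed=seed,
        outlier_pvals=outlier_pvals,
        variant_ids=list(h.variant_ids),
        _sim_rss=sim_terms,
    )


def presso_outliers(
    h: HarmonizedSet, global_result: PressoResult, alpha: float = 0.05
) -> list[str]:
    """Flag variants whose per-variant RSS is extreme under the null.

    Bonferroni multiplicity: variant j is an outlier iff its Monte-Carlo
    p-value is below alpha / n_snp.  ``alpha = 0`` flags nothing.
    """
    if list(global_result.variant_ids) != list(h.variant_ids):
        raise ConfigurationError("global result was computed on a different variant set")
    thresh = alpha / h.n_snp
    flagged = [
        vid
        for vid, p in zip(h.variant_ids, global_result.outlier_pvals)
        if p < thresh
    ]
    global_result.outlier_ids = flagged
    return flagged


def presso_distortion(
    h: HarmonizedSet,
    outlier_ids: list[str],
    n_sim: int = 1000,
    seed: int = 0,
) -> tuple[float, MREstimate]:
    """Distortion test and outlier-corrected IVW estimate.

    The corrected estimate is IVW on the non-outliers.  The distortion
    statistic is the relative change (beta_all - beta_corrected) /
    beta_corrected; its null distribution removes random subsets of the same
    size, and the p-value is the two-sided Monte-Carlo tail probability.
    """
    if not outlier_ids:
        raise ConfigurationError("distortion test requires a nonempty outlier set")
    outliers = set(outlier_ids)
    keep_mask = np.array([v not in outliers for v in h.variant_ids])
    if not keep_mask.any():
        raise CannotCorrectError("all instruments flagged as outliers; cannot correct")
    corrected = ivw(h.subset(keep_mask))
    beta_all = ivw(h).beta
    d_obs = (beta_all - corrected.beta) / corrected.beta

    n_out = int((~keep_mask).sum())
    n = h.n_snp
    bx = h.beta_exposure[:, 0]
    by = h.beta_outcome
    w = 1.0 / h.se_outcome**2
    rng = np.random.default_rng(seed)
    d_null = np.empty(n_sim)
    for b in range(n_sim):
        drop = rng.choice(n, size=n_out, replace=False)
        m = np.ones(n, dtype=bool)
        m[drop] = False
        beta_sub = np.sum(w[m] * bx[m] * by[m]) / np.sum(w[m] * bx[m] ** 2)
        d_null[b] = (beta_all - beta_sub) / beta_sub
    pval = (1.0 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1.0)
    return float(pval), corrected


class MRPresso:
    """Convenience runner chaining the global, outlier and distortion tests.

    After :meth:`fit`, the attributes ``result_`` (a :class:`PressoResult`)
    and ``corrected_`` are populated; the distortion test runs only when
    outliers were flagged.
    """

    def __init__(self, n_sim: int = 1000, alpha: float = 0.05, seed: int = 0):
        self.n_sim = n_sim
        self.alpha = alpha
        self.seed = seed

    def fit(self, h: HarmonizedSet) -> "MRPresso":
        res = presso_global(h, n_sim=self.n_sim, seed=self.seed)
        flagged = presso_outliers(h, res, alpha=self.alpha)
        if flagged and len(flagged) < h.n_snp:
            res.distortion_pval, res.corrected = presso_distortion(
                h, flagged, n_sim=self.n_sim, seed=self.seed
            )
        self.result_ = res
        self.corrected_ = res.corrected
        return self
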