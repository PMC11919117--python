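"""Synthetic two-sample GWAS summary statistics under an explicit
exposure -> mediator -> outcome causal model.

The generator draws individual-level cohorts (independent binomial genotypes
under Hardy-Weinberg, LD-free unless block correlation is requested) and
derives per-variant summary statistics exactly the way the consumed real
GWASs do: simple linear regression per variant for continuous traits, a
logistic score test per variant for the binary outcome.  Three disjoint
cohorts yield the three summary files of a clean two-sample (three-sample)
design: one measuring the exposure, one the mediator, one the outcome.

Causal model (all continuous traits standardized to unit variance):

    X = sum_j gamma_j g_j + eps_X            (instruments explain h2_exposure)
    M = beta1 * X + sum_j delta_j g_j + eps_M  (mediator-specific instruments
                                               explain h2_mediator)
    liability = direct * X + beta2 * M + sum_j alpha_j g_j + eps_Y
    Y ~ Bernoulli(expit(a + lambda * liability))

Two generator design choices matter for interpretation and are detailed in
the methods note:

* Effect sizes follow a two-tier architecture (a strong tier carrying most
  of the heritability over half the variants, a weak sub-threshold tier),
  emulating the situation the selection step faces in real data where
  retained instruments are the strong tail of a polygenic background rather
  than a set of variants hovering at the significance threshold.
* The binary-outcome scale is calibrated (the ``lambda`` above) so that the
  user-specified log-odds effects are the *marginal* per-allele estimands
  that logistic summary statistics actually measure; without this, odds-ratio
  non-collapsibility would make every stated effect unrecoverable by several
  percent regardless of the MR method.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import optimize, stats
from scipy.special import expit

from .errors import ConfigurationError
from .summary import GwasSummary, LDMatrix

__all__ = [
    "SimConfig",
    "MultiExposureConfig",
    "simulate_cohorts",
    "simulate_multi_exposure",
    "ld_matrix",
]

_PVAL_FLOOR = 1e-300

# ordered non-palindromic allele pairs a variant can be assigned
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass
class SimConfig:
    """Generative parameters of the synthetic two-sample mediation model.

    Defaults encode the desk-scale study conditions: 50 instruments per
    trait, cohorts of 20,000, exposure heritability 0.10, mediator (own-
    instrument) heritability 0.20, effects beta1 = 0.5 and beta2 = -1.0 with
    a small residual direct effect 0.04 so the total exposure -> outcome
    effect is -0.46 log-odds per SD, and outcome prevalence 5.5%.
    """

    n_snps: int = 50
    n_snps_mediator: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure_cohort: int = 20_000
    n_mediator_cohort: int = 20_000
    n_outcome_cohort: int = 20_000
    h2_exposure: float = 0.10
    h2_mediator: float = 0.20
    beta1_true: float = 0.5
    beta2_true: float = -1.0
    direct_true: float = 0.04
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    outcome_prevalence: float = 0.055
    strong_fraction: float = 0.5
    strong_h2_share: float = 0.9
    ld_block_size: int | None = None
    ld_block_r2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        for name in ("n_exposure_cohort", "n_mediator_cohort", "n_outcome_cohort"):
            if getattr(self, name) < 100:
                raise ConfigurationError(f"{name} must be at least 100")
        if not 0 < self.h2_exposure < 1:
            raise ConfigurationError("h2_exposure must be in (0, 1)")
        if not 0 <= self.h2_mediator < 1:
            raise ConfigurationError("h2_mediator must be in [0, 1)")
        if not 0 < self.outcome_prevalence < 1:
            raise ConfigurationError("outcome_prevalence must be in (0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigurationError(
                "pleiotropy_mode must be none, balanced or directional"
            )
        if self.beta1_true**2 + self.h2_mediator >= 1:
            raise ConfigurationError(
                "beta1_true^2 + h2_mediator must be < 1 so the mediator can be "
                "standardized to unit variance"
            )
        if self.ld_block_size is not None and not 0 <= self.ld_block_r2 <= 1:
            raise ConfigurationError("ld_block_r2 must be in [0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        return cls(**raw)


def _two_tier_effects(
    rng: np.random.Generator, n: int, h2: float, strong_fraction: float, share: float
) -> np.ndarray:
    """Per-SD-of-genotype effects with a strong tier and a weak tier.

    ``n_strong = round(strong_fraction * n)`` variants share ``share`` of the
    heritability equally; the rest share the remainder.  Signs are random.
    """
    n_strong = int(round(strong_fraction * n))
    n_strong = min(max(n_strong, 1), n)
    out = np.empty(n)
    out[:n_strong] = np.sqrt(share * h2 / n_strong)
    if n > n_strong:
        out[n_strong:] = np.sqrt((1 - share) * h2 / (n - n_strong))
    signs = rng.choice([-1.0, 1.0], size=n)
    return out * signs


def _genotypes(
    rng: np.random.Generator,
    n: int,
    mafs: np.ndarray,
    block_size: int | None = None,
    block_r2: float = 0.0,
) -> np.ndarray:
    """(n, m) genotype dosages; optional within-block correlation.

    Block members after the first copy the block's base genotype per
    individual with probability sqrt(block_r2), giving pairwise r^2 of
    ``block_r2`` with the base variant (and block_r2^2 between non-base
    members).
    """
    m = len(mafs)
    g = rng.binomial(2, mafs, size=(n, m)).astype(np.float64)
    if block_size and block_size > 1 and block_r2 > 0:
        pi = np.sqrt(block_r2)
        for start in range(0, m, block_size):
            base = g[:, start]
            for j in range(start + 1, min(start + block_size, m)):
                copy = rng.random(n) < pi
                g[copy, j] = base[copy]
    return g


def _linear_gwas(g: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sgg = np.einsum("ij,ij->j", gc, gc)
    sgy = gc.T @ yc
    beta = sgy / sgg
    rss = float(yc @ yc) - beta * sgy
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sgg)
    z = beta / se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), _PVAL_FLOOR, 1.0)
    return {"beta": beta, "se": se, "pval": pval, "eaf": g.mean(axis=0) / 2.0, "n": n}


def _logistic_score_gwas(g: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    n = len(y)
    pbar = y.mean()
    gc = g - g.mean(axis=0)
    u = gc.T @ (y - pbar)
    v = pbar * (1 - pbar) * np.einsum("ij,ij->j", gc, gc)
    beta = u / v
    se = 1.0 / np.sqrt(v)
    pval = np.clip(stats.chi2.sf(u**2 / v, 1), _PVAL_FLOOR, 1.0)
    return {"beta": beta, "se": se, "pval": pval, "eaf": g.mean(axis=0) / 2.0, "n": n}


def _solve_intercept(u: np.ndarray, prevalence: float) -> float:
    f = lambda a: float(np.mean(expit(a + u))) - prevalence
    return optimize.brentq(f, -40.0, 40.0)


def _calibrated_probs(liability: np.ndarray, prevalence: float) -> np.ndarray:
    """Bernoulli probabilities with marginal-scale calibration.

    Solves for the liability scale ``lambda`` at which the average logistic
    score-test attenuation factor kappa = E[p(1-p)] / (pbar (1-pbar))
    satisfies lambda * kappa = 1, so small per-allele conditional effects on
    the liability equal the marginal log-odds effects the GWAS estimates.
    """
    lc = liability - liability.mean()
    if float(lc @ lc) == 0.0:
        return np.full_like(lc, prevalence)
    lam = 1.0
    for _ in range(100):
        a = _solve_intercept(lam * lc, prevalence)
        p = expit(a + lam * lc)
        pbar = p.mean()
        kappa = float(np.mean(p * (1 - p)) / (pbar * (1 - pbar)))
        lam_new = 1.0 / kappa
        if abs(lam_new - lam) < 1e-9:
            lam = lam_new
            break
        lam = 0.5 * lam + 0.5 * lam_new  # damped fixed point
    a = _solve_intercept(lam * lc, prevalence)
    p = expit(a + lam * lc)
    pbar = p.mean()
    kappa = float(np.mean(p * (1 - p)) / (pbar * (1 - pbar)))
    if abs(lam * kappa - 1.0) > 1e-3:
        # no exact solution (the marginal slope plateaus for very dispersed
        # liabilities, e.g. extreme pleiotropy); use the closest scale
        import warnings

        warnings.warn(
            "marginal-scale calibration did not converge; stated log-odds "
            "effects will be attenuated in the summary statistics",
            RuntimeWarning,
            stacklevel=3,
        )
    return p


def _make_summary(
    stats_dict: dict[str, np.ndarray],
    ids: list[str],
    alleles: list[tuple[str, str]],
    trait: str,
    is_binary: bool,
    sex_restriction: str = "all",
) -> GwasSummary:
    import pandas as pd

    df = pd.DataFrame(
        {
            "variant_id": ids,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "eaf": stats_dict["eaf"],
            "beta": stats_dict["beta"],
            "se": stats_dict["se"],
            "pval": stats_dict["pval"],
            "n": stats_dict["n"],
        }
    )
    return GwasSummary(trait=trait, data=df, is_binary=is_binary, sex_restriction=sex_restriction)


def simulate_cohorts(
    cfg: SimConfig,
) -> tuple[GwasSummary, GwasSummary, GwasSummary]:
    """Generate the (exposure, mediator, outcome) GWAS summary triple.

    Three disjoint cohorts are drawn with the same variants and allele
    assignments; all randomness flows from ``cfg.seed`` through a single
    generator, so identical configs give byte-identical summary tables.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_snps + cfg.n_snps_mediator
    mafs = rng.uniform(*cfg.maf_range, size=m)
    if cfg.ld_block_size:
        # same maf within a block so the copy construction preserves HWE
        for start in range(0, m, cfg.ld_block_size):
            mafs[start : start + cfg.ld_block_size] = mafs[start]
    ids = [f"rs{i + 1:05d}" for i in range(m)]
    alleles = [(_ALLELE_PAIRS[k]) for k in rng.integers(0, len(_ALLELE_PAIRS), size=m)]

    # per-SD-of-genotype effects -> per-allele effects
    sd_g = np.sqrt(2 * mafs * (1 - mafs))
    gamma = np.zeros(m)
    gamma[: cfg.n_snps] = _two_tier_effects(
        rng, cfg.n_snps, cfg.h2_exposure, cfg.strong_fraction, cfg.strong_h2_share
    )
    delta = np.zeros(m)
    if cfg.n_snps_mediator and cfg.h2_mediator > 0:
        delta[cfg.n_snps :] = _two_tier_effects(
            rng, cfg.n_snps_mediator, cfg.h2_mediator, cfg.strong_fraction, cfg.strong_h2_share
        )
    gamma_allele = gamma / sd_g
    delta_allele = delta / sd_g

    # Horizontal pleiotropy applies to the exposure's instruments (the
    # variants whose validity the sensitivity analyses interrogate).
    # "Directional" means a positive mean relative to the exposure-increasing
    # allele, the orientation in which the Egger intercept is defined;
    # without that anchoring, random instrument signs would cancel the mean.
    alpha_allele = np.zeros(m)
    if cfg.pleiotropy_mode != "none" and cfg.pleiotropy_sd > 0:
        draw = rng.normal(0.0, cfg.pleiotropy_sd, size=cfg.n_snps)
        if cfg.pleiotropy_mode == "directional":
            # shift three SDs so essentially every direct effect shares the
            # sign of the exposure-increasing allele (pure directionality)
            draw = np.sign(gamma[: cfg.n_snps]) * (3.0 * cfg.pleiotropy_sd + draw)
        alpha_allele[: cfg.n_snps] = draw

    var_ex = 1.0 - cfg.h2_exposure
    var_em = 1.0 - cfg.beta1_true**2 - cfg.h2_mediator

    def draw_traits(n: int):
        g = _genotypes(rng, n, mafs, cfg.ld_block_size, cfg.ld_block_r2)
        x = g @ gamma_allele + rng.normal(0, np.sqrt(var_ex), n)
        mm = cfg.beta1_true * x + g @ delta_allele + rng.normal(0, np.sqrt(var_em), n)
        return g, x, mm

    g1, x1, _ = draw_traits(cfg.n_exposure_cohort)
    exposure = _make_summary(_linear_gwas(g1, x1), ids, alleles, "exposure", False)
    del g1, x1

    g2, _, m2 = draw_traits(cfg.n_mediator_cohort)
    mediator = _make_summary(_linear_gwas(g2, m2), ids, alleles, "mediator", False)
    del g2, m2

    g3, x3, m3 = draw_traits(cfg.n_outcome_cohort)
    liability = cfg.direct_true * x3 + cfg.beta2_true * m3 + g3 @ alpha_allele
    probs = _calibrated_probs(liability, cfg.outcome_prevalence)
    y = (rng.random(cfg.n_outcome_cohort) < probs).astype(np.float64)
    outcome = _make_summary(
        _logistic_score_gwas(g3, y), ids, alleles, "outcome", True, "female"
    )
    return exposure, mediator, outcome


def ld_matrix(
    cfg: SimConfig, block_r2: float | None = None, block_size: int | None = None
) -> LDMatrix:
    """Pairwise r^2 lookup matching :func:`simulate_cohorts`' genotypes.

    Default is the identity structure (all off-diagonal r^2 = 0, the LD-free
    genotypes the generator draws).  With block correlation, pairs involving
    a block's base variant have r^2 = block_r2 and other within-block pairs
    block_r2^2, mirroring the copy construction in the generator.
    """
    if block_r2 is None:
        block_r2 = cfg.ld_block_r2 if cfg.ld_block_size else 0.0
    if block_size is None:
        block_size = cfg.ld_block_size or 1
    m = cfg.n_snps + cfg.n_snps_mediator
    ids = [f"rs{i + 1:05d}" for i in range(m)]
    r2 = np.zeros((m, m))
    if block_r2 > 0 and block_size > 1:
        for start in range(0, m, block_size):
            stop = min(start + block_size, m)
            for i in range(start, stop):
                for j in range(i + 1, stop):
                    val = block_r2 if (i == start or j == start) else block_r2**2
                    r2[i, j] = r2[j, i] = val
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(ids, r2)


# ---------------------------------------------------------------------------
# multi-exposure generator (shared genetic factor)


@dataclass
class MultiExposureConfig:
    """Correlated co-exposure model for the multivariable design.

    ``n_exposures`` traits load on one shared genetic factor (heritable
    component h2_common, loadings per trait) and each carries its own unique
    instruments (h2_unique); only the exposures with nonzero entries in
    ``causal`` affect the binary outcome.  This reproduces the qualitative
    situation of genetically correlated traits (e.g. schooling,
    qualifications, cognition) where univariable MR flags all of them and
    only multivariable MR isolates the truly causal one.
    """

    n_exposures: int = 3
    n_common: int = 40
    n_unique: int = 20
    h2_common: float = 0.15
    loadings: tuple[float, ...] = (0.9, 0.9, 0.9)
    h2_unique: float = 0.06
    causal: tuple[float, ...] = (-0.46, 0.0, 0.0)
    n_cohort: int = 20_000
    n_outcome_cohort: int = 20_000
    outcome_prevalence: float = 0.055
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.loadings) != self.n_exposures or len(self.causal) != self.n_exposures:
            raise ConfigurationError("loadings and causal must have n_exposures entries")
        for lam in self.loadings:
            if lam**2 * self.h2_common + self.h2_unique >= 1:
                raise ConfigurationError("per-exposure genetic variance must be < 1")


def simulate_multi_exposure(
    cfg: MultiExposureConfig,
) -> tuple[list[GwasSummary], GwasSummary]:
    """Generate per-exposure GWASs (disjoint cohorts) and the outcome GWAS."""
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_exposures
    m = cfg.n_common + k * cfg.n_unique
    mafs = rng.uniform(*cfg.maf_range, size=m)
    ids = [f"rs{i + 1:05d}" for i in range(m)]
    alleles = [(_ALLELE_PAIRS[j]) for j in rng.integers(0, len(_ALLELE_PAIRS), size=m)]
    sd_g = np.sqrt(2 * mafs * (1 - mafs))

    # shared factor effects (variance h2_common) and per-exposure unique effects
    c = np.zeros(m)
    c[: cfg.n_common] = np.sqrt(cfg.h2_common / cfg.n_common) * rng.choice(
        [-1.0, 1.0], cfg.n_common
    )
    uniq = []
    for e in range(k):
        u = np.zeros(m)
        start = cfg.n_common + e * cfg.n_unique
        u[start : start + cfg.n_unique] = np.sqrt(cfg.h2_unique / cfg.n_unique) * rng.choice(
            [-1.0, 1.0], cfg.n_unique
        )
        uniq.append(u)

    def draw_exposures(n: int):
        g = _genotypes(rng, n, mafs)
        common = g @ (c / sd_g)
        es = []
        for e in range(k):
            var_noise = 1.0 - cfg.loadings[e] ** 2 * cfg.h2_common - cfg.h2_unique
            es.append(
                cfg.loadings[e] * common
                + g @ (uniq[e] / sd_g)
                + rng.normal(0, np.sqrt(var_noise), n)
            )
        return g, es

    summaries = []
    for e in range(k):
        g, es = draw_exposures(cfg.n_cohort)
        summaries.append(
            _make_summary(_linear_gwas(g, es[e]), ids, alleles, f"exposure_{e + 1}", False)
        )
        del g, es

    g, es = draw_exposures(cfg.n_outcome_cohort)
    liability = sum(cfg.causal[e] * es[e] for e in range(k))
    probs = _calibrated_probs(np.asarray(liability), cfg.outcome_prevalence)
    y = (rng.random(cfg.n_outcome_cohort) < probs).astype(np.float64)
    outcome = _make_summary(_logistic_score_gwas(g, y), ids, alleles, "outcome", True)
    return summaries, outcome
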