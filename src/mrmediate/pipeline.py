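"""Config-driven orchestration of the two-stage study design.

Stage 1 screens exposures against the outcome with univariable MR (all
requested methods) and, when several exposures are supplied, estimates each
exposure's direct effect with MVMR adjusted for each co-exposure and for all
jointly.  Stage 2 runs two-step MR mediation for each mediator and emits a
publication-style mediation table.

Outputs are TSV (with a provenance header: config hash, seed, package
version) plus a full-precision JSON sidecar; row order is deterministic
(sorted by exposure label, then adjustment, then method).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .estimators import ivw, mr_egger, to_odds_ratio, weighted_median
from .mediation import MediationResult, mediation_table, two_step_mediation
from .mvmr import mvmr_ivw
from .presso import MRPresso
from .summary import (
    GwasSummary,
    InstrumentCriteria,
    LDMatrix,
    harmonize,
    read_exclusion_list,
    read_gwas_table,
    select_instruments,
)

logger = logging.getLogger("mrmediate")

__all__ = ["StudyConfig", "run_stage1", "run_stage2", "run_study"]

KNOWN_METHODS = ("ivw", "egger", "weighted_median", "presso")


@dataclass
class StudyConfig:
    """Declarative description of a full two-stage analysis."""

    exposures: list[str]
    outcome: str
    mediators: list[str] = field(default_factory=list)
    criteria: InstrumentCriteria = field(default_factory=InstrumentCriteria)
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median")
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int | None = 0
    output_dir: str = "results"
    simulate: dict | None = None
    sources: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcome:
            raise ConfigurationError("at least one exposure and one outcome required")
        unknown = set(self.methods) - set(KNOWN_METHODS)
        if unknown:
            raise ConfigurationError(f"unknown methods: {sorted(unknown)}")
        stochastic = {"weighted_median", "presso"} & set(self.methods)
        if stochastic and self.seed is None:
            raise ConfigurationError(
                f"seed required for stochastic methods {sorted(stochastic)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        crit = raw.pop("criteria", None)
        cfg = cls(**raw)
        if crit:
            if "exclusion_list" in crit and isinstance(crit["exclusion_list"], str):
                crit["exclusion_list"] = read_exclusion_list(crit["exclusion_list"])
            cfg.criteria = InstrumentCriteria(**crit)
        if isinstance(cfg.methods, list):
            cfg.methods = tuple(cfg.methods)
        return cfg

    def config_hash(self) -> str:
        # output_dir is not part of the analysis; equal analyses hash equal
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k not in ("criteria", "output_dir")
        }
        payload["criteria"] = {
            "p_threshold": self.criteria.p_threshold,
            "ld_r2_max": self.criteria.ld_r2_max,
            "clump_window_kb": self.criteria.clump_window_kb,
            "exclusion_list": list(self.criteria.exclusion_list),
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _uvmr_rows(
    label: str,
    h,
    methods: tuple[str, ...],
    seed: int,
    n_boot: int,
    n_sim: int,
) -> list[dict]:
    rows = []
    estimates = []
    if "ivw" in methods or not methods:
        estimates.append(ivw(h))
    if "egger" in methods and h.n_snp >= 3:
        estimates.append(mr_egger(h))
    if "weighted_median" in methods and h.n_snp >= 3:
        estimates.append(weighted_median(h, n_boot=n_boot, seed=seed))
    for e in estimates:
        row = {
            "exposure": label,
            "adjusted_for": "none",
            "method": e.method,
            "n_snp": e.n_snp,
            "beta": e.beta,
            "se": e.se,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "pval": e.pval,
            "q_stat": e.q_stat,
            "q_pval": e.q_pval,
            "egger_intercept": e.egger_intercept,
            "egger_intercept_pval": e.egger_intercept_pval,
        }
        if e.outcome_binary:
            orr = to_odds_ratio(e)
            row.update(
                odds_ratio=orr.odds_ratio, or_ci_low=orr.ci_low, or_ci_high=orr.ci_high
            )
        rows.append(row)
    if "presso" in methods and h.n_snp >= 4:
        pr = MRPresso(n_sim=n_sim, seed=seed).fit(h)
        res = pr.result_
        corrected = res.corrected
        rows.append(
            {
                "exposure": label,
                "adjusted_for": "none",
                "method": "mr_presso",
                "n_snp": h.n_snp,
                "beta": corrected.beta if corrected else np.nan,
                "se": corrected.se if corrected else np.nan,
                "ci_low": corrected.ci_low if corrected else np.nan,
                "ci_high": corrected.ci_high if corrected else np.nan,
                "pval": corrected.pval if corrected else np.nan,
                "presso_global_pval": res.global_pval,
                "presso_n_outliers": len(res.outlier_ids),
                "presso_distortion_pval": res.distortion_pval,
            }
        )
    return rows


def run_stage1(
    exposures: dict[str, GwasSummary],
    outcome: GwasSummary,
    criteria: InstrumentCriteria | None = None,
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median"),
    ld: LDMatrix | None = None,
    seed: int = 0,
    n_boot: int = 1000,
    n_sim: int = 1000,
) -> pd.DataFrame:
    """Univariable screen of every exposure plus the MVMR adjustment grid.

    With a single exposure the output reduces to a univariable table; with
    several, each exposure is additionally adjusted for each co-exposure
    pairwise and for all co-exposures jointly.
    """
    criteria = criteria or InstrumentCriteria()
    rows: list[dict] = []
    instruments = {
        label: select_instruments(s, criteria, ld) for label, s in exposures.items()
    }
    for label, summary in exposures.items():
        h = harmonize([summary], outcome, variant_ids=instruments[label])
        rows.extend(_uvmr_rows(label, h, methods, seed, n_boot, n_sim))

    labels = list(exposures)
    if len(labels) >= 2:
        subsets = [list(pair) for pair in _pairs(labels)]
        if len(labels) > 2:
            subsets.append(labels)
        for subset in subsets:
            union: list[str] = []
            for lab in subset:
                union.extend(instruments[lab])
            union = list(dict.fromkeys(union))
            h = harmonize(
                [exposures[lab] for lab in subset], outcome, variant_ids=union
            )
            fit = mvmr_ivw(h)
            for i, lab in enumerate(subset):
                adj = "+".join(l for l in subset if l != lab)
                row = {
                    "exposure": lab,
                    "adjusted_for": adj,
                    "method": "mvmr_ivw",
                    "n_snp": fit.n_snp,
                    "beta": float(fit.direct_beta[i]),
                    "se": float(fit.direct_se[i]),
                    "ci_low": float(fit.ci_low[i]),
                    "ci_high": float(fit.ci_high[i]),
                    "pval": float(fit.direct_pval[i]),
                    "q_stat": fit.q_validity,
                    "q_pval": fit.q_pval,
                    "conditional_f": float(fit.conditional_f[i])
                    if fit.conditional_f is not None
                    else np.nan,
                }
                if outcome.is_binary:
                    row.update(
                        odds_ratio=float(np.exp(fit.direct_beta[i])),
                        or_ci_low=float(np.exp(fit.ci_low[i])),
                        or_ci_high=float(np.exp(fit.ci_high[i])),
                    )
                rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["exposure", "adjusted_for", "method"], kind="mergesort"
    ).reset_index(drop=True)


def _pairs(labels: list[str]):
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            yield a, b


def run_stage2(
    exposure: GwasSummary,
    mediators: dict[str, GwasSummary],
    outcome: GwasSummary,
    criteria: InstrumentCriteria | None = None,
    ld: LDMatrix | None = None,
    seed: int = 0,
) -> tuple[list[MediationResult], pd.DataFrame]:
    """Two-step MR mediation for each mediator; returns results and the
    formatted mediation table (empty table for zero mediators)."""
    results: list[MediationResult] = []
    for label in sorted(mediators):
        logger.info("mediation via %s", label)
        results.append(
            two_step_mediation(
                exposure, mediators[label], outcome, criteria, ld=ld, seed=seed
            )
        )
    if not results:
        logger.warning("no mediators supplied; stage 2 table is empty")
        return [], pd.DataFrame(
            columns=[
                "mediator", "beta1", "se_beta1", "beta2", "se_beta2",
                "indirect", "ci_low", "ci_high", "se_indirect", "pval",
                "classification",
            ]
        )
    return results, mediation_table(results)


def _provenance(cfg: StudyConfig) -> list[str]:
    return [
        f"# mrmediate {__version__}",
        f"# config_hash: {cfg.config_hash()}",
        f"# seed: {cfg.seed}",
    ]


def _write(df: pd.DataFrame, path: Path, header: list[str]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(
            {"provenance": header, "rows": df.replace({np.nan: None}).to_dict("records")},
            fh,
            indent=1,
            default=str,
        )


def _load_data(cfg: StudyConfig):
    """Resolve GwasSummary objects from the simulate block or file sources."""
    data: dict[str, GwasSummary] = {}
    if cfg.simulate is not None:
        from .simulate import SimConfig, simulate_cohorts

        sim = dict(cfg.simulate)
        sim.setdefault("seed", cfg.seed or 0)
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        exp, med, out = simulate_cohorts(SimConfig(**sim))
        data[exp.trait] = exp
        data[med.trait] = med
        data[out.trait] = out
    for label, src in cfg.sources.items():
        data[label] = read_gwas_table(
            src["path"],
            column_map=src.get("column_map"),
            trait=label,
            is_binary=bool(src.get("is_binary", False)),
            sex_restriction=src.get("sex_restriction", "all"),
            sep=src.get("sep", "\t"),
        )
    missing = [
        lab
        for lab in [*cfg.exposures, *cfg.mediators, cfg.outcome]
        if lab not in data
    ]
    if missing:
        raise ConfigurationError(f"no data source for traits: {missing}")
    return data


def run_study(cfg: StudyConfig, ld: LDMatrix | None = None) -> dict[str, pd.DataFrame]:
    """Run the full two-stage design and write outputs to cfg.output_dir."""
    data = _load_data(cfg)
    outdir = Path(cfg.output_dir)
    header = _provenance(cfg)
    out: dict[str, pd.DataFrame] = {}

    stage1 = run_stage1(
        {lab: data[lab] for lab in cfg.exposures},
        data[cfg.outcome],
        cfg.criteria,
        cfg.methods,
        ld=ld,
        seed=cfg.seed or 0,
        n_boot=cfg.n_boot,
        n_sim=cfg.n_sim,
    )
    _write(stage1, outdir / "stage1.tsv", header)
    out["stage1"] = stage1

    if cfg.mediators:
        _, table = run_stage2(
            data[cfg.exposures[0]],
            {lab: data[lab] for lab in cfg.mediators},
            data[cfg.outcome],
            cfg.criteria,
            ld=ld,
            seed=cfg.seed or 0,
        )
    else:
        _, table = run_stage2(
            data[cfg.exposures[0]], {}, data[cfg.outcome], cfg.criteria, seed=cfg.seed or 0
        )
    _write(table, outdir / "stage2.tsv", header)
    out["stage2"] = table
    logger.info("study outputs written to %s", outdir)
    return out
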