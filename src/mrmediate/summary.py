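"""GWAS summary statistics: ingestion, validation, harmonization, instrument selection.

The canonical in-memory container for one trait's summary statistics is
:class:`GwasSummary`, a thin wrapper around a :class:`pandas.DataFrame` with
one row per variant and columns

    variant_id, effect_allele, other_allele, eaf, beta, se, pval, n
    (+ optional chrom, pos)

``beta`` is the additive per-effect-allele effect: per SD of the trait for
continuous traits, log-odds for binary traits.  Harmonization expresses every
trait's effect for a shared variant relative to the same effect allele so that
instrument-level effect matrices can be assembled (:class:`HarmonizedSet`);
instrument selection implements p-value thresholding plus greedy LD clumping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    EmptyInputError,
    EmptySelectionError,
)

__all__ = [
    "GwasSummary",
    "HarmonizedSet",
    "InstrumentCriteria",
    "LDMatrix",
    "DROP_REASONS",
    "read_gwas_table",
    "read_exclusion_list",
    "harmonize",
    "select_instruments",
    "f_statistics",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Fixed enumeration of reasons a shared candidate variant can be dropped
#: during harmonization / selection.  ``not_in_exposure`` covers multivariable
#: harmonization where a variant is absent from a secondary exposure.
DROP_REASONS = frozenset(
    {
        "not_in_outcome",
        "not_in_exposure",
        "palindromic_ambiguous",
        "allele_mismatch",
        "excluded_confounder",
        "clumped",
    }
)

CANONICAL_COLUMNS = ("variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")
OPTIONAL_COLUMNS = ("chrom", "pos")


def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


@dataclass
class GwasSummary:
    """Validated summary statistics for a single trait.

    Rows failing basic invariants (se <= 0, identical alleles, p outside
    (0, 1], |beta/se| inconsistent with p) are removed at construction and
    tallied in :attr:`drop_counts`.
    """

    trait: str
    data: pd.DataFrame
    is_binary: bool = False
    sex_restriction: str = "all"
    drop_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex_restriction not in ("female", "all"):
            raise ConfigurationError(
                f"sex_restriction must be 'female' or 'all', got {self.sex_restriction!r}"
            )
        self.data, self.drop_counts = _validate_rows(self.data)
        if self.data["variant_id"].duplicated().any():
            dupes = self.data.loc[self.data["variant_id"].duplicated(), "variant_id"].tolist()
            raise ConfigurationError(f"duplicate variant_id in {self.trait!r}: {dupes[:5]}")
        if len(self.data) == 0:
            raise EmptyInputError(f"no valid rows for trait {self.trait!r}")
        self.data = self.data.reset_index(drop=True)

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.data["variant_id"])

    def subset(self, variant_ids: Iterable[str]) -> "GwasSummary":
        """Restrict to the given variants (order of appearance preserved)."""
        keep = self.data[self.data["variant_id"].isin(set(variant_ids))].copy()
        return dataclasses.replace(self, data=keep, drop_counts={})

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing mandatory columns: {missing}")
    df = df.copy()
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    counts: dict[str, int] = {}

    def _drop(mask: pd.Series, reason: str) -> pd.Series:
        k = int(mask.sum())
        if k:
            counts[reason] = counts.get(reason, 0) + k
        return ~mask

    keep = pd.Series(True, index=df.index)
    keep &= _drop(~df["effect_allele"].isin(VALID_ALLELES) | ~df["other_allele"].isin(VALID_ALLELES), "invalid_allele")
    keep &= _drop(keep & (df["effect_allele"] == df["other_allele"]), "identical_alleles")
    keep &= _drop(keep & (~np.isfinite(df["beta"])), "missing_beta")
    keep &= _drop(keep & (~(df["se"] > 0)), "nonpositive_se")
    keep &= _drop(keep & (~((df["pval"] > 0) & (df["pval"] <= 1))), "invalid_pval")
    keep &= _drop(keep & (~(df["n"] > 0)), "nonpositive_n")
    keep &= _drop(keep & df["eaf"].notna() & ~df["eaf"].between(0, 1), "invalid_eaf")

    # p must agree with the two-sided normal p of beta/se to 10% relative
    # error; skipped in the extreme tail where the comparison underflows.
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(df["beta"] / df["se"])
        expected = 2.0 * stats.norm.sf(z)
    checkable = keep & (df["pval"] > 1e-280) & (expected > 1e-280)
    rel = np.abs(df["pval"] - expected) / expected
    keep &= _drop(checkable & (rel > 0.10), "inconsistent_pval")

    return df.loc[keep], counts


def read_gwas_table(
    path,
    column_map: Mapping[str, str] | None = None,
    trait: str = "trait",
    is_binary: bool = False,
    sex_restriction: str = "all",
    sep: str = "\t",
) -> GwasSummary:
    """Read a delimited summary-statistics file into a :class:`GwasSummary`.

    Parameters
    ----------
    column_map
        Mapping from canonical names (``variant_id`` ...) to the file's
        column names.  Canonical names absent from the map are assumed to be
        used verbatim in the file.
    """
    raw = pd.read_csv(path, sep=sep)
    column_map = dict(column_map or {})
    rename = {}
    for canon in CANONICAL_COLUMNS + OPTIONAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon in CANONICAL_COLUMNS:
            raise ConfigurationError(
                f"column {src!r} (for {canon!r}) not found in {path}"
            )
    df = raw.rename(columns=rename)[list(rename.values())]
    return GwasSummary(
        trait=trait, data=df, is_binary=is_binary, sex_restriction=sex_restriction
    )


def read_exclusion_list(path) -> list[str]:
    """Plain-text exclusion list: one variant_id per line, '#' comments."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


@dataclass
class InstrumentCriteria:
    """Instrument-selection thresholds.

    Defaults follow standard practice: genome-wide significance 5e-8 and
    clumping to pairwise r^2 <= 0.001 within a 10,000 kb window.
    """

    p_threshold: float = 5e-8
    ld_r2_max: float = 0.001
    clump_window_kb: float = 10_000.0
    exclusion_list: Sequence[str] = ()

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if not (0 <= self.ld_r2_max <= 1):
            raise ConfigurationError("ld_r2_max must be in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ConfigurationError("clump_window_kb must be positive")


class LDMatrix:
    """Pairwise r^2 lookup for a set of variants.

    Pairs not covered by the matrix are treated as unlinked (r^2 = 0), which
    is the correct default for the LD-free synthetic genotypes.
    """

    def __init__(self, variant_ids: Sequence[str], r2: np.ndarray | None = None):
        self.variant_ids = list(variant_ids)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if r2 is None:
            r2 = np.zeros((len(self.variant_ids), len(self.variant_ids)))
        r2 = np.asarray(r2, dtype=float)
        if r2.shape != (len(self.variant_ids),) * 2:
            raise ConfigurationError("r2 matrix shape does not match variant_ids")
        if not np.allclose(r2, r2.T):
            raise ConfigurationError("r2 matrix must be symmetric")
        if (r2 < 0).any() or (r2 > 1).any():
            raise ConfigurationError("r2 values must lie in [0, 1]")
        self.matrix = r2
        np.fill_diagonal(self.matrix, 1.0)

    def r2(self, a: str, b: str) -> float:
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.matrix[ia, ib])


def select_instruments(
    summary: GwasSummary,
    criteria: InstrumentCriteria | None = None,
    ld: LDMatrix | None = None,
) -> list[str]:
    """Select approximately independent genome-wide-significant instruments.

    Greedy clumping: candidates below ``p_threshold`` (and not excluded) are
    visited in order of ascending p-value; a candidate is accepted iff its
    r^2 with every already-accepted variant inside the clump window is at
    most ``ld_r2_max``.  When positions are absent the window is ignored and
    every accepted variant is compared (conservative).
    """
    criteria = criteria or InstrumentCriteria()
    df = summary.data
    excl = set(criteria.exclusion_list)
    cand = df[(df["pval"] < criteria.p_threshold) & ~df["variant_id"].isin(excl)]
    if len(cand) == 0:
        raise EmptySelectionError(
            f"no variant passes p < {criteria.p_threshold:g} for trait {summary.trait!r}"
        )
    # deterministic tie-break on variant_id
    cand = cand.sort_values(["pval", "variant_id"], kind="mergesort")
    have_pos = "pos" in cand.columns and "chrom" in cand.columns and cand["pos"].notna().all()
    window = criteria.clump_window_kb * 1_000.0

    accepted: list[pd.Series] = []
    for _, row in cand.iterrows():
        ok = True
        for acc in accepted:
            if have_pos:
                same_chrom = acc["chrom"] == row["chrom"]
                # 1-based inclusive window on both ends
                close = same_chrom and abs(acc["pos"] - row["pos"]) <= window
                if not close:
                    continue
            r2 = ld.r2(acc["variant_id"], row["variant_id"]) if ld is not None else 0.0
            if r2 > criteria.ld_r2_max:
                ok = False
                break
        if ok:
            accepted.append(row)
    return [row["variant_id"] for row in accepted]


# ---------------------------------------------------------------------------
# harmonization


@dataclass
class HarmonizedSet:
    """Instrument-aligned effect matrices for exposure(s) and outcome.

    ``beta_exposure`` / ``se_exposure`` have shape (n_snp, k); the outcome
    vectors have length n_snp.  ``table`` keeps per-variant aligned records
    (alleles, eafs, per-trait effects) for serialization and re-harmonization.
    ``dropped`` records every shared candidate that was not retained, each
    with exactly one reason from :data:`DROP_REASONS`.
    """

    exposures: list[str]
    outcome: str
    variant_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    dropped: list[tuple[str, str]]
    table: pd.DataFrame
    outcome_binary: bool = False

    @property
    def n_snp(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return self.beta_exposure.shape[1]

    def subset(self, keep: Sequence[str] | np.ndarray) -> "HarmonizedSet":
        """Restrict to a subset of variants (boolean mask or id list)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            mask = keep
        else:
            wanted = set(keep)
            mask = np.array([v in wanted for v in self.variant_ids])
        ids = [v for v, m in zip(self.variant_ids, mask) if m]
        return HarmonizedSet(
            exposures=self.exposures,
            outcome=self.outcome,
            variant_ids=ids,
            beta_exposure=self.beta_exposure[mask],
            se_exposure=self.se_exposure[mask],
            beta_outcome=self.beta_outcome[mask],
            se_outcome=self.se_outcome[mask],
            dropped=list(self.dropped),
            table=self.table[mask].reset_index(drop=True),
            outcome_binary=self.outcome_binary,
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def drop_log(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped, columns=["variant_id", "reason"])


def _orient(
    row: pd.Series, target_ea: str, target_oa: str, eaf_tol: float
) -> tuple[float, float, float | None] | str:
    """Align one record to the target effect/other allele pair.

    Returns (beta, se, eaf) after alignment, or a drop reason string.
    """
    ea, oa = row["effect_allele"], row["other_allele"]
    beta, se = float(row["beta"]), float(row["se"])
    eaf = float(row["eaf"]) if pd.notna(row["eaf"]) else None

    if _is_palindromic(target_ea, target_oa):
        if {ea, oa} != {target_ea, target_oa}:
            return "allele_mismatch"
        # Strand is unidentifiable from alleles alone; infer from eaf when it
        # is informative on both sides, otherwise drop as ambiguous.
        if eaf is None or abs(eaf - 0.5) <= eaf_tol:
            return "palindromic_ambiguous"
        target_eaf = row.get("_target_eaf")
        if target_eaf is None or pd.isna(target_eaf) or abs(target_eaf - 0.5) <= eaf_tol:
            return "palindromic_ambiguous"
        if ea == target_ea:  # letters already aligned
            aligned_beta, aligned_eaf = beta, eaf
        else:  # letters swapped
            aligned_beta, aligned_eaf = -beta, 1.0 - eaf
        # opposite-strand report shows the complementary frequency
        if (aligned_eaf < 0.5) != (target_eaf < 0.5):
            aligned_beta, aligned_eaf = -aligned_beta, 1.0 - aligned_eaf
        return aligned_beta, se, aligned_eaf

    if (ea, oa) == (target_ea, target_oa):
        return beta, se, eaf
    if (ea, oa) == (target_oa, target_ea):
        return -beta, se, (None if eaf is None else 1.0 - eaf)
    cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
    if (cea, coa) == (target_ea, target_oa):
        return beta, se, eaf
    if (cea, coa) == (target_oa, target_ea):
        return -beta, se, (None if eaf is None else 1.0 - eaf)
    return "allele_mismatch"


def harmonize(
    exposures: Sequence[GwasSummary] | GwasSummary,
    outcome: GwasSummary,
    palindromic_eaf_tol: float = 0.08,
    variant_ids: Sequence[str] | None = None,
    exclusion_list: Sequence[str] = (),
) -> HarmonizedSet:
    """Align exposure and outcome effects to a common effect allele.

    Candidates are the variants of the first exposure (optionally restricted
    to ``variant_ids``, e.g. a selected instrument list).  For each candidate
    present in every trait, all effects are re-expressed relative to the first
    exposure's effect allele: swapped alleles flip the sign of beta and
    complement eaf; strand-complement pairs (A<->T, C<->G) are complemented
    then aligned.  Palindromic variants are resolved through allele
    frequency when it is informative on both sides and dropped as ambiguous
    otherwise.  Irreconcilable allele pairs are dropped, never raised.
    """
    if isinstance(exposures, GwasSummary):
        exposures = [exposures]
    exposures = list(exposures)
    if not exposures:
        raise ConfigurationError("at least one exposure is required")
    first = exposures[0]
    excl = set(exclusion_list)

    cand_ids = list(first.variant_ids)
    if variant_ids is not None:
        wanted = set(variant_ids)
        cand_ids = [v for v in cand_ids if v in wanted]

    indexed = [s.data.set_index("variant_id") for s in exposures[1:]]
    out_ix = outcome.data.set_index("variant_id")

    dropped: list[tuple[str, str]] = []
    rows: list[dict] = []
    first_ix = first.data.set_index("variant_id")
    for vid in cand_ids:
        if vid in excl:
            dropped.append((vid, "excluded_confounder"))
            continue
        if vid not in out_ix.index:
            dropped.append((vid, "not_in_outcome"))
            continue
        if any(vid not in ix.index for ix in indexed):
            dropped.append((vid, "not_in_exposure"))
            continue
        base = first_ix.loc[vid]
        tea, toa = base["effect_allele"], base["other_allele"]
        base_eaf = float(base["eaf"]) if pd.notna(base["eaf"]) else None
        if _is_palindromic(tea, toa) and (
            base_eaf is None or abs(base_eaf - 0.5) <= palindromic_eaf_tol
        ):
            dropped.append((vid, "palindromic_ambiguous"))
            continue

        rec = {
            "variant_id": vid,
            "effect_allele": tea,
            "other_allele": toa,
        }
        ok = True
        reason = ""
        for label, row in [(first.trait, base)] + [
            (s.trait, ix.loc[vid]) for s, ix in zip(exposures[1:], indexed)
        ] + [(outcome.trait, out_ix.loc[vid])]:
            row = row.copy()
            row["_target_eaf"] = base_eaf
            res = _orient(row, tea, toa, palindromic_eaf_tol)
            if isinstance(res, str):
                ok, reason = False, res
                break
            b, s_, f = res
            rec[f"beta_{label}"] = b
            rec[f"se_{label}"] = s_
            rec[f"eaf_{label}"] = np.nan if f is None else f
        if not ok:
            dropped.append((vid, reason))
            continue
        rows.append(rec)

    labels = [s.trait for s in exposures]
    table = pd.DataFrame(rows)
    if len(rows):
        bx = np.column_stack([table[f"beta_{t}"].to_numpy(float) for t in labels])
        sx = np.column_stack([table[f"se_{t}"].to_numpy(float) for t in labels])
        by = table[f"beta_{outcome.trait}"].to_numpy(float)
        sy = table[f"se_{outcome.trait}"].to_numpy(float)
        ids = table["variant_id"].tolist()
    else:
        bx = np.empty((0, len(labels)))
        sx = np.empty((0, len(labels)))
        by = np.empty(0)
        sy = np.empty(0)
        ids = []
    return HarmonizedSet(
        exposures=labels,
        outcome=outcome.trait,
        variant_ids=ids,
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=by,
        se_outcome=sy,
        dropped=dropped,
        table=table,
        outcome_binary=outcome.is_binary,
    )


@dataclass
class FStatistics:
    f_values: np.ndarray
    mean_f: float
    weak_instruments: bool


def f_statistics(h: HarmonizedSet, exposure_index: int = 0) -> FStatistics:
    """Univariable instrument strength: per-variant F = (beta/se)^2.

    ``weak_instruments`` flags mean F <= 10, the conventional rule of thumb.
    The conditional (multivariable) analogue lives in :mod:`mrmediate.mvmr`.
    """
    if not 0 <= exposure_index < h.n_exposures:
        raise ConfigurationError(f"exposure_index {exposure_index} out of range")
    z = h.beta_exposure[:, exposure_index] / h.se_exposure[:, exposure_index]
    f = z**2
    mean_f = float(np.mean(f)) if len(f) else float("nan")
    return FStatistics(f_values=f, mean_f=mean_f, weak_instruments=not mean_f > 10)
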