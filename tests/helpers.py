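"""Shared builders for summary-level test fixtures."""

import numpy as np
import pandas as pd
from scipy import stats

from mrmediate.summary import GwasSummary, HarmonizedSet


def pval_of(beta, se):
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(np.asarray(beta, dtype=float) / np.asarray(se, dtype=float))
    return np.clip(2.0 * stats.norm.sf(z), 1e-300, 1.0)


def make_summary(
    trait,
    beta,
    se,
    effect_allele=None,
    other_allele=None,
    eaf=None,
    variant_ids=None,
    n=10_000,
    is_binary=False,
    pval=None,
    pos=None,
    chrom=None,
):
    beta = np.asarray(beta, dtype=float)
    m = len(beta)
    se = np.broadcast_to(np.asarray(se, dtype=float), (m,))
    df = pd.DataFrame(
        {
            "variant_id": variant_ids if variant_ids is not None else [f"rs{i + 1}" for i in range(m)],
            "effect_allele": effect_allele if effect_allele is not None else ["A"] * m,
            "other_allele": other_allele if other_allele is not None else ["G"] * m,
            "eaf": eaf if eaf is not None else np.full(m, 0.3),
            "beta": beta,
            "se": se,
            "pval": pval if pval is not None else pval_of(beta, se),
            "n": n,
        }
    )
    if pos is not None:
        df["pos"] = pos
        df["chrom"] = chrom if chrom is not None else 1
    return GwasSummary(trait=trait, data=df, is_binary=is_binary)


def make_harmonized(bx, sx, by, sy, binary=False, exposures=None, ids=None):
    """HarmonizedSet straight from effect arrays (k inferred from bx shape)."""
    bx = np.asarray(bx, dtype=float)
    if bx.ndim == 1:
        bx = bx[:, None]
    sx = np.asarray(sx, dtype=float)
    if sx.ndim == 1:
        sx = sx[:, None]
    sx = np.broadcast_to(sx, bx.shape)
    n, k = bx.shape
    ids = list(ids) if ids is not None else [f"rs{i + 1}" for i in range(n)]
    labels = exposures or [f"x{j + 1}" for j in range(k)]
    return HarmonizedSet(
        exposures=list(labels),
        outcome="y",
        variant_ids=ids,
        beta_exposure=bx,
        se_exposure=np.array(sx, dtype=float),
        beta_outcome=np.asarray(by, dtype=float),
        se_outcome=np.broadcast_to(np.asarray(sy, dtype=float), (n,)).astype(float),
        dropped=[],
        table=pd.DataFrame({"variant_id": ids}),
        outcome_binary=binary,
    )


def summary_from_harmonized_table(h, label, n=50_000):
    """Rebuild an aligned GwasSummary for one trait from a HarmonizedSet table."""
    t = h.table
    df = pd.DataFrame(
        {
            "variant_id": t["variant_id"],
            "effect_allele": t["effect_allele"],
            "other_allele": t["other_allele"],
            "eaf": t[f"eaf_{label}"],
            "beta": t[f"beta_{label}"],
            "se": t[f"se_{label}"],
            "pval": pval_of(t[f"beta_{label}"], t[f"se_{label}"]),
            "n": n,
        }
    )
    return GwasSummary(trait=label, data=df, is_binary=False)
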