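"""Ingestion, harmonization and instrument-selection behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import mrmediate as mm
from mrmediate.summary import COMPLEMENT, LDMatrix, _orient
from helpers import make_summary, pval_of, summary_from_harmonized_table


def _write_tsv(tmp_path, rows, name="gwas.tsv", columns=None):
    df = pd.DataFrame(rows)
    if columns:
        df = df.rename(columns=columns)
    path = tmp_path / name
    df.to_csv(path, sep="\t", index=False)
    return path


def _row(vid="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.02, n=1000, pval=None):
    return {
        "variant_id": vid,
        "effect_allele": ea,
        "other_allele": oa,
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "pval": pval if pval is not None else float(pval_of(beta, se)),
        "n": n,
    }


class TestReadGwasTable:
    def test_well_formed_rows_are_ingested(self, tmp_path):
        path = _write_tsv(tmp_path, [_row("rs1"), _row("rs2", beta=-0.05), _row("rs3", ea="C")])
        g = mm.read_gwas_table(path, trait="edu")
        assert len(g.data) == 3
        assert g.trait == "edu"
        assert g.drop_counts == {}

    def test_invalid_rows_dropped_with_reason_counts(self, tmp_path):
        path = _write_tsv(
            tmp_path,
            [_row("rs1"), _row("rs2", se=0.0), _row("rs3", ea="A", oa="A")],
        )
        g = mm.read_gwas_table(path)
        assert list(g.data["variant_id"]) == ["rs1"]
        assert g.drop_counts == {"nonpositive_se": 1, "identical_alleles": 1}

    def test_column_map_renames(self, tmp_path):
        mapping = {"variant_id": "SNP", "beta": "b", "se": "stderr"}
        path = _write_tsv(
            tmp_path, [_row()], columns={"variant_id": "SNP", "beta": "b", "se": "stderr"}
        )
        g = mm.read_gwas_table(path, column_map=mapping)
        assert len(g.data) == 1

    def test_missing_column_is_configuration_error(self, tmp_path):
        row = _row()
        row.pop("se")
        path = _write_tsv(tmp_path, [row])
        with pytest.raises(mm.ConfigurationError):
            mm.read_gwas_table(path)

    def test_zero_valid_rows_is_empty_input_error(self, tmp_path):
        path = _write_tsv(tmp_path, [_row(se=0.0)])
        with pytest.raises(mm.EmptyInputError):
            mm.read_gwas_table(path)

    def test_inconsistent_pval_dropped(self, tmp_path):
        path = _write_tsv(tmp_path, [_row("rs1"), _row("rs2", pval=0.9)])
        g = mm.read_gwas_table(path)
        assert g.drop_counts.get("inconsistent_pval") == 1


class TestHarmonize:
    def test_swapped_alleles_flip_sign_and_eaf(self):
        exp = make_summary("x", [0.1], 0.02, ["A"], ["G"], [0.3])
        out = make_summary("y", [0.2], 0.02, ["G"], ["A"], [0.3])
        h = mm.harmonize([exp], out)
        assert h.n_snp == 1
        assert h.beta_outcome[0] == pytest.approx(-0.2)
        assert h.table["eaf_y"][0] == pytest.approx(0.7)

    def test_strand_complement_aligns_without_flip(self):
        exp = make_summary("x", [0.1], 0.02, ["A"], ["G"], [0.3])
        out = make_summary("y", [0.2], 0.02, ["T"], ["C"], [0.3])
        h = mm.harmonize([exp], out)
        assert h.beta_outcome[0] == pytest.approx(0.2)

    def test_palindromic_near_half_eaf_dropped(self):
        exp = make_summary("x", [0.1], 0.02, ["A"], ["T"], [0.50])
        out = make_summary("y", [0.2], 0.02, ["A"], ["T"], [0.50])
        h = mm.harmonize([exp], out)
        assert h.n_snp == 0
        assert h.dropped == [("rs1", "palindromic_ambiguous")]

    def test_palindromic_informative_eaf_resolved_by_frequency(self):
        # discordant frequencies imply opposite strands: flip
        exp = make_summary("x", [0.1], 0.02, ["A"], ["T"], [0.2])
        out = make_summary("y", [0.2], 0.02, ["A"], ["T"], [0.8])
        h = mm.harmonize([exp], out)
        assert h.beta_outcome[0] == pytest.approx(-0.2)
        assert h.table["eaf_y"][0] == pytest.approx(0.2)

    def test_irreconcilable_alleles_dropped_not_raised(self):
        exp = make_summary("x", [0.1], 0.02, ["A"], ["G"], [0.3])
        out = make_summary("y", [0.2], 0.02, ["A"], ["C"], [0.3])
        h = mm.harmonize([exp], out)
        assert h.dropped == [("rs1", "allele_mismatch")]

    def test_missing_from_outcome_dropped(self):
        exp = make_summary("x", [0.1, 0.1], 0.02, variant_ids=["rs1", "rs2"])
        out = make_summary("y", [0.2], 0.02, variant_ids=["rs2"])
        h = mm.harmonize([exp], out)
        assert ("rs1", "not_in_outcome") in h.dropped
        assert h.variant_ids == ["rs2"]

    def test_exclusion_list_applied(self):
        exp = make_summary("x", [0.1, 0.1], 0.02, variant_ids=["rs1", "rs2"])
        out = make_summary("y", [0.2, 0.2], 0.02, variant_ids=["rs1", "rs2"])
        h = mm.harmonize([exp], out, exclusion_list=["rs2"])
        assert ("rs2", "excluded_confounder") in h.dropped

    def test_partition_retained_plus_dropped_equals_candidates(self):
        exp = make_summary(
            "x", [0.1] * 4, 0.02, ["A", "A", "A", "A"], ["G", "T", "G", "G"],
            [0.3, 0.5, 0.3, 0.3], variant_ids=[f"rs{i}" for i in range(4)],
        )
        out = make_summary(
            "y", [0.2] * 3, 0.02, ["A", "C", "A"], ["G", "G", "G"], [0.3, 0.3, 0.3],
            variant_ids=["rs0", "rs2", "rs3"],
        )
        h = mm.harmonize([exp], out)
        assert h.n_snp + len(h.dropped) == 4
        reasons = {r for _, r in h.dropped}
        assert reasons <= {"not_in_outcome", "palindromic_ambiguous", "allele_mismatch"}

    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from(["AG", "AC", "TC", "AT", "CG"]),
                st.booleans(),  # swap alleles in outcome
                st.booleans(),  # complement strand in outcome
                st.floats(0.05, 0.95),
                st.floats(-0.5, 0.5),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_harmonization_idempotent(self, data):
        """Re-harmonizing already-aligned summaries changes nothing."""
        exp_rows, out_rows = [], []
        for i, (pair, swap, comp, eaf, bout) in enumerate(data):
            ea, oa = pair[0], pair[1]
            exp_rows.append(_row(f"rs{i}", ea, oa, eaf, 0.1, 0.02))
            oea, ooa, oeaf, ob = ea, oa, eaf, bout
            if swap:
                oea, ooa, oeaf, ob = ooa, oea, 1 - oeaf, -ob
            if comp:
                oea, ooa = COMPLEMENT[oea], COMPLEMENT[ooa]
            out_rows.append(_row(f"rs{i}", oea, ooa, oeaf, ob, 0.02))
        exp = mm.GwasSummary("x", pd.DataFrame(exp_rows))
        out = mm.GwasSummary("y", pd.DataFrame(out_rows))
        h1 = mm.harmonize([exp], out)
        if h1.n_snp == 0:
            return
        exp2 = summary_from_harmonized_table(h1, "x")
        out2 = summary_from_harmonized_table(h1, "y")
        h2 = mm.harmonize([exp2], out2)
        assert h2.variant_ids == h1.variant_ids
        np.testing.assert_allclose(h2.beta_outcome, h1.beta_outcome)
        np.testing.assert_allclose(h2.beta_exposure, h1.beta_exposure)
        assert not h2.dropped

    def test_allele_flip_is_involution(self):
        row = pd.Series(
            {"effect_allele": "G", "other_allele": "A", "beta": 0.2, "se": 0.05, "eaf": 0.3}
        )
        b, s, f = _orient(row, "A", "G", 0.08)
        back = pd.Series(
            {"effect_allele": "A", "other_allele": "G", "beta": b, "se": s, "eaf": f}
        )
        b2, s2, f2 = _orient(back, "G", "A", 0.08)
        assert (b2, f2) == pytest.approx((0.2, 0.3))


def se_for(beta, pval):
    """Standard errors consistent with the stated two-sided normal p."""
    return np.abs(np.asarray(beta)) / sps.norm.isf(np.asarray(pval) / 2)


class TestSelectInstruments:
    def test_p_threshold_applied(self):
        pv = [1e-9, 6e-8, 1e-10]
        s = make_summary(
            "x", [0.1, 0.1, 0.1], se_for([0.1] * 3, pv),
            variant_ids=["v1", "v2", "v3"],
            pval=pv,
        )
        sel = mm.select_instruments(s, mm.InstrumentCriteria())
        assert sel == ["v3", "v1"]  # v2 fails p >= 5e-8; sorted by p

    def test_clump_prefers_smaller_p(self):
        s = make_summary(
            "x", [0.1, 0.1], se_for([0.1] * 2, [1e-9, 1e-8]),
            variant_ids=["a", "b"], pval=[1e-9, 1e-8],
        )
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert mm.select_instruments(s, mm.InstrumentCriteria(), ld) == ["a"]

    def test_empty_selection_names_trait(self):
        s = make_summary("schooling", [0.01], 0.02)
        with pytest.raises(mm.EmptySelectionError, match="schooling"):
            mm.select_instruments(s)

    def test_window_limits_ld_comparison(self):
        # same r2 but far apart on the chromosome: both kept
        s = make_summary(
            "x", [0.1, 0.1], se_for([0.1] * 2, [1e-9, 1e-8]), variant_ids=["a", "b"],
            pval=[1e-9, 1e-8], pos=[1_000, 900_000_000],
        )
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        crit = mm.InstrumentCriteria(clump_window_kb=10_000)
        assert mm.select_instruments(s, crit, ld) == ["a", "b"]

    def test_matches_independent_greedy_oracle(self, rng):
        n = 10
        pvals = rng.uniform(1e-12, 1e-7, n)
        ids = [f"v{i}" for i in range(n)]
        r2 = rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.4)
        r2 = np.triu(r2, 1)
        r2 = r2 + r2.T
        np.fill_diagonal(r2, 1.0)
        s = make_summary("x", 0.1 * np.ones(n), se_for(0.1 * np.ones(n), pvals), variant_ids=ids, pval=pvals)
        crit = mm.InstrumentCriteria(ld_r2_max=0.3)
        ld = LDMatrix(ids, r2)
        sel = mm.select_instruments(s, crit, ld)

        # independent re-implementation of thresholded, p-ranked greedy clumping
        order = np.argsort(pvals, kind="mergesort")
        oracle = []
        for i in order:
            if pvals[i] < crit.p_threshold and all(r2[i, j] <= 0.3 for j in oracle):
                oracle.append(i)
        assert sel == [ids[i] for i in oracle]
        # defining properties: mutual independence; every sub-threshold reject
        # conflicts with an accepted variant of smaller p
        idx = {v: i for i, v in enumerate(ids)}
        for a in sel:
            for b in sel:
                if a != b:
                    assert r2[idx[a], idx[b]] <= 0.3
        for v in set(ids) - set(sel):
            if pvals[idx[v]] >= crit.p_threshold:
                continue
            conflicts = [a for a in sel if r2[idx[v], idx[a]] > 0.3 and pvals[idx[a]] <= pvals[idx[v]]]
            assert conflicts

    def test_row_order_invariance(self, rng):
        n = 8
        pvals = rng.uniform(1e-12, 1e-7, n)
        ids = [f"v{i}" for i in range(n)]
        s = make_summary("x", [0.1] * n, se_for([0.1] * n, pvals), variant_ids=ids, pval=pvals)
        perm = rng.permutation(n)
        s_perm = mm.GwasSummary("x", s.data.iloc[perm].reset_index(drop=True))
        assert mm.select_instruments(s) == mm.select_instruments(s_perm)


class TestFStatistics:
    def test_per_variant_and_mean(self):
        from helpers import make_harmonized

        h = make_harmonized([0.1, 0.01], [0.01, 0.01], [0.0, 0.0], 0.1)
        fs = mm.f_statistics(h)
        np.testing.assert_allclose(fs.f_values, [100.0, 1.0])
        assert fs.mean_f == pytest.approx(50.5)
        assert not fs.weak_instruments

    def test_weak_flag_for_single_weak_instrument(self):
        from helpers import make_harmonized

        h = make_harmonized([0.01], [0.01], [0.0], 0.1)
        fs = mm.f_statistics(h)
        assert fs.mean_f == pytest.approx(1.0)
        assert fs.weak_instruments

    def test_mean_equals_mean_squared_z(self, rng):
        from helpers import make_harmonized

        bx = rng.normal(0.1, 0.05, 5)
        sx = rng.uniform(0.01, 0.05, 5)
        h = make_harmonized(bx, sx, np.zeros(5), 0.1)
        assert mm.f_statistics(h).mean_f == pytest.approx(np.mean((bx / sx) ** 2))
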