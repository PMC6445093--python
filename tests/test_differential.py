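"""Differential selection: paired t, loess, candidate and concordance rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import small_config
from oracles import concordance_rules, per_cohort_rules
from tgfbsig.differential import (
    P_DEGENERATE,
    concordant_progression_proteins,
    differential_analysis,
    loess_normalize,
    paired_t,
    per_cohort_candidates,
    protein_table,
    up_down_sets,
)
from tgfbsig.simulate import generate_plasma_cohorts


class TestPairedT:
    def test_all_pairs_equal_gives_t0_p1(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0 and not res.degenerate

    def test_constant_nonzero_difference_is_degenerate(self):
        res = paired_t([3.0, 4.0, 5.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert res.pvalue == P_DEGENERATE
        assert res.statistic == np.inf

    def test_closed_form_example(self):
        # frozen from the closed form t = mean(d)/(sd(d)/sqrt(n)), df = 3
        res = paired_t([2.0, 1.5, 3.0, 2.2], [1.0, 1.2, 2.0, 2.1])
        assert res.statistic == pytest.approx(2.558408596267, abs=1e-9)
        assert res.pvalue == pytest.approx(0.083329582162, abs=1e-9)
        assert res.df == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=3, max_size=30))
    def test_matches_scipy_on_nondegenerate_input(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        if np.std(a - b, ddof=1) == 0:
            return
        res = paired_t(a, b)
        ref = stats.ttest_rel(a, b)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-10)


class TestLoessNormalize:
    def _base(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(10, 25, size=n)   # log2 abundances

    def test_constant_offset_removed(self):
        a = self._base()
        table = pd.DataFrame({"A": 2.0 ** a, "B": 2.0 ** (a + 0.5)})
        norm = loess_normalize(table, span=0.5)
        assert np.max(np.abs(norm["B"] - norm["A"])) < 1e-6

    def test_identity_when_already_centred(self):
        a = self._base()
        table = pd.DataFrame({"A": 2.0 ** a, "B": 2.0 ** a, "C": 2.0 ** a})
        norm = loess_normalize(table, span=0.5)
        for col in table:
            assert np.max(np.abs(norm[col] - a)) < 1e-9

    def test_linear_intensity_bias_removed(self):
        # sample B has deviation 0.1 * abundance; after normalization the
        # residual trend measured by an independent LS fit must be < 0.01
        a = self._base(n=200, seed=1)
        table = pd.DataFrame({"A": 2.0 ** a, "B": 2.0 ** (a + 0.1 * (a - a.mean()))})
        norm = loess_normalize(table, span=0.4)
        dev = (norm["B"] - norm["A"]).to_numpy()
        slope = np.polyfit(a, dev, 1)[0]
        assert abs(slope) < 0.01

    def test_sample_medians_equal_reference_median(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(2.0 ** rng.uniform(8, 20, size=(80, 5)),
                             columns=list("abcde"))
        norm = loess_normalize(table)
        ref_median = np.log2(table).median(axis=1).median()
        for col in norm:
            assert norm[col].median() == pytest.approx(ref_median, abs=1e-9)

    @pytest.mark.parametrize("span", [0.0, -0.1, 1.5])
    def test_bad_span_rejected(self, span):
        table = pd.DataFrame(np.ones((12, 2)), columns=["A", "B"])
        with pytest.raises(ValueError, match="span"):
            loess_normalize(table, span=span)

    def test_nonpositive_abundance_names_rows(self):
        table = pd.DataFrame(np.ones((12, 2)), columns=["A", "B"],
                             index=[f"P{i}" for i in range(12)])
        table.loc["P3", "A"] = -1.0
        with pytest.raises(ValueError, match="P3"):
            loess_normalize(table)

    def test_too_few_proteins_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            loess_normalize(pd.DataFrame(np.ones((5, 2)), columns=["A", "B"]))


def _peptide_row(symbol, m, nm, score=9.0, n_mapped=1, pid=None):
    return {"peptide_id": pid or f"{symbol}_{m}", "protein_symbol": symbol,
            "n_mapped_proteins": n_mapped, "peptide_score": score,
            "abundance_M": m, "abundance_nonM": nm, "cohort_id": "c1"}


class TestPerCohortCandidates:
    def test_low_score_single_peptide_excluded(self):
        # score 5.9 < 6.0 excludes even a 2-fold change
        df = pd.DataFrame([_peptide_row("A", 200.0, 100.0, score=5.9)])
        out = per_cohort_candidates(df)
        assert not out.loc["A", "candidate"]
        assert out.loc["A", "reason"] == "low_score"

    def test_multi_mapped_single_peptide_excluded(self):
        df = pd.DataFrame([_peptide_row("A", 200.0, 100.0, n_mapped=3)])
        out = per_cohort_candidates(df)
        assert not out.loc["A", "candidate"]
        assert out.loc["A", "reason"] == "multi_mapped"

    def test_good_single_peptide_kept_on_fold_change_alone(self):
        df = pd.DataFrame([_peptide_row("A", 200.0, 100.0, score=6.0)])
        out = per_cohort_candidates(df)
        assert out.loc["A", "candidate"] and out.loc["A", "direction"] == "up"

    def test_fc_boundary_strict(self):
        df = pd.DataFrame([_peptide_row("A", 125.0, 100.0, score=8.0)])
        assert not per_cohort_candidates(df)["candidate"].loc["A"]

    def test_multipeptide_constant_ratio_degenerate_included(self):
        # all peptide ratios exactly 1.30: zero-noise, degenerate paired t
        df = pd.DataFrame([_peptide_row("A", 130.0, 100.0, pid="p1"),
                           _peptide_row("A", 260.0, 200.0, pid="p2"),
                           _peptide_row("A", 390.0, 300.0, pid="p3")])
        out = per_cohort_candidates(df)
        assert out.loc["A", "candidate"]
        assert out.loc["A", "direction"] == "up"
        assert out.loc["A", "degenerate"]

    def test_multipeptide_needs_significant_p(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(4):   # large scatter, mean FC ~1.5 but p >> 0.05
            nm = 100.0 * (i + 1)
            rows.append(_peptide_row("A", nm * rng.uniform(0.5, 3.0), nm,
                                     pid=f"p{i}"))
        out = per_cohort_candidates(pd.DataFrame(rows))
        res = paired_t(np.log2(pd.DataFrame(rows)["abundance_M"]),
                       np.log2(pd.DataFrame(rows)["abundance_nonM"]))
        assert out.loc["A", "candidate"] == (
            res.pvalue < 0.05 and (out.loc["A", "fc"] > 1.25
                                   or out.loc["A", "fc"] < 0.8))

    def test_matches_bruteforce_on_random_table(self):
        cohorts, _ = generate_plasma_cohorts(small_config(), seed=31)
        df = cohorts["pre_II"]
        out = per_cohort_candidates(df)
        oracle = per_cohort_rules(df)
        for symbol, (fc, cand) in oracle.items():
            assert out.loc[symbol, "fc"] == pytest.approx(fc, rel=1e-12)
            assert bool(out.loc[symbol, "candidate"]) == cand, symbol

    def test_nonpositive_abundance_rejected(self):
        df = pd.DataFrame([_peptide_row("A", -5.0, 100.0)])
        with pytest.raises(ValueError, match="positive"):
            per_cohort_candidates(df)


def _protein_tbl(rows):
    """rows: symbol -> list of 4 (M, nonM) tuples."""
    data = {}
    for c, cid in enumerate(["c1", "c2", "c3", "c4"]):
        data[(cid, "M")] = {s: v[c][0] for s, v in rows.items()}
        data[(cid, "nonM")] = {s: v[c][1] for s, v in rows.items()}
    tbl = pd.DataFrame(data)
    tbl.columns = pd.MultiIndex.from_tuples(tbl.columns,
                                            names=["cohort", "channel"])
    return tbl


class TestConcordance:
    def test_three_of_four_up(self):
        # FCs (1.3, 1.3, 1.3, 1.0), cross-cohort paired t p ~ 0.058 < 0.1
        tbl = _protein_tbl({"A": [(130, 100), (260, 200), (390, 300), (100, 100)]})
        out = concordant_progression_proteins(tbl, normalize=False)
        assert out.loc["A", "direction"] == "up"
        assert out.loc["A", "n_concordant"] == 3

    def test_opposite_direction_veto(self):
        tbl = _protein_tbl({"A": [(130, 100), (130, 100), (70, 100), (130, 100)]})
        out = concordant_progression_proteins(tbl, normalize=False)
        assert out.loc["A", "direction"] == "none"

    def test_fc_boundary_strict_at_1_25(self):
        tbl = _protein_tbl({"A": [(125, 100)] * 4})
        out = concordant_progression_proteins(tbl, normalize=False)
        assert out.loc["A", "direction"] == "none"

    def test_zero_noise_planted_truth_recovered_exactly(self, zero_noise_study):
        res = differential_analysis(zero_noise_study.cohorts)
        truth = zero_noise_study.truth
        assert res.up == set(truth.up_proteins)
        assert res.down == set(truth.down_proteins)

    def test_matches_bruteforce_rules(self):
        cohorts, _ = generate_plasma_cohorts(small_config(), seed=41)
        tbl = protein_table(cohorts)
        out = concordant_progression_proteins(tbl, normalize=False)
        oracle = concordance_rules(np.log2(tbl), list(cohorts))
        assert dict(out["direction"]) == oracle

    def test_missing_cohort_treated_nonconcordant(self):
        tbl = _protein_tbl({"A": [(200, 100)] * 4})
        tbl.loc["A", ("c4", "M")] = np.nan
        tbl.loc["A", ("c4", "nonM")] = np.nan
        out = concordant_progression_proteins(tbl, normalize=False)
        # still 3 concordant cohorts -> up; but only 3 pairs in the t-test
        assert out.loc["A", "direction"] == "up"
        assert out.loc["A", "n_concordant"] == 3

    def test_monotone_in_fc_cutoff_and_p(self, small_study):
        tbl = protein_table(small_study.cohorts)
        loose = up_down_sets(concordant_progression_proteins(tbl, fc_cutoff=1.25))
        tight_fc = up_down_sets(concordant_progression_proteins(tbl, fc_cutoff=1.5))
        tight_p = up_down_sets(concordant_progression_proteins(
            tbl, combined_p_cutoff=0.01))
        for i in (0, 1):
            assert tight_fc[i] <= loose[i]
            assert tight_p[i] <= loose[i]

    def test_up_down_disjoint_and_min_concordant(self, small_study):
        res = differential_analysis(small_study.cohorts)
        assert not res.up & res.down
        sel = res.concordant[res.concordant["direction"] != "none"]
        assert (sel["n_concordant"] >= 3).all()

    def test_bh_adjustment_shrinks_selection(self, small_study):
        tbl = protein_table(small_study.cohorts)
        raw = up_down_sets(concordant_progression_proteins(tbl))
        adj = up_down_sets(concordant_progression_proteins(tbl, adjust="bh"))
        assert adj[0] <= raw[0] and adj[1] <= raw[1]


class TestProteinTable:
    def test_reliability_filter_masks_bad_singletons(self):
        df = pd.DataFrame([
            _peptide_row("A", 150.0, 100.0, score=5.0),       # low score singleton
            _peptide_row("B", 150.0, 100.0, score=9.0),
            _peptide_row("C", 150.0, 100.0, pid="c1"),
            _peptide_row("C", 300.0, 200.0, pid="c2"),
        ])
        tbl = protein_table({"c1": df})
        assert np.isnan(tbl.loc["A", ("c1", "M")])
        assert tbl.loc["B", ("c1", "M")] == 150.0
        assert tbl.loc["C", ("c1", "M")] == 225.0   # mean of peptides
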