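"""DE filter, GO binomial test, single-cell QC gate, pattern summaries."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omnquant.selection import (de_filter, go_overrepresentation,
                                pattern_summary, sc_qc_filter)
from omnquant.synthetic import generate_de_table, generate_qc_table


def _de(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2_fold_change",
                                       "adjusted_p"])


class TestDEFilter:
    def test_passing_gene_routed_by_sign(self):
        out = de_filter(_de([("g1", 1.5, 0.001), ("g2", -1.5, 0.001)]))
        assert out["early_candidates"] == ["g1"]
        assert out["late_candidates"] == ["g2"]

    def test_fold_change_boundary_is_strict(self):
        # log2FC = 1.0 means fold change exactly 2: excluded
        out = de_filter(_de([("g1", 1.0, 0.001)]))
        assert out["early_candidates"] == []

    def test_padj_boundary_is_strict(self):
        out = de_filter(_de([("g1", 2.0, 0.01)]))
        assert out["early_candidates"] == []

    def test_spiked_table_counts(self):
        out = de_filter(generate_de_table(100, 7, 3, seed=2))
        assert len(out["early_candidates"]) == 7
        assert len(out["late_candidates"]) == 3

    def test_missing_padj_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="adjusted p"):
            out = de_filter(_de([("g1", 3.0, np.nan), ("g2", 3.0, 1e-5)]))
        assert out["early_candidates"] == ["g2"]

    def test_monotone_in_thresholds(self):
        table = generate_de_table(200, 20, 20, effect_log2fc=1.2, seed=3)
        loose = de_filter(table, fc_threshold=2, padj_threshold=0.01)
        tight_fc = de_filter(table, fc_threshold=3, padj_threshold=0.01)
        tight_p = de_filter(table, fc_threshold=2, padj_threshold=0.001)
        for key in ("early_candidates", "late_candidates"):
            assert set(tight_fc[key]) <= set(loose[key])
            assert set(tight_p[key]) <= set(loose[key])


def exact_binomial_upper_tail(k, n, q: Fraction) -> float:
    """P(X >= k) for X ~ Binomial(n, q) by exact rational summation."""
    total = sum(comb(n, j) * q ** j * (1 - q) ** (n - j)
                for j in range(k, n + 1))
    return float(total)


class TestGOOverrepresentation:
    @staticmethod
    def _toy(n_background=100, term_fraction=0.05):
        background = [f"g{i}" for i in range(n_background)]
        n_term = int(term_fraction * n_background)
        annotation = {g: {"GO:0001"} for g in background[:n_term]}
        return background, annotation

    def test_matches_exact_summation(self):
        # 10 of 50 selected genes carry a term at background frequency 0.05
        background, _ = self._toy(1000, 0.05)
        annotation = {g: {"GO:0001"} for g in background[:50]}
        selected = background[:10] + background[500:540]
        res = go_overrepresentation(selected, background, annotation)
        r = res[0]
        assert (r.k, r.n, r.K, r.N) == (10, 50, 50, 1000)
        expected = exact_binomial_upper_tail(10, 50, Fraction(50, 1000))
        assert r.p_binomial == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n=st.integers(5, 200), data=st.data())
    def test_exact_oracle_property(self, n, data):
        """Binomial upper tail matches exact rational summation to 1e-12
        for any selection size up to 200."""
        K = data.draw(st.integers(1, 40))
        N = 400
        k = data.draw(st.integers(1, min(n, K)))
        background = [f"g{i}" for i in range(N)]
        annotation = {g: {"T"} for g in background[:K]}
        # build a selection with exactly k annotated genes
        selected = background[:k] + background[K:K + (n - k)]
        res = go_overrepresentation(selected, background, annotation)
        expected = exact_binomial_upper_tail(k, n, Fraction(K, N))
        assert res[0].p_binomial == pytest.approx(expected, abs=1e-12)

    def test_selected_equals_background_never_significant(self):
        background = [f"g{i}" for i in range(20)]
        annotation = {g: {f"T{i % 4}"} for i, g in enumerate(background)}
        res = go_overrepresentation(background, background, annotation)
        for r in res:
            assert r.k / r.n == r.K / r.N
            assert r.p_bonferroni > 0.05

    def test_bonferroni_uses_tested_term_count(self):
        background = [f"g{i}" for i in range(40)]
        annotation = {background[0]: {"A"}, background[1]: {"B"},
                      background[30]: {"C"}}  # C never selected
        res = go_overrepresentation(background[:10], background, annotation)
        tested = {r.term_id for r in res}
        assert tested == {"A", "B"}
        for r in res:
            assert r.p_bonferroni == pytest.approx(
                min(1.0, r.p_binomial * 2))

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            go_overrepresentation([], ["g1"], {})

    def test_selection_outside_background_rejected(self):
        with pytest.raises(ValueError, match="not in background"):
            go_overrepresentation(["x"], ["g1"], {})

    def test_orphan_terms_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            res = go_overrepresentation(
                ["g1"], ["g1", "g2"],
                {"g1": {"A"}, "zz": {"ORPHAN"}})
        assert {r.term_id for r in res} == {"A"}


class TestSCQCFilter:
    @pytest.mark.parametrize("n_genes,mito,kept", [
        (1000, 1.0, False),   # too few genes
        (1100, 4.0, True),    # both boundaries: retained
        (15000, 0.0, True),
        (15001, 0.0, False),  # too many genes
        (5000, 5.0, False),   # too much mitochondrial signal
        (5000, 3.9, True),
    ])
    def test_gate_conventions(self, n_genes, mito, kept):
        df = pd.DataFrame({"cell_id": ["c"], "n_genes_detected": [n_genes],
                           "pct_mito": [mito]})
        assert (len(sc_qc_filter(df)) == 1) is kept

    def test_spiked_table_retains_exactly_the_passing_cells(self):
        table = generate_qc_table(84, 60, 8, 40, seed=0)
        out = sc_qc_filter(table)
        assert len(out) == 84
        assert (out["true_label"] == "pass").all()

    def test_idempotent(self):
        table = generate_qc_table(seed=1)
        once = sc_qc_filter(table)
        twice = sc_qc_filter(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_negative_counts_rejected(self):
        df = pd.DataFrame({"cell_id": ["c"], "n_genes_detected": [-1],
                           "pct_mito": [0.0]})
        with pytest.raises(ValueError):
            sc_qc_filter(df)


class TestPatternSummary:
    def test_single_dorsal_early_gene(self):
        calls = pd.DataFrame({"gene_id": ["g1"],
                              "expressed_in": ["dorsal_nIII"],
                              "predicted_category": ["early"]})
        venn, agreement = pattern_summary(calls)
        assert venn["dorsal_nIII"] == 1
        assert agreement["agrees"].all()

    def test_early_gene_outcome_counts(self):
        # 13 predicted-early probes: 10 exclusive to dorsal nIII,
        # 3 in dorsal nIII and nIV
        calls = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(13)],
            "expressed_in": ["dorsal_nIII"] * 10 + ["dorsal_nIII+nIV"] * 3,
            "predicted_category": ["early"] * 13,
        })
        venn, agreement = pattern_summary(calls)
        assert venn["dorsal_nIII"] == 10
        assert venn["dorsal_nIII+nIV"] == 3
        assert agreement["agrees"].all()

    def test_triple_intersection_counted_once(self):
        calls = pd.DataFrame({
            "gene_id": ["g1"],
            "expressed_in": ["dorsal_nIII+ventral_nIII+nIV"],
            "predicted_category": ["late"],
        })
        venn, _ = pattern_summary(calls)
        assert venn["dorsal_nIII+ventral_nIII+nIV"] == 1
        assert sum(venn.values()) == 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(
        st.sets(st.sampled_from(["dorsal_nIII", "ventral_nIII", "nIV"]),
                min_size=1, max_size=3),
        min_size=1, max_size=30))
    def test_venn_partition_property(self, region_sets):
        """Venn region counts always sum to the number of genes."""
        calls = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(region_sets))],
            "expressed_in": [frozenset(s) for s in region_sets],
            "predicted_category": ["early"] * len(region_sets),
        })
        venn, _ = pattern_summary(calls)
        assert sum(venn.values()) == len(region_sets)

    def test_empty_expression_rejected(self):
        calls = pd.DataFrame({"gene_id": ["g1"], "expressed_in": [set()],
                              "predicted_category": ["early"]})
        with pytest.raises(ValueError, match="empty"):
            pattern_summary(calls)

    def test_disagreement_detected(self):
        calls = pd.DataFrame({"gene_id": ["g1"],
                              "expressed_in": ["ventral_nIII"],
                              "predicted_category": ["early"]})
        _, agreement = pattern_summary(calls)
        assert not agreement["agrees"].any()
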