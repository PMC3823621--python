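"""Correlation screening, database intersection, interactome construction,
direction classification and overlap statistics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirglia import (
    build_interactome,
    classify_directions,
    correlate_mirna_genes,
    filter_candidates,
    intersect_targets,
    load_published_interactome,
    overlap_fractions,
    run_contrast,
)
from mirglia.io import TargetDatabase
from mirglia.targets import INVERSE, POSITIVE, sort_interactome

from conftest import make_matrix


def _paired_matrices(sheet, gene_rows, mirna_row):
    samples = sheet.sample_ids
    genes = make_matrix(gene_rows, [f"G{i}" for i in range(len(gene_rows))], samples)
    mirna = make_matrix([mirna_row], ["miR-155"], samples, "miRNA")
    return mirna, genes


class TestCorrelation:
    def test_identical_profile_r_one(self, sheet_3x3):
        profile = [1.0, 2, 3, 4, 5, 6, 0, 0, 0]
        mirna, genes = _paired_matrices(sheet_3x3, [profile], profile)
        corr = correlate_mirna_genes(mirna, genes, sheet_3x3, "miR-155", ("M1", "M0"))
        assert corr.loc["G0", "r"] == pytest.approx(1.0)
        assert corr.loc["G0", "n_samples"] == 6

    def test_negated_profile_r_minus_one(self, sheet_3x3):
        profile = [1.0, 2, 3, 4, 5, 6, 0, 0, 0]
        negated = [-v for v in profile]
        mirna, genes = _paired_matrices(sheet_3x3, [negated], profile)
        corr = correlate_mirna_genes(mirna, genes, sheet_3x3, "miR-155", ("M1", "M0"))
        assert corr.loc["G0", "r"] == pytest.approx(-1.0)

    def test_six_sample_toy_matches_reference_formula(self, sheet_3x3):
        rng = np.random.default_rng(9)
        gene_rows = rng.normal(0, 1, (5, 9))
        mirna_row = rng.normal(0, 1, 9)
        mirna, genes = _paired_matrices(sheet_3x3, gene_rows, mirna_row)
        corr = correlate_mirna_genes(mirna, genes, sheet_3x3, "miR-155", ("M1", "M0"))
        used = sheet_3x3.data["condition"].isin(["M1", "M0"]).to_numpy()
        for i in range(5):
            expected = np.corrcoef(gene_rows[i, used], mirna_row[used])[0, 1]
            assert corr.loc[f"G{i}", "r"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_flagged_r_zero(self, sheet_3x3):
        mirna, genes = _paired_matrices(sheet_3x3, [[5.0] * 9], [1.0, 2, 3, 4, 5, 6, 0, 0, 0])
        corr = correlate_mirna_genes(mirna, genes, sheet_3x3, "miR-155", ("M1", "M0"))
        assert corr.loc["G0", "r"] == 0.0
        assert corr.loc["G0", "degenerate"]

    def test_missing_mirna_raises(self, sheet_3x3):
        mirna, genes = _paired_matrices(sheet_3x3, [[0.0] * 9], [0.0] * 9)
        with pytest.raises(KeyError):
            correlate_mirna_genes(mirna, genes, sheet_3x3, "miR-999", ("M1", "M0"))


class TestFilterCandidates:
    def _tables(self, r_values, p_values):
        genes = [f"G{i}" for i in range(len(r_values))]
        corr = pd.DataFrame({"r": r_values}, index=genes)
        de = pd.DataFrame({"p_value": p_values, "log2_fold_change": 1.0}, index=genes)
        return corr, de

    def test_boundary_r_excluded_by_strict_inequality(self):
        corr, de = self._tables([0.5, -0.5, 0.51], [1e-5] * 3)
        assert filter_candidates(corr, de) == {"G2"}

    def test_significance_required(self):
        corr, de = self._tables([0.9], [0.01])
        assert filter_candidates(corr, de) == frozenset()

    def test_hand_enumerated_survivors(self):
        r = [0.9, -0.8, 0.4, 0.6, -0.55, 0.7, -0.2, 0.95, -0.99, 0.51]
        p = [1e-5, 1e-6, 1e-6, 0.2, 1e-5, 9e-5, 1e-6, 1.1e-4, 1e-9, 1e-5]
        corr, de = self._tables(r, p)
        # pass both: G0, G1, G4, G5, G8(p=1e-9), G9; G7 fails p (1.1e-4 > 1e-4)
        assert filter_candidates(corr, de) == {"G0", "G1", "G4", "G5", "G8", "G9"}


class TestIntersection:
    def test_basic_triple_intersection(self):
        db_a = TargetDatabase("a", {"miR-155": frozenset({"B", "C", "D"})})
        db_b = TargetDatabase("b", {"miR-155": frozenset({"C", "B"})})
        assert intersect_targets({"A", "B", "C"}, db_a, db_b, "miR-155") == {"B", "C"}

    def test_disjoint_sets_empty(self):
        db_a = TargetDatabase("a", {"miR-155": frozenset({"X"})})
        db_b = TargetDatabase("b", {"miR-155": frozenset({"Y"})})
        assert intersect_targets({"A"}, db_a, db_b, "miR-155") == frozenset()

    def test_missing_mirna_warns_and_empties(self):
        db_a = TargetDatabase("a", {"miR-155": frozenset({"A"})})
        db_b = TargetDatabase("b", {})
        with pytest.warns(UserWarning, match="absent from database"):
            out = intersect_targets({"A"}, db_a, db_b, "miR-155")
        assert out == frozenset()


class TestInteractome:
    def test_direction_from_correlation_sign(self):
        corr = pd.DataFrame({"r": [-0.94, 0.8]}, index=["FAM105A", "SOCS1"])
        de = pd.DataFrame(
            {"log2_fold_change": [-3.370, 2.744], "p_value": [7.86e-10, 1.96e-8]},
            index=["FAM105A", "SOCS1"],
        )
        table = build_interactome("miR-155", {"FAM105A", "SOCS1"}, corr, de)
        by_gene = table.set_index("gene_symbol")
        assert by_gene.loc["FAM105A", "direction"] == INVERSE
        assert by_gene.loc["SOCS1", "direction"] == POSITIVE

    def test_missing_candidate_raises(self):
        corr = pd.DataFrame({"r": [0.9]}, index=["A"])
        de = pd.DataFrame({"log2_fold_change": [1.0], "p_value": [1e-6]}, index=["A"])
        with pytest.raises(KeyError):
            build_interactome("miR-155", {"A", "B"}, corr, de)

    def test_empty_candidates_empty_table(self):
        corr = pd.DataFrame({"r": []})
        de = pd.DataFrame({"log2_fold_change": [], "p_value": []})
        table = build_interactome("miR-155", frozenset(), corr, de)
        assert table.empty
        assert classify_directions(table) == (0, 0)

    def test_canonical_sort_is_idempotent_on_published_table(self):
        t2 = load_published_interactome()
        once = sort_interactome(t2)
        twice = sort_interactome(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_published_order_matches_canonical_sort_up_to_one_printed_tie(self):
        """The printed table is |log2FC|-descending within each direction
        block except one adjacent pair whose magnitudes differ by 5e-4."""
        t2 = load_published_interactome()
        canonical = sort_interactome(t2)
        mismatches = [
            (a, b)
            for a, b in zip(t2["gene_symbol"], canonical["gene_symbol"])
            if a != b
        ]
        assert set(g for pair in mismatches for g in pair) <= {"TCF7L2", "RREB1"}

    def test_rebuild_from_emitted_table_is_identity(self, sheet_3x3):
        rng = np.random.default_rng(2)
        n = 12
        genes = [f"G{i}" for i in range(n)]
        corr = pd.DataFrame({"r": rng.uniform(-1, 1, n)}, index=genes)
        de = pd.DataFrame(
            {"log2_fold_change": rng.normal(0, 2, n), "p_value": rng.uniform(0, 1e-4, n)},
            index=genes,
        )
        table = build_interactome("miR-155", set(genes), corr, de)
        corr2 = table.set_index("gene_symbol").rename(columns={"correlation_factor": "r"})
        de2 = table.set_index("gene_symbol").rename(columns={"power": "p_value"})
        rebuilt = build_interactome("miR-155", set(table["gene_symbol"]), corr2, de2)
        pd.testing.assert_frame_equal(rebuilt, table)


class TestClassifyAndOverlap:
    def test_published_direction_split(self):
        t2 = load_published_interactome()
        assert classify_directions(t2) == (44, 68)

    def test_random_table_matches_sign_count(self):
        rng = np.random.default_rng(5)
        r = rng.uniform(-1, 1, 200)
        table = pd.DataFrame({"direction": np.where(r < 0, INVERSE, POSITIVE)})
        n_pos, n_neg = classify_directions(table)
        assert n_pos == int((r >= 0).sum())
        assert n_neg == int((r < 0).sum())
        assert n_pos + n_neg == len(table)

    def test_nested_sets_give_unit_fractions(self):
        c = {"A", "B"}
        stats = overlap_fractions(c, c | {"C"}, c | {"C", "D"})
        assert stats.frac_overlap_a == stats.frac_overlap_b == stats.frac_triple == 1.0

    def test_published_overlap_arithmetic(self):
        candidates = {f"G{i}" for i in range(100)}
        db_a = {f"G{i}" for i in range(18)}  # 18 shared
        # 6 shared with candidates, of which only 3 are also in db_a
        db_b = {f"G{i}" for i in range(3)} | {f"G{i}" for i in range(50, 53)}
        stats = overlap_fractions(candidates, db_a, db_b)
        assert stats.frac_overlap_a == pytest.approx(0.18)
        assert stats.frac_overlap_b == pytest.approx(0.06)
        assert stats.frac_triple == pytest.approx(0.03)

    def test_empty_candidates_flagged_undefined(self):
        stats = overlap_fractions(set(), {"A"}, {"B"})
        assert stats.undefined
        assert np.isnan(stats.frac_triple)

    @given(
        st.sets(st.integers(0, 30), max_size=20),
        st.sets(st.integers(0, 30), max_size=20),
        st.sets(st.integers(0, 30), max_size=20),
    )
    @settings(derandomize=True, max_examples=200)
    def test_triple_bounded_by_pairwise_overlaps(self, c, a, b):
        c = {str(x) for x in c}
        a = {str(x) for x in a}
        b = {str(x) for x in b}
        stats = overlap_fractions(c, a, b)
        if not stats.undefined:
            assert stats.frac_triple <= min(stats.frac_overlap_a, stats.frac_overlap_b) + 1e-12
            assert stats.n_overlap_a == len(c & a)
            assert stats.n_triple == len(c & a & b)


class TestEmittedRecordsSatisfyFilters:
    def test_post_hoc_threshold_check_on_synthetic_screen(self, small_dataset):
        d = small_dataset
        de = run_contrast(d.mrna, d.sheet, "M1", "M0")
        corr = correlate_mirna_genes(d.mirna, d.mrna, d.sheet, "miR-155-like", ("M1", "M0"))
        candidates = filter_candidates(corr, de, 0.5, 1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            triple = intersect_targets(candidates, d.db_a, d.db_b, "miR-155-like")
        table = build_interactome("miR-155-like", triple, corr, de)
        assert (table["correlation_factor"].abs() > 0.5).all()
        assert (table["power"] < 1e-4).all()
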