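import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from etkras.diffexpr import (bh_adjust, protein_de, replicate_filter, rna_de,
                             size_factors, venn_partition)
from tests.conftest import make_protein_matrix, make_rna_matrix


def brute_force_size_factors(counts: np.ndarray, pseudocount=1.0) -> np.ndarray:
    """Literal re-computation from the median-of-ratios definition."""
    mat = counts + pseudocount
    geo = np.array([np.prod(row) ** (1 / len(row)) for row in mat])
    keep = geo > 0
    return np.array([
        np.median(mat[keep, j] / geo[keep]) for j in range(mat.shape[1])
    ])


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = make_rna_matrix(np.tile([[10.0], [100.0], [7.0]], 4))
        assert np.allclose(size_factors(m), 1.0)

    def test_doubled_column_gives_sqrt2_split(self):
        # large counts so the pseudocount is negligible
        rng = np.random.default_rng(0)
        base = rng.integers(1000, 50000, size=50).astype(float)
        vals = np.column_stack([base, 2 * base, base, base])
        m = make_rna_matrix(vals)
        sf = size_factors(m).to_numpy()
        expected = brute_force_size_factors(vals)
        assert np.allclose(sf, expected, rtol=1e-12)
        assert abs(sf[1] / sf[0] - 2.0) < 0.01

    def test_matches_brute_force_oracle_on_random_matrix(self):
        rng = np.random.default_rng(42)
        vals = rng.integers(0, 500, size=(50, 6)).astype(float)
        m = make_rna_matrix(vals, conditions=[f"C{i}" for i in range(6)])
        assert np.allclose(size_factors(m).to_numpy(),
                           brute_force_size_factors(vals), atol=1e-10)

    def test_single_sample_rejected(self):
        m = make_rna_matrix(np.array([[1.0], [2.0], [3.0]]), conditions=["C0"])
        with pytest.raises(ValueError):
            size_factors(m)


class TestRnaDE:
    def test_fourfold_feature_passes_up(self):
        vals = np.array([[25.0, 25, 100, 25],
                         [50.0, 50, 50, 50],
                         [1000.0, 1000, 1000, 1000]])
        m = make_rna_matrix(vals)
        res = {r.feature: r for r in rna_de(m, ("HPNE_KRAS", "HPNE"))}
        assert res["G001"].passed and res["G001"].direction == "up"
        assert res["G001"].p is None
        assert not res["G002"].passed

    def test_equal_feature_unchanged(self):
        m = make_rna_matrix(np.full((3, 4), 40.0))
        res = rna_de(m, ("HPNE_EtOH", "HPNE"))
        assert all(abs(r.log2fc) < 1e-12 and not r.passed for r in res)

    def test_1p9_fold_below_threshold_not_passed(self):
        # large counts: pseudocount effect negligible, 1.9-fold stays < 2
        vals = np.array([[10000.0, 10000, 19000, 10000],
                         [10000.0, 10000, 10000, 10000],
                         [10000.0, 10000, 10000, 10000]])
        res = {r.feature: r for r in
               rna_de(make_rna_matrix(vals), ("HPNE_KRAS", "HPNE"))}
        assert not res["G001"].passed

    def test_exactly_twofold_inclusive(self):
        vals = np.full((3, 4), 10000.0)
        m = make_rna_matrix(vals)
        norm = (m.values + 1).div(size_factors(m), axis=1)
        # construct a feature at exactly 2x on the normalized scale
        vals2 = vals.copy()
        vals2[0, 2] = 2 * vals[0, 0] + 1  # 2*(x+1) - 1 => exact on pseudocounted scale
        res = {r.feature: r for r in
               rna_de(make_rna_matrix(vals2), ("HPNE_KRAS", "HPNE"))}
        assert res["G001"].log2fc >= 1.0 - 1e-9
        assert res["G001"].passed

    def test_scale_invariance_of_log2fc(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(5000, 100000, size=(100, 4)).astype(float)
        a = rna_de(make_rna_matrix(vals), ("HPNE_KRAS_EtOH", "HPNE_KRAS"))
        scaled = vals.copy()
        scaled[:, 1] *= 3.0
        b = rna_de(make_rna_matrix(scaled), ("HPNE_KRAS_EtOH", "HPNE_KRAS"))
        assert np.allclose([r.log2fc for r in a], [r.log2fc for r in b],
                           atol=1e-6)

    def test_mean_expr_averages_all_conditions(self):
        vals = np.array([[100.0, 200, 300, 400]])
        m = make_rna_matrix(vals, features=["G1"])
        res = rna_de(m, ("HPNE_EtOH", "HPNE"))
        norm = (m.values + 1).div(size_factors(m), axis=1)
        assert res[0].mean_expr == pytest.approx(norm.mean(axis=1)["G1"])

    def test_absent_condition_rejected(self):
        m = make_rna_matrix(np.full((3, 4), 10.0))
        with pytest.raises(KeyError):
            rna_de(m, ("NOPE", "HPNE"))


class TestProteinDE:
    def test_clean_twofold_passes(self):
        vals = np.ones((5, 12))
        vals[0, 9:12] = 2.0  # treated (last condition) doubled, zero variance
        vals[0, 0:9] = 1.0
        # add tiny jitter so the t-test is defined
        rng = np.random.default_rng(0)
        vals *= np.exp(rng.normal(0, 1e-4, vals.shape))
        m = make_protein_matrix(vals)
        res = {r.feature: r for r in
               protein_de(m, ("HPNE_KRAS_EtOH", "HPNE_KRAS"))}
        assert res["P001"].log2fc == pytest.approx(1.0, abs=1e-3)
        assert res["P001"].passed

    def test_identical_groups_fold_one_p_one(self):
        vals = np.ones((3, 12))
        res = protein_de(make_protein_matrix(vals),
                         ("HPNE_KRAS_EtOH", "HPNE_KRAS"))
        assert all(r.log2fc == 0 and r.p == 1.0 and not r.passed for r in res)

    def test_all_missing_feature_excluded_with_warning(self, caplog):
        vals = np.ones((3, 12))
        vals[1, 9:12] = np.nan
        with caplog.at_level("WARNING"):
            res = protein_de(make_protein_matrix(vals),
                             ("HPNE_KRAS_EtOH", "HPNE_KRAS"))
        assert len(res) == 2
        assert "excluded" in caplog.text

    def test_null_proteins_rarely_pass(self):
        """BH at alpha=0.05 keeps false discoveries near the nominal bound."""
        n_called = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vals = np.exp2(rng.normal(0, 0.2, size=(200, 12)))
            res = protein_de(make_protein_matrix(vals),
                             ("HPNE_KRAS_EtOH", "HPNE_KRAS"))
            n_called += sum(r.passed for r in res)
        assert n_called <= 10  # 2000 null tests in total


class TestReplicateFilter:
    def test_hand_enumerated_pattern(self):
        vals = np.ones((5, 12))
        vals[1, 0:2] = np.nan          # 1/3 present in condition 1 -> removed
        vals[2, 0] = np.nan            # 2/3 present everywhere -> kept
        vals[3, 3] = np.nan
        vals[3, 6] = np.nan            # 2/3 in two conditions -> kept
        vals[4, 9:11] = np.nan         # 1/3 in last condition -> removed
        m = make_protein_matrix(vals)
        kept = replicate_filter(m).feature_ids
        assert kept == ["P001", "P003", "P004"]

    def test_fully_present_kept(self):
        m = make_protein_matrix(np.ones((2, 12)))
        assert len(replicate_filter(m).feature_ids) == 2

    def test_requires_protein_assay(self):
        m = make_rna_matrix(np.ones((3, 4)))
        with pytest.raises(ValueError):
            replicate_filter(m)


def bh_oracle(p):
    """Step-up formula applied literally."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestBHAdjust:
    def test_hand_derived_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    def test_matches_step_up_oracle_and_dominates_input(self, p):
        adj = bh_adjust(p)
        assert np.allclose(adj, bh_oracle(p), atol=1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)


class TestVennPartition:
    def test_common_and_exclusive_regions(self):
        v = venn_partition({"c1": ({"A", "B"}, set()),
                            "c2": ({"B", "C"}, set())})
        assert v.regions["common_up"] == {"B"}
        assert v.regions["c1_only_up"] == {"A"}
        assert v.regions["c2_only_up"] == {"C"}

    def test_disjoint_sets_have_empty_common(self):
        v = venn_partition({"c1": ({"A"}, {"X"}), "c2": ({"B"}, {"Y"})})
        assert v.regions["common_up"] == set()
        assert v.regions["common_down"] == set()

    def test_identical_sets_have_empty_exclusives(self):
        v = venn_partition({"c1": ({"A"}, set()), "c2": ({"A"}, set())})
        assert v.regions["common_up"] == {"A"}
        assert v.regions["c1_only_up"] == set()
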