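import numpy as np
import pytest

from etkras.diffcoexp import (CorrelationTensor, condition_correlations,
                              hub_ranking, hub_subnetwork,
                              permutation_null_edge_counts, signflip_edges)
from tests.conftest import make_protein_matrix

CONDS = ["HPNE", "HPNE_EtOH", "HPNE_KRAS", "HPNE_KRAS_EtOH"]
FOCAL = "HPNE_KRAS_EtOH"


def tensor_from_values(r_by_cond, features):
    return CorrelationTensor(conditions=list(r_by_cond), features=features,
                             r={c: np.asarray(m, float)
                                for c, m in r_by_cond.items()},
                             n_per_condition={c: 3 for c in r_by_cond})


def pair_tensor(r_values):
    """2-feature tensor with the given per-condition correlations."""
    mats = {}
    for cond, r in zip(CONDS, r_values):
        mats[cond] = np.array([[1.0, r], [r, 1.0]])
    return tensor_from_values(mats, ["A", "B"])


class TestConditionCorrelations:
    def test_scaled_partner_gives_r_one(self):
        vals = np.ones((2, 12))
        rng = np.random.default_rng(0)
        hub = rng.normal(0, 1, 12)
        vals[0] = np.exp2(hub)
        vals[1] = np.exp2(2 * hub)  # log-scale partner = 2 x hub
        m = make_protein_matrix(np.log2(vals) + 5)
        t = condition_correlations(m)
        for c in CONDS:
            assert t.r[c][0, 1] == pytest.approx(1.0)

    def test_negated_partner_gives_r_minus_one(self):
        rng = np.random.default_rng(1)
        hub = rng.normal(0, 1, 12)
        vals = np.vstack([hub, -hub + 3.0])
        m = make_protein_matrix(vals)
        t = condition_correlations(m)
        for c in CONDS:
            assert t.r[c][0, 1] == pytest.approx(-1.0)

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, size=(20, 12))
        m = make_protein_matrix(vals)
        t = condition_correlations(m)
        for ci, cond in enumerate(CONDS):
            block = vals[:, 3 * ci: 3 * ci + 3]
            for i in range(20):
                for j in range(i + 1, 20):
                    x, y = block[i], block[j]
                    r = (np.sum((x - x.mean()) * (y - y.mean()))
                         / np.sqrt(np.sum((x - x.mean())**2)
                                   * np.sum((y - y.mean())**2)))
                    assert t.r[cond][i, j] == pytest.approx(r, abs=1e-12)

    def test_missing_feature_dropped_first(self):
        vals = np.random.default_rng(3).normal(size=(5, 12))
        vals[2, 4] = np.nan
        t = condition_correlations(make_protein_matrix(vals))
        assert len(t.features) == 4 and "P003" not in t.features

    def test_constant_feature_has_undefined_r(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(3, 12))
        vals[1, :] = 7.0
        t = condition_correlations(make_protein_matrix(vals))
        for c in CONDS:
            assert np.isnan(t.r[c][0, 1])

    def test_fewer_than_three_replicates_rejected(self):
        m = make_protein_matrix(np.random.default_rng(5).normal(size=(4, 8)),
                                n_rep=2)
        with pytest.raises(ValueError, match="replicates"):
            condition_correlations(m)


class TestSignflipEdges:
    def test_positive_edge_from_flip_pattern(self):
        net = signflip_edges(pair_tensor([-0.9, -0.8, -0.95, 0.9]), FOCAL)
        assert net.edge_set() == {("A", "B", "positive")}

    def test_focal_below_threshold_gives_no_edge(self):
        net = signflip_edges(pair_tensor([-0.9, -0.8, -0.95, 0.7]), FOCAL)
        assert net.edges == []

    def test_no_sign_flip_gives_no_edge(self):
        net = signflip_edges(pair_tensor([0.9, 0.9, 0.9, 0.9]), FOCAL)
        assert net.edges == []

    def test_boundary_exactly_075_included(self):
        net = signflip_edges(pair_tensor([-0.75, -0.75, -0.75, 0.75]), FOCAL)
        assert net.edge_set() == {("A", "B", "positive")}

    def test_negative_edge_class(self):
        net = signflip_edges(pair_tensor([0.8, 0.76, 0.99, -0.8]), FOCAL)
        assert net.edge_set() == {("A", "B", "negative")}

    def test_missing_r_excludes_pair(self):
        t = pair_tensor([-0.9, np.nan, -0.9, 0.9])
        assert signflip_edges(t, FOCAL).edges == []

    def test_negating_all_slices_swaps_edge_classes(self):
        """Metamorphic: negating every correlation slice swaps pos<->neg.

        (The positive criterion is the elementwise negation of the negative
        one across *all* conditions, so the involution must negate every
        slice, not just the focal one.)
        """
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(15, 12))
        t = condition_correlations(make_protein_matrix(vals))
        net = signflip_edges(t, FOCAL, threshold=0.4)
        for c in list(t.r):
            t.r[c] = -t.r[c]
        flipped = signflip_edges(t, FOCAL, threshold=0.4)
        swap = {"positive": "negative", "negative": "positive"}
        assert flipped.edge_set() == {(a, b, swap[s])
                                      for a, b, s in net.edge_set()}

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(25, 12))
        t = condition_correlations(make_protein_matrix(vals))
        counts = [len(signflip_edges(t, FOCAL, thr).edges)
                  for thr in (0.2, 0.4, 0.6, 0.8)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            signflip_edges(pair_tensor([0.9, 0.9, 0.9, -0.9]), FOCAL, 1.5)
        with pytest.raises(ValueError):
            signflip_edges(pair_tensor([0.9, 0.9, 0.9, -0.9]), FOCAL, 0.0)


class TestHubRanking:
    def star_net(self):
        mats = {c: -0.9 * np.ones((7, 7)) for c in CONDS[:3]}
        mats[FOCAL] = 0.9 * np.ones((7, 7))
        for m in mats.values():
            np.fill_diagonal(m, 1.0)
        feats = ["HUB", "p1", "p2", "p3", "p4", "p5", "x"]
        t = tensor_from_values(mats, feats)
        # only hub-partner pairs flip; zero out the rest
        for c, m in t.r.items():
            keep = np.zeros_like(m)
            keep[0, 1:6] = m[0, 1:6]
            keep[1:6, 0] = m[1:6, 0]
            np.fill_diagonal(keep, 1.0)
            t.r[c] = keep
        return signflip_edges(t, FOCAL)

    def test_star_hub_ranked_first_with_degree_5(self):
        ranked = hub_ranking(self.star_net())
        assert ranked[0] == ("HUB", 5, 5, 0)

    def test_ties_break_lexicographically(self):
        net = self.star_net()
        ranked = hub_ranking(net)
        partners = [r for r in ranked if r[1] == 1]
        assert [p[0] for p in partners] == sorted(p[0] for p in partners)

    def test_empty_network_empty_ranking(self):
        net = signflip_edges(pair_tensor([0.9, 0.9, 0.9, 0.9]), FOCAL)
        assert hub_ranking(net) == []

    def test_hub_subnetwork_extracts_incident_edges(self):
        net = self.star_net()
        sub = hub_subnetwork(net, "HUB")
        assert len(sub.edges) == 5
        assert all("HUB" in (e.source, e.target) for e in sub.edges)


def test_permutation_preserves_marginals_and_counts_edges(small_simulation):
    _, protein, truth = small_simulation
    logp = protein.with_values(np.log2(protein.values))
    counts = permutation_null_edge_counts(logp, FOCAL, n_permutations=3, seed=0)
    assert counts.shape == (3,)
    assert (counts >= 0).all()
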