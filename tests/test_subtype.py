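import numpy as np
import pytest

from etkras.subtype import (SignatureModel, plsda_train, project_scores,
                            resubstitution_accuracy, score_subtypes,
                            select_variable_features, youden_cutoff)
from tests.conftest import make_protein_matrix


def two_class_matrix(seed=0, n_per_class=6, n_feat=20, effect=3.0):
    rng = np.random.default_rng(seed)
    vals = np.exp2(rng.normal(0, 0.3, size=(n_feat, 2 * n_per_class)))
    vals[0, n_per_class:] *= 2.0**effect  # class B elevated on feature 1
    conds = ["HPNE"] * 1  # wrapper conditions are irrelevant here
    m = make_protein_matrix(vals, n_rep=2 * n_per_class, conditions=["HPNE"])
    labels = {s: ("A" if i < n_per_class else "B")
              for i, s in enumerate(m.sample_ids)}
    return m, labels


class TestSelectVariableFeatures:
    def test_dominant_variance_feature_selected(self):
        rng = np.random.default_rng(0)
        vals = np.exp2(rng.normal(0, 0.1, size=(10, 12)))
        vals[3] = np.exp2(rng.normal(0, 3.0, size=12))
        m = make_protein_matrix(vals)
        assert select_variable_features(m, 1) == ["P004"]

    def test_k_equal_n_returns_all(self):
        m = make_protein_matrix(np.exp2(np.random.default_rng(1)
                                        .normal(size=(8, 12))))
        assert sorted(select_variable_features(m, 8)) == m.feature_ids

    def test_variance_tie_breaks_lexicographically(self):
        vals = np.ones((3, 12))
        vals[0] = vals[1] = [1, 2] * 6  # identical variance for P001/P002
        m = make_protein_matrix(vals)
        assert select_variable_features(m, 1) == ["P001"]

    def test_k_above_n_rejected(self):
        m = make_protein_matrix(np.ones((3, 12)))
        with pytest.raises(ValueError):
            select_variable_features(m, 4)


class TestPlsdaTrain:
    def test_separable_classes_load_on_informative_feature(self):
        # idealized case: the other features carry no class covariance at
        # all, so the first component must load on the separating feature
        vals = np.ones((10, 12))
        vals[0] = [1.0] * 6 + [8.0] * 6
        m = make_protein_matrix(vals, n_rep=12, conditions=["HPNE"])
        labels = {s: ("A" if i < 6 else "B")
                  for i, s in enumerate(m.sample_ids)}
        model = plsda_train(m, labels, n_components=1)
        w = model.rotations[:, 0]
        assert abs(w[0]) >= 0.99 * np.linalg.norm(w)

    def test_weights_columns_orthonormal(self):
        m, labels = two_class_matrix(seed=2)
        model = plsda_train(m, labels, n_components=2)
        gram = model.weights.T @ model.weights
        assert np.allclose(gram, np.eye(2), atol=1e-8)

    def test_singleton_class_rejected(self):
        m, labels = two_class_matrix()
        labels[m.sample_ids[0]] = "C"
        with pytest.raises(ValueError, match="fewer than 2"):
            plsda_train(m, labels)

    def test_shuffled_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(3)
        accs = []
        for seed in range(8):
            m, labels = two_class_matrix(seed=seed, n_per_class=8)
            ids = list(labels)
            shuffled = dict(zip(ids, rng.permutation([labels[s] for s in ids])))
            model = plsda_train(m, shuffled, n_components=1)
            # accuracy on fresh data from the same generative process
            m2, labels2 = two_class_matrix(seed=seed + 100, n_per_class=8)
            accs.append(resubstitution_accuracy(model, m2, labels2))
        assert 0.25 <= np.mean(accs) <= 0.75

    def test_save_load_round_trip_scores_identical(self, tmp_path):
        m, labels = two_class_matrix(seed=4)
        model = plsda_train(m, labels, n_components=2)
        model.cutoffs = {"A": 0.1, "B": -0.2}
        model.to_json(tmp_path / "model.json")
        loaded = SignatureModel.from_json(tmp_path / "model.json")
        a = project_scores(model, m).to_numpy()
        b = project_scores(loaded, m).to_numpy()
        assert np.allclose(a, b, atol=1e-10)
        assert loaded.cutoffs == model.cutoffs


class TestYoudenCutoff:
    def exhaustive_best_j(self, scores, positive):
        best = -np.inf
        for thr in np.unique(scores):
            calls = scores >= thr
            tpr = (calls & positive).sum() / positive.sum()
            fpr = (calls & ~positive).sum() / (~positive).sum()
            best = max(best, tpr - fpr)
        return best

    def test_perfect_separation_gives_j_one(self):
        scores = np.array([0.1, 0.2, 0.3, 2.1, 2.2, 2.3])
        positive = np.array([False] * 3 + [True] * 3)
        cut = youden_cutoff(scores, positive)
        calls = scores >= cut
        assert (calls == positive).all()

    def test_matches_exhaustive_search_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            scores = rng.normal(size=40)
            positive = rng.random(40) < 0.4
            if positive.all() or not positive.any():
                continue
            cut = youden_cutoff(scores, positive)
            calls = scores >= cut
            tpr = (calls & positive).sum() / positive.sum()
            fpr = (calls & ~positive).sum() / (~positive).sum()
            assert tpr - fpr == pytest.approx(
                self.exhaustive_best_j(scores, positive), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_cutoff(np.array([1.0, 2.0]), np.array([True, True]))


class TestScoreSubtypes:
    def test_resubstitution_calls_own_class(self):
        m, labels = two_class_matrix(seed=6, n_per_class=10, n_feat=8,
                                     effect=4.0)
        model = plsda_train(m, labels, n_components=1)
        scores = score_subtypes(model, m, calibration_labels=labels)
        for s in scores:
            assert s.top_class == labels[s.sample]
            assert s.calls[labels[s.sample]]

    def test_no_cutoffs_no_labels_rejected(self):
        m, labels = two_class_matrix(seed=7)
        model = plsda_train(m, labels, n_components=1)
        with pytest.raises(ValueError, match="cutoff"):
            score_subtypes(model, m)

    def test_scores_invariant_to_feature_order(self):
        m, labels = two_class_matrix(seed=8)
        model = plsda_train(m, labels, n_components=2)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(m.feature_ids))
        a = project_scores(model, m).to_numpy()
        b = project_scores(model, m.subset_features(perm)).to_numpy()
        assert np.allclose(a, b, atol=1e-10)

    def test_missing_model_feature_imputed_at_center(self, caplog):
        m, labels = two_class_matrix(seed=9)
        model = plsda_train(m, labels, n_components=1)
        reduced = m.subset_features(m.feature_ids[1:])  # drop informative feat
        with caplog.at_level("WARNING"):
            df = project_scores(model, reduced)
        assert df.shape == (len(m.sample_ids), 2)
        assert "imputed" in caplog.text
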