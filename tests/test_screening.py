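"""Oversampling, SVM screening, thresholding and AUROC."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from gelgen.screening import (
    GelationClassifier,
    grid_search_svm,
    oversample_to_balance,
)


class TestOversampling:
    def test_minority_duplicated_to_parity(self):
        recs = [f"m{i}" for i in range(110)]
        labels = [1] * 10 + [0] * 100
        out, y = oversample_to_balance(recs, labels, seed=0)
        assert (y == 1).sum() == (y == 0).sum() == 100

    def test_balanced_input_unchanged(self):
        recs = [f"m{i}" for i in range(100)]
        labels = [1] * 50 + [0] * 50
        out, y = oversample_to_balance(recs, labels, seed=0)
        assert out == recs and np.array_equal(y, labels)

    def test_deterministic_multiset(self):
        recs = [f"m{i}" for i in range(10)]
        labels = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        a, ya = oversample_to_balance(recs, labels, seed=3)
        b, yb = oversample_to_balance(recs, labels, seed=3)
        assert a == b and np.array_equal(ya, yb)

    def test_distinct_set_unchanged_only_multiplicities(self):
        recs = [f"m{i}" for i in range(20)]
        labels = [1] * 4 + [0] * 16
        out, y = oversample_to_balance(recs, labels, seed=1)
        assert set(out) == set(recs)
        assert len(out) == 32

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            oversample_to_balance(["a", "b"], [1, 1], seed=0)


class _FixedScores(GelationClassifier):
    """Classifier stub returning predetermined positive-class scores."""

    def __init__(self, scores):
        super().__init__()
        self._scores = np.asarray(scores, dtype=float)
        self.classes_ = np.array([0, 1])
        self.svm_ = object()

    def predict_proba(self, X):
        s = self._scores[: len(list(X))]
        return np.column_stack([1 - s, s])


class TestAuroc:
    def test_perfect_and_reversed_ranking(self):
        from gelgen.screening import evaluate_auroc

        y = [1] * 5 + [0] * 5
        clf = _FixedScores([0.9, 0.8, 0.7, 0.6, 0.55, 0.5, 0.4, 0.3, 0.2, 0.1])
        assert evaluate_auroc(clf, list(range(10)), y) == 1.0
        clf_rev = _FixedScores([0.1, 0.2, 0.3, 0.4, 0.45, 0.5, 0.6, 0.7, 0.8, 0.9])
        assert evaluate_auroc(clf_rev, list(range(10)), y) == 0.0

    def test_hand_counted_concordant_pairs(self):
        from gelgen.screening import evaluate_auroc

        clf = _FixedScores([0.9, 0.8, 0.4, 0.7, 0.3, 0.2])
        y = [1, 1, 1, 0, 0, 0]
        assert evaluate_auroc(clf, list(range(6)), y) == pytest.approx(8 / 9)

    def test_single_class_test_set_rejected(self):
        from gelgen.screening import evaluate_auroc

        with pytest.raises(ValueError):
            evaluate_auroc(_FixedScores([0.5, 0.5]), [0, 1], [1, 1])

    def test_equals_mann_whitney_concordance(self):
        # rank AUROC == U / (n_pos * n_neg) on random score sets
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_pos, n_neg = rng.integers(3, 20, size=2)
            y = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
            scores = rng.normal(size=n_pos + n_neg).round(1)  # ties included
            u = mannwhitneyu(scores[:n_pos], scores[n_pos:]).statistic
            assert roc_auc_score(y, scores) == pytest.approx(u / (n_pos * n_neg))


class TestGelationClassifier:
    @pytest.fixture(scope="class")
    def fitted(self, labeled_set):
        corpus, labels = labeled_set
        smiles = corpus.smiles()
        n = len(smiles)
        rng = np.random.default_rng(1)
        order = rng.permutation(n)
        cut = int(0.7 * n)
        train_idx, test_idx = order[:cut], order[cut:]
        clf = GelationClassifier(seed=0).fit(
            [smiles[i] for i in train_idx], [labels[i] for i in train_idx]
        )
        return clf, smiles, labels, train_idx, test_idx

    def test_planted_rule_recovered(self, fitted):
        from gelgen.screening import evaluate_auroc

        clf, smiles, labels, _, test_idx = fitted
        auroc = evaluate_auroc(
            clf, [smiles[i] for i in test_idx], [labels[i] for i in test_idx]
        )
        assert auroc >= 0.95

    def test_training_positive_called_active(self, fitted):
        clf, smiles, labels, train_idx, _ = fitted
        pos = next(i for i in train_idx if labels[i] == 1)
        assert clf.screen([smiles[pos]]).active[0]

    def test_shuffled_labels_give_chance_auroc(self, labeled_set):
        from gelgen.screening import evaluate_auroc

        corpus, labels = labeled_set
        smiles = corpus.smiles()[:400]
        rng = np.random.default_rng(7)
        y = np.asarray(labels[:400]).copy()
        rng.shuffle(y)
        # guard: keep both classes in both halves
        clf = GelationClassifier(seed=0).fit(smiles[:280], y[:280])
        auroc = evaluate_auroc(clf, smiles[280:], y[280:])
        assert auroc == pytest.approx(0.5, abs=0.1)

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            GelationClassifier().fit(["C", "CC", "CCC"], [1, 1, 1])

    def test_fewer_than_two_per_class_rejected(self):
        with pytest.raises(ValueError):
            GelationClassifier().fit(["C", "CC", "CCC"], [1, 0, 0])

    def test_screen_flags_unparseable_lines(self, fitted):
        clf, smiles, *_ = fitted
        res = clf.screen(["C(", smiles[0]])
        assert not res.valid[0] and res.valid[1]
        assert np.isnan(res.probability[0])
        assert not res.active[0]

    def test_threshold_strictly_greater(self):
        clf = _FixedScores([0.5, 0.500001])
        res_like = clf.predict_proba([0, 1])[:, 1]
        assert not (res_like[0] > 0.5) and (res_like[1] > 0.5)

    def test_model_file_round_trip_and_fp_guard(self, fitted, tmp_path):
        clf, smiles, *_ = fitted
        path = str(tmp_path / "svm.json")
        clf.save(path)
        loaded = GelationClassifier.load(path)
        a = clf.screen(smiles[:5]).probability
        b = loaded.screen(smiles[:5]).probability
        assert np.allclose(a, b)
        with pytest.raises(ValueError, match="radius"):
            GelationClassifier.load(path, radius=3)

    def test_grid_search_returns_well_defined_argmax(self, labeled_set):
        corpus, labels = labeled_set
        pos = [s for s, l in zip(corpus.smiles(), labels) if l == 1][:30]
        neg = [s for s, l in zip(corpus.smiles(), labels) if l == 0][:70]
        C, gamma, score = grid_search_svm(
            pos + neg, [1] * 30 + [0] * 70,
            C_grid=(1.0, 10.0), gamma_grid=(0.01, 0.1), cv=2, seed=0,
        )
        assert C in (1.0, 10.0) and gamma in (0.01, 0.1)
        assert 0.0 <= score <= 1.0
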