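"""Features, LOOCV, ROC/AUC against a brute-force oracle, confusion."""

import itertools

import numpy as np
import pytest

from smrr.classify import (
    CaseScore,
    ConfusionMatrix,
    FeatureVector,
    confusion,
    features_from_profile,
    latency_threshold_classify,
    loocv_scores,
    roc_metrics,
)
from smrr.config import ClassifierSpec
from smrr.coupling import case_profile


def mann_whitney_auc(scores, labels):
    """Brute-force pairwise rank oracle: P(score_pos > score_neg) + ties/2."""
    pos = [s for s, lab in zip(scores, labels) if lab == "MCI"]
    neg = [s for s, lab in zip(scores, labels) if lab == "NC"]
    wins = ties = 0
    for p, q in itertools.product(pos, neg):
        if p > q:
            wins += 1
        elif p == q:
            ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def _features(vectors, ids=None):
    ids = ids or [f"c{i}" for i in range(len(vectors))]
    return [FeatureVector(case_id=i, values=np.asarray(v, float))
            for i, v in zip(ids, vectors)]


class TestFeatures:
    def test_fraction_negative_zero(self):
        p = case_profile("c", [74.0] * 6)
        f = features_from_profile(p)
        assert f.values[-1] == 0.0

    def test_fraction_negative_two_thirds(self):
        p = case_profile("c", [-90.0, -50.0, 80.0])
        f = features_from_profile(p)
        assert f.values[-1] == pytest.approx(2.0 / 3.0)

    def test_deterministic(self):
        p = case_profile("c", [-90.0, -50.0, 80.0])
        np.testing.assert_array_equal(
            features_from_profile(p).values, features_from_profile(p).values
        )

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError, match="empty"):
            features_from_profile(case_profile("c", []))


class TestLatencyThreshold:
    def test_above_threshold_nc(self):
        assert latency_threshold_classify(case_profile("c", [150.0] * 5)) == "NC"

    def test_below_threshold_mci(self):
        assert latency_threshold_classify(case_profile("c", [-50.0] * 5)) == "MCI"

    def test_boundary_goes_mci(self):
        assert latency_threshold_classify(case_profile("c", [70.0] * 5)) == "MCI"


class TestLOOCV:
    def _separable(self, n=4):
        vecs = []
        labels = []
        rng = np.random.default_rng(0)
        for i in range(n):
            vecs.append(np.concatenate([rng.normal(5, 0.1, 6), [(-50.0), -80, -20, 0.9]]))
            labels.append("MCI")
        for i in range(n):
            vecs.append(np.concatenate([rng.normal(-5, 0.1, 6), [150.0, 80, 220, 0.0]]))
            labels.append("NC")
        return _features(vecs), labels

    @pytest.mark.parametrize("family", ["neural_network", "gaussian", "kernel"])
    def test_separable_perfect_auc(self, family):
        feats, labels = self._separable()
        spec = ClassifierSpec(family=family, seed=0)
        scores = loocv_scores(feats, labels, spec)
        assert roc_metrics(scores).auc == 1.0

    def test_fold_bookkeeping(self):
        feats, labels = self._separable(n=2)
        scores = loocv_scores(feats, labels, ClassifierSpec(family="gaussian", seed=0))
        assert len(scores) == 4
        assert sorted(s.fold for s in scores) == [0, 1, 2, 3]
        assert len({s.case_id for s in scores}) == 4

    def test_single_class_rejected(self):
        feats, _ = self._separable(n=2)
        with pytest.raises(ValueError, match="class"):
            loocv_scores(feats, ["MCI"] * 4, ClassifierSpec(family="gaussian", seed=0))

    def test_no_leakage_into_own_fold(self):
        """Fold i's model (incl. standardization) is fitted without case i:
        scoring a corrupted case 0 must agree with an oracle model trained
        on the untouched remaining cases."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.preprocessing import StandardScaler

        feats, labels = self._separable(n=3)
        spec = ClassifierSpec(family="gaussian", seed=0)
        corrupted = list(feats)
        bad = corrupted[0].values.copy()
        bad[:] = 1e6  # would wreck any scaler fitted with this case included
        corrupted[0] = FeatureVector(case_id="c0", values=bad)
        fold0 = loocv_scores(corrupted, labels, spec)[0]

        x_train = np.stack([f.values for f in feats[1:]])
        y_train = np.array([1 if lab == "MCI" else 0 for lab in labels[1:]])
        scaler = StandardScaler().fit(x_train)
        oracle = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        oracle.fit(scaler.transform(x_train), y_train)
        expected = oracle.predict_proba(scaler.transform(bad.reshape(1, -1)))[0, 1]
        assert fold0.score == pytest.approx(expected)

    def test_permuted_labels_near_chance(self):
        """Permutation null: AUC within [0.3, 0.7] for n=40."""
        rng = np.random.default_rng(42)
        feats, labels = self._separable(n=20)
        perm = list(labels)
        rng.shuffle(perm)
        scores = loocv_scores(feats, perm, ClassifierSpec(family="gaussian", seed=0))
        assert 0.3 <= roc_metrics(scores).auc <= 0.7

    def test_seed_required_for_nn(self):
        with pytest.raises(ValueError, match="seed"):
            ClassifierSpec(family="neural_network")


class TestROC:
    def _scores(self, s, labs):
        return [CaseScore(f"c{i}", lab, v, i) for i, (v, lab) in enumerate(zip(s, labs))]

    def test_perfect_separation(self):
        r = roc_metrics(self._scores([0.9, 0.8, 0.3, 0.1], ["MCI", "MCI", "NC", "NC"]))
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_interleaved_matches_rank_oracle(self):
        labs = ["MCI", "NC", "MCI", "NC"]
        s = [0.9, 0.8, 0.3, 0.1]
        r = roc_metrics(self._scores(s, labs))
        # brute force over the 4 pos/neg pairs: 3 concordant, 1 discordant
        assert mann_whitney_auc(s, labs) == 0.75
        assert r.auc == pytest.approx(0.75)

    def test_degenerate_scores_flagged(self):
        r = roc_metrics(self._scores([1.0, 1.0, 1.0, 1.0], ["MCI", "MCI", "NC", "NC"]))
        assert r.degenerate
        assert r.auc == 0.5

    @pytest.mark.parametrize("seed", range(6))
    def test_auc_equals_rank_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 60))
        s = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labs = ["MCI" if v else "NC" for v in rng.integers(0, 2, size=n)]
        if len(set(labs)) < 2:
            labs[0] = "MCI" if labs[0] == "NC" else "NC"
        r = roc_metrics(self._scores(s, labs))
        assert r.auc == pytest.approx(mann_whitney_auc(s, labs), abs=1e-12)

    def test_curve_monotone(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=30)
        labs = ["MCI" if v else "NC" for v in rng.integers(0, 2, size=30)]
        r = roc_metrics(self._scores(s, labs))
        assert np.all(np.diff(r.fpr) >= 0)
        assert np.all(np.diff(r.tpr) >= 0)

    def test_metrics_reproduce_from_confusion(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=40)
        labs = ["MCI" if v else "NC" for v in rng.integers(0, 2, size=40)]
        r = roc_metrics(self._scores(s, labs))
        cm = r.confusion
        assert r.sensitivity == cm.tp / (cm.tp + cm.fn)
        assert r.specificity == cm.tn / (cm.tn + cm.fp)


class TestConfusion:
    def test_perfect(self):
        cm = confusion(["MCI"] * 20 + ["NC"] * 20, ["MCI"] * 20 + ["NC"] * 20)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (20, 20, 0, 0)
        assert cm.sensitivity == cm.specificity == cm.ppv == 1.0

    def test_hand_count(self):
        cm = confusion(["MCI", "NC", "NC", "MCI"], ["MCI", "MCI", "NC", "NC"])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)
        assert cm.ppv == 0.5

    def test_undefined_ppv_reported_as_none(self):
        cm = confusion(["NC", "NC"], ["MCI", "NC"])
        assert cm.ppv is None

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["weird"], ["MCI"])

    def test_counts_sum(self):
        cm = ConfusionMatrix(tp=3, tn=4, fp=2, fn=1)
        assert cm.n == 10
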