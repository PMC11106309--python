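"""Uncertainty-aware classifier: loss algebra, confidence, AUROC, U test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from tcrlatent.nn.autodiff import Tensor
from tcrlatent.ood import (ClassifierConfig, InputError, OODClassifier,
                           balanced_class_weights, build_classifier,
                           classifier_loss_from_probs, confidence,
                           evaluate_ood, mannwhitney_compare, ood_auroc,
                           train_classifier)


def gaussian_fixture(n_classes=8, n_per_class=40, shift=6.0, seed=0,
                     n_ood=100, dim=16):
    """Well-separated ID class blobs plus a shifted OOD component."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=2.0, size=(n_classes, dim))
    x_id = np.concatenate([c + rng.normal(scale=0.3, size=(n_per_class, dim))
                           for c in centers])
    y_id = np.repeat(np.arange(n_classes), n_per_class)
    x_ood = rng.normal(loc=shift, scale=1.0, size=(n_ood, dim))
    return x_id, y_id, x_ood


class TestClassifierForward:
    def test_softmax_rows_sum_to_one(self):
        clf = build_classifier(16, 8, seed=0)
        probs = clf.predict_proba(np.random.default_rng(0).normal(size=(5, 16)))
        assert probs.shape == (5, 8)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_deterministic(self):
        clf = build_classifier(16, 8, seed=0)
        x = np.random.default_rng(1).normal(size=(3, 16))
        assert np.array_equal(clf.predict_proba(x), clf.predict_proba(x))

    def test_layer_widths(self):
        clf = build_classifier(16, 8, seed=0)
        assert clf.fc1.W.shape == (16, 128)
        assert clf.fc2.W.shape == (128, 128)
        assert clf.out.W.shape == (128, 8)

    def test_retention_switch_flips_keep_probs(self):
        literal = OODClassifier(ClassifierConfig(retention_is_keep_prob=True))
        flipped = OODClassifier(ClassifierConfig(retention_is_keep_prob=False))
        assert literal.drop0.keep_prob == pytest.approx(0.25)
        assert flipped.drop0.keep_prob == pytest.approx(0.75)


class TestClassifierLoss:
    def test_alpha_zero_is_pure_cross_entropy(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(6, 4))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        labels = rng.integers(0, 4, size=6)
        w = np.ones(4)
        base = classifier_loss_from_probs(probs, labels, None, 0.0, w)
        with_ood = classifier_loss_from_probs(probs, labels, probs, 0.0, w)
        expected = -np.mean(np.log(probs[np.arange(6), labels]))
        assert base == pytest.approx(expected, rel=1e-5)
        assert with_ood == pytest.approx(base, rel=1e-9)

    def test_uniform_ood_prediction_zeroes_auxiliary(self):
        probs_id = np.full((2, 8), 1 / 8)
        probs_ood = np.full((4, 8), 1 / 8)
        labels = np.array([0, 1])
        w = np.ones(8)
        a0 = classifier_loss_from_probs(probs_id, labels, probs_ood, 0.0, w)
        a1 = classifier_loss_from_probs(probs_id, labels, probs_ood, 1.0, w)
        assert a1 == pytest.approx(a0, abs=1e-6)

    def test_auxiliary_matches_hand_computation(self):
        p = np.array([[0.93] + [0.01] * 7])
        expected_kl = sum((1 / 8) * np.log((1 / 8) / pc) for pc in p[0])
        probs_id = np.full((1, 8), 1 / 8)
        labels = np.array([0])
        w = np.ones(8)
        without = classifier_loss_from_probs(probs_id, labels, None, 0.0, w)
        with_aux = classifier_loss_from_probs(probs_id, labels, p, 1.0, w)
        assert with_aux - without == pytest.approx(expected_kl, rel=1e-5)

    def test_class_weights_scale_terms(self):
        probs = np.array([[0.9, 0.1], [0.2, 0.8]])
        labels = np.array([0, 1])
        unweighted = classifier_loss_from_probs(probs, labels, None, 0.0,
                                                np.ones(2))
        weighted = classifier_loss_from_probs(probs, labels, None, 0.0,
                                              np.array([2.0, 2.0]))
        assert weighted == pytest.approx(2 * unweighted, rel=1e-6)

    def test_balanced_weights_formula(self):
        y = np.array([0, 0, 0, 1])
        w = balanced_class_weights(y, 2)
        assert w == pytest.approx([4 / (2 * 3), 4 / (2 * 1)])

    def test_missing_class_rejected(self):
        with pytest.raises(InputError):
            balanced_class_weights(np.array([0, 0]), 2)


class TestConfidence:
    def test_uniform_probability_floor(self):
        assert confidence(np.full(8, 1 / 8))[0] == pytest.approx(8 / 8 / 7)

    def test_certain_prediction_ceiling(self):
        p = np.zeros(8)
        p[3] = 1.0
        assert confidence(p)[0] == pytest.approx(8 / 7)

    def test_strictly_increasing_in_max_prob(self):
        maxps = np.linspace(0.2, 0.99, 20)
        vals = []
        for m in maxps:
            p = np.full(8, (1 - m) / 7)
            p[0] = m
            vals.append(confidence(p)[0])
        assert (np.diff(vals) > 0).all()

    def test_unnormalized_input_rejected(self):
        with pytest.raises(InputError):
            confidence(np.array([0.5, 0.4]))


class TestOODAuroc:
    def test_perfect_separation(self):
        assert ood_auroc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_identical_samples_half(self):
        assert ood_auroc([0.5, 0.5], [0.5, 0.5]) == 0.5

    def test_hand_example_three_quarters(self):
        # pairwise wins: (0.9>0.8), (0.9>0.1), (0.7<0.8), (0.7>0.1) -> 3/4
        assert ood_auroc([0.9, 0.7], [0.8, 0.1]) == pytest.approx(0.75)

    def test_confidence_vs_maxp_rank_equivalent(self):
        rng = np.random.default_rng(0)
        p_id = rng.dirichlet(np.ones(8) * 0.5, size=30)
        p_ood = rng.dirichlet(np.ones(8) * 5.0, size=30)
        auc_conf = ood_auroc(confidence(p_id), confidence(p_ood))
        auc_maxp = ood_auroc(p_id.max(axis=1), p_ood.max(axis=1))
        assert auc_conf == pytest.approx(auc_maxp, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            ood_auroc([], [0.5])


class TestMannWhitney:
    def test_effect_size_u_over_100_for_10v10(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        u, p, eff = mannwhitney_compare(a, b)
        assert eff == pytest.approx(u / 100)

    def test_identical_samples_effect_half(self):
        a = np.ones(10)
        u, p, eff = mannwhitney_compare(a, a)
        assert eff == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = 5, 6
        pooled = rng.normal(size=n1 + n2)
        a, b = pooled[:n1], pooled[n1:]
        u_obs, p_obs, _ = mannwhitney_compare(a, b)

        def u_stat(x, y):
            return sum((xi > yi) + 0.5 * (xi == yi)
                       for xi in x for yi in y)

        us = []
        for idx in itertools.combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            us.append(u_stat(pooled[mask], pooled[~mask]))
        us = np.array(us)
        mean_u = n1 * n2 / 2
        p_enum = np.mean(np.abs(us - mean_u) >= np.abs(u_obs - mean_u) - 1e-12)
        assert p_obs == pytest.approx(p_enum, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            mannwhitney_compare([], [1.0])


class TestTraining:
    def test_mc_splits_produce_models_and_partitions(self):
        x_id, y_id, x_ood = gaussian_fixture(n_classes=4, n_per_class=30)
        cfg = ClassifierConfig(n_classes=4, alpha=0.0, n_mc_splits=3,
                               max_epochs=15, seed=0)
        splits = train_classifier(x_id, y_id, None, cfg)
        assert len(splits) == 3
        report = evaluate_ood(splits, x_ood)
        assert len(report) == 3
        assert report["id_test_auroc_ovr"].median() > 0.9

    def test_alpha_zero_loss_ignores_unlabeled(self):
        rng = np.random.default_rng(0)
        probs_id = rng.dirichlet(np.ones(4), size=8)
        labels = rng.integers(0, 4, size=8)
        probs_ood = rng.dirichlet(np.ones(4), size=8)
        w = np.ones(4)
        assert classifier_loss_from_probs(probs_id, labels, probs_ood, 0.0, w) \
            == classifier_loss_from_probs(probs_id, labels, None, 0.0, w)

    def test_id_confidence_exceeds_ood_with_alpha_one(self):
        x_id, y_id, x_ood = gaussian_fixture(n_classes=4, n_per_class=40,
                                             seed=1)
        cfg = ClassifierConfig(n_classes=4, alpha=1.0, n_mc_splits=1,
                               max_epochs=25, seed=1)
        background = np.random.default_rng(2).normal(5.0, 1.0, size=x_ood.shape)
        splits = train_classifier(x_id, y_id, background, cfg)
        model = splits[0]["model"]
        conf_id = confidence(model.predict_proba(splits[0]["test_x"]))
        conf_ood = confidence(model.predict_proba(x_ood))
        assert conf_id.mean() > conf_ood.mean()
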