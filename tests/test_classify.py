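import numpy as np
import pytest

from scadapt.classify import (DualHeadClassifier, TrainSchedule, evaluate,
                              per_class_silhouette, smote_oversample,
                              tomek_remove, vae_augment)
from scadapt.resvae import ResVAE


class TestSMOTE:
    def test_interpolation_formula_with_known_draw(self):
        minority = np.array([[0.0, 0.0], [1.0, 1.0]])
        majority = np.zeros((3, 2)) + 10
        out_min, _ = smote_oversample(minority, majority, k=1, seed=0)
        assert out_min.shape == (3, 2)
        new = out_min[2]
        # synthetic point lies on the segment between the two parents
        assert new[0] == pytest.approx(new[1], abs=1e-12)
        assert 0.0 <= new[0] <= 1.0

    def test_all_synthetic_points_on_parent_segments(self):
        rng = np.random.default_rng(1)
        minority = rng.standard_normal((10, 3))
        majority = rng.standard_normal((40, 3))
        out_min, _ = smote_oversample(minority, majority, k=5, seed=2)
        assert out_min.shape[0] == majority.shape[0]
        for p in out_min[10:]:
            # each new point lies on a segment between some minority point
            # and one of its neighbors
            on_segment = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    seg = np.linalg.norm(minority[i] - minority[j])
                    through = (np.linalg.norm(minority[i] - p)
                               + np.linalg.norm(p - minority[j]))
                    if through <= seg + 1e-8:
                        on_segment = True
            assert on_segment

    def test_balanced_input_adds_nothing(self):
        x = np.random.default_rng(3).standard_normal((8, 2))
        out_min, _ = smote_oversample(x, x.copy(), k=3, seed=0)
        assert out_min.shape == x.shape

    def test_too_few_minority_errors(self):
        with pytest.raises(ValueError):
            smote_oversample(np.ones((1, 2)), np.ones((5, 2)))


class TestTomek:
    def test_hand_example_removes_majority_link_member(self):
        X = np.array([[0.0], [0.5], [0.6]])
        y = np.array([0, 0, 1])  # majority class 0
        Xf, yf = tomek_remove(X, y)
        assert Xf.ravel().tolist() == [0.0, 0.6]
        assert yf.tolist() == [0, 1]

    def test_separated_clusters_untouched(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.1, (20, 2)),
                       rng.normal(10, 0.1, (10, 2))])
        y = np.array([0] * 20 + [1] * 10)
        Xf, yf = tomek_remove(X, y)
        assert len(yf) == 30

    def test_minority_never_removed(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 2))
        y = (rng.random(60) < 0.25).astype(int)
        _, yf = tomek_remove(X, y)
        assert (yf == 1).sum() == (y == 1).sum()

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            tomek_remove(np.ones((4, 1)), np.zeros(4))


class TestRebalancing:
    def test_smote_plus_tomek_reaches_near_balance(self):
        rng = np.random.default_rng(6)
        majority = rng.standard_normal((200, 4))
        minority = rng.standard_normal((30, 4)) + 1.5
        out_min, out_maj = smote_oversample(minority, majority, k=5, seed=7)
        X = np.vstack([out_maj, out_min])
        y = np.array([0] * len(out_maj) + [1] * len(out_min))
        Xf, yf = tomek_remove(X, y)
        ratio = (yf == 1).sum() / (yf == 0).sum()
        assert 0.9 <= ratio <= 1.0 or 1.0 <= ratio <= 1 / 0.9


class TestVAEAugment:
    def test_deterministic_and_counts(self, small_vae, small_two_domain):
        x = small_two_domain.source.values[:20]
        a = vae_augment(small_vae, x, 15, seed=9)
        b = vae_augment(small_vae, x, 15, seed=9)
        assert a.shape == (15, x.shape[1])
        np.testing.assert_array_equal(a, b)
        assert vae_augment(small_vae, x, 0, seed=9).shape[0] == 0

    def test_vanishing_variance_approaches_decoded_means(self, small_vae,
                                                         small_two_domain):
        from scadapt.resvae import LatentCode
        x = small_two_domain.source.values[:5]
        code = small_vae.encode(x)

        class Shrunk:  # same posterior means, near-zero posterior variance
            decoder_ = small_vae.decoder_
            decode = staticmethod(small_vae.decode)

            @staticmethod
            def encode(X, deterministic=True):
                return LatentCode(code.mu, np.full_like(code.log_var, -60.0),
                                  code.mu, np.zeros_like(code.mu))

        out = vae_augment(Shrunk(), x, 8, seed=11)
        idx = np.random.default_rng(11).integers(5, size=8)
        np.testing.assert_allclose(out, small_vae.decode(code.mu[idx]),
                                   atol=1e-6)

    def test_unfitted_model_rejected(self):
        with pytest.raises(ValueError):
            vae_augment(ResVAE(), np.ones((3, 2)), 2)


class TestClassifierTraining:
    def test_probabilities_sum_to_one(self, small_classifier, small_two_domain):
        proba = small_classifier.predict_proba(small_two_domain.target,
                                               apply_adain=True)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_predict_is_deterministic(self, small_classifier, small_two_domain):
        p1 = small_classifier.predict_proba(small_two_domain.target, True)
        p2 = small_classifier.predict_proba(small_two_domain.target, True)
        np.testing.assert_array_equal(p1, p2)

    def test_stem_frozen_during_head_only_phase(self, small_two_domain):
        vae = ResVAE(latent_dim=4, encoder_block_dims=(8,), epochs=10, seed=3)
        vae.fit(small_two_domain.source.values)
        before = [p.value.copy() for p in vae.stem_params()]
        clf = DualHeadClassifier(
            stem=vae, schedule=TrainSchedule(total_epochs=5,
                                             head_only_epochs=5, seed=4))
        clf.fit(small_two_domain.source.values,
                small_two_domain.source_labels.response)
        for b, p in zip(before, vae.stem_params()):
            np.testing.assert_array_equal(b, p.value)

    def test_joint_phase_updates_stem(self, small_two_domain):
        vae = ResVAE(latent_dim=4, encoder_block_dims=(8,), epochs=10, seed=3)
        vae.fit(small_two_domain.source.values)
        before = [p.value.copy() for p in vae.stem_params()]
        clf = DualHeadClassifier(
            stem=vae, schedule=TrainSchedule(total_epochs=6,
                                             head_only_epochs=3, seed=4))
        clf.fit(small_two_domain.source.values,
                small_two_domain.source_labels.response)
        changed = any(not np.array_equal(b, p.value)
                      for b, p in zip(before, vae.stem_params()))
        assert changed

    def test_separable_data_learned(self):
        rng = np.random.default_rng(12)
        x = np.vstack([rng.normal(-2, 0.3, (100, 6)),
                       rng.normal(2, 0.3, (100, 6))])
        y = np.array([0] * 100 + [1] * 100)
        vae = ResVAE(latent_dim=3, encoder_block_dims=(8,), epochs=20, seed=5)
        vae.fit(x)
        clf = DualHeadClassifier(
            stem=vae, schedule=TrainSchedule(total_epochs=60,
                                             head_only_epochs=50, seed=6))
        clf.fit(x, y)
        assert (clf.predict(x) == y).mean() >= 0.98

    def test_mmd_transfer_requires_target(self, small_vae, small_two_domain):
        clf = DualHeadClassifier(stem=small_vae, transfer="mmd")
        with pytest.raises(ValueError):
            clf.fit(small_two_domain.source.values,
                    small_two_domain.source_labels.response)

    def test_mmd_term_decreases_during_joint_phase(self, small_two_domain):
        from scadapt.transfer import mmd2
        vae = ResVAE(latent_dim=4, encoder_block_dims=(8,), epochs=15, seed=3)
        vae.fit(small_two_domain.source.values)
        src = small_two_domain.source.values
        tgt = small_two_domain.target.values
        clf = DualHeadClassifier(
            stem=vae, transfer="mmd",
            schedule=TrainSchedule(total_epochs=40, head_only_epochs=10,
                                   seed=7))
        before = None
        z_s, z_t = vae.transform(src), vae.transform(tgt)
        clf_pre_gamma = None
        clf.fit(src, small_two_domain.source_labels.response, target_X=tgt)
        before = mmd2(z_s, z_t, clf.mmd_gamma_)
        after = mmd2(vae.transform(src), vae.transform(tgt), clf.mmd_gamma_)
        assert after < before


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        m = evaluate(y, y.astype(float), y)
        for key in ("auroc", "auprc", "f1", "mcc", "accuracy", "precision",
                    "recall"):
            assert m[key] == pytest.approx(1.0)

    def test_mcc_hand_value(self):
        # TP=2, TN=1, FP=1, FN=0  ->  MCC = 2/sqrt(12)
        y_true = np.array([1, 1, 0, 0])
        calls = np.array([1, 1, 1, 0])
        m = evaluate(y_true, calls.astype(float), calls)
        assert m["mcc"] == pytest.approx(2 / np.sqrt(12), abs=1e-9)

    def test_anti_ranking_gives_zero_auroc(self):
        y = np.array([0, 1, 0, 1])
        m = evaluate(y, 1.0 - y, 1 - y)
        assert m["auroc"] == 0.0

    def test_single_class_truth(self):
        m = evaluate(np.zeros(4, dtype=int), np.linspace(0, 1, 4),
                     np.zeros(4, dtype=int))
        assert np.isnan(m["auroc"]) and m["accuracy"] == 1.0


class TestSilhouette:
    def test_hand_computed_two_cluster_value(self):
        emb = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([0, 0, 1, 1])
        s = per_class_silhouette(emb, labels)
        # sample 0: a=1, b=10.5; sample 1: a=1, b=9.5
        expected = ((10.5 - 1) / 10.5 + (9.5 - 1) / 9.5) / 2
        assert s["sensitive"] == pytest.approx(expected, abs=1e-9)

    def test_interleaved_clusters_score_low(self):
        rng = np.random.default_rng(13)
        emb = rng.standard_normal((40, 2))
        labels = np.array([0, 1] * 20)
        s = per_class_silhouette(emb, labels)
        assert s["sensitive"] <= 0.05 and s["resistant"] <= 0.05

    def test_permutation_invariance(self):
        rng = np.random.default_rng(14)
        emb = rng.standard_normal((20, 3))
        labels = (rng.random(20) < 0.5).astype(int)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        perm = rng.permutation(20)
        a = per_class_silhouette(emb, labels)
        b = per_class_silhouette(emb[perm], labels[perm])
        assert a["sensitive"] == pytest.approx(b["sensitive"])
        assert a["resistant"] == pytest.approx(b["resistant"])
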