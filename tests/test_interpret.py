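"""Native interpretation modalities and post-hoc attribution baselines."""

import itertools

import numpy as np
import pytest

from flan import FLAN, TrainConfig
from flan.grouping import FeatureSpec, encode_tabular
from flan.interpret import (
    interpretation_report,
    latent_norm_scores,
    nearest_neighbors,
    pam_kmedoids,
    posthoc_scores,
    prototypes,
    single_feature_prediction,
)


class TestFeatureImportance:
    def test_matches_norm_oracle(self, trained_results, tiny_tabular_ds):
        imp = trained_results.feature_importance(tiny_tabular_ds)
        latent = trained_results.encode(tiny_tabular_ds)
        oracle = np.sqrt((latent.per_feature**2).sum(axis=2))
        np.testing.assert_allclose(imp.scores, oracle, atol=1e-6)

    def test_zero_encoders_zero_scores(self, tiny_tabular_ds):
        res = FLAN(tiny_tabular_ds, latent_dim=4).as_results()
        for p in res.network.params:
            p[...] = 0.0
        assert np.all(res.feature_importance(tiny_tabular_ds).scores == 0.0)

    def test_output_scaling_homogeneity(self, tiny_tabular_ds):
        """Scaling one encoder's output layer by c scales its column by |c|."""
        res = FLAN(tiny_tabular_ds, latent_dim=4, encoder_hidden=(6,)).as_results()
        before = res.feature_importance(tiny_tabular_ds).scores.copy()
        c = -2.5
        res.network.encoder.weights[-1][2] *= c
        res.network.encoder.biases[-1][2] *= c
        after = res.feature_importance(tiny_tabular_ds).scores
        np.testing.assert_allclose(after[:, 2], np.abs(c) * before[:, 2], rtol=1e-9)
        np.testing.assert_allclose(np.delete(after, 2, 1), np.delete(before, 2, 1))


class TestGlobalImportance:
    def test_single_sample_single_class(self, trained_results, tiny_tabular_ds):
        one = tiny_tabular_ds.subset(np.asarray([0]))
        gi = trained_results.global_importance(one, normalization="none")
        imp = trained_results.feature_importance(one)
        c = int(np.flatnonzero(trained_results.classes_ == one.labels[0])[0])
        np.testing.assert_allclose(gi.table[c], imp.scores[0])

    def test_per_feature_max_normalization(self, trained_results, tiny_tabular_ds):
        gi = trained_results.global_importance(tiny_tabular_ds)
        col_max = np.nanmax(gi.table, axis=0)
        np.testing.assert_allclose(col_max[col_max > 0], 1.0)

    def test_empty_class_flagged_not_zeroed(self, trained_results, tiny_tabular_ds):
        subset = tiny_tabular_ds.subset(np.flatnonzero(tiny_tabular_ds.labels == 0))
        gi = trained_results.global_importance(subset, grouping="true_label")
        assert 1 in gi.empty_classes
        assert np.isnan(gi.table[1]).all()

    def test_both_grouping_modes_available(self, trained_results, tiny_tabular_ds):
        for grouping in ("true_label", "predicted_label"):
            gi = trained_results.global_importance(tiny_tabular_ds, grouping=grouping)
            assert gi.table.shape == (2, tiny_tabular_ds.spec.n_features)


class TestAlgorithmicInterpretation:
    def test_linear_zero_bias_head_exact(self, tiny_tabular_ds):
        """With a linear zero-bias psi the first-order residual vanishes."""
        res = FLAN(tiny_tabular_ds, latent_dim=4, encoder_hidden=(6,),
                   predictor="linear", predictor_bias=False).as_results()
        for s in range(3):
            for i in range(tiny_tabular_ds.spec.n_features):
                interp = single_feature_prediction(res, tiny_tabular_ds, s, i)
                assert interp.residual <= 1e-5

    def test_residual_matches_definitional_oracle(self, trained_results,
                                                  tiny_tabular_ds):
        s, i = 4, 2
        interp = single_feature_prediction(trained_results, tiny_tabular_ds, s, i)
        latent = trained_results.encode(tiny_tabular_ds)
        psi = trained_results.network.psi_logits
        z_i = latent.per_feature[s, i]
        z_star = latent.aggregate[s] - z_i
        oracle = np.linalg.norm(
            (psi((z_star + z_i)[None])[0] - psi(z_star[None])[0]) - psi(z_i[None])[0]
        )
        assert interp.residual == pytest.approx(oracle, abs=1e-12)

    def test_deep_head_residual_at_least_linear(self, tiny_tabular_ds):
        """Mean residual with a deep psi >= residual with a linear psi."""
        def mean_residual(res):
            vals = [
                single_feature_prediction(res, tiny_tabular_ds, s, i).residual
                for s in range(5)
                for i in range(tiny_tabular_ds.spec.n_features)
            ]
            return float(np.mean(vals))

        cfg = TrainConfig(epochs=10, seed=2, patience=0)
        deep = FLAN(tiny_tabular_ds, latent_dim=4, predictor_hidden=(16, 16)).fit(cfg)
        linear = FLAN(tiny_tabular_ds, latent_dim=4, predictor="linear",
                      predictor_bias=False).fit(cfg)
        assert mean_residual(linear) <= 1e-5
        assert mean_residual(deep) >= mean_residual(linear)

    def test_out_of_range_feature(self, trained_results, tiny_tabular_ds):
        with pytest.raises(IndexError):
            single_feature_prediction(trained_results, tiny_tabular_ds, 0, 99)

    def test_report_layout(self, trained_results, tiny_tabular_ds):
        """Top-3 classes for the full prediction and for each of the 7
        highest-norm features."""
        report = interpretation_report(trained_results, tiny_tabular_ds, 0,
                                       top_features=7, top_classes=3)
        assert len(report["full"]) <= 3
        assert len(report["features"]) == min(7, tiny_tabular_ds.spec.n_features)
        for entry in report["features"]:
            assert len(entry["top_classes"]) <= 3
            probs = [c["probability"] for c in entry["top_classes"]]
            assert probs == sorted(probs, reverse=True)


class TestPrototypes:
    def test_pam_matches_exhaustive_search(self):
        """PAM objective equals the exhaustive optimum for groups <= 12."""
        rng = np.random.default_rng(0)
        for n, k in [(8, 2), (12, 3), (10, 6), (5, 1)]:
            Z = rng.normal(size=(n, 3))
            dist = np.linalg.norm(Z[:, None] - Z[None], axis=2)
            medoids = pam_kmedoids(dist, k, rng)
            best = min(
                dist[:, list(combo)].min(axis=1).sum()
                for combo in itertools.combinations(range(n), k)
            )
            assert dist[:, medoids].min(axis=1).sum() == pytest.approx(best, abs=1e-9)

    def test_small_group_returned_whole(self, trained_results, tiny_tabular_ds):
        ps = prototypes(trained_results, tiny_tabular_ds.subset(np.arange(4)),
                        k_per_class=6)
        total = sum(len(v) for v in ps.medoid_ids.values())
        assert total == 4

    def test_medoids_come_from_their_predicted_class(self, trained_results,
                                                     tiny_tabular_ds):
        ps = prototypes(trained_results, tiny_tabular_ds, k_per_class=3)
        predicted = trained_results.predict(tiny_tabular_ds)
        for c, ids in ps.medoid_ids.items():
            assert all(predicted[i] == c for i in ids)


class TestNearestNeighbors:
    def test_query_ranks_itself_first(self, trained_results, tiny_tabular_ds):
        ids, dists = nearest_neighbors(trained_results, tiny_tabular_ds, query=5, k=3)
        assert ids[0] == 5
        assert dists[0] == 0.0

    def test_matches_exhaustive_scan(self, trained_results, tiny_tabular_ds):
        latent = trained_results.encode(tiny_tabular_ds)
        q = 7
        full = np.linalg.norm(latent.aggregate - latent.aggregate[q][None], axis=1)
        expected = np.lexsort((np.arange(len(full)), full))[:4]
        ids, dists = nearest_neighbors(trained_results, tiny_tabular_ds, query=q, k=4)
        np.testing.assert_array_equal(ids, expected)
        np.testing.assert_allclose(dists, full[expected])

    def test_oversized_k_warns_and_returns_all(self, trained_results, tiny_tabular_ds):
        small = tiny_tabular_ds.subset(np.arange(5))
        with pytest.warns(UserWarning, match="exceeds"):
            ids, _ = nearest_neighbors(trained_results, small, query=0, k=10)
        assert len(ids) == 5


class TestPosthocScores:
    def test_constant_model_all_zero(self, tiny_tabular_ds):
        res = FLAN(tiny_tabular_ds, latent_dim=4).as_results()
        for p in res.network.params:
            p[...] = 0.0
        for method in ("saliency", "input_x_gradient", "integrated_gradients"):
            scores = posthoc_scores(res, tiny_tabular_ds, method, steps=4)
            assert np.all(scores == 0.0)

    def test_integrated_gradients_linear_completeness(self):
        """On a linear model IG from a zero baseline equals input x weight."""
        rng = np.random.default_rng(0)
        ds = encode_tabular(rng.normal(size=(12, 5)), FeatureSpec.tabular(5),
                            labels=rng.integers(0, 2, 12))
        res = FLAN(ds, latent_dim=3, encoder_hidden=(), predictor="linear").as_results()
        ig = posthoc_scores(res, ds, "integrated_gradients", steps=8)
        grad, logits = res.network.input_gradients(ds.features, logits_argmax(res, ds))
        expected = (ds.features * grad)[:, :, 0]
        np.testing.assert_allclose(ig, expected, atol=1e-10)
        # step count is irrelevant for a linear path integral
        np.testing.assert_allclose(
            posthoc_scores(res, ds, "integrated_gradients", steps=2), ig, atol=1e-10
        )

    def test_token_scores_computed_at_embeddings(self, sequence_results,
                                                 tiny_sequence_task):
        ds = tiny_sequence_task.encoded(idx=np.arange(6))
        scores = posthoc_scores(sequence_results, ds, "saliency")
        assert scores.shape == (6, ds.spec.n_features)
        assert np.all(scores >= 0.0)

    def test_image_scores_shape(self, image_results, tiny_image_task):
        ds = tiny_image_task.encoded(idx=np.arange(5))
        for method in ("saliency", "input_x_gradient", "integrated_gradients"):
            assert posthoc_scores(image_results, ds, method, steps=4).shape == (5, 49)

    def test_unknown_method_rejected(self, trained_results, tiny_tabular_ds):
        with pytest.raises(ValueError):
            posthoc_scores(trained_results, tiny_tabular_ds, "shap")


def logits_argmax(res, ds):
    return res.predict_logits(ds).argmax(axis=1)


class TestImportanceGroundTruth:
    def test_planted_features_dominate(self):
        """Training with the sparsity regularizer concentrates mean latent
        norms on the planted informative features."""
        from flan.synthetic import SyntheticTabularSpec, gen_tabular

        task = gen_tabular(SyntheticTabularSpec(
            n_samples=1000, n_features=6, informative=(0, 1),
            effects=("quadratic", "identity"), weight_scale=2.0, seed=7,
        ))
        ds = task.encoded()
        res = FLAN(ds, latent_dim=5, encoder_hidden=(8, 8)).fit(
            TrainConfig(epochs=100, seed=0, sparsity_weight=0.05, patience=0,
                        batch_size=64)
        )
        mean_imp = latent_norm_scores(res, ds).mean(axis=0)
        top2 = set(np.argsort(-mean_imp)[:2].tolist())
        assert top2 == set(task.spec.informative)
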