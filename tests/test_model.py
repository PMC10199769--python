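"""The additive architecture's structural guarantees and training behavior."""

import numpy as np
import pytest

from flan import FLAN, TrainConfig, aggregate
from flan.exceptions import (
    DegenerateLabelsError,
    InputShapeError,
    SpecValidationError,
)
from flan.grouping import FeatureSpec, encode_tabular
from flan.model import FLANResults
from flan.synthetic import SyntheticTabularSpec, gen_tabular


def zeroed(results):
    for p in results.network.params:
        p[...] = 0.0
    return results


class TestEncoding:
    def test_zero_weights_give_zero_latents(self, tiny_tabular_ds):
        model = FLAN(tiny_tabular_ds, latent_dim=4, encoder_hidden=(6,))
        res = zeroed(model.as_results())
        latent = res.encode(tiny_tabular_ds)
        assert np.all(latent.per_feature == 0.0)

    @pytest.mark.parametrize("mode", ["independent", "shared", "token"])
    def test_separability(self, mode, tiny_tabular_ds, tiny_sequence_task,
                          tiny_image_task):
        """Perturbing feature j changes only column j of the latents."""
        if mode == "independent":
            ds = tiny_tabular_ds
            res = FLAN(ds, latent_dim=4, encoder_hidden=(6,)).as_results()
        elif mode == "shared":
            ds = tiny_image_task.encoded()
            res = FLAN(ds, latent_dim=4, encoder_hidden=(6,)).as_results()
        else:
            ds = tiny_sequence_task.encoded()
            res = FLAN(ds, latent_dim=4, encoder_hidden=(6,), embed_dim=3).as_results()
        feats = ds.features[:4].copy()
        base = res.network.encode(feats)
        rng = np.random.default_rng(0)
        for j in (0, ds.spec.n_features - 1):
            bumped = feats.copy()
            if ds.spec.kind == "token":
                bumped[:, j, :] = (bumped[:, j, :] + 1) % len(ds.spec.vocabulary)
            else:
                bumped[:, j, :] += rng.standard_normal(bumped[:, j, :].shape)
            z = res.network.encode(bumped)
            others = [i for i in range(ds.spec.n_features) if i != j]
            np.testing.assert_array_equal(z[:, others, :], base[:, others, :])
            assert not np.array_equal(z[:, j, :], base[:, j, :])

    def test_spec_mismatch_rejected(self, tiny_tabular_ds, untrained_results):
        other = encode_tabular(np.zeros((2, 3)), FeatureSpec.tabular(3))
        with pytest.raises(InputShapeError):
            untrained_results.predict_proba(other)


class TestAggregation:
    def test_aggregate_matches_loop_oracle(self, untrained_results, tiny_tabular_ds):
        latent = untrained_results.encode(tiny_tabular_ds)
        explicit = np.zeros_like(latent.aggregate)
        for i in range(latent.per_feature.shape[1]):
            explicit = explicit + latent.per_feature[:, i, :]
        np.testing.assert_allclose(latent.aggregate, explicit, rtol=1e-6)

    def test_permutation_invariance(self, untrained_results, tiny_tabular_ds):
        latent = untrained_results.encode(tiny_tabular_ds)
        rng = np.random.default_rng(1)
        perm = rng.permutation(latent.per_feature.shape[1])
        permuted = latent.per_feature[:, perm, :]
        np.testing.assert_allclose(permuted.sum(axis=1), latent.aggregate, rtol=1e-9)

    def test_single_feature_identity(self):
        ds = encode_tabular(np.random.default_rng(0).normal(size=(5, 1)),
                            FeatureSpec.tabular(1), labels=[0, 1, 0, 1, 0])
        res = FLAN(ds, latent_dim=3, encoder_hidden=(4,)).as_results()
        latent = res.encode(ds)
        np.testing.assert_array_equal(latent.aggregate, latent.per_feature[:, 0, :])


class TestPrediction:
    def test_zero_head_gives_uniform_probabilities(self, tiny_tabular_ds):
        res = zeroed(FLAN(tiny_tabular_ds, latent_dim=4).as_results())
        probs = res.predict_proba(tiny_tabular_ds)
        np.testing.assert_allclose(probs, 0.5)

    def test_rows_are_probability_vectors(self, trained_results, tiny_tabular_ds):
        probs = trained_results.predict_proba(tiny_tabular_ds)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_composition_identity(self, trained_results, tiny_tabular_ds):
        """predict == softmax(psi(aggregate(encode(.)))) by construction."""
        from flan.nn import softmax

        latent = trained_results.encode(tiny_tabular_ds)
        via_parts = softmax(trained_results.network.psi_logits(aggregate(latent)))
        np.testing.assert_array_equal(
            trained_results.predict_proba(tiny_tabular_ds), via_parts
        )

    def test_predict_from_latent_matches_predict(self, trained_results, tiny_tabular_ds):
        latent = trained_results.encode(tiny_tabular_ds)
        np.testing.assert_array_equal(
            trained_results.predict_proba_from_latent(latent.aggregate),
            trained_results.predict_proba(tiny_tabular_ds),
        )

    def test_identical_latents_identical_outputs(self, trained_results):
        z = np.random.default_rng(2).normal(size=(1, 5))
        two = np.concatenate([z, z])
        out = trained_results.predict_proba_from_latent(two)
        np.testing.assert_array_equal(out[0], out[1])

    def test_latent_width_mismatch_rejected(self, trained_results):
        with pytest.raises(InputShapeError):
            trained_results.predict_proba_from_latent(np.zeros((2, 7)))

    def test_zero_contribution_bitwise(self, trained_results, tiny_tabular_ds):
        """A zeroed latent and an omitted latent give bit-identical outputs."""
        latent = trained_results.encode(tiny_tabular_ds)
        i = 3
        pf = latent.per_feature.copy()
        pf[:, i, :] = 0.0
        omitted = np.delete(latent.per_feature, i, axis=1)
        np.testing.assert_array_equal(
            trained_results.network.psi_logits(pf.sum(axis=1)),
            trained_results.network.psi_logits(omitted.sum(axis=1)),
        )


class TestTraining:
    def test_zero_sparsity_weight_means_zero_penalty(self, tiny_tabular_ds):
        res = FLAN(tiny_tabular_ds, latent_dim=4, encoder_hidden=(6,)).fit(
            TrainConfig(epochs=3, seed=0, sparsity_weight=0.0)
        )
        assert all(p == 0.0 for p in res.history["penalty"])

    def test_linearly_separable_data_learned(self):
        """Well separated linear task reaches >= 0.99 training accuracy."""
        rng = np.random.default_rng(0)
        n = 400
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 2)) * 0.3 + np.where(y[:, None] == 1, 2.0, -2.0)
        ds = encode_tabular(X, FeatureSpec.tabular(2), labels=y)
        res = FLAN(ds, latent_dim=4, encoder_hidden=(8,)).fit(
            TrainConfig(epochs=40, seed=0, patience=0, val_fraction=0.0)
        )
        assert res.accuracy(ds) >= 0.99

    def test_sparsity_weight_reduces_active_features(self, tiny_tabular_task):
        """Larger lambda weakly decreases the number of features whose mean
        latent norm exceeds 1% of the maximum."""
        ds = tiny_tabular_task.encoded()
        counts = []
        for lam in (0.0, 0.3):
            res = FLAN(ds, latent_dim=5, encoder_hidden=(8,)).fit(
                TrainConfig(epochs=30, seed=1, sparsity_weight=lam, patience=0)
            )
            norms = res.encode(ds).norms().mean(axis=0)
            counts.append(int((norms > 0.01 * norms.max()).sum()))
        assert counts[1] <= counts[0]

    def test_fixed_seed_reproducible_log(self, tiny_tabular_ds):
        cfg = TrainConfig(epochs=5, seed=11, batch_size=32)
        m = FLAN(tiny_tabular_ds, latent_dim=4, encoder_hidden=(6,))
        h1 = m.fit(cfg).history
        h2 = m.fit(cfg).history
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_single_class_rejected(self):
        ds = encode_tabular(np.zeros((10, 2)), FeatureSpec.tabular(2), labels=[1] * 10)
        with pytest.raises(DegenerateLabelsError):
            FLAN(ds, latent_dim=2).fit(TrainConfig(epochs=1))

    def test_invalid_config_rejected(self):
        with pytest.raises(SpecValidationError):
            TrainConfig(sparsity_weight=-1.0)
        with pytest.raises(SpecValidationError):
            TrainConfig(val_fraction=0.9)

    def test_smote_balances_minority_class(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(-2, 1, (90, 3)), rng.normal(2, 1, (12, 3))])
        y = np.array([0] * 90 + [1] * 12)
        ds = encode_tabular(X, FeatureSpec.tabular(3), labels=y)
        res = FLAN(ds, latent_dim=3, encoder_hidden=(6,)).fit(
            TrainConfig(epochs=15, seed=0, class_balance="smote", val_fraction=0.0,
                        patience=0)
        )
        assert res.accuracy(ds) > 0.9

    def test_smote_rejected_for_token_data(self, tiny_sequence_task):
        ds = tiny_sequence_task.encoded()
        with pytest.raises(SpecValidationError):
            FLAN(ds, latent_dim=4, embed_dim=3).fit(
                TrainConfig(epochs=1, class_balance="smote")
            )


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, trained_results, tiny_tabular_ds,
                                             tmp_path):
        path = tmp_path / "model.npz"
        trained_results.save(path)
        loaded = FLANResults.load(path)
        np.testing.assert_array_equal(
            loaded.predict_proba(tiny_tabular_ds),
            trained_results.predict_proba(tiny_tabular_ds),
        )

    def test_version_mismatch_fails_loudly(self, trained_results, tmp_path):
        import json

        from flan.exceptions import CheckpointError

        path = tmp_path / "model.npz"
        trained_results.save(path)
        with np.load(path) as archive:
            arrays = {k: archive[k] for k in archive.files}
        meta = json.loads(str(arrays["meta"]))
        meta["format"] = "flan-checkpoint-0"
        arrays["meta"] = json.dumps(meta)
        np.savez(path, **arrays)
        with pytest.raises(CheckpointError):
            FLANResults.load(path)


class TestModelSurface:
    def test_from_dataframe_carries_feature_names(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["CD8A", "CD8B", "NKG7"])
        df["cell_type"] = rng.integers(0, 2, 30)
        model = FLAN.from_dataframe(df, "cell_type", latent_dim=3)
        assert model.spec.feature_names == ("CD8A", "CD8B", "NKG7")

    def test_single_cell_configuration_accepted(self):
        """117 independent gene encoders into a 24-dimensional latent space."""
        rng = np.random.default_rng(0)
        ds = encode_tabular(rng.normal(size=(20, 117)), FeatureSpec.tabular(117),
                            labels=rng.integers(0, 7, 20))
        model = FLAN(ds, latent_dim=24)
        assert model.network.latent_dim == 24
        assert not model.network.shared
        z = model.as_results().encode(ds)
        assert z.per_feature.shape == (20, 117, 24)

    def test_summary_mentions_architecture(self, trained_results):
        text = trained_results.summary()
        assert "latent dim" in text and "per-feature" in text
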