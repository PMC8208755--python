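"""Autoencoder training, assembly, persistence and grid search."""

import itertools

import numpy as np
import pytest

import ecolatent as el
from ecolatent.models import (GRID_ACTIVATIONS_ENCDEC, GRID_ACTIVATIONS_LATENT,
                              GRID_BATCH_SIZES, GRID_HIDDEN_LAYERS,
                              GRID_LATENT_DIMS, GRID_LEARNING_RATES, GRID_LOSSES,
                              GRID_NORMALIZATIONS, decoder_digest)
from ecolatent.transforms import encode_environment, tss


def _split_small(small_dataset, seed=1):
    counts, taxonomy, env, truth = small_dataset
    split = el.split_dataset(counts.sample_ids, 0.2, 2, seed=seed)
    return (counts.select_samples(split.train_ids), counts.select_samples(split.test_ids),
            env.select_samples(split.train_ids), env.select_samples(split.test_ids))


class TestArchitectureConfig:
    def test_simplex_loss_requires_tss(self):
        with pytest.raises(ValueError, match="tss"):
            el.ArchitectureConfig(loss_kind="braycurtis", normalization="tss_clr")
        with pytest.raises(ValueError, match="tss"):
            el.ArchitectureConfig(loss_kind="crossentropy", normalization="tss_clr")

    def test_output_head_follows_normalization(self):
        assert el.ArchitectureConfig(normalization="tss").output_head == "softmax"
        assert el.ArchitectureConfig(normalization="tss_clr",
                                     loss_kind="mse").output_head == "identity"

    def test_roundtrip_dict(self):
        cfg = el.ArchitectureConfig(latent_dim=50, hidden_layers=(512, 256))
        assert el.ArchitectureConfig.from_dict(cfg.to_dict()) == cfg


class TestGridEnumeration:
    def test_raw_and_valid_cell_counts_match_brute_force(self):
        """The raw grid has 3·3·3·2·2·2·2·3 = 1296 cells; removing the
        simplex-loss × CLR pairs leaves the count a direct enumeration of the
        constraint gives."""
        raw = el.grid_cells(filter_invalid=False)
        assert len(raw) == 1296
        valid = el.grid_cells(filter_invalid=True)
        brute = sum(
            1
            for _, _, _, _, norm, loss, _, _ in itertools.product(
                GRID_LATENT_DIMS, GRID_HIDDEN_LAYERS, GRID_ACTIVATIONS_ENCDEC,
                GRID_ACTIVATIONS_LATENT, GRID_NORMALIZATIONS, GRID_LOSSES,
                GRID_LEARNING_RATES, GRID_BATCH_SIZES)
            if not (loss in ("crossentropy", "braycurtis") and norm != "tss")
        )
        assert len(valid) == brute
        assert all(isinstance(c, el.ArchitectureConfig) for c in valid)


class TestOTUAutoencoder:
    def test_untrained_is_no_better_than_default(self, small_dataset):
        tr, te, _, _ = _split_small(small_dataset)
        cfg = el.ArchitectureConfig(latent_dim=5, hidden_layers=(32,), epochs=0, seed=0)
        ae = el.train_otu_autoencoder(tr, te, cfg)
        rec = ae.reconstruct(te)
        actual = tss(te)
        default = el.fit_default(tss(tr)).predict(None, n_samples=te.n_samples)
        r_untrained = el.mean_pearson(rec.values, actual.values)
        r_default = el.mean_pearson(default.values, actual.values)
        assert r_untrained <= r_default + 0.05

    def test_training_improves_reconstruction(self, small_dataset):
        tr, te, _, _ = _split_small(small_dataset)
        cfg = el.ArchitectureConfig(latent_dim=5, hidden_layers=(32,), epochs=40, seed=0)
        untrained = el.train_otu_autoencoder(
            tr, te, el.ArchitectureConfig(latent_dim=5, hidden_layers=(32,),
                                          epochs=0, seed=0))
        trained = el.train_otu_autoencoder(tr, te, cfg)
        actual = tss(te)
        r0 = el.mean_pearson(untrained.reconstruct(te).values, actual.values)
        r1 = el.mean_pearson(trained.reconstruct(te).values, actual.values)
        assert r1 >= r0

    def test_seeded_determinism(self, small_dataset):
        tr, te, _, _ = _split_small(small_dataset)
        cfg = el.ArchitectureConfig(latent_dim=5, hidden_layers=(32,), epochs=10, seed=3)
        a = el.train_otu_autoencoder(tr, te, cfg)
        b = el.train_otu_autoencoder(tr, te, cfg)
        assert a.history["val_loss"][-1] == b.history["val_loss"][-1]
        assert decoder_digest(a) == decoder_digest(b)

    def test_clr_pathway_trains(self, small_dataset):
        tr, te, _, _ = _split_small(small_dataset)
        cfg = el.ArchitectureConfig(latent_dim=5, hidden_layers=(32,), epochs=30,
                                    normalization="tss_clr", loss_kind="mse", seed=0)
        ae = el.train_otu_autoencoder(tr, te, cfg)
        rec = ae.reconstruct(te)
        np.testing.assert_allclose(rec.values.sum(axis=0), 1.0, atol=1e-9)
        assert el.mean_pearson(rec.values, tss(te).values) > 0.5


@pytest.fixture(scope="module")
def trained(small_dataset):
    tr, te, env_tr, env_te = _split_small(small_dataset)
    cfg = el.ArchitectureConfig(latent_dim=5, hidden_layers=(32,), epochs=40,
                                latent_align_weight=1.0, seed=0)
    return el.train_combined_autoencoder(tr, env_tr, te, env_te, cfg), (tr, te, env_te)


class TestCombinedAutoencoder:
    def test_alignment_term_decreases(self, trained):
        """The penalized latent distance shrinks from initialization to
        convergence, and trends downward over training."""
        ae, _ = trained
        align = ae.history["val_align"]
        assert align[-1] < align[0]
        mid = len(align) // 2
        assert np.mean(align[mid:]) < np.mean(align[:mid])

    def test_env_reconstruction_close_to_otu_reconstruction(self, trained):
        ae, (tr, te, env_te) = trained
        actual = tss(te)
        r_otu = el.mean_pearson(ae.reconstruct(te).values, actual.values)
        e_val, _ = encode_environment(env_te, ae.schema)
        out = ae.decoder.predict(ae.env_encoder.predict(e_val))
        from ecolatent.transforms import inverse_to_relative
        rel = inverse_to_relative(out.T, ae.norm_state)
        r_env = el.mean_pearson(rel, actual.values)
        assert r_env >= r_otu - 0.15

    def test_zero_weight_does_not_collapse_latents(self, small_dataset):
        tr, te, env_tr, env_te = _split_small(small_dataset)
        cfg = el.ArchitectureConfig(latent_dim=5, hidden_layers=(32,), epochs=15,
                                    latent_align_weight=0.0, seed=0)
        ae = el.train_combined_autoencoder(tr, env_tr, te, env_te, cfg)
        align = ae.history["val_align"]
        assert align[-1] > 0.05 * align[0]


class TestLatentPredictor:
    def test_recovers_linear_map_vs_ols_oracle(self):
        rng = np.random.default_rng(9)
        e = rng.normal(size=(400, 4))
        b = rng.normal(size=(4, 3))
        z = e @ b + rng.normal(0, 0.02, size=(400, 3))
        cfg = el.ArchitectureConfig(hidden_layers=(32,), epochs=200, patience=30,
                                    learning_rate=0.01, seed=0)
        net = el.train_latent_predictor(e[:300], z[:300], cfg)
        pred = net.predict(e[300:])
        resid = ((pred - z[300:]) ** 2).sum()
        total = ((z[300:] - z[300:].mean(axis=0)) ** 2).sum()
        r2 = 1 - resid / total
        # OLS on the same rows is the attainable ceiling
        coef, *_ = np.linalg.lstsq(e[:300], z[:300], rcond=None)
        ols_r2 = 1 - ((e[300:] @ coef - z[300:]) ** 2).sum() / total
        assert r2 >= 0.95
        assert r2 <= ols_r2 + 0.01

    def test_constant_targets_predicted_exactly(self):
        rng = np.random.default_rng(10)
        e = rng.normal(size=(100, 3))
        z = np.tile([0.5, -1.0], (100, 1))
        cfg = el.ArchitectureConfig(hidden_layers=(8,), epochs=300,
                                    learning_rate=0.01, patience=50, seed=0)
        net = el.train_latent_predictor(e, z, cfg)
        assert ((net.predict(e) - z) ** 2).mean() < 1e-3

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="row counts"):
            el.train_latent_predictor(np.zeros((5, 2)), np.zeros((4, 3)),
                                      el.ArchitectureConfig())


class TestAssembly:
    def test_combined_assembly_outputs_simplex(self, small_dataset):
        tr, te, env_tr, env_te = _split_small(small_dataset)
        cfg = el.ArchitectureConfig(latent_dim=5, hidden_layers=(32,), epochs=10, seed=0)
        ae = el.train_combined_autoencoder(tr, env_tr, te, env_te, cfg)
        model = el.assemble_prediction_model(ae, "combined")
        pred = model.predict(env_te)
        np.testing.assert_allclose(pred.values.sum(axis=0), 1.0, atol=1e-9)
        assert np.all(pred.values >= 0)

    def test_missing_component_errors(self, small_dataset):
        tr, te, _, _ = _split_small(small_dataset)
        cfg = el.ArchitectureConfig(latent_dim=5, hidden_layers=(32,), epochs=0, seed=0)
        ae = el.train_otu_autoencoder(tr, te, cfg)
        with pytest.raises(ValueError, match="latent predictor"):
            el.assemble_prediction_model(ae, "otu_latent")
        with pytest.raises(ValueError, match="env encoder"):
            el.assemble_prediction_model(ae, "combined")

    def test_beats_default_baseline_on_fixture(self, fixture_prediction_model,
                                               fixture_tables):
        actual = fixture_tables["actual_test"]
        pred = fixture_prediction_model.predict(fixture_tables["env_test"])
        r_model = el.mean_pearson(pred.values, actual.values)
        default = el.fit_default(tss(fixture_tables["train"]))
        r_default = el.mean_pearson(
            default.predict(fixture_tables["env_test"]).values, actual.values)
        assert r_model > r_default

    def test_persistence_bit_identical(self, small_dataset, tmp_path):
        tr, te, env_tr, env_te = _split_small(small_dataset)
        cfg = el.ArchitectureConfig(latent_dim=4, hidden_layers=(16,), epochs=5, seed=0)
        ae = el.train_combined_autoencoder(tr, env_tr, te, env_te, cfg)
        model = el.assemble_prediction_model(ae, "combined")
        el.save_prediction_model(model, tmp_path / "m")
        back = el.load_prediction_model(tmp_path / "m")
        np.testing.assert_array_equal(back.predict(env_te).values,
                                      model.predict(env_te).values)

    def test_trained_ae_roundtrip(self, small_dataset, tmp_path):
        tr, te, _, _ = _split_small(small_dataset)
        cfg = el.ArchitectureConfig(latent_dim=4, hidden_layers=(16,), epochs=5, seed=0)
        ae = el.train_otu_autoencoder(tr, te, cfg)
        el.save_trained_ae(ae, tmp_path / "ae")
        back = el.load_trained_ae(tmp_path / "ae")
        assert decoder_digest(back) == decoder_digest(ae)
        np.testing.assert_array_equal(back.encode(te), ae.encode(te))


class TestGridSearch:
    def test_single_config_grid(self, small_dataset):
        counts, _, env, _ = small_dataset
        sub_ids = counts.sample_ids[:120]
        counts = counts.select_samples(sub_ids)
        env = env.select_samples(sub_ids)
        cfg = el.ArchitectureConfig(latent_dim=3, hidden_layers=(16,), epochs=5, seed=0)
        table = el.grid_search(counts, env, [cfg], k=2, seed=0)
        assert len(table) == 1
        assert table.loc[0, "config_index"] == 0
        assert {"cv_pearson", "cv_braycurtis"} <= set(table.columns)

    def test_empty_grid_rejected(self, small_dataset):
        counts, _, env, _ = small_dataset
        with pytest.raises(ValueError, match="non-empty"):
            el.grid_search(counts, env, [], k=2)

    def test_fold_hygiene_ids_disjoint(self, small_dataset):
        counts, _, env, _ = small_dataset
        sub_ids = counts.sample_ids[:100]
        counts, env = counts.select_samples(sub_ids), env.select_samples(sub_ids)
        cfg = el.ArchitectureConfig(latent_dim=3, hidden_layers=(16,), epochs=3, seed=0)
        table = el.grid_search(counts, env, [cfg], k=3, seed=1)
        folds = table.loc[0, "fold_val_ids"]
        seen = set()
        for val in folds:
            assert not seen & set(val)
            seen |= set(val)
        assert seen == set(sub_ids)
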