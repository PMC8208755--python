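"""Shared fixtures: the synthetic study dataset and models trained on it.

The heavy objects (the full-size dataset, the trained autoencoder and the
assembled prediction model) are session-scoped so the module tests and the
acceptance suite share one training run each.
"""

import numpy as np
import pytest

import ecolatent as el
from ecolatent.models import assemble_prediction_model, train_latent_predictor
from ecolatent.transforms import encode_environment, tss

FIXTURE_AE_CONFIG = dict(latent_dim=10, hidden_layers=(256,), normalization="tss",
                         loss_kind="braycurtis", epochs=100, patience=10, seed=0)


@pytest.fixture(scope="session")
def fixture_dataset():
    """The reference synthetic study: 2000 samples × 200 taxa, 5 true latent
    dimensions, sequencing depth 10 000, seed 7."""
    cfg = el.SyntheticConfig(seed=7)
    return el.generate(cfg)


@pytest.fixture(scope="session")
def fixture_split(fixture_dataset):
    counts, _, _, _ = fixture_dataset
    return el.split_dataset(counts.sample_ids, test_fraction=0.1, k=5, seed=7)


@pytest.fixture(scope="session")
def fixture_tables(fixture_dataset, fixture_split):
    counts, taxonomy, env, truth = fixture_dataset
    split = fixture_split
    return {
        "train": counts.select_samples(split.train_ids),
        "test": counts.select_samples(split.test_ids),
        "env_train": env.select_samples(split.train_ids),
        "env_test": env.select_samples(split.test_ids),
        "actual_test": tss(counts.select_samples(split.test_ids)),
        "taxonomy": taxonomy,
        "truth": truth,
        "counts": counts,
        "env": env,
    }


@pytest.fixture(scope="session")
def fixture_ae(fixture_tables):
    """Composition autoencoder trained under the reference configuration."""
    cfg = el.ArchitectureConfig(**FIXTURE_AE_CONFIG)
    return el.train_otu_autoencoder(fixture_tables["train"], fixture_tables["test"], cfg)


@pytest.fixture(scope="session")
def fixture_prediction_model(fixture_ae, fixture_tables):
    """Environment → composition model on top of the session autoencoder."""
    e_train, schema = encode_environment(fixture_tables["env_train"])
    codes = fixture_ae.encode(fixture_tables["train"])
    predictor = train_latent_predictor(e_train, codes, fixture_ae.config)
    return assemble_prediction_model(fixture_ae, "otu_latent", predictor=predictor,
                                     schema=schema)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick-to-train dataset for unit tests (300 samples × 40 taxa)."""
    cfg = el.SyntheticConfig(n_samples=300, n_taxa=40, n_phyla=5,
                             true_latent_dim=3, depth=5000, seed=11)
    return el.generate(cfg)
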