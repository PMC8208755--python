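"""Compositional normalizations, encoding and taxonomic aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecolatent as el
from ecolatent.containers import RANKS, TaxonomyTable
from ecolatent.transforms import (NormalizationState, clr_columns,
                                  fit_encoding_schema, inverse_to_relative)


def _table(values, scale="counts"):
    values = np.asarray(values, dtype=float)
    return el.AbundanceTable(values, [f"t{i}" for i in range(values.shape[0])],
                             [f"s{j}" for j in range(values.shape[1])], scale)


class TestTSS:
    def test_simple_column(self):
        out = el.tss(_table([[2], [2], [4]]))
        np.testing.assert_allclose(out.values[:, 0], [0.25, 0.25, 0.5])
        assert out.scale == "tss"

    def test_single_taxon(self):
        np.testing.assert_allclose(el.tss(_table([[7]])).values, [[1.0]])

    def test_zero_depth_sample_named(self):
        with pytest.raises(ValueError, match="zero-depth sample: 's1'"):
            el.tss(_table([[1, 0], [2, 0]]))


class TestCLR:
    def test_equal_counts_map_to_zero(self):
        out = el.clr(_table([[1], [1], [1], [1]]), pseudocount=1)
        np.testing.assert_allclose(out.values[:, 0], np.zeros(4), atol=1e-12)

    def test_hand_computed_values(self):
        # proportions (1,2,4,8)/15; geometric mean 2^1.5; natural log
        p = np.array([[1.0], [2.0], [4.0], [8.0]]) / 15.0
        out = clr_columns(p)
        np.testing.assert_allclose(out[:, 0], [-1.0397, -0.3466, 0.3466, 1.0397],
                                   atol=1e-4)

    def test_scale_invariance(self):
        p = np.array([[1.0], [2.0], [4.0], [8.0]])
        np.testing.assert_allclose(clr_columns(p / p.sum()),
                                   clr_columns(10 * p / p.sum() / 10), atol=1e-12)

    def test_requires_counts_scale(self):
        t = el.tss(_table([[1], [3]]))
        with pytest.raises(ValueError, match="counts-scale"):
            el.clr(t)

    def test_columns_sum_to_zero(self):
        rng = np.random.default_rng(1)
        out = el.clr(_table(rng.integers(0, 50, (30, 8))), pseudocount=1)
        np.testing.assert_allclose(out.values.sum(axis=0), 0.0, atol=1e-9)


class TestInverseToRelative:
    def test_clr_symmetry(self):
        out = inverse_to_relative(np.zeros((3, 1)), NormalizationState("tss_clr"))
        np.testing.assert_allclose(out[:, 0], [1 / 3] * 3)

    def test_clr_roundtrip_identity(self):
        p = np.array([[0.2], [0.3], [0.5]])
        back = inverse_to_relative(clr_columns(p), NormalizationState("tss_clr"))
        np.testing.assert_allclose(back, p, atol=1e-9)

    def test_tss_clip_and_reclose(self):
        out = inverse_to_relative(np.array([[0.5], [-0.1], [0.7]]),
                                  NormalizationState("tss"))
        np.testing.assert_allclose(out[:, 0], [0.41667, 0.0, 0.58333], atol=1e-5)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0.01, 0.99), min_size=3, max_size=12))
    def test_clr_inverse_is_identity_on_simplex(self, raw):
        p = np.array(raw)[:, None]
        p = p / p.sum()
        back = inverse_to_relative(clr_columns(p), NormalizationState("tss_clr"))
        np.testing.assert_allclose(back, p, atol=1e-9)


class TestAggregateTaxa:
    def _taxonomy(self, phyla):
        rows = {f"t{i}": {"Kingdom": "B", "Phylum": p, "Class": f"c{i}",
                          "Order": f"o{i}", "Family": f"f{i}", "Genus": f"g{i}",
                          "Species": f"t{i}"} for i, p in enumerate(phyla)}
        return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index")[list(RANKS)])

    def test_phylum_sums(self):
        t = _table([[3], [2], [5]])
        out = el.aggregate_taxa(t, self._taxonomy(["P1", "P1", "P2"]), "Phylum")
        assert out.n_taxa == 2
        np.testing.assert_array_equal(sorted(out.values[:, 0]), [5, 5])

    def test_mass_conserved_on_fixture(self, fixture_dataset):
        counts, taxonomy, _, _ = fixture_dataset
        out = el.aggregate_taxa(counts, taxonomy, "Phylum")
        assert out.n_taxa == 12
        np.testing.assert_array_equal(out.values.sum(axis=0), counts.values.sum(axis=0))

    def test_declared_rank_sizes_respected(self):
        """A taxonomy declaring 16 phyla / 45 classes aggregates to exactly
        those row counts (rank-size template of a large field study)."""
        rng = np.random.default_rng(5)
        n = 300
        # taxon i → class i mod 45 → phylum (class mod 16); all groups appear
        classes = [f"C{i % 45:02d}" for i in range(n)]
        phyla = [f"P{(i % 45) % 16:02d}" for i in range(n)]
        rows = {f"t{i}": {"Kingdom": "B", "Phylum": phyla[i], "Class": classes[i],
                          "Species": f"t{i}"} for i in range(n)}
        tax = TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index"))
        t = _table(rng.integers(1, 100, (n, 4)))
        assert el.aggregate_taxa(t, tax, "Phylum").n_taxa == 16
        assert el.aggregate_taxa(t, tax, "Class").n_taxa == 45

    def test_clr_input_rejected(self):
        t = el.clr(_table([[1], [3]]))
        with pytest.raises(ValueError, match="clr"):
            el.aggregate_taxa(t, self._taxonomy(["P1", "P1"]), "Phylum")


class TestEncodeEnvironment:
    def _env(self, data, schema):
        return el.EnvironmentTable(pd.DataFrame(data, index=[f"s{i}" for i in
                                   range(len(next(iter(data.values()))))]), schema)

    def test_population_zscore(self):
        env = self._env({"temp": [50.0, 60.0, 70.0]}, {"temp": "numeric"})
        x, schema = el.encode_environment(env)
        np.testing.assert_allclose(x[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_one_hot(self):
        env = self._env({"line": ["B73", "Mo17", "B73"]}, {"line": "categorical"})
        x, schema = el.encode_environment(env)
        np.testing.assert_array_equal(x[0], [1, 0])
        np.testing.assert_array_equal(x[1], [0, 1])
        assert schema.column_names() == ["line=B73", "line=Mo17"]

    def test_unseen_category_encodes_to_zeros(self, caplog):
        train = self._env({"line": ["B73", "Mo17"]}, {"line": "categorical"})
        _, schema = el.encode_environment(train)
        new = self._env({"line": ["W22"]}, {"line": "categorical"})
        with caplog.at_level("WARNING"):
            x, _ = el.encode_environment(new, schema)
        np.testing.assert_array_equal(x, [[0, 0]])
        assert "outside the training vocabulary" in caplog.text

    def test_zero_variance_feature_constant_zero(self, caplog):
        env = self._env({"ph": [7.0, 7.0, 7.0]}, {"ph": "numeric"})
        with caplog.at_level("WARNING"):
            x, _ = el.encode_environment(env)
        np.testing.assert_array_equal(x, np.zeros((3, 1)))
        assert "zero variance" in caplog.text

    def test_schema_idempotence(self):
        """Transforming the training set gives mean 0 / sd 1 numeric columns,
        so re-fitting on the encoded data would change nothing."""
        rng = np.random.default_rng(2)
        env = self._env({"a": list(rng.normal(10, 3, 40)),
                         "b": list(rng.uniform(0, 5, 40))},
                        {"a": "numeric", "b": "numeric"})
        x, _ = el.encode_environment(env)
        np.testing.assert_allclose(x.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(x.std(axis=0), 1.0, atol=1e-9)

    def test_training_range_recorded(self):
        env = self._env({"temp": [50.0, 60.0, 70.0]}, {"temp": "numeric"})
        schema = fit_encoding_schema(env)
        assert schema.numeric_range["temp"] == (50.0, 70.0)
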