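"""Compositional normalizations, feature encoding and taxonomic aggregation.

Microbiome count vectors carry only relative information, so models are
trained on one of two per-sample normalizations:

* TSS (total-sum scaling): divide each sample by its total; the result lives
  on the probability simplex.
* TSS + CLR (centered log-ratio): after a pseudocount and TSS, take the log
  of each component over the sample's geometric mean; the result has
  zero-sum coordinates and no simplex constraint.

`inverse_to_relative` maps model output back to the simplex, so every
evaluation happens on the relative-abundance scale regardless of the
normalization a model was trained under.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RANKS, AbundanceTable, EnvironmentTable, TaxonomyTable

logger = logging.getLogger(__name__)


@dataclass
class NormalizationState:
    """Which normalization a model was trained under, recorded so that its
    outputs can be mapped back to relative abundances."""

    method: str  # 'tss' | 'tss_clr'
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in ("tss", "tss_clr"):
            raise ValueError(f"unknown normalization {self.method!r}")
        if self.method == "tss_clr" and self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive for tss_clr")


def tss(table: AbundanceTable) -> AbundanceTable:
    """Total-sum scaling: each sample (column) divided by its total."""
    if table.scale == "clr":
        raise ValueError("cannot TSS-normalize a clr-scale table")
    sums = table.values.sum(axis=0)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise ValueError(f"zero-depth sample: {table.sample_ids[zero[0]]!r}")
    return AbundanceTable(table.values / sums, list(table.taxon_ids),
                          list(table.sample_ids), scale="tss")


def clr_columns(proportions: np.ndarray) -> np.ndarray:
    """CLR of strictly positive per-column proportion vectors (pseudocount-free
    helper). Columns of the result sum to zero."""
    if np.any(proportions <= 0):
        raise ValueError("clr requires strictly positive proportions")
    logp = np.log(proportions)
    return logp - logp.mean(axis=0, keepdims=True)


def clr(table: AbundanceTable, pseudocount: float = 1.0) -> AbundanceTable:
    """Centered log-ratio after adding ``pseudocount`` to counts and TSS."""
    if table.scale != "counts":
        raise ValueError("clr expects a counts-scale table (pseudocount applies to counts)")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    shifted = table.values + pseudocount
    props = shifted / shifted.sum(axis=0)
    return AbundanceTable(clr_columns(props), list(table.taxon_ids),
                          list(table.sample_ids), scale="clr")


def softmax_columns(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def inverse_to_relative(matrix: np.ndarray, state: NormalizationState) -> np.ndarray:
    """Map a model-output matrix (taxa × samples) back to the simplex.

    TSS-trained output is clipped at zero and re-closed; CLR-trained output is
    mapped through a column softmax, which inverts CLR up to the closure
    constant.
    """
    matrix = np.asarray(matrix, dtype=float)
    if state.method == "tss":
        clipped = np.clip(matrix, 0.0, None)
        sums = clipped.sum(axis=0, keepdims=True)
        n_taxa = matrix.shape[0]
        # a fully non-positive column has no information; fall back to uniform
        out = np.where(sums > 0, clipped / np.where(sums > 0, sums, 1.0), 1.0 / n_taxa)
        return out
    return softmax_columns(matrix)


def aggregate_taxa(table: AbundanceTable, taxonomy: TaxonomyTable, level: str) -> AbundanceTable:
    """Sum rows sharing the same lineage prefix up to ``level``.

    Mass per sample is conserved exactly; the output taxon id is the
    lineage joined with ``;`` down to ``level``.
    """
    if level not in RANKS[1:6]:  # Phylum .. Genus
        raise ValueError(f"level must be one of {RANKS[1:6]}, got {level!r}")
    if table.scale == "clr":
        raise ValueError("cannot aggregate a clr-scale table: sums are not meaningful")
    taxonomy.check_covers(table)
    prefixes = [taxonomy.lineage_prefix(t, level) for t in table.taxon_ids]
    order: list[tuple[str, ...]] = sorted(set(prefixes))
    index = {p: i for i, p in enumerate(order)}
    out = np.zeros((len(order), table.n_samples))
    for row, p in enumerate(prefixes):
        out[index[p]] += table.values[row]
    new_ids = [";".join(p) for p in order]
    return AbundanceTable(out, new_ids, list(table.sample_ids), table.scale)


def aggregated_taxonomy(taxonomy: TaxonomyTable, level: str) -> TaxonomyTable:
    """Taxonomy for the output of :func:`aggregate_taxa` at the same level."""
    stop = RANKS.index(level) + 1
    rows = {}
    for t in taxonomy.taxon_ids:
        p = taxonomy.lineage_prefix(t, level)
        new_id = ";".join(p)
        rows[new_id] = dict(zip(RANKS[:stop], p))
    df = pd.DataFrame.from_dict(rows, orient="index")
    return TaxonomyTable(df)


@dataclass
class EncodingSchema:
    """Environmental-feature encoding learned on training samples.

    Numeric features are z-scored with the training mean and population
    standard deviation; categorical features are one-hot with the training
    vocabulary (unseen categories encode to an all-zeros block). Column order
    is the feature declaration order, one-hot blocks in sorted vocabulary
    order.
    """

    feature_order: list[str]
    kinds: dict[str, str]
    numeric_stats: dict[str, tuple[float, float]] = field(default_factory=dict)  # mean, sd
    numeric_range: dict[str, tuple[float, float]] = field(default_factory=dict)  # min, max
    vocabularies: dict[str, list[str]] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        n = 0
        for f in self.feature_order:
            n += 1 if self.kinds[f] == "numeric" else len(self.vocabularies[f])
        return n

    def column_names(self) -> list[str]:
        cols = []
        for f in self.feature_order:
            if self.kinds[f] == "numeric":
                cols.append(f)
            else:
                cols.extend(f"{f}={v}" for v in self.vocabularies[f])
        return cols


def fit_encoding_schema(env: EnvironmentTable) -> EncodingSchema:
    schema = EncodingSchema(feature_order=list(env.features), kinds=dict(env.schema),
                            units=dict(env.units))
    for f in env.features:
        col = env.data[f]
        if env.schema[f] == "numeric":
            x = col.to_numpy(dtype=float)
            sd = float(x.std())  # population sd
            if sd == 0.0:
                logger.warning("feature %r has zero variance; encoded as constant 0", f)
            schema.numeric_stats[f] = (float(x.mean()), sd)
            schema.numeric_range[f] = (float(x.min()), float(x.max()))
        else:
            schema.vocabularies[f] = sorted(col.astype(str).unique())
    return schema


def encode_environment(env: EnvironmentTable,
                       schema: EncodingSchema | None = None) -> tuple[np.ndarray, EncodingSchema]:
    """Encode metadata into a samples × columns design matrix.

    With ``schema=None`` the schema is fitted on ``env`` (the training set)
    first; otherwise the given training schema is applied.
    """
    if schema is None:
        schema = fit_encoding_schema(env)
    missing = [f for f in schema.feature_order if f not in env.data.columns]
    if missing:
        raise ValueError(f"metadata lacks features required by the schema: {missing}")
    blocks = []
    for f in schema.feature_order:
        col = env.data[f]
        if schema.kinds[f] == "numeric":
            mean, sd = schema.numeric_stats[f]
            x = col.to_numpy(dtype=float)
            blocks.append(((x - mean) / sd if sd > 0 else np.zeros_like(x))[:, None])
        else:
            vocab = schema.vocabularies[f]
            pos = {v: i for i, v in enumerate(vocab)}
            block = np.zeros((len(col), len(vocab)))
            unseen = 0
            for r, v in enumerate(col.astype(str)):
                if v in pos:
                    block[r, pos[v]] = 1.0
                else:
                    unseen += 1
            if unseen:
                logger.warning("feature %r: %d values outside the training vocabulary "
                               "encoded as all-zeros", f, unseen)
            blocks.append(block)
    return np.hstack(blocks), schema
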