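"""Typed containers for abundance, taxonomy and environmental metadata tables.

The on-disk format for all three tables is plain TSV. Abundance tables are
stored taxa-as-rows, samples-as-columns (the common QIIME/biom TSV export
orientation); an orientation flag transposes on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species")

UNCLASSIFIED = "unclassified"

_SCALES = ("counts", "tss", "clr")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class AbundanceTable:
    """A taxa × samples matrix of counts or normalized abundances.

    Parameters
    ----------
    values
        Array of shape ``(n_taxa, n_samples)``. Nonnegative for ``counts``
        and ``tss`` scales; unconstrained sign for ``clr``.
    taxon_ids, sample_ids
        Unique row and column identifiers.
    scale
        One of ``counts`` (raw), ``tss`` (columns sum to 1) or ``clr``
        (columns sum to 0).
    """

    values: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    scale: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (taxa × samples)")
        if self.values.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.taxon_ids)} taxa × {len(self.sample_ids)} samples"
            )
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        if self.scale in ("counts", "tss") and np.any(self.values < 0):
            raise ValueError("negative abundance in a counts/tss-scale table")
        if self.scale == "tss":
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("tss-scale columns must sum to 1 within 1e-9")
        if self.scale == "clr":
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 0.0, atol=1e-9):
                raise ValueError("clr-scale columns must sum to 0 within 1e-9")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxon_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        """Column subset in the given order."""
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return AbundanceTable(self.values[:, idx], list(self.taxon_ids), list(sample_ids), self.scale)

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "taxon_id"
        df.to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class TaxonomyTable:
    """Seven-rank lineage per taxon; missing ranks hold ``unclassified``."""

    lineages: pd.DataFrame  # index taxon_id, columns RANKS

    def __post_init__(self) -> None:
        df = self.lineages.copy()
        missing_cols = [r for r in RANKS if r not in df.columns]
        for r in missing_cols:
            df[r] = UNCLASSIFIED
        df = df[list(RANKS)].fillna(UNCLASSIFIED).astype(str)
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate taxon identifier in taxonomy: {dup!r}")
        self.lineages = df

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.lineages.index.astype(str))

    def rank_of(self, taxon_id: str, rank: str) -> str:
        return str(self.lineages.loc[taxon_id, rank])

    def lineage_prefix(self, taxon_id: str, level: str) -> tuple[str, ...]:
        """Lineage truncated at (and including) ``level``."""
        stop = RANKS.index(level) + 1
        row = self.lineages.loc[taxon_id]
        return tuple(str(row[r]) for r in RANKS[:stop])

    def check_covers(self, table: AbundanceTable) -> None:
        missing = set(table.taxon_ids) - set(self.taxon_ids)
        if missing:
            raise ValueError(f"taxonomy is missing lineages for: {sorted(missing)[:5]} ...")

    def write_tsv(self, path) -> None:
        df = self.lineages.copy()
        df.index.name = "taxon_id"
        df.to_csv(path, sep="\t")


@dataclass
class EnvironmentTable:
    """Per-sample environmental features with a declared schema.

    ``schema`` maps feature name → kind (``numeric`` or ``categorical``).
    Numeric units, when known, live in ``units``.
    """

    data: pd.DataFrame  # index sample_id, columns features
    schema: dict[str, str]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample identifier in metadata: {dup!r}")
        unknown = [c for c in df.columns if c not in self.schema]
        if unknown:
            raise ValueError(f"features missing from schema: {unknown}")
        bad = [k for k, v in self.schema.items() if v not in ("numeric", "categorical")]
        if bad:
            raise ValueError(f"schema kinds must be numeric/categorical; bad: {bad}")
        if df.isna().any().any():
            n_before = len(df)
            df = df.dropna()
            logger.info("dropped %d metadata rows with missing values", n_before - len(df))
        out = df.copy()
        for c in df.columns:
            if self.schema[c] == "numeric":
                out[c] = pd.to_numeric(df[c])
            else:
                out[c] = df[c].astype(str)
        self.data = out

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    def select_samples(self, sample_ids: list[str]) -> "EnvironmentTable":
        return EnvironmentTable(self.data.loc[sample_ids].copy(), dict(self.schema), dict(self.units))

    def select_features(self, features: list[str]) -> "EnvironmentTable":
        missing = [f for f in features if f not in self.data.columns]
        if missing:
            raise ValueError(f"unknown features: {missing}")
        return EnvironmentTable(
            self.data[features].copy(),
            {f: self.schema[f] for f in features},
            {f: u for f, u in self.units.items() if f in features},
        )

    def check_paired(self, table: AbundanceTable) -> None:
        if set(self.sample_ids) != set(table.sample_ids):
            raise ValueError("metadata sample_ids do not match the abundance table 1:1")

    def write_tsv(self, path) -> None:
        df = self.data.copy()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


@dataclass
class SplitIndices:
    """Train/test partition plus cross-validation folds within the training set."""

    train_ids: list[str]
    test_ids: list[str]
    cv_folds: list[tuple[list[str], list[str]]]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")
        covered: set[str] = set()
        for fit_ids, val_ids in self.cv_folds:
            if covered & set(val_ids):
                raise ValueError("cv fold validation sets overlap")
            covered |= set(val_ids)
            if set(fit_ids) | set(val_ids) != set(self.train_ids):
                raise ValueError("each fold must partition train_ids")
        if self.cv_folds and covered != set(self.train_ids):
            raise ValueError("cv folds do not cover train_ids")


def load_abundance_table(path, orientation: str = "taxa_as_rows") -> AbundanceTable:
    """Read a TSV count table.

    ``orientation='taxa_as_rows'`` expects the first column to hold taxon
    identifiers; ``'samples_as_rows'`` transposes after reading.
    """
    if orientation not in ("taxa_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if orientation == "samples_as_rows":
        df = df.T
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    _check_unique(row_ids, "taxon")
    _check_unique(col_ids, "sample")
    values = np.empty(df.shape, dtype=float)
    for j, c in enumerate(df.columns):
        try:
            # numpy's parser round-trips float64 exactly (pd.to_numeric does not)
            values[:, j] = df[c].to_numpy().astype(float)
        except (ValueError, TypeError):
            col = pd.to_numeric(df[c], errors="coerce")
            i = int(np.flatnonzero(col.isna().to_numpy())[0])
            raise ValueError(
                f"non-numeric cell at row {row_ids[i]!r}, column {c!r}: {df[c].iloc[i]!r}"
            ) from None
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(f"negative abundance at row {row_ids[i]!r}, column {col_ids[j]!r}")
    return AbundanceTable(values, row_ids, col_ids, scale="counts")


def load_taxonomy_table(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return TaxonomyTable(df)


def load_environment_table(path, schema: dict[str, str] | None = None,
                           units: dict[str, str] | None = None) -> EnvironmentTable:
    """Read per-sample metadata. Without an explicit schema, columns that parse
    fully as numbers are declared numeric, the rest categorical."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if schema is None:
        schema = {}
        for c in df.columns:
            try:
                pd.to_numeric(df[c].dropna())
                schema[c] = "numeric"
            except (ValueError, TypeError):
                schema[c] = "categorical"
    return EnvironmentTable(df, schema, units or {})


def split_dataset(sample_ids: list[str], test_fraction: float, k: int, seed: int) -> SplitIndices:
    """Random train/test split plus ``k``-fold CV partition of the training set.

    ``|test| = round(test_fraction · n)``; fold sizes differ by at most one.
    Deterministic for a given seed.
    """
    n = len(sample_ids)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    perm = [sample_ids[i] for i in rng.permutation(n)]
    n_test = int(round(test_fraction * n))
    test_ids = sorted(perm[:n_test])
    train_perm = perm[n_test:]
    if k > len(train_perm):
        raise ValueError(f"k={k} exceeds the {len(train_perm)} training samples")
    chunks = np.array_split(np.arange(len(train_perm)), k)
    folds = []
    for ch in chunks:
        val = sorted(train_perm[i] for i in ch)
        fit = sorted(set(train_perm) - set(val))
        folds.append((fit, val))
    return SplitIndices(sorted(train_perm), test_ids, folds, seed)
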