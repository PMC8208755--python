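"""Losses and evaluation metrics for composition prediction.

All evaluation here compares a predicted against an actual taxa × samples
matrix on the relative-abundance scale. Scale-independent metrics (mean
Pearson correlation, Bray–Curtis dissimilarity, per-taxon RRSE) are the
primary ones; MAE/MSE/MAPE are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import TaxonomyTable

CROSSENTROPY_EPS = 1e-8

LOSS_KINDS = ("mse", "crossentropy", "braycurtis")


def bray_curtis(u, v) -> float:
    """Bray–Curtis dissimilarity Σ|u−v| / Σ(u+v) between two nonnegative
    abundance vectors. Equals Σ|u−v|/2 when both vectors sum to 1."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("Bray–Curtis requires nonnegative entries")
    denom = float((u + v).sum())
    if denom == 0:
        raise ValueError("Bray–Curtis undefined for two all-zero vectors")
    return float(np.abs(u - v).sum() / denom)


def mean_bray_curtis(pred: np.ndarray, actual: np.ndarray) -> float:
    """Mean per-sample (column) Bray–Curtis between two taxa × samples matrices."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("matrices must have the same shape")
    return float(np.mean([bray_curtis(pred[:, j], actual[:, j])
                          for j in range(pred.shape[1])]))


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
    """Row-wise Pearson correlations; constant rows (in either matrix) are
    excluded. Returns (correlations, number excluded)."""
    # a vector is constant iff all entries equal (scipy's convention; a
    # variance threshold would misread roundoff in x - mean(x) as signal)
    const_a = np.all(a == a[:, :1], axis=1)
    const_b = np.all(b == b[:, :1], axis=1)
    ok = ~(const_a | const_b)
    ac = a[ok] - a[ok].mean(axis=1, keepdims=True)
    bc = b[ok] - b[ok].mean(axis=1, keepdims=True)
    sa = np.sqrt((ac ** 2).sum(axis=1))
    sb = np.sqrt((bc ** 2).sum(axis=1))
    r = (ac * bc).sum(axis=1) / (sa * sb)
    return r, int((~ok).sum())


def mean_pearson(pred: np.ndarray, actual: np.ndarray,
                 orientation: str = "per_sample",
                 return_excluded: bool = False):
    """Mean Pearson correlation between predicted and actual matrices.

    ``per_sample`` correlates each sample's composition across taxa and
    averages over samples; ``per_otu`` correlates each taxon across samples
    and averages over taxa. Vector pairs where either side is constant carry
    no correlation signal and are excluded (their count is available via
    ``return_excluded``); if every pair is excluded the mean is undefined and
    a ValueError is raised rather than silently returning a number.
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("matrices must have the same shape")
    if orientation == "per_sample":
        a, b = pred.T, actual.T
    elif orientation == "per_otu":
        a, b = pred, actual
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if a.shape[1] < 2:
        raise ValueError("need at least 2 values per correlated vector")
    r, excluded = _pearson_rows(a, b)
    if r.size == 0:
        raise ValueError(
            f"mean Pearson ({orientation}) undefined: all {excluded} vector pairs "
            "are constant and were excluded"
        )
    mean = float(r.mean())
    if return_excluded:
        return mean, excluded
    return mean


def error_metrics(pred: np.ndarray, actual: np.ndarray) -> tuple[float, float, float]:
    """Element-wise MAE, MSE and MAPE.

    MAPE averages |pred−actual|/actual only over entries with actual > 0 —
    zeros dominate sparse microbiome matrices and would make the ratio
    undefined — and is returned as a percentage.
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("matrices must have the same shape")
    diff = pred - actual
    mae = float(np.abs(diff).mean())
    mse = float((diff ** 2).mean())
    pos = actual > 0
    mape = float((np.abs(diff[pos]) / actual[pos]).mean() * 100.0) if pos.any() else float("nan")
    return mae, mse, mape


def rrse_per_otu(pred: np.ndarray, actual: np.ndarray,
                 taxon_ids: list[str] | None = None,
                 baseline_mean: np.ndarray | None = None) -> tuple[pd.Series, list[str]]:
    """Root relative squared error per taxon (row).

    RRSE_j = sqrt( Σ_s (pred_js − actual_js)² / Σ_s (actual_js − mean_j)² ),
    where mean_j is the taxon's mean over the evaluation samples (or a
    supplied training-set mean via ``baseline_mean``). A value of 1 means no
    better than predicting the mean. Taxa with zero variance in ``actual``
    are excluded; their ids are returned separately.
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("matrices must have the same shape")
    if pred.shape[1] < 2:
        raise ValueError("RRSE needs at least 2 samples")
    if taxon_ids is None:
        taxon_ids = [f"t{i}" for i in range(pred.shape[0])]
    mean = actual.mean(axis=1) if baseline_mean is None else np.asarray(baseline_mean, dtype=float)
    num = ((pred - actual) ** 2).sum(axis=1)
    den = ((actual - mean[:, None]) ** 2).sum(axis=1)
    ok = den > 0
    values = np.sqrt(num[ok] / den[ok])
    kept = [t for t, o in zip(taxon_ids, ok) if o]
    excluded = [t for t, o in zip(taxon_ids, ok) if not o]
    return pd.Series(values, index=kept, name="rrse"), excluded


def rank_best_predicted(rrse: pd.Series, taxonomy: TaxonomyTable,
                        top_fraction: float) -> tuple[pd.Series, pd.Series]:
    """Top ``⌈fraction·n⌉`` best-predicted taxa by ascending RRSE, with the
    percentage breakdown of their Phylum labels.

    Ties in RRSE are broken by taxon id (lexicographic) for determinism.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    df = pd.DataFrame({"rrse": rrse})
    df["taxon_id"] = df.index.astype(str)
    df = df.sort_values(["rrse", "taxon_id"], kind="mergesort")
    n_top = int(np.ceil(top_fraction * len(df)))
    top = df.head(n_top)["rrse"]
    phyla = pd.Series([taxonomy.rank_of(t, "Phylum") for t in top.index], index=top.index)
    breakdown = (phyla.value_counts() / n_top * 100.0).sort_values(ascending=False)
    return top, breakdown


def loss(kind: str, pred_batch: np.ndarray, target_batch: np.ndarray) -> float:
    """Batch-mean training loss value (rows are samples).

    ``crossentropy`` and ``braycurtis`` require simplex-valued predictions;
    the configuration layer rejects them under CLR normalization.
    """
    pred = np.atleast_2d(np.asarray(pred_batch, dtype=float))
    target = np.atleast_2d(np.asarray(target_batch, dtype=float))
    if pred.shape != target.shape:
        raise ValueError("prediction and target shapes differ")
    if kind == "mse":
        return float(((pred - target) ** 2).mean())
    if kind == "crossentropy":
        return float(-(target * np.log(pred + CROSSENTROPY_EPS)).sum(axis=1).mean())
    if kind == "braycurtis":
        num = np.abs(pred - target).sum(axis=1)
        den = (pred + target).sum(axis=1)
        return float((num / den).mean())
    raise ValueError(f"unknown loss kind {kind!r}")


@dataclass
class EvaluationReport:
    """Aggregated comparison of a predicted vs actual composition matrix."""

    pearson_mean: float
    braycurtis_mean: float
    mae: float
    mse: float
    mape: float
    per_otu_rrse: pd.Series
    rrse_excluded: list[str]
    n_samples: int
    n_taxa: int
    pearson_excluded: int = 0
    orientation: str = "per_sample"
    extras: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "pearson_mean": self.pearson_mean,
            "braycurtis_mean": self.braycurtis_mean,
            "mae": self.mae,
            "mse": self.mse,
            "mape": self.mape,
            "n_samples": self.n_samples,
            "n_taxa": self.n_taxa,
            "n_rrse_excluded": len(self.rrse_excluded),
            "orientation": self.orientation,
        }

    def write(self, path_prefix) -> None:
        import json
        from pathlib import Path

        prefix = Path(path_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(f"{prefix}.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)
        self.per_otu_rrse.rename_axis("taxon_id").to_csv(f"{prefix}_rrse.tsv", sep="\t")


def evaluate(pred: np.ndarray, actual: np.ndarray,
             taxon_ids: list[str] | None = None,
             orientation: str = "per_sample") -> EvaluationReport:
    """Full evaluation of a taxa × samples prediction on the relative scale."""
    pearson, excluded = mean_pearson(pred, actual, orientation, return_excluded=True)
    bc = mean_bray_curtis(pred, actual)
    mae, mse, mape = error_metrics(pred, actual)
    rrse, rrse_excl = rrse_per_otu(pred, actual, taxon_ids)
    return EvaluationReport(
        pearson_mean=pearson, braycurtis_mean=bc, mae=mae, mse=mse, mape=mape,
        per_otu_rrse=rrse, rrse_excluded=rrse_excl,
        n_samples=int(np.asarray(pred).shape[1]), n_taxa=int(np.asarray(pred).shape[0]),
        pearson_excluded=excluded, orientation=orientation,
    )
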