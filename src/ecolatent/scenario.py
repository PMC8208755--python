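"""Hypothetical-scenario prediction.

Predict community composition under named environmental conditions — e.g.
climate-change settings such as a hot-and-dry summer — by overriding
selected features of a base metadata table and running the fitted
prediction model on each variant. Values outside the training range are
allowed (near-boundary scenarios are the point) but trigger a logged
extrapolation warning.
"""

from __future__ import annotations

import logging

import pandas as pd

from .containers import EnvironmentTable, TaxonomyTable
from .models import PredictionModel
from .transforms import aggregate_taxa

logger = logging.getLogger(__name__)


def _apply_overrides(env: EnvironmentTable, overrides: dict,
                     model: PredictionModel) -> EnvironmentTable:
    df = env.data.copy()
    for feature, value in overrides.items():
        if feature not in df.columns:
            raise ValueError(f"unknown feature {feature!r}")
        if env.schema[feature] == "numeric":
            value = float(value)
            lo_hi = model.schema.numeric_range.get(feature)
            if lo_hi and not lo_hi[0] <= value <= lo_hi[1]:
                logger.warning(
                    "scenario sets %s=%s outside the training range [%g, %g]; "
                    "prediction extrapolates", feature, value, *lo_hi)
        df[feature] = value
    return EnvironmentTable(df, dict(env.schema), dict(env.units))


def scenario_predict(model: PredictionModel, base_env: EnvironmentTable,
                     conditions: dict[str, dict],
                     taxonomy: TaxonomyTable | None = None,
                     aggregate_level: str | None = None) -> pd.DataFrame:
    """Predict compositions under each named condition.

    ``conditions`` maps a condition label to a ``{feature: value}`` override
    dict (an empty dict reproduces the plain prediction on ``base_env``).
    Returns a long-format table with columns ``condition``, ``sample_id``,
    ``taxon_id``, ``abundance``; with ``aggregate_level`` (and a taxonomy)
    predictions are summed to that rank first. Per-condition means across
    samples are the caller's groupby away.
    """
    if aggregate_level is not None and taxonomy is None:
        raise ValueError("aggregation to a rank requires a taxonomy")
    frames = []
    for label, overrides in conditions.items():
        env = _apply_overrides(base_env, overrides, model)
        pred = model.predict(env)
        if aggregate_level is not None:
            pred = aggregate_taxa(pred, taxonomy, aggregate_level)
        long = (pred.to_dataframe()
                .rename_axis("taxon_id")
                .reset_index()
                .melt(id_vars="taxon_id", var_name="sample_id", value_name="abundance"))
        long.insert(0, "condition", label)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)


def condition_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean predicted abundance per condition × taxon (wide: taxa rows)."""
    return (table.groupby(["taxon_id", "condition"])["abundance"]
            .mean().unstack("condition"))
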