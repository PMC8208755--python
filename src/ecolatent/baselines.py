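"""Reference predictors: per-taxon mean, multi-output linear regression, MLP.

These are the yardsticks the latent-space models are compared against. All
three emit simplex predictions after inverse mapping, so every comparison
happens on the relative-abundance scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import AbundanceTable, EnvironmentTable
from .models import ArchitectureConfig, normalize_table, _rngs
from .nn import Network, fit_network
from .transforms import (EncodingSchema, NormalizationState, encode_environment,
                         inverse_to_relative, tss)

logger = logging.getLogger(__name__)


@dataclass
class BaselineModel:
    """A fitted baseline. ``default`` ignores its input features entirely."""

    kind: str  # 'default' | 'linear' | 'mlp'
    norm_state: NormalizationState
    taxon_ids: list[str]
    schema: EncodingSchema | None = None
    mean_composition: np.ndarray | None = None   # default
    coefficients: np.ndarray | None = None       # linear: (features+1) × taxa
    network: Network | None = None               # mlp

    def predict(self, env: EnvironmentTable | None, n_samples: int | None = None,
                sample_ids: list[str] | None = None) -> AbundanceTable:
        if self.kind == "default":
            if n_samples is None:
                if env is None:
                    raise ValueError("default baseline needs env or n_samples")
                n_samples = len(env.sample_ids)
            if sample_ids is None:
                sample_ids = (env.sample_ids if env is not None
                              else [f"s{i}" for i in range(n_samples)])
            rel = np.tile(self.mean_composition[:, None], (1, n_samples))
            return AbundanceTable(rel, list(self.taxon_ids), list(sample_ids), "tss")
        e, _ = encode_environment(env, self.schema)
        if self.kind == "linear":
            design = np.hstack([e, np.ones((e.shape[0], 1))])
            out = design @ self.coefficients
        else:
            out = self.network.predict(e)
        rel = inverse_to_relative(out.T, self.norm_state)
        return AbundanceTable(rel, list(self.taxon_ids), list(env.sample_ids), "tss")


def fit_default(train: AbundanceTable) -> BaselineModel:
    """Per-taxon mean relative abundance over training samples, re-closed to
    sum 1; the same vector is returned for every input."""
    if train.scale != "tss":
        train = tss(train)
    mean = train.values.mean(axis=1)
    mean = mean / mean.sum()
    return BaselineModel(kind="default", norm_state=NormalizationState("tss"),
                         taxon_ids=list(train.taxon_ids), mean_composition=mean)


def fit_linear(env: EnvironmentTable, target: AbundanceTable,
               normalization: str = "tss", pseudocount: float = 1.0,
               schema: EncodingSchema | None = None) -> BaselineModel:
    """Independent least squares per taxon (one multi-output solve with an
    intercept column). Rank-deficient designs fall back to the least-norm
    solution with a logged warning."""
    state = NormalizationState(normalization, pseudocount)
    env = env.select_samples(target.sample_ids)
    e, schema = encode_environment(env, schema)
    y = normalize_table(target, state)
    design = np.hstack([e, np.ones((e.shape[0], 1))])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        logger.warning("rank-deficient design (rank %d < %d columns); "
                       "least-norm solution used", rank, design.shape[1])
    return BaselineModel(kind="linear", norm_state=state,
                         taxon_ids=list(target.taxon_ids), schema=schema,
                         coefficients=coef)


def fit_mlp(env: EnvironmentTable, target: AbundanceTable,
            cfg: ArchitectureConfig | None = None,
            schema: EncodingSchema | None = None) -> BaselineModel:
    """Feed-forward net environment → taxa directly (no bottleneck, no AE),
    trained with the same conventions as the latent-space models. Defaults
    to the largest hidden-layer grid entry, (512, 256)."""
    if cfg is None:
        cfg = ArchitectureConfig(hidden_layers=(512, 256))
    state = cfg.norm_state()
    env = env.select_samples(target.sample_ids)
    e, schema = encode_environment(env, schema)
    y = normalize_table(target, state)
    init_rng, shuffle_rng, split_rng = _rngs(cfg.seed + 2, 3)
    if cfg.hidden_layers:
        net = Network([e.shape[1], *cfg.hidden_layers, target.n_taxa],
                      cfg.activation_encdec, cfg.output_head, init_rng)
    else:
        net = Network([e.shape[1], target.n_taxa], cfg.activation_encdec,
                      cfg.output_head, init_rng)
    n = e.shape[0]
    if n >= 50:
        order = split_rng.permutation(n)
        n_val = max(1, n // 10)
        val_idx, fit_idx = order[:n_val], order[n_val:]
        x_val, y_val = e[val_idx], y[val_idx]
        x_fit, y_fit = e[fit_idx], y[fit_idx]
    else:
        x_fit, y_fit, x_val, y_val = e, y, None, None
    fit_network(net, x_fit, y_fit, loss_kind=cfg.loss_kind,
                learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
                epochs=cfg.epochs, patience=cfg.patience, rng=shuffle_rng,
                x_val=x_val, y_val=y_val)
    return BaselineModel(kind="mlp", norm_state=state,
                         taxon_ids=list(target.taxon_ids), schema=schema, network=net)
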