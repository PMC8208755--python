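"""Latent-space model architectures, training, assembly and grid search.

Three network modules are combined into two autoencoder architectures and
one deployable predictor:

* an OTU encoder: composition → latent code;
* an environmental encoder: encoded environmental features → latent code;
* a decoder: latent code → composition.

The plain autoencoder trains the OTU encoder and decoder alone. The
combined (heterogeneous) autoencoder trains both encoders against one
shared decoder while penalizing the mean squared distance between the two
latent codes, so the environmental code lands in the same geometry as the
composition code. The final prediction model maps environmental features to
a latent code — either through a dedicated regressor trained on frozen OTU
codes, or through the environmental encoder — and decodes it, with the
decoder frozen.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceTable, EnvironmentTable
from .nn import Network, fit_network, loss_value_and_grad, Adam, minibatches
from .transforms import (EncodingSchema, NormalizationState, clr, encode_environment,
                         inverse_to_relative, tss)
from . import metrics as _metrics

logger = logging.getLogger(__name__)

# the hyperparameter sets explored during model selection
GRID_LATENT_DIMS = (10, 50, 100)
GRID_HIDDEN_LAYERS = ((512, 256), (256,), ())
GRID_ACTIVATIONS_ENCDEC = ("tanh", "relu", "sigmoid")
GRID_ACTIVATIONS_LATENT = ("tanh", "sigmoid")
GRID_NORMALIZATIONS = ("tss", "tss_clr")
GRID_LOSSES = ("mse", "crossentropy", "braycurtis")
GRID_LEARNING_RATES = (0.01, 0.001)
GRID_BATCH_SIZES = (64, 128)


@dataclass
class ArchitectureConfig:
    """Hyperparameters of the autoencoder / predictor family.

    ``crossentropy`` and ``braycurtis`` losses require simplex-valued
    predictions and are therefore only valid under ``tss`` normalization
    (the model then carries a softmax output head; under ``tss_clr`` the
    head is linear).
    """

    latent_dim: int = 10
    hidden_layers: tuple[int, ...] = (256,)
    activation_encdec: str = "tanh"
    activation_latent: str = "tanh"
    normalization: str = "tss"
    loss_kind: str = "braycurtis"
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 100
    patience: int = 10
    latent_align_weight: float = 1.0
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_layers = tuple(int(h) for h in self.hidden_layers)
        self.validate()

    def validate(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if self.normalization not in ("tss", "tss_clr"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.loss_kind not in _metrics.LOSS_KINDS:
            raise ValueError(f"unknown loss {self.loss_kind!r}")
        if self.loss_kind in ("crossentropy", "braycurtis") and self.normalization != "tss":
            raise ValueError(
                f"{self.loss_kind} loss requires simplex predictions; "
                "use normalization='tss'"
            )
        if self.latent_align_weight < 0:
            raise ValueError("latent_align_weight must be nonnegative")

    @property
    def output_head(self) -> str:
        return "softmax" if self.normalization == "tss" else "identity"

    def norm_state(self) -> NormalizationState:
        return NormalizationState(self.normalization, self.pseudocount)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_layers"] = list(self.hidden_layers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        d = dict(d)
        d["hidden_layers"] = tuple(d.get("hidden_layers", ()))
        return cls(**d)


def grid_cells(filter_invalid: bool = True) -> list[ArchitectureConfig]:
    """Enumerate the full hyperparameter grid.

    With ``filter_invalid=True`` the loss × normalization combinations that
    would pair a simplex loss with CLR output are dropped.
    """
    cells = []
    for latent, hidden, act, act_lat, norm, loss, lr, bs in itertools.product(
            GRID_LATENT_DIMS, GRID_HIDDEN_LAYERS, GRID_ACTIVATIONS_ENCDEC,
            GRID_ACTIVATIONS_LATENT, GRID_NORMALIZATIONS, GRID_LOSSES,
            GRID_LEARNING_RATES, GRID_BATCH_SIZES):
        invalid = loss in ("crossentropy", "braycurtis") and norm != "tss"
        if invalid and filter_invalid:
            continue
        kwargs = dict(latent_dim=latent, hidden_layers=hidden, activation_encdec=act,
                      activation_latent=act_lat, normalization=norm, loss_kind=loss,
                      learning_rate=lr, batch_size=bs)
        if invalid:
            cells.append(kwargs)  # raw cell; cannot be instantiated
        else:
            cells.append(ArchitectureConfig(**kwargs))
    return cells


def normalize_table(table: AbundanceTable, state: NormalizationState) -> np.ndarray:
    """Model-space design matrix (samples × taxa) under a normalization."""
    if table.scale == "counts":
        norm = tss(table) if state.method == "tss" else clr(table, state.pseudocount)
    elif (table.scale, state.method) in (("tss", "tss"), ("clr", "tss_clr")):
        norm = table
    else:
        raise ValueError(
            f"table scale {table.scale!r} does not match normalization {state.method!r}")
    return norm.values.T.copy()


@dataclass
class TrainedAE:
    """A trained autoencoder bundle: encoder(s), decoder and their context."""

    otu_encoder: Network
    decoder: Network
    config: ArchitectureConfig
    norm_state: NormalizationState
    taxon_ids: list[str]
    env_encoder: Network | None = None
    schema: EncodingSchema | None = None
    history: dict = field(default_factory=dict)

    def encode(self, table: AbundanceTable) -> np.ndarray:
        """Latent codes (samples × latent_dim) of a composition table."""
        x = normalize_table(table, self.norm_state)
        return self.otu_encoder.predict(x)

    def reconstruct(self, table: AbundanceTable) -> AbundanceTable:
        """Encode then decode, returned on the relative-abundance scale."""
        out = self.decoder.predict(self.encode(table))
        rel = inverse_to_relative(out.T, self.norm_state)
        return AbundanceTable(rel, list(self.taxon_ids), list(table.sample_ids), "tss")


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _build_encoder(n_in: int, cfg: ArchitectureConfig, rng) -> Network:
    sizes = [n_in, *cfg.hidden_layers, cfg.latent_dim]
    return Network(sizes, cfg.activation_encdec, cfg.activation_latent, rng)


def _build_decoder(n_out: int, cfg: ArchitectureConfig, rng) -> Network:
    sizes = [cfg.latent_dim, *reversed(cfg.hidden_layers), n_out]
    return Network(sizes, cfg.activation_encdec, cfg.output_head, rng)


def train_otu_autoencoder(train: AbundanceTable, val: AbundanceTable,
                          cfg: ArchitectureConfig) -> TrainedAE:
    """Train the composition-only autoencoder (OTU latent space).

    Minimizes ``cfg.loss_kind`` reconstruction loss by mini-batch Adam with
    early stopping on the validation reconstruction loss.
    """
    state = cfg.norm_state()
    x_train = normalize_table(train, state)
    x_val = normalize_table(val, state)
    init_rng, shuffle_rng = _rngs(cfg.seed, 2)
    encoder = _build_encoder(train.n_taxa, cfg, init_rng)
    decoder = _build_decoder(train.n_taxa, cfg, init_rng)

    class _Pipe(Network):  # encoder+decoder viewed as one stack for fit_network
        def __init__(self):
            self.layers = encoder.layers + decoder.layers
            self.sizes = encoder.sizes + decoder.sizes[1:]
            self.hidden_activation = cfg.activation_encdec
            self.output_activation = cfg.output_head

    pipe = _Pipe()
    history = fit_network(pipe, x_train, x_train, loss_kind=cfg.loss_kind,
                          learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
                          epochs=cfg.epochs, patience=cfg.patience, rng=shuffle_rng,
                          x_val=x_val, y_val=x_val)
    return TrainedAE(otu_encoder=encoder, decoder=decoder, config=cfg,
                     norm_state=state, taxon_ids=list(train.taxon_ids),
                     history=history)


def train_combined_autoencoder(train_otu: AbundanceTable, train_env: EnvironmentTable,
                               val_otu: AbundanceTable, val_env: EnvironmentTable,
                               cfg: ArchitectureConfig) -> TrainedAE:
    """Train the heterogeneous autoencoder with a combined latent space.

    Total loss per batch:
    ``L_rec(decoder(z_otu), x) + L_rec(decoder(z_env), x)
    + latent_align_weight · mean((z_otu − z_env)²)``.
    Both encoders share one decoder; the decoder receives gradients from
    both reconstruction paths.
    """
    train_env = train_env.select_samples(train_otu.sample_ids)
    val_env = val_env.select_samples(val_otu.sample_ids)
    state = cfg.norm_state()
    x_train = normalize_table(train_otu, state)
    x_val = normalize_table(val_otu, state)
    e_train, schema = encode_environment(train_env)
    e_val, _ = encode_environment(val_env, schema)

    init_rng, shuffle_rng = _rngs(cfg.seed, 2)
    enc_otu = _build_encoder(train_otu.n_taxa, cfg, init_rng)
    enc_env = _build_encoder(e_train.shape[1], cfg, init_rng)
    decoder = _build_decoder(train_otu.n_taxa, cfg, init_rng)
    nets = [enc_otu, enc_env, decoder]
    params = [p for net in nets for p in net.parameters()]
    opt = Adam(params, lr=cfg.learning_rate)

    def total_loss(x, e):
        z_o = enc_otu.predict(x)
        z_e = enc_env.predict(e)
        l_o, _ = loss_value_and_grad(cfg.loss_kind, decoder.predict(z_o), x)
        l_e, _ = loss_value_and_grad(cfg.loss_kind, decoder.predict(z_e), x)
        align = float(((z_o - z_e) ** 2).mean())
        return l_o + l_e + cfg.latent_align_weight * align, l_o, l_e, align

    history: dict = {"train_loss": [], "val_loss": [], "val_recon_otu": [],
                     "val_recon_env": [], "val_align": []}
    best_val = np.inf
    best_state = [net.get_state() for net in nets]
    bad = 0
    w = cfg.latent_align_weight
    for epoch in range(cfg.epochs):
        epoch_loss, n_seen = 0.0, 0
        for idx in minibatches(x_train.shape[0], cfg.batch_size, shuffle_rng):
            xb, eb = x_train[idx], e_train[idx]
            for net in nets:
                net.zero_grad()
            # composition path (complete forward+backward before the decoder
            # caches are reused by the environmental path)
            z_o = enc_otu.forward(xb)
            y_o = decoder.forward(z_o)
            l_o, g_o = loss_value_and_grad(cfg.loss_kind, y_o, xb)
            gz_o = decoder.backward(g_o)
            # environmental path
            z_e = enc_env.forward(eb)
            y_e = decoder.forward(z_e)
            l_e, g_e = loss_value_and_grad(cfg.loss_kind, y_e, xb)
            gz_e = decoder.backward(g_e)
            # latent alignment
            diff = z_o - z_e
            align = float((diff ** 2).mean())
            g_align = 2.0 * w * diff / diff.size
            enc_otu.backward(gz_o + g_align)
            enc_env.backward(gz_e - g_align)
            value = l_o + l_e + w * align
            if not np.isfinite(value):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            opt.step([g for net in nets for g in net.gradients()])
            epoch_loss += value * len(idx)
            n_seen += len(idx)
        val_total, val_o, val_e, val_align = total_loss(x_val, e_val)
        if not np.isfinite(val_total):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        history["train_loss"].append(epoch_loss / max(n_seen, 1))
        history["val_loss"].append(val_total)
        history["val_recon_otu"].append(val_o)
        history["val_recon_env"].append(val_e)
        history["val_align"].append(val_align)
        if val_total < best_val - 1e-12:
            best_val = val_total
            best_state = [net.get_state() for net in nets]
            bad = 0
        else:
            bad += 1
            if bad > cfg.patience:
                break
    for net, st in zip(nets, best_state):
        net.set_state(st)
    history["best_val_loss"] = float(best_val)
    return TrainedAE(otu_encoder=enc_otu, decoder=decoder, config=cfg,
                     norm_state=state, taxon_ids=list(train_otu.taxon_ids),
                     env_encoder=enc_env, schema=schema, history=history)


def train_latent_predictor(env_matrix: np.ndarray, latent_targets: np.ndarray,
                           cfg: ArchitectureConfig) -> Network:
    """Fit the environment → latent-code regressor by MSE.

    ``latent_targets`` are the OTU-encoder codes of the training samples.
    Uses the same hidden-layer family as the autoencoder; a 10% tail of the
    rows (after a seeded shuffle) is held out for early stopping when there
    are enough samples.
    """
    env_matrix = np.asarray(env_matrix, dtype=float)
    latent_targets = np.asarray(latent_targets, dtype=float)
    if env_matrix.shape[0] != latent_targets.shape[0]:
        raise ValueError("env_matrix and latent_targets row counts differ")
    init_rng, shuffle_rng, split_rng = _rngs(cfg.seed + 1, 3)
    net = Network([env_matrix.shape[1], *cfg.hidden_layers, latent_targets.shape[1]],
                  cfg.activation_encdec, "identity", init_rng)
    n = env_matrix.shape[0]
    if n >= 50:
        order = split_rng.permutation(n)
        n_val = max(1, n // 10)
        val_idx, fit_idx = order[:n_val], order[n_val:]
        x_val, y_val = env_matrix[val_idx], latent_targets[val_idx]
        x_fit, y_fit = env_matrix[fit_idx], latent_targets[fit_idx]
    else:
        x_fit, y_fit = env_matrix, latent_targets
        x_val = y_val = None
    fit_network(net, x_fit, y_fit, loss_kind="mse", learning_rate=cfg.learning_rate,
                batch_size=cfg.batch_size, epochs=cfg.epochs, patience=cfg.patience,
                rng=shuffle_rng, x_val=x_val, y_val=y_val)
    return net


@dataclass
class PredictionModel:
    """The deployable artifact: environment → latent → (frozen) decoder."""

    predictor: Network
    decoder: Network
    schema: EncodingSchema
    norm_state: NormalizationState
    taxon_ids: list[str]
    config: ArchitectureConfig
    mode: str = "otu_latent"  # or 'combined'
    feature_subset: list[str] | None = None
    decoder_frozen: bool = True

    def predict_matrix(self, env_encoded: np.ndarray) -> np.ndarray:
        """Relative abundances (taxa × samples) from an encoded design matrix."""
        z = self.predictor.predict(env_encoded)
        out = self.decoder.predict(z)
        return inverse_to_relative(out.T, self.norm_state)

    def predict(self, env: EnvironmentTable) -> AbundanceTable:
        if self.feature_subset is not None:
            env = env.select_features(self.feature_subset)
        e, _ = encode_environment(env, self.schema)
        rel = self.predict_matrix(e)
        return AbundanceTable(rel, list(self.taxon_ids), list(env.sample_ids), "tss")


def assemble_prediction_model(ae: TrainedAE, mode: str,
                              predictor: Network | None = None,
                              schema: EncodingSchema | None = None,
                              feature_subset: list[str] | None = None) -> PredictionModel:
    """Compose the final environment → composition pipeline.

    ``otu_latent`` mode requires a trained latent predictor (and the schema
    its design matrix was encoded with); ``combined`` mode reuses the
    autoencoder's environmental encoder and schema. The decoder is frozen.
    """
    if mode == "otu_latent":
        if predictor is None:
            raise ValueError("otu_latent mode requires a trained latent predictor")
        if schema is None:
            raise ValueError("otu_latent mode requires the predictor's encoding schema")
    elif mode == "combined":
        if ae.env_encoder is None or ae.schema is None:
            raise ValueError("combined mode requires an AE trained with an env encoder")
        predictor = ae.env_encoder
        schema = ae.schema
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PredictionModel(predictor=predictor, decoder=ae.decoder, schema=schema,
                           norm_state=ae.norm_state, taxon_ids=list(ae.taxon_ids),
                           config=ae.config, mode=mode, feature_subset=feature_subset)


def decoder_digest(obj: TrainedAE | PredictionModel) -> str:
    """SHA-256 digest of the decoder parameters (frozen-decoder checks)."""
    h = hashlib.sha256()
    for p in obj.decoder.parameters():
        h.update(np.ascontiguousarray(p).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# persistence

def _save_network(net: Network, payload: dict, prefix: str) -> dict:
    for i, p in enumerate(net.parameters()):
        payload[f"{prefix}_p{i}"] = p
    return {"sizes": net.sizes, "hidden_activation": net.hidden_activation,
            "output_activation": net.output_activation,
            "n_params": len(net.parameters())}


def _load_network(meta: dict, payload, prefix: str) -> Network:
    net = Network(meta["sizes"], meta["hidden_activation"], meta["output_activation"],
                  np.random.default_rng(0))
    net.set_state([payload[f"{prefix}_p{i}"] for i in range(meta["n_params"])])
    return net


def _schema_to_dict(schema: EncodingSchema) -> dict:
    return {
        "feature_order": schema.feature_order,
        "kinds": schema.kinds,
        "numeric_stats": {k: list(v) for k, v in schema.numeric_stats.items()},
        "numeric_range": {k: list(v) for k, v in schema.numeric_range.items()},
        "vocabularies": schema.vocabularies,
        "units": schema.units,
    }


def _schema_from_dict(d: dict) -> EncodingSchema:
    return EncodingSchema(
        feature_order=list(d["feature_order"]), kinds=dict(d["kinds"]),
        numeric_stats={k: tuple(v) for k, v in d["numeric_stats"].items()},
        numeric_range={k: tuple(v) for k, v in d["numeric_range"].items()},
        vocabularies={k: list(v) for k, v in d["vocabularies"].items()},
        units=dict(d.get("units", {})),
    )


def save_prediction_model(model: PredictionModel, directory) -> None:
    """Persist a prediction model as a directory (params + JSON metadata)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload: dict = {}
    meta = {
        "kind": "prediction_model",
        "mode": model.mode,
        "feature_subset": model.feature_subset,
        "decoder_frozen": model.decoder_frozen,
        "taxon_ids": model.taxon_ids,
        "config": model.config.to_dict(),
        "norm_state": {"method": model.norm_state.method,
                       "pseudocount": model.norm_state.pseudocount},
        "schema": _schema_to_dict(model.schema),
        "predictor": _save_network(model.predictor, payload, "predictor"),
        "decoder": _save_network(model.decoder, payload, "decoder"),
    }
    np.savez(directory / "params.npz", **payload)
    (directory / "model.json").write_text(json.dumps(meta, indent=2))


def load_prediction_model(directory) -> PredictionModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    payload = np.load(directory / "params.npz")
    return PredictionModel(
        predictor=_load_network(meta["predictor"], payload, "predictor"),
        decoder=_load_network(meta["decoder"], payload, "decoder"),
        schema=_schema_from_dict(meta["schema"]),
        norm_state=NormalizationState(**meta["norm_state"]),
        taxon_ids=list(meta["taxon_ids"]),
        config=ArchitectureConfig.from_dict(meta["config"]),
        mode=meta["mode"],
        feature_subset=meta["feature_subset"],
        decoder_frozen=meta["decoder_frozen"],
    )


def save_trained_ae(ae: TrainedAE, directory) -> None:
    """Persist a trained autoencoder bundle as a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload: dict = {}
    meta = {
        "kind": "trained_ae",
        "taxon_ids": ae.taxon_ids,
        "config": ae.config.to_dict(),
        "norm_state": {"method": ae.norm_state.method,
                       "pseudocount": ae.norm_state.pseudocount},
        "otu_encoder": _save_network(ae.otu_encoder, payload, "otu_encoder"),
        "decoder": _save_network(ae.decoder, payload, "decoder"),
        "env_encoder": (_save_network(ae.env_encoder, payload, "env_encoder")
                        if ae.env_encoder is not None else None),
        "schema": _schema_to_dict(ae.schema) if ae.schema is not None else None,
        "history": {k: v for k, v in ae.history.items() if not callable(v)},
    }
    np.savez(directory / "params.npz", **payload)
    (directory / "model.json").write_text(json.dumps(meta, indent=2))


def load_trained_ae(directory) -> TrainedAE:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    payload = np.load(directory / "params.npz")
    return TrainedAE(
        otu_encoder=_load_network(meta["otu_encoder"], payload, "otu_encoder"),
        decoder=_load_network(meta["decoder"], payload, "decoder"),
        config=ArchitectureConfig.from_dict(meta["config"]),
        norm_state=NormalizationState(**meta["norm_state"]),
        taxon_ids=list(meta["taxon_ids"]),
        env_encoder=(_load_network(meta["env_encoder"], payload, "env_encoder")
                     if meta["env_encoder"] is not None else None),
        schema=(_schema_from_dict(meta["schema"]) if meta["schema"] is not None else None),
        history=dict(meta.get("history", {})),
    )


# ---------------------------------------------------------------------------
# model selection

def fit_prediction_model(train_otu: AbundanceTable, train_env: EnvironmentTable,
                         val_otu: AbundanceTable, val_env: EnvironmentTable,
                         cfg: ArchitectureConfig, mode: str = "otu_latent",
                         feature_subset: list[str] | None = None) -> PredictionModel:
    """Train an AE and assemble the final model in one call.

    In ``otu_latent`` mode: composition-only AE, then a latent predictor on
    the frozen encoder codes. In ``combined`` mode: heterogeneous AE, the
    environmental encoder is the predictor.
    """
    if feature_subset is not None:
        train_env = train_env.select_features(feature_subset)
        val_env = val_env.select_features(feature_subset)
    train_env = train_env.select_samples(train_otu.sample_ids)
    val_env = val_env.select_samples(val_otu.sample_ids)
    if mode == "combined":
        ae = train_combined_autoencoder(train_otu, train_env, val_otu, val_env, cfg)
        return assemble_prediction_model(ae, "combined", feature_subset=feature_subset)
    ae = train_otu_autoencoder(train_otu, val_otu, cfg)
    e_train, schema = encode_environment(train_env)
    codes = ae.encode(train_otu)
    predictor = train_latent_predictor(e_train, codes, cfg)
    return assemble_prediction_model(ae, "otu_latent", predictor=predictor,
                                     schema=schema, feature_subset=feature_subset)


def grid_search(counts: AbundanceTable, env: EnvironmentTable,
                grid: list[ArchitectureConfig], k: int = 5, seed: int = 0,
                mode: str = "otu_latent") -> pd.DataFrame:
    """Cross-validated hyperparameter search for the prediction model.

    Each configuration is scored by the mean CV Pearson correlation
    (per-sample) and mean CV Bray–Curtis of the assembled environment →
    composition model on the held-out folds. Ranking: descending Pearson,
    ties broken by ascending Bray–Curtis. Returns the full ranked table;
    the fold sample ids used per row are in the ``fold_val_ids`` column.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    env = env.select_samples(counts.sample_ids)
    rng = np.random.default_rng(seed)
    perm = [counts.sample_ids[i] for i in rng.permutation(counts.n_samples)]
    chunks = np.array_split(np.arange(len(perm)), k)
    folds = []
    for ch in chunks:
        val_ids = [perm[i] for i in ch]
        fit_ids = [s for s in perm if s not in set(val_ids)]
        folds.append((fit_ids, val_ids))

    rows = []
    for ci, cfg in enumerate(grid):
        pearsons, bcs = [], []
        for fit_ids, val_ids in folds:
            model = fit_prediction_model(
                counts.select_samples(fit_ids), env.select_samples(fit_ids),
                counts.select_samples(val_ids), env.select_samples(val_ids), cfg, mode)
            pred = model.predict(env.select_samples(val_ids))
            actual = tss(counts.select_samples(val_ids))
            pearsons.append(_metrics.mean_pearson(pred.values, actual.values, "per_sample"))
            bcs.append(_metrics.mean_bray_curtis(pred.values, actual.values))
        row = cfg.to_dict()
        row["hidden_layers"] = str(tuple(cfg.hidden_layers))
        row["config_index"] = ci
        row["cv_pearson"] = float(np.mean(pearsons))
        row["cv_braycurtis"] = float(np.mean(bcs))
        row["fold_val_ids"] = [val for _, val in folds]
        rows.append(row)
        logger.info("grid cell %d/%d: pearson=%.4f braycurtis=%.4f",
                    ci + 1, len(grid), row["cv_pearson"], row["cv_braycurtis"])
    table = pd.DataFrame(rows)
    table = table.sort_values(["cv_pearson", "cv_braycurtis"],
                              ascending=[False, True], kind="mergesort")
    return table.reset_index(drop=True)
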