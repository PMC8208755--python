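"""Seeded synthetic microbiome datasets with a known generative truth.

The generator emulates the statistical structure the latent-space models
assume: a handful of environmental covariates drive a low-dimensional
latent factor through a smooth nonlinearity; taxa log-abundances are linear
in that factor; observed counts are multinomial draws at a fixed
sequencing depth. Because the true mapping and every intermediate quantity
are retained, the generated datasets double as oracles for model tests.

Generative model (per sample)
-----------------------------
``h = tanh(E_std · M + m0)``, ``z = h · A + ε``, ``ε ~ N(0, σ_z²)``,
``logits = z · W + b``, ``p = softmax(logits)``,
``counts ~ Multinomial(depth, p)``,
where ``E_std`` is the standardized/one-hot encoded environment. A
configurable fraction of taxa receive a strongly negative intercept so most
counts are zero, matching microbiome sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RANKS, AbundanceTable, EnvironmentTable, TaxonomyTable


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Environmental ranges follow typical maize field campaigns: plant age
    0–20 weeks, temperature 50–90 °F, 3-day rain accumulation 0–5 inches,
    plus one categorical line/variety factor.
    """

    n_samples: int = 2000
    n_taxa: int = 200
    n_phyla: int = 12
    true_latent_dim: int = 5
    depth: int = 10_000
    numeric_features: dict = field(default_factory=lambda: {
        "age": (0.0, 20.0), "temperature": (50.0, 90.0), "rain": (0.0, 5.0)})
    categorical_features: dict = field(default_factory=lambda: {
        "line": ["L1", "L2", "L3"]})
    units: dict = field(default_factory=lambda: {
        "age": "weeks", "temperature": "F", "rain": "inches"})
    latent_noise_sd: float = 0.3
    loading_scale: float = 1.0
    sparsity_fraction: float = 0.4
    sparsity_offset: float = 4.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.true_latent_dim < 1 or self.n_taxa < 2 or self.n_samples < 1:
            raise ValueError("invalid synthetic configuration")
        if not 0 <= self.sparsity_fraction < 1:
            raise ValueError("sparsity_fraction must be in [0, 1)")


@dataclass
class TruthBundle:
    """Everything needed to check a model against the generative process."""

    config: SyntheticConfig
    env_encoded: np.ndarray          # samples × encoded features (standardized)
    mix_matrix: np.ndarray           # M: encoded features × latent
    mix_offset: np.ndarray           # m0
    factor_matrix: np.ndarray        # A: latent × latent
    z_true: np.ndarray               # samples × latent (with noise)
    loadings: np.ndarray             # W: latent × taxa
    intercepts: np.ndarray           # b: taxa
    proportions: np.ndarray          # samples × taxa, rows on the simplex

    def true_proportions_for(self, z: np.ndarray) -> np.ndarray:
        logits = z @ self.loadings + self.intercepts
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


def _make_taxonomy(n_taxa: int, n_phyla: int, rng: np.random.Generator) -> TaxonomyTable:
    """Nested random lineages: phyla split into classes, classes into orders,
    and so on, roughly doubling per rank until the taxon level."""
    taxon_ids = [f"OTU{i:04d}" for i in range(n_taxa)]
    counts = {"Phylum": n_phyla}
    prev = n_phyla
    for rank in ("Class", "Order", "Family", "Genus"):
        prev = min(max(prev * 2, prev + 1), n_taxa)
        counts[rank] = prev
    # child group index per rank for every taxon; nested so lineages are consistent
    assignment = {"Phylum": rng.integers(0, counts["Phylum"], size=n_taxa)}
    parent_rank = "Phylum"
    for rank in ("Class", "Order", "Family", "Genus"):
        n_groups = counts[rank]
        n_parents = counts[parent_rank]
        children_per_parent = max(n_groups // n_parents, 1)
        child = rng.integers(0, children_per_parent, size=n_taxa)
        assignment[rank] = assignment[parent_rank] * children_per_parent + child
        parent_rank = rank
    rows = {}
    prefix = {"Phylum": "P", "Class": "C", "Order": "O", "Family": "F", "Genus": "G"}
    for i, t in enumerate(taxon_ids):
        lineage = {"Kingdom": "Bacteria"}
        for rank in ("Phylum", "Class", "Order", "Family", "Genus"):
            lineage[rank] = f"{prefix[rank]}{assignment[rank][i]:03d}"
        lineage["Species"] = t
        rows[t] = lineage
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index")[list(RANKS)])


def _encode_env(env_df: pd.DataFrame, config: SyntheticConfig) -> np.ndarray:
    """Internal standardization of the drawn environment (midrange/half-range
    for numerics, one-hot for the categorical) — deliberately simpler than
    the package's training-fitted schema, since this is the data-generating
    side."""
    blocks = []
    for f, (lo, hi) in config.numeric_features.items():
        x = env_df[f].to_numpy(dtype=float)
        mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        blocks.append(((x - mid) / half)[:, None])
    for f, levels in config.categorical_features.items():
        onehot = np.zeros((len(env_df), len(levels)))
        pos = {v: i for i, v in enumerate(levels)}
        for r, v in enumerate(env_df[f]):
            onehot[r, pos[v]] = 1.0
        blocks.append(onehot)
    return np.hstack(blocks)


def generate(config: SyntheticConfig
             ) -> tuple[AbundanceTable, TaxonomyTable, EnvironmentTable, TruthBundle]:
    """Draw one dataset under ``config``; fully determined by ``config.seed``.

    All randomness flows from one root seed through named spawned streams,
    so sub-draws (environment, mapping, noise, counts, taxonomy) are
    independently reproducible.
    """
    root = np.random.SeedSequence(config.seed)
    rng_env, rng_map, rng_noise, rng_counts, rng_tax = (
        np.random.default_rng(s) for s in root.spawn(5))

    n, d = config.n_samples, config.true_latent_dim
    sample_ids = [f"S{i:05d}" for i in range(n)]
    taxon_ids = [f"OTU{i:04d}" for i in range(config.n_taxa)]

    env_cols = {}
    for f, (lo, hi) in config.numeric_features.items():
        env_cols[f] = rng_env.uniform(lo, hi, size=n)
    for f, levels in config.categorical_features.items():
        env_cols[f] = rng_env.choice(levels, size=n)
    env_df = pd.DataFrame(env_cols, index=sample_ids)
    schema = {f: "numeric" for f in config.numeric_features}
    schema.update({f: "categorical" for f in config.categorical_features})
    env = EnvironmentTable(env_df, schema, dict(config.units))

    e_std = _encode_env(env_df, config)
    n_enc = e_std.shape[1]
    mix = rng_map.normal(0.0, 1.0, size=(n_enc, d)) / np.sqrt(n_enc)
    mix_offset = rng_map.normal(0.0, 0.3, size=d)
    factor = rng_map.normal(0.0, 1.0, size=(d, d)) / np.sqrt(d) + np.eye(d)
    loadings = rng_map.normal(0.0, config.loading_scale, size=(d, config.n_taxa))
    intercepts = rng_map.normal(0.0, 1.0, size=config.n_taxa)
    n_sparse = int(round(config.sparsity_fraction * config.n_taxa))
    sparse_idx = rng_map.choice(config.n_taxa, size=n_sparse, replace=False)
    intercepts[sparse_idx] -= config.sparsity_offset

    h = np.tanh(e_std @ mix + mix_offset)
    z_true = h @ factor + rng_noise.normal(0.0, config.latent_noise_sd, size=(n, d))
    logits = z_true @ loadings + intercepts
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    proportions = expl / expl.sum(axis=1, keepdims=True)

    counts = np.empty((n, config.n_taxa), dtype=float)
    for i in range(n):
        counts[i] = rng_counts.multinomial(config.depth, proportions[i])

    abundance = AbundanceTable(counts.T, taxon_ids, sample_ids, scale="counts")
    taxonomy = _make_taxonomy(config.n_taxa, config.n_phyla, rng_tax)
    truth = TruthBundle(config=config, env_encoded=e_std, mix_matrix=mix,
                        mix_offset=mix_offset, factor_matrix=factor, z_true=z_true,
                        loadings=loadings, intercepts=intercepts, proportions=proportions)
    return abundance, taxonomy, env, truth


def perturb_for_transfer(truth: TruthBundle, abundance: AbundanceTable,
                         n: int = 100, exclude_ids: list[str] | None = None,
                         seed: int = 0
                         ) -> tuple[AbundanceTable, EnvironmentTable, np.ndarray]:
    """A small dataset whose features are novel functions of the hidden factor.

    Emulates a follow-up study that measured soil chemistry instead of
    weather: three new numeric features (stand-ins for pH and nitrogen /
    carbon concentration) are deterministic nonlinear functions of the true
    latent factor plus noise. Samples are drawn from the source dataset
    outside ``exclude_ids``; their compositions are reused as-is.
    """
    rng = np.random.default_rng(np.random.SeedSequence((truth.config.seed, seed, 11)))
    pool = [s for s in abundance.sample_ids
            if not exclude_ids or s not in set(exclude_ids)]
    if n > len(pool):
        raise ValueError(f"requested {n} samples but only {len(pool)} are available")
    chosen = sorted(rng.choice(len(pool), size=n, replace=False).tolist())
    sample_ids = [pool[i] for i in chosen]
    pos = {s: i for i, s in enumerate(abundance.sample_ids)}
    z = truth.z_true[[pos[s] for s in sample_ids]]

    d = z.shape[1]
    noise = rng.normal(0.0, 0.1, size=(n, 3))
    ph = 6.5 + 1.2 * np.tanh(z[:, 0 % d]) + noise[:, 0]
    nitrogen = np.exp(0.5 * z[:, 1 % d]) + noise[:, 1]
    carbon = 2.0 + z[:, 2 % d] ** 2 + 0.8 * z[:, 0 % d] + noise[:, 2]
    env_df = pd.DataFrame({"soil_ph": ph, "nitrogen": nitrogen, "carbon": carbon},
                          index=sample_ids)
    schema = {f: "numeric" for f in env_df.columns}
    units = {"soil_ph": "pH", "nitrogen": "mg/kg", "carbon": "percent"}
    small_env = EnvironmentTable(env_df, schema, units)
    small_otu = abundance.select_samples(sample_ids)
    return small_otu, small_env, z
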