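"""Frozen-decoder transfer learning.

The transferable knowledge of a trained autoencoder lives in its latent
geometry and decoder. Given a small follow-up dataset — possibly with
entirely different environmental features — a new environment → latent
predictor is fitted against the source OTU-encoder's codes of the small
dataset's own compositions, and composed with the unchanged source decoder.
"""

from __future__ import annotations

from .containers import AbundanceTable, EnvironmentTable
from .models import (ArchitectureConfig, PredictionModel, TrainedAE,
                     assemble_prediction_model, decoder_digest,
                     train_latent_predictor)
from .transforms import encode_environment


def transfer_fit(source: TrainedAE, small_otu: AbundanceTable,
                 small_env: EnvironmentTable,
                 cfg: ArchitectureConfig | None = None) -> PredictionModel:
    """Fit a prediction model for a small dataset on top of a source AE.

    The small dataset's taxa must match the source decoder's output taxa
    exactly (same ids, same order); harmonize heterogeneous studies first by
    aggregating BOTH to a common taxonomic rank with
    :func:`ecolatent.transforms.aggregate_taxa`. A new encoding schema is
    fitted on ``small_env`` (its features may differ entirely from the
    source's). The decoder is frozen: its parameters are bit-identical
    before and after this call.
    """
    if small_otu.n_samples == 0:
        raise ValueError("transfer requires at least one training sample")
    if list(small_otu.taxon_ids) != list(source.taxon_ids):
        unmatched = (set(small_otu.taxon_ids) ^ set(source.taxon_ids)) or {"<order differs>"}
        raise ValueError(
            "small dataset taxa do not match the source decoder's output taxa; "
            f"unmatched: {sorted(unmatched)[:10]}"
        )
    small_env = small_env.select_samples(small_otu.sample_ids)
    if cfg is None:
        cfg = source.config
    digest_before = decoder_digest(source)
    e_small, schema = encode_environment(small_env)
    codes = source.encode(small_otu)
    predictor = train_latent_predictor(e_small, codes, cfg)
    model = assemble_prediction_model(source, "otu_latent", predictor=predictor,
                                      schema=schema)
    assert decoder_digest(source) == digest_before  # frozen-decoder contract
    return model
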