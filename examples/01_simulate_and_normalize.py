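"""Generate a synthetic microbiome study and normalize it.

Draws a seeded dataset in which environmental covariates (plant age,
temperature, rain, maize line) drive taxa abundances through a hidden
5-dimensional factor, then shows the two compositional normalizations and
taxonomic aggregation.
"""

import ecolatent as el

cfg = el.SyntheticConfig(n_samples=500, n_taxa=80, n_phyla=8, seed=7)
counts, taxonomy, env, truth = el.generate(cfg)
print(f"counts table: {counts.n_taxa} taxa x {counts.n_samples} samples, "
      f"depth {int(counts.values[:, 0].sum())} reads/sample")
print(f"environment features: {env.features}")

rel = el.tss(counts)
print(f"TSS columns sum to 1: {rel.values.sum(axis=0).round(12).min()} .. "
      f"{rel.values.sum(axis=0).round(12).max()}")

balances = el.clr(counts, pseudocount=1.0)
print(f"CLR columns sum to ~0: max |sum| = {abs(balances.values.sum(axis=0)).max():.2e}")

phylum = el.aggregate_taxa(counts, taxonomy, "Phylum")
print(f"aggregated to {phylum.n_taxa} phyla; per-sample reads conserved: "
      f"{bool((phylum.values.sum(axis=0) == counts.values.sum(axis=0)).all())}")
# The conserved totals mean aggregation only regroups reads — no mass is
# created or lost, so metrics at different ranks describe the same samples.
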