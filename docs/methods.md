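# Methods

## Problem setting

Microbiome compositions are compositional: a sample is a vector of relative
abundances on the simplex, typically observed as sequencing counts at some
depth. The package models the map from a few environmental covariates to
the full composition by routing it through a low-dimensional latent code
learned by autoencoders. This document records the modelling choices, the
defaults and their rationale, what the synthetic data generator does and
does not emulate, and the package's known limitations.

## Normalizations

Two per-sample normalizations are supported, recorded in every trained
model's `NormalizationState` so outputs can always be mapped back to
relative abundances:

* **TSS** — divide each sample by its total count. Output lives on the
  simplex; models then carry a softmax output head.
* **TSS + CLR** — add a pseudocount to counts, TSS, then log of each
  component over the sample's geometric mean. Output is unconstrained with
  zero-sum coordinates; models carry a linear head and predictions return
  to the simplex through a softmax (which inverts CLR up to the closure
  constant).

The pseudocount default is 1 count, the standard simple choice for zero
replacement; it is configurable because zero handling is a genuine open
choice in compositional analysis. Evaluation always happens after mapping
back to relative abundances, so models trained under different
normalizations are directly comparable; scale-dependent errors (MAE/MSE)
computed on different training scales would not be.

## Losses

Three reconstruction losses: MSE (any scale), crossentropy and Bray–Curtis
(simplex predictions only, hence TSS + softmax head; the configuration
layer rejects them under CLR). The Bray–Curtis loss is the dissimilarity
Σ|x̂−x| / Σ(x̂+x) averaged over the batch; its elementwise subgradient
sign(x̂−x)/S − D/S² (S the denominator, D the numerator) is exact away from
ties. Crossentropy uses an internal ε = 1e-8 inside the logarithm.

## Architectures and training

Encoders are dense stacks `taxa → hidden… → latent` with a tanh/relu/sigmoid
hidden activation and a tanh or sigmoid latent activation; the decoder
mirrors the hidden widths in reverse. Defaults: latent 10, hidden (256,),
tanh throughout, TSS + Bray–Curtis loss, Adam at learning rate 0.001, batch
64, up to 100 epochs with early stopping (patience 10 on validation loss,
best parameters restored). The engine is pure numpy; gradients are tested
against central finite differences for every loss × head × activation
combination.

The combined (heterogeneous) autoencoder trains the composition encoder and
the environmental encoder against one shared decoder; both reconstruction
paths contribute gradients to the decoder, and a latent-alignment penalty
λ·mean((z_otu − z_env)²) with λ = 1 by default pulls the two codes
together. Reconstructing from *both* paths is a deliberate choice: it is
what makes the final environment-driven assembly coherent, since the
decoder must be good at decoding environmental codes, not only composition
codes. λ and the distance are exposed in the configuration; nothing in the
method fixes them uniquely.

The deployable prediction model composes an environment → latent map with
the frozen decoder. In `otu_latent` mode that map is a dedicated regressor
trained by MSE on the frozen OTU-encoder codes (no end-to-end fine-tuning
by default: keeping the decoder and codes fixed preserves the latent
geometry that transfer learning relies on). In `combined` mode it is the
environmental encoder itself.

Hyperparameter selection is a grid over latent size {10, 50, 100}, hidden
layers {(512, 256), (256), none}, encoder/decoder activation {tanh, relu,
sigmoid}, latent activation {tanh, sigmoid}, normalization {TSS, TSS+CLR},
loss {MSE, crossentropy, Bray–Curtis}, learning rate {0.01, 0.001} and
batch size {64, 128} — 1296 raw cells, 864 after removing simplex-loss ×
CLR pairs — scored by 5-fold cross-validated mean per-sample Pearson of the
assembled prediction model, ties broken by ascending Bray–Curtis. Fold
validation ids are retained in the result table so fold hygiene is
auditable.

## Evaluation metrics

* **Mean Pearson** in two orientations: *per-sample* (correlate each
  sample's predicted vs actual composition across taxa, average over
  samples; the default) and *per-taxon* (correlate each taxon across
  samples, average over taxa). Constant vectors carry no correlation signal
  and are excluded with a count; if everything is excluded the mean is
  undefined and the code raises rather than returning a number. This
  matters for the mean-composition baseline: it is constant per taxon, so
  its per-taxon Pearson is undefined while its per-sample Pearson is
  finite — the reason per-sample is the default for model comparison
  tables. The per-taxon orientation is the right lens for questions about
  individual taxa, e.g. whether aggregating to a higher rank makes each
  aggregated variable more predictable (it does, on the reference study:
  per-taxon Pearson rises from ≈0.65 at species level to ≈0.80 at phylum
  level for the same predictions, while per-sample Pearson stays at its
  ≈0.89 ceiling — with randomly assigned lineages there is no coherent
  block structure for per-sample correlation to gain from).
* **Mean Bray–Curtis** per sample; in [0, 1] for nonnegative input.
* **MAE / MSE / MAPE** elementwise; MAPE only over entries with positive
  actual abundance (zeros dominate sparse microbiome matrices), reported as
  a percentage with the contributing count.
* **Per-taxon RRSE** — sqrt of the squared prediction error over the
  squared error of predicting the taxon's mean (evaluation-set mean by
  default, training-set mean optionally); 1.0 means no better than the
  mean. Zero-variance taxa are excluded and listed. Taxa ranked ascending
  (ties broken by id) give the "best-predicted taxa" view with a phylum
  percentage breakdown.

## Synthetic data generator

The generator emulates the statistical structure the models assume, at a
desk scale of 2000 samples × 200 taxa by default: environmental covariates
(age 0–20 weeks, temperature 50–90 °F, rain accumulation 0–5 inches, one
categorical line factor) pass through a tanh of an affine map into a
5-dimensional latent factor with Gaussian noise (sd 0.3); taxa logits are
linear in that factor; 40% of taxa get a strongly negative intercept
(offset −4) so most counts are zero, matching microbiome sparsity; counts
are multinomial at depth 10 000 per sample. The tanh nonlinearity is
smooth, bounded and learnable by the grid's activation set — deliberately
neither trivially linear nor adversarial. Lineages are fabricated by
nested random assignment (12 phyla by default). All randomness flows from
one root seed through named spawned streams, and the truth bundle (maps,
latent values, proportions) is retained so tests can compare models against
the generative process itself.

What it does **not** emulate: phylogenetic signal (taxa sharing lineage do
not share response profiles — real phylum-level aggregates are more
coherent than these), overdispersion beyond multinomial noise, spatial or
temporal autocorrelation between samples, and batch effects. Passing tests
therefore demonstrate that the machinery recovers structure it was designed
to recover under the stated noise; they do not certify performance on any
real study.

A companion perturbation produces small transfer datasets whose metadata
are *novel* nonlinear functions of the hidden factor (stand-ins for soil
pH, nitrogen and carbon), emulating a follow-up study that measured soil
chemistry instead of weather.

## Data handling choices

* On-disk orientation is taxa-as-rows TSV (the common ecosystem export);
  a flag transposes on load. Numeric parsing uses numpy's exact float
  parser so write/load round-trips are bit-identical.
* Metadata rows with missing values are dropped with a logged count.
* Train/test splitting is a uniform random permutation under an explicit
  seed (no stratification — nothing in the modelling requires it), test
  size round(fraction·n), cross-validation folds differing by at most one
  sample.
* Feature encoding: z-scores with training mean and *population* sd for
  numerics (training min/max retained for extrapolation warnings), one-hot
  with the sorted training vocabulary for categoricals; unseen categories
  encode to an all-zeros block with a warning; zero-variance numerics
  encode to constant 0 with a warning.
* Taxonomic aggregation sums rows sharing a lineage prefix, conserving
  per-sample mass exactly; it refuses CLR input, where sums are
  meaningless.

## Transfer learning

The transferable knowledge is the latent geometry and decoder. For a small
dataset, latent targets are obtained by running the *source* OTU encoder on
the small dataset's own compositions (small studies are sequenced — they
just have too few samples to train a decoder de novo), a fresh encoding
schema is fitted on the small dataset's features, and only the environment
→ latent regressor is trained. The decoder is frozen and its parameter
digest is asserted unchanged. Taxa must match the decoder's outputs by
exact id; heterogeneous studies are harmonized by aggregating *both*
datasets to a common rank first and transferring at that rank (a
rank-aggregated source decoder), which is the supported path rather than
predicting at species level and aggregating afterwards — it avoids claiming
resolution the small study cannot verify.

## Scenario prediction

Named conditions override selected features of a base metadata table; the
model predicts each variant, optionally aggregated to a rank. Values
outside the training range are allowed with a logged extrapolation warning
rather than an error — near-boundary climate scenarios are the use case —
but no causal validity is claimed for extrapolated predictions. Units are
whatever the schema records (°F, inches, weeks in the reference study);
conversions are the caller's responsibility. Outputs are per-sample in long
format; grouping (e.g. by plant age) is left to the caller, with a
`condition_means` convenience for the condition × taxon summary.

## Numerical and determinism notes

* All training randomness (initialization, shuffling) flows from the
  configuration seed via spawned streams; identical configuration and data
  give bit-identical models.
* Softmax and CLR computations are max-shifted for stability; the TSS
  inverse clips negatives and re-closes, mapping fully non-positive output
  columns to the uniform composition.
* Constant-vector detection in correlations is exact equality (a variance
  threshold would misread floating-point roundoff as signal).
* Pipelines are sized for a single CPU: the reference study trains the
  default autoencoder in seconds, the full acceptance recomputation in a
  few minutes.

## Limitations

The models are correlational; the decoder constrains predictions to the
training manifold, so genuinely novel communities (new taxa, regime shifts)
are invisible. Cross-study transfer requires identifier harmonization by
exact match after optional rank aggregation — no fuzzy taxonomy matching is
attempted. The numpy engine implements exactly the dense feed-forward
family used here; it is not a general deep-learning substrate.
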