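# ecolatent

Deep latent-space models of microbial community composition: compress a
taxa-abundance table (hundreds of taxa) into a ~10-value latent code with
autoencoders, predict the **full** composition from a handful of
environmental features, and transfer a trained decoder to small follow-up
studies.

The package is aimed at microbiome researchers — e.g. working on crop
rhizospheres — who want to answer: *given only easily measured covariates
(plant age, temperature, recent rainfall, plant line), what community
should I expect?* Sequencing is expensive; a model that maps environment to
composition lets small farms, hypothetical climate scenarios, or follow-up
studies with few samples borrow statistical strength from one large
sequenced study.

## Model

Let x ∈ Δ^p be a sample's relative-abundance composition (p taxa, after
total-sum scaling, optionally followed by a centered log-ratio transform)
and v its encoded environmental feature vector. Three network modules are
trained:

* an **OTU encoder** f: x → z ∈ R^d (d ≈ 10),
* an **environmental encoder** g: v → z,
* a shared **decoder** h: z → x̂ with a softmax (simplex) head under TSS.

Two autoencoders are assembled from them. The composition-only AE minimizes
a reconstruction loss L(h(f(x)), x) where L is MSE, crossentropy or the
Bray–Curtis dissimilarity Σ|x̂−x| / Σ(x̂+x). The heterogeneous (combined)
AE trains both encoders against the shared decoder with

L = L(h(f(x)), x) + L(h(g(v)), x) + λ‖f(x) − g(v)‖²/d,

so the environmental code lands in the same latent geometry as the
composition code. The deployable model is v → z → h(z): either g directly,
or a dedicated regressor trained by MSE on the frozen OTU-encoder codes.
Transfer learning keeps h (and the latent geometry) frozen and refits only
the v → z map on a small dataset — whose features may differ entirely from
the source study's.

Evaluation is always on the relative-abundance scale: mean per-sample
Pearson correlation, mean Bray–Curtis dissimilarity, MAE/MSE/MAPE, and
per-taxon RRSE (root relative squared error; 1.0 = no better than
predicting the mean) for ranking which taxa are predicted best.

## Worked example

`examples/03_predict_from_environment.py` generates the reference synthetic
study (2000 samples × 200 taxa whose abundances are driven by age,
temperature, rain and line through a hidden 5-dimensional factor, with
multinomial sequencing noise at depth 10 000), trains the latent-space
model and the three reference baselines, and prints:

```
default (mean)         Pearson 0.4876  Bray-Curtis 0.6016
linear regression      Pearson 0.7307  Bray-Curtis 0.4148
MLP                    Pearson 0.8846  Bray-Curtis 0.2355
OTU latent space       Pearson 0.8868  Bray-Curtis 0.2332
```

Reading: every model is scored on held-out samples by how well its
predicted composition correlates with the observed one (higher is better)
and how dissimilar the two communities are (lower is better). The
feature-blind mean predictor sets the floor; the latent-space model tops
both metrics because its frozen decoder constrains predictions to the
manifold of realistic communities. `examples/02_autoencoder_reconstruction.py`
shows the compression itself is nearly lossless (held-out reconstruction
Pearson 0.9983, Bray–Curtis 0.0443 through the 10-value code), and
`examples/04_transfer_and_scenarios.py` shows frozen-decoder transfer to a
100-sample study with entirely new features (soil pH, nitrogen, carbon)
beating a de novo linear model (Pearson 0.7276 vs 0.6494) plus
class-level predictions for hot-and-dry versus cold-and-wet seasons.

A thin CLI mirrors the library (`ecolatent simulate | train-ae |
grid-search | baseline | evaluate | predict | scenario | transfer`); every
run writes a manifest with input digests and seeds.

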