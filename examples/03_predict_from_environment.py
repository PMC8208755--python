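"""Predict the full composition from environmental features alone.

Builds the final model (environment -> latent code -> frozen decoder) and
compares it against the three reference baselines on a held-out test set.
"""

import ecolatent as el

counts, taxonomy, env, _ = el.generate(el.SyntheticConfig(seed=7))
split = el.split_dataset(counts.sample_ids, test_fraction=0.1, k=5, seed=7)
train = counts.select_samples(split.train_ids)
test = counts.select_samples(split.test_ids)
env_train = env.select_samples(split.train_ids)
env_test = env.select_samples(split.test_ids)
actual = el.tss(test)


def report(name, pred):
    r = el.mean_pearson(pred.values, actual.values, "per_sample")
    bc = el.mean_bray_curtis(pred.values, actual.values)
    print(f"{name:22s} Pearson {r:.4f}  Bray-Curtis {bc:.4f}")


report("default (mean)", el.fit_default(el.tss(train)).predict(env_test))
report("linear regression", el.fit_linear(env_train, train).predict(env_test))
report("MLP", el.fit_mlp(env_train, train,
                         el.ArchitectureConfig(hidden_layers=(512, 256),
                                               seed=0)).predict(env_test))

cfg = el.ArchitectureConfig(latent_dim=10, hidden_layers=(256,), seed=0)
model = el.fit_prediction_model(train, env_train, test, env_test, cfg,
                                mode="otu_latent")
report("OTU latent space", model.predict(env_test))
# Higher Pearson / lower Bray-Curtis is better; the latent-space model should
# top the table because the decoder constrains predictions to realistic
# community compositions.

# best-predicted taxa, ranked by per-taxon RRSE (1.0 = no better than the mean)
rep = el.evaluate(model.predict(env_test).values, actual.values, actual.taxon_ids)
top, phyla = el.rank_best_predicted(rep.per_otu_rrse, taxonomy, top_fraction=0.05)
print(f"\ntop 5% best-predicted taxa ({len(top)}):")
print(top.round(3).to_string())
print("phylum breakdown of the top set (%):")
print(phyla.round(1).to_string())
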