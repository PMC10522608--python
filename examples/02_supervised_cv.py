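"""Supervised classification under the three label schemes.

Generates a small synthetic study with planted taxonomic and environmental
compositional effects, then cross-validates a random forest on k=6
signatures labelled by domain, by environment category, and by uniform
pseudo-labels.  The expected pattern: taxonomy > environment > random
(~1/c), showing a strong taxonomic and a weaker but real environmental
component in the signature.
"""

import numpy as np

import extremosig as es

cfg = es.GeneratorConfig(seed=0)  # 120 genomes, 500 kbp usable sequence each
contigsets, meta, _ = es.generate_dataset(cfg)
sig = es.signatures_from_contigsets(contigsets, k=6, seed=0)
X = sig.to_numpy()
spec = es.ClassifierSpec("random_forest_gini", seed=0)

domain = np.array([m.domain for m in meta])
env = np.array([m.temp_category for m in meta])
rand = es.assign_pseudo_labels(len(X), es.LabelScheme("random", n_classes=4,
                                                      seed=0))

for name, y in [("taxonomy (domain)", domain),
                ("environment category", env),
                ("random pseudo-labels", rand)]:
    plan = es.build_standard_folds(y, n_folds=10, seed=0)
    res = es.run_cv(X, y, plan, spec)
    print(f"{name:22s}: mean 10-fold CV accuracy {res.mean_accuracy:5.1f}%")

genus = np.array([m.genus for m in meta])
plan_r = es.build_genus_restricted_folds(genus, env, n_folds=10, seed=0)
res_r = es.run_cv(X, env, plan_r, spec)
print(f"environment, genus-restricted CV (test genera unseen in training): "
      f"{res_r.mean_accuracy:.1f}% — still above the 25% random baseline, so "
      f"the environmental signal is not just genus memorization")
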