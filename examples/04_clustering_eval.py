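"""Unsupervised structure: clustering accuracy and genus recovery.

Clusters k=6 signatures with parametric backends and scores them with the
Hungarian-matched clustering accuracy (ACC) against both the taxonomic and
the environmental ground truth, then checks how well clusters recover
genera via completeness/contamination quality criteria.
"""

import numpy as np

import extremosig as es

cfg = es.GeneratorConfig(seed=0, n_genera_per_domain=6, samples_per_genus=4,
                         genome_length=120_000)
contigsets, meta, _ = es.generate_dataset(cfg)
sig = es.signatures_from_contigsets(contigsets, k=6, target_len=100_000, seed=0)

truths = {"taxonomy": [m.domain for m in meta],
          "environment": [m.temp_category for m in meta]}
for backend in ("kmeans", "kmedoids", "gmm"):
    for nc in (2, 4):
        _, accs = es.evaluate_parametric(sig, backend, nc, truths, seed=0)
        print(f"{backend:8s} n_clusters={nc}: "
              + ", ".join(f"ACC({t}) = {100 * a:.1f}%"
                          for t, a in accs.items()))
print("higher ACC against taxonomy than environment = the taxonomic "
      "component dominates, as with real prokaryotic signatures")

assign, _ = es.evaluate_parametric(sig, "kmeans", 12, {}, seed=0)
report = es.cluster_quality(assign, [m.genus for m in meta])
print(f"\nkmeans n_clusters=12 genus recovery: {report.n_qualifying} clusters "
      f">=50% complete & <=50% contaminated; {report.n_recovered_genera} of "
      f"{report.n_considered_genera} genera (with >2 sequences) recovered")
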