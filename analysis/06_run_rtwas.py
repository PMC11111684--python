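#!/usr/bin/env python
"""Retrotranscriptome-wide association of predicted expression with the trait.

Computes Z = w'z / sqrt(w'Rw) per feature from the harmonised summary
statistics and the panel LD, with Bonferroni correction over the features
actually tested.
"""

import sys

import pandas as pd

from retrowas.pipeline import RunConfig, pipeline_run

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
report = pipeline_run(
    RunConfig(seed=SEED, out_dir="results/pipeline"),
    stages=["simulate", "quantify", "prep", "qc", "weights", "assoc"],
)
a = report["stages"]["assoc"]
print(f"features tested: {a['m_tested']}; per-trait significance threshold "
      f"{a['sig_threshold']:.3e}")
print(f"Bonferroni-significant: {a['n_significant']} "
      f"({a.get('pct_herv', 0)}% HERV, {a.get('pct_gene', 0)}% gene)")
res = pd.read_csv("results/pipeline/twas_results.tsv", sep="\t")
top = res.reindex(res["z"].abs().sort_values(ascending=False).index).head(5)
print(top[["feature", "cls", "best_method", "z", "p", "bonf_p"]].to_string(index=False))
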