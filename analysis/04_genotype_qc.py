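#!/usr/bin/env python
"""Variant/sample QC and GWAS summary-statistic harmonisation.

Filters variants (MAF > 0.05, HWE p >= 5e-6, missingness < 0.05, strand-
ambiguous removed) and samples (heterozygosity, missingness, relatedness),
then aligns the simulated GWAS z-scores to the panel's allele coding.
"""

import sys

from retrowas.pipeline import RunConfig, pipeline_run

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
report = pipeline_run(
    RunConfig(seed=SEED, out_dir="results/pipeline"),
    stages=["simulate", "quantify", "prep", "qc"],
)
q = report["stages"]["qc"]
print(f"variants kept: {q['n_variants_kept']} / {q['n_variants_total']}")
print(f"samples kept: {q['n_samples_kept']}")
print(f"sumstat harmonisation actions: {q['sumstat_actions']}")
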