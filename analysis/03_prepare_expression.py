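#!/usr/bin/env python
"""Filter, normalise and covariate-adjust the expression matrix.

Applies the joint count/TPM expression filter, TMM between-sample
normalisation, logCPM, genotype PCs and covariate + surrogate-variable
residualisation, producing the adjusted matrix used for weight
construction.
"""

import sys

from retrowas.pipeline import RunConfig, pipeline_run

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
report = pipeline_run(
    RunConfig(seed=SEED, out_dir="results/pipeline"),
    stages=["simulate", "quantify", "prep"],
)
p = report["stages"]["prep"]
print(f"expressed features: {p['n_expressed']} of {p['n_input_features']} "
      f"(count >= 6 and TPM >= 0.1 in >= 20% of samples)")
print(f"TMM reference sample: {p['reference_sample']}")
print(f"surrogate variables regressed out: {p['n_surrogate']}")
print("adjusted expression written to results/pipeline/adjusted_expression.tsv")
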