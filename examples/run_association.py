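"""Run the hybrid association test on a small simulated study, end to end.

Simulates a 3-gene study in which one gene carries rare causal variants,
exports it to standard files (VCF, phenotype TSV, gene models, GMT), and
runs the file-based association pipeline exactly as the CLI would.
"""

import tempfile

import numpy as np

from bomp import BompConfig, WeightConfig, run_association
from bomp.simulate import Scenario, export_study, simulate_study

scenario = Scenario(
    name="demo_set", population=10_000, n_case=80, n_ctrl=80,
    n_genes=3, n_causal=1, etiology="rare",
)
study = simulate_study(scenario, np.random.default_rng(7))
causal = [g.name for g in study.layouts if g.effects.any()]
print(f"simulated {study.samples.n_cases} cases / {study.samples.n_controls} "
      f"controls over {len(study.layouts)} genes; causal gene: {causal[0]}")

with tempfile.TemporaryDirectory() as tmp:
    paths = export_study(study, tmp)
    config = BompConfig(permutations=999, weights=WeightConfig(mode="af"))
    frame = run_association(paths["vcf"], paths["genes"], paths["gmt"],
                            paths["pheno"], config=config, seed=11)

print(frame.to_string(index=False))
print(
    "\nllr_burden/llr_position are the two component log-likelihood ratios "
    "on the observed labels;\nllr_combined is their sum; p_* are permutation "
    "p-values (999 label shuffles, add-one rule),\nso the smallest reachable "
    "p-value is 1/1000; fdr is the Benjamini-Hochberg adjustment across\n"
    "the tested groups (one group here). A small p_combined says the gene "
    "set's variant burden\nand/or variant placement separates cases from "
    "controls."
)
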