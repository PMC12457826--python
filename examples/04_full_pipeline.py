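"""End-to-end run on a synthetic day-level training log.

Discretizes the continuous columns by quantile thresholds, validates with
ANOVA, learns the latent DAG, bootstraps CPDAG edge frequencies, and
computes the ordinal causal effect of sprint kilometres on injury.
All artifacts are written as provenance-stamped CSV files.
"""

import shutil

from ordcause import PipelineConfig, run_pipeline
from ordcause.synthetic import make_training_log_like

frame, column_types = make_training_log_like(n=1500, seed=0)
config = PipelineConfig(
    column_types=column_types,
    effect_pairs=[("Kmsprinting", "Injury")],
    bootstrap_B=10,      # demo size; the reference setting is B=500
    max_iter=8,
    seed=1,
    out_dir="scratch/pipeline_demo",
)
shutil.rmtree(config.out_dir, ignore_errors=True)

bundle = run_pipeline(frame, config)

print("ANOVA validation of the discretization (one row per continuous column):")
cols = ["variable", "mean_0", "mean_1", "mean_2", "F", "p", "stars"]
print(bundle["anova"][cols].round(3).to_string(index=False))
print("\nlearned DAG edges:", bundle["model"].edges())
print("\nOCE of Kmsprinting on Injury (point estimate):")
print(bundle["oce"][("Kmsprinting", "Injury")][0].round(4).to_string(index=False))
print(f"\nartifacts in {config.out_dir}/")
# Group means rising 0 -> 1 -> 2 with p < 0.05 show the quantile thresholds
# separate each load variable; the OCE rows quantify how forcing sprint
# volume into a higher level shifts the injury-level probabilities.  An
# all-zero OCE table is an honest answer: the learner found no directed
# path from Kmsprinting to Injury in this synthetic log, and without a path
# the interventional contrast vanishes identically.
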