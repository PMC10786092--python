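"""Run the whole study replica end to end and print its summary report.

Simulation -> preprocessing -> RSA -> cluster inference -> trait scoring ->
mediation -> sampling variability, with every stage's tables and JSON
results written to a run directory.
"""

from pathlib import Path

import rsamediate as rm

config = rm.PipelineConfig(
    simulation=rm.SimulationConfig(seed=0, n_channels=16, trials_per_condition=16),
    n_participants=24,
    n_permutations=1000,
    n_boot=1000,
    sampling_n_intervals=6,
    sampling_n_resamples=200,
    seed=0,
)

out = Path("scratch/pipeline_demo")
result = rm.run_pipeline(config, out)
print(result.summary)
print(f"artifacts written to {out}/ "
      "(cohort.csv, betas.csv, clusters.json, mediation.json, ...)")
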