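"""A miniature method-comparison grid.

Runs a scaled-down version of the scenario grid (signal density x
confounding strength), a few replicates each, comparing the adjustment
methods on observed FDR and power.  The full-size grid (10,000 CpGs,
20+ replicates) is what scripts/acceptance.py reproduces.
"""
from smartsva import SimulationConfig, run_benchmark

grid = run_benchmark(
    SimulationConfig(p=2000, n=60),
    signal_fracs=(0.01, 0.1),
    confounding_sds=(0.0, 0.6),
    n_reps=3,
    methods=("unadjusted", "pca", "smartsva", "perfect"),
    seed=4,
)
cols = ["signal_frac", "confounding_sd", "method",
        "mean_lambda_nondmp", "mean_observed_fdr", "mean_tpr_fdr"]
print(grid.summary[cols].round(3).to_string(index=False))
print("\nEach row averages 3 replicates; se columns are in grid.summary too.")
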