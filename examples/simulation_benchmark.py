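"""Small simulation study: repeat simulate -> analyze -> score over seeds.

Each run builds a fresh synthetic base and experiment, analyzes it end to
end, and scores calls against the known induced regions; metrics are then
averaged. (The full-scale study uses q = 20,000 and 30 runs; see
scripts/acceptance.py.)
"""

from cssq.benchmark import aggregate_runs, run_simulation_study

runs = run_simulation_study(
    n_runs=5, q=4_000, dbi_fraction=0.025, multiplier_mode="variable", seed=2024
)
summary = aggregate_runs(runs)
for metric in ("auc", "sensitivity", "fdr"):
    m = summary[metric]
    print(f"{metric:12s} mean {m['mean']:.3f}  SD {m['sd']:.3f}")
# AUC measures how well the 1-p ranking separates induced from non-induced
# regions; sensitivity and FDR score the thresholded calls at FDR 0.05.
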