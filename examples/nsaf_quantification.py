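"""NSAF quantification and replicate correlation on a tiny simulated study.

Builds a two-group spectral-count experiment, computes NSAF abundances
(spectral count / protein length, normalized to sum to 1 per sample),
median-of-ratios size factors, and the Johnson-transformed Pearson
correlation between whole-cell replicates.
"""

import itertools

from microprot import (
    GroupSpec,
    SimulationConfig,
    compute_nsaf,
    correlate_pairs,
    estimate_size_factors,
    generate_experiment,
)

cfg = SimulationConfig(
    n_proteins=800,
    groups=(
        GroupSpec("whole_cell", 3, "whole_cell_control", 12000.0),
        GroupSpec("protrusion", 2, "protrusion", 3000.0),
    ),
    seed=7,
)
table, truth, _ = generate_experiment(cfg)
print(f"simulated table: {table.shape[0]} proteins x {table.shape[1]} samples")

nsaf = compute_nsaf(table)
print("NSAF column sums (must each be 1):", nsaf.values.sum(axis=0).round(12).tolist())

factors = estimate_size_factors(nsaf)
print("size factors (geometric mean 1):")
for s, f in factors.factors.items():
    print(f"  {s:>14s}  {f:.4f}")

pairs = list(itertools.combinations(["whole_cell_1", "whole_cell_2", "whole_cell_3"], 2))
corr = correlate_pairs(nsaf, pairs, comparisons={"whole_cell": pairs})
print(corr.pairs.to_string(index=False))
print(f"r_avg(whole_cell) = {corr.r_avg['whole_cell']:.3f}")
print(
    "Each r is the Pearson correlation of Johnson-transformed NSAF values over\n"
    "proteins detected in at least one replicate of the pair; r_avg near 0.5-0.8\n"
    "indicates reproducible replicate recovery despite count noise and dropout."
)
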