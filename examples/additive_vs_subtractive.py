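"""Additive vs subtractive candidate selection with known ground truth.

Plants 500 group-exclusive proteins detected with probability 0.7 per
replicate and compares how many each selection rule recovers.  The additive
rule ("in at least 2 replicates") needs two detections (p^2 = 0.49); the
subtractive rule ("absent from every other group") needs only one
(1-(1-p)^2 = 0.91).
"""

from microprot import (
    GroupSpec,
    SimulationConfig,
    build_candidate_lists,
    generate_experiment,
    sample_groups,
    truth_recovery_report,
)

cfg = SimulationConfig(
    n_proteins=2000,
    groups=(
        GroupSpec("A", 2, "whole_cell_control", 100000.0),
        GroupSpec("B", 2, "whole_cell_control", 100000.0),
    ),
    core_fraction=0.3,
    exclusive_fraction=0.25,       # 500 exclusives per group
    exclusive_abundance_scale=1.0,
    abundance_log_sigma=0.3,
    detection_prob=0.7,
    contaminant_count=0,
    seed=42,
)
table, truth, _ = generate_experiment(cfg)
presence = {
    name: [table.presence(r) for r in grp.replicates]
    for name, grp in sample_groups(cfg).items()
}
lists = build_candidate_lists(presence, k=2)
report = truth_recovery_report(truth, lists)

for group, entry in report["groups"].items():
    print(f"group {group} ({entry['additive']['n_planted']} planted exclusives):")
    for approach in ("additive", "subtractive"):
        e = entry[approach]
        print(f"  {approach:>11s}: recall {e['sensitivity']:.3f}, "
              f"precision {e['precision']:.3f}, list size {e['n_list']}")
print("\nExpected recalls: additive 0.49 (both replicates must detect),")
print("subtractive 0.91 (one detection suffices; exclusives cannot appear")
print("elsewhere).  The subtractive rule nearly doubles recovery of")
print("low-abundance group-specific proteins in small samples.")
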