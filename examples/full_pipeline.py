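"""End-to-end analysis of the default simulated 18-sample experiment.

Runs quantify -> correlate -> compare -> select -> enrich on the default
synthetic study (3 whole-cell groups, 4 protrusion groups, negative
controls) and prints the report sections that mirror the headline analyses:
per-sample depth, replicate intersections, candidate-list sizes, and the
percentage of protrusion-related terms among the top enriched terms under
each selection approach.
"""

from microprot import RunConfig, SimulationConfig, run_pipeline

report = run_pipeline(RunConfig(simulation=SimulationConfig(seed=0), seed=0))

print("per-sample identifications (protrusion samples are far shallower):")
for sample, entry in report["per_sample"].items():
    print(f"  {sample:>20s}: {entry['n_proteins']:4d} proteins, "
          f"{entry['total_spectra']:6d} spectra")

print("\nreplicate overlap significance (all-replicates intersection):")
for group, entry in report["intersections"].items():
    full = entry["all_replicates"]
    print(f"  {group:>16s}: observed {full['observed']:4d}, "
          f"FE {full['fold_enrichment']:.0f}, p {full['p_display']}")

print("\ncandidate lists per group:")
for group, s in report["candidate_lists"].items():
    print(f"  {group:>16s}: total {s['n_total']:4d}, "
          f"additive {s['n_additive']:4d} ({s['pct_additive']:.1f}%), "
          f"subtractive {s['n_subtractive']:3d} ({s['pct_subtractive']:.1f}%)")

print("\npercent protrusion-related terms in the top 50 enriched terms:")
print(f"  {'group':>16s}  {'total':>6s}  {'additive':>8s}  {'subtractive':>11s}")
for group, entry in report["protrusion_term_pct"].items():
    print(f"  {group:>16s}  {entry['total']:6.1f}  {entry['additive']:8.1f}  "
          f"{entry['subtractive']:11.1f}")
print("\nSubtractive selection concentrates protrusion biology in every")
print("protrusion group: discarding proteins shared with whole cells keeps")
print("the low-abundance, protrusion-specific candidates the additive")
print("two-replicate rule throws away.")
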