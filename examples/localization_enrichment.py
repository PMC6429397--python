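"""2x2 contingency enrichment of subcellular localization.

Recomputes the protrusion-localization enrichment of a microdissection
proteome against an imaging atlas in which 560 of 12,073 proteins (4.6%)
show clear protrusion localization: a 904-protein identified list with 118
localized hits, and an 87-protein exclusive list with 19.
"""

from microprot import AnnotationTerm, contingency_enrichment, localization_profile

print("identified-in-protrusions list (118 of 904 vs 560 of 12,073):")
r = contingency_enrichment(118, 904, 560, 12073)
print(f"  sample {r.pct_sample:.1f}% vs background {r.pct_background:.1f}%")
print(f"  FE = {r.fold_enrichment:.1f}, OR = {r.odds_ratio:.2f}")
print(f"  Pearson chi2 = {r.chi2_pearson:.1f} (p = {r.p_pearson:.3g}), "
      f"Yates chi2 = {r.chi2_yates:.1f} (p = {r.p_yates:.3g})")

print("\nexclusive-to-one-protrusion-subtype list (19 of 87):")
r2 = contingency_enrichment(19, 87, 560, 12073)
print(f"  sample {r2.pct_sample:.1f}% -> FE = {r2.fold_enrichment:.1f}, "
      f"p = {r2.p_pearson:.3g}")
print("Exclusive lists are enriched ~1.7x beyond the full identified list:")
print("subtracting shared abundant proteins concentrates genuine protrusion")
print("residents.\n")

# compartment-level profile of a sample against its whole-cell control
control = {f"g{i}" for i in range(120)}
sample = {f"g{i}" for i in range(70, 120)}  # avoids the 'nuclear' block below
compartments = [
    AnnotationTerm("nucleus", frozenset(f"g{i}" for i in range(50))),
    AnnotationTerm("plasma_membrane", frozenset(f"g{i}" for i in range(80, 120))),
    AnnotationTerm("cytoskeleton", frozenset(f"g{i}" for i in range(60, 90))),
]
profile = localization_profile(sample, control, compartments)
print(profile[["compartment", "fold_enrichment", "p_pearson", "direction"]]
      .to_string(index=False))
print("A protrusion-style sample is depleted of nuclear proteins and enriched")
print("for plasma-membrane ones, mirroring expected protrusion biology.")
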