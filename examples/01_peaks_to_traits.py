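"""From a CE peak table to derived glycan traits.

Builds a tiny single-sample peak table at the reference RMU positions,
annotates it (note the dropped carryover peak near RMU 220), normalises
to percent of assigned area and derives the five glycan groups plus the
Gal-ratio.
"""

import glycoage as ga

ref = ga.default_reference()

# areas in arbitrary AUC units at a few reference positions, plus a
# carryover artifact at RMU 220 and one unassignable stray peak
peaks = ga.PeakTable(
    "donor01",
    (
        (176.2, 2000.0),   # FA2
        (210.3, 1800.0),   # FA2[6]G1
        (256.1, 1400.0),   # FA2G2
        (286.0, 1100.0),   # FA2G2S1
        (334.5, 200.0),    # assigned but unidentified
        (220.4, 300.0),    # carryover -> excluded
        (399.0, 50.0),     # stray -> residual
    ),
)

assignment = ga.assign_peaks(peaks, ref)
print("excluded:", assignment.excluded)
print("residual:", assignment.residual)

profile = ga.normalize_abundances(assignment.assigned, peaks.sample_id)
print("\nprofile (% of assigned area):")
for name, pct in sorted(profile.abundances.items()):
    print(f"  {name:10s} {pct:6.2f}")
print(f"  {'UNIDENT.':10s} {profile.unidentified_percent:6.2f}")

traits = ga.derive_groups(profile)
print("\nderived groups (%):")
for k, v in traits.as_dict().items():
    print(f"  {k:24s} {v:8.4f}")

# The three galactosylation-state groups plus the unidentified share
# partition the profile; the Gal-ratio G0/(G1+2*G2) summarises how far
# galactosylation has been lost (higher = more agalactosylated).
partition = (
    traits.agalactosylated + traits.terminal_galactosylated + traits.sialylated
    + profile.unidentified_percent
)
print(f"\npartition check (should be 100): {partition:.10f}")
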