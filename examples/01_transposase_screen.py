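"""WGS screen for a mobilizing transposase gene on a simulated sample trio.

Builds the annotated helper-style reference, simulates reads for three
sample classes (wild-type background, construct-carrying strain, and a
hypothetical transposase carrier), maps each read full-length at >= 98%
identity, and calls presence of the transposase ORF from coverage of
the ORF interior — the part of the ORF absent from the construct arms —
gated on the endogenous positive-control regions.
"""

from drivescreen import (
    PresenceThresholds,
    ReadSimParams,
    ReferenceConfig,
    run_screen,
    simulate_sample_classes,
)

helper, reads = simulate_sample_classes(
    ReferenceConfig(seed=42),
    ReadSimParams(read_length=150, mean_depth=20.0, substitution_rate=0.002, seed=1),
    seed=7,
)

tracks, calls = run_screen(reads, helper, thresholds=PresenceThresholds())

print(f"reference: {helper.identifier} ({len(helper)} bp), "
      f"ORF interior {helper.named_intervals['orf_interior']}")
print(f"{'sample':<18}{'mapped':>8}{'scale':>8}  verdict   interior breadth / longest run")
for track in tracks:
    call = calls[track.sample_id]
    ev = call.evidence["orf_interior"]
    print(
        f"{track.sample_id:<18}{track.total_mapped_reads:>8}{track.scale_factor:>8.2f}"
        f"  {call.status:<9} {ev['breadth']:.3f} / {ev['longest_run']} bp"
    )

print(
    "\nA 'present' verdict means reads tile the ORF interior continuously —\n"
    "a genuine transposase source. Construct-only samples light up only the\n"
    "ORF ends carried on the arms, so their interior breadth is ~0 and the\n"
    "call is 'absent'; the positive controls confirm each library was usable."
)
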