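"""Progeny summaries and the sex-ratio distortion test.

Simulates per-female progeny for an X-shredder-like distorter strain
(95% sons) and a Y-linked strain whose shredder is silenced (Mendelian
50%), then summarizes each the way distortion experiments are reported
and tests the pooled counts against the 50% male expectation.
"""

from drivescreen import (
    CrossSimParams,
    records_from_dataframe,
    simulate_progeny,
    summarize_strain,
    test_sex_ratio,
)

for strain, m, seed in (("distorter", 0.95, 11), ("y_linked_silenced", 0.50, 13)):
    df = simulate_progeny(
        CrossSimParams(n_females=25, mean_eggs=110, hatch_prob=0.85, male_fraction=m, seed=seed),
        strain,
    )
    s = summarize_strain(records_from_dataframe(df))
    t = test_sex_ratio(s.total_males, s.total_females, strain=strain)
    print(f"{strain}: n = {s.n_females} females")
    print(f"  eggs/female     {s.mean_eggs:6.1f} +- {s.sem_eggs:.1f} (SEM)")
    print(f"  hatch rate      {s.mean_hatch_pct:6.1f} +- {s.sem_hatch_pct:.1f} %")
    print(f"  males           {s.mean_male_pct:6.1f} +- {s.sem_male_pct:.1f} % "
          f"(pooled {s.total_males}/{s.total_males + s.total_females})")
    print(f"  chi2 vs 50%     {t.chi_square:8.2f} (df=1), p = {t.p_value:.3g}\n")

print(
    "The distorter's pooled counts reject the Mendelian 50% null decisively;\n"
    "the silenced Y-linked strain does not — the pattern expected when the\n"
    "X-shredder is transcriptionally suppressed on the Y chromosome."
)
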