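"""Comparative-Ct (ddCt) quantification of transgene expression.

Simulates Ct tables for a wild-type calibrator, an autosomal strain
expressing the transgene ~30-fold over background, and a Y-linked
strain with no expression above background, then runs the standard
relative-quantification workflow and an unpaired t-test on dCt.
"""

from drivescreen import (
    QpcrSimParams,
    collapse_technical,
    compare_strains,
    relative_quantity,
    simulate_ct,
)

params = QpcrSimParams(amplification_efficiency=2.0, ct_noise_sd=0.2,
                       n_replicates=3, n_technical=2, seed=99)
ct = simulate_ct(params, {"wild_type": 1.0, "autosomal": 30.0, "y_linked": 1.1})
collapsed = collapse_technical(ct)
rq = relative_quantity(collapsed, calibrator_strain="wild_type", efficiency=2.0)

print(f"{'strain':<12}{'ddCt':>8}{'RQ':>10}   RQ range over replicates")
for strain, r in rq.items():
    print(f"{strain:<12}{r.delta_delta_ct:>8.2f}{r.rq:>10.3f}   [{r.rq_min:.3f}, {r.rq_max:.3f}]")

for strain in ("autosomal", "y_linked"):
    a = rq["wild_type"].delta_ct
    b = rq[strain].delta_ct
    t, p = compare_strains(a, b)
    print(f"unpaired t-test wild_type vs {strain}: t = {t:.2f}, p = {p:.4f}")

print(
    "\nRQ = 2^-ddCt relative to the wild-type calibrator (RQ = 1). The\n"
    "autosomal strain shows strong expression; the Y-linked strain is\n"
    "statistically indistinguishable from wild type — no expression from\n"
    "the Y chromosome."
)
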