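# drivescreen

Computational surveillance tools for assessing whether an autosomal
X-shredder transgene could become a driving Y chromosome.

Sex-ratio distorters built on X-chromosome shredding are leading
candidates for malaria-mosquito population suppression. An autosomal
X-shredder is self-limiting — but if its piggyBac-flanked construct were
ever remobilized onto the Y chromosome by a transposase supplied in
*trans*, it could turn into an invasive meiotic driver. `drivescreen`
implements the computational evidence chain used to evaluate that risk,
as a tested, reusable Python library exercisable end to end on synthetic
data:

1. **WGS transposase screen** (`drivescreen.screen`) — detect whether a
   sample's sequencing reads contain the complete transposase open
   reading frame (ORF), by full-read-length mapping at ≥ 98% identity to
   an annotated reference with internal positive controls.
2. **Insertion-site genotyping** (`drivescreen.genotyping`) — in-silico
   PCR reproduction of the transgene-stability assay (empty-site
   control, internal marker, junction reactions) with cohort
   concordance.
3. **Phenotype statistics** (`drivescreen.phenotype`) — per-female
   progeny summaries (± SEM) and the pooled chi-square sex-ratio test.
4. **qPCR quantification** (`drivescreen.qpcr`) — comparative-Ct (ΔΔCt)
   relative expression with calibrator RQ = 1 and unpaired t-tests.
5. **Translocation model** (`drivescreen.translocation`) — gamete-class
   enumeration for reciprocal autosome–Y translocations and the
   three-requirement driving-Y pathway checklist.
6. **Synthetic data** (`drivescreen.synthetic`) — seeded generators for
   every input: annotated references, genomes of the three sample
   classes, FASTQ reads, progeny tables, Ct tables.

## The core method

A read *r* of length *L* is kept only if some ungapped placement covers
the **entire** read with Hamming distance ≤ ⌊0.02·L⌋ (98% identity over
the full read length; ambiguous bases count as mismatches). Raw depth
X(p) piles one unit per reported placement; for display, tracks are
library-size scaled by N_max/N_i (counts normalized to the most deeply
sequenced sample) and reported every 10 bp.

Presence of the transposase is judged on the **ORF interior** — the part
of the ORF carried by neither construct arm, so construct-derived reads
cannot light it up. With breadth = fraction of covered positions:

* *indeterminate* if any positive-control region has breadth < 0.8;
* *present* if interior breadth ≥ 0.8 **and** the longest contiguous
  covered run spans ≥ 0.5 of the interior ("continuous mapping");
* *absent* otherwise.

For the translocation model, a heterozygote male's quadrivalent
(A, Y, A^Y, Y^A) segregates by *alternate* (A+Y, A^Y+Y^A — both gamete
classes balanced) or *adjacent-1* (A+Y^A, A^Y+Y — both carry a
duplication and a deficiency). At equal mode frequencies only 50% of
offspring are genetically balanced: translocation males are
semi-sterile.

## Worked example

`python examples/01_transposase_screen.py` simulates a wild-type
background sample, a construct-carrying strain and a hypothetical
transposase carrier at 20× coverage, screens all three against the
helper-style reference, and prints:

```
reference: helper_plasmid (2700 bp), ORF interior (950, 1850)
sample              mapped   scale  verdict   interior breadth / longest run
background_only         64    4.89  absent    0.000 / 0 bp
construct_only         177    1.77  absent    0.007 / 6 bp
transposase            313    1.00  present   1.000 / 900 bp
```

Reading the table: every sample maps well to the endogenous
positive-control (vasa regulatory) regions, so each library is usable;
the construct-only strain additionally maps to the ORF ends carried on
its arms (hence more mapped reads than background), but its ORF-interior
breadth is ~0 — there is no transposase gene, only the immobile
construct. Only the transposase carrier tiles the interior contiguously
(breadth 1.0 over all 900 bp) and is called *present*. `scale` is the
N_max/N_i factor applied to the exported depth tracks.

The other examples (`examples/02…05`) walk through stability
genotyping of a 162-individual cohort (concordance 1.0), sex-ratio
summaries and the chi-square test, ΔΔCt quantification showing no
expression from the Y, and the translocation/pathway model.

A thin CLI wraps the screen for shell use:

```bash
drivescreen run --reference ref.fa --regions regions.tsv \
    --samples sheet.csv --out outdir
```

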