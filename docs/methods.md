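# Methods

## Scope and model

`drivescreen` treats the question "could an autosomal X-shredder become
a driving Y?" as a chain of five computational checks, each implemented
as an independent module with explicit inputs: a sequence-level screen
for a transposase gene in WGS reads, an in-silico PCR stability assay,
sex-ratio statistics, comparative-Ct expression quantification, and a
combinatorial model of translocation gamete balance. Every input can be
fabricated by the synthetic module under a seed, so the whole chain runs
end to end without external data.

## Reference anatomy

The screen's reference emulates a piggyBac helper plasmid: a 5′ and a 3′
germline (vasa-type) regulatory region flanking the complete transposase
ORF. The regulatory regions are copies of endogenous single-copy
sequence and act as internal positive controls: reads from *any*
usable mosquito library cover them, so a dark query region can be
distinguished from a failed library. The transformation construct
carries the two piggyBac arms — inverted terminal repeats plus the
terminal fragments of the ORF — around a marker and the payload
cassette. The **ORF interior** (default 900 bp: an 1800 bp ORF minus
450 bp carried on each arm) appears on neither arm; its 25-mers do not
occur in the construct (asserted by exhaustive k-mer scan), so interior
coverage can only come from a genuine transposase source. Default
segment lengths (500/1800/400 bp helper; 700/600/3000/700 bp construct)
give a 2.7 kb helper and a 5.0 kb construct, compact enough to screen in
milliseconds yet long relative to the read length.

## Alignment and presence calling

Reads are mapped ungapped over their full length; a placement is kept
iff its Hamming distance is ≤ ⌊f·L⌋ with f = 0.02 (98% identity over
the entire read; N counts as a mismatch). The search splits each read
into ⌊f·L⌋+1 chunks, looks up exact chunk matches in the reference, and
verifies candidates by full Hamming count — by pigeonhole this is
*exact*: it returns precisely the placements an exhaustive scan over
every offset and both strands finds, which the test suite asserts
against a brute-force oracle. Multi-mapping reads contribute one depth
unit per placement by default (`multimap="per_read"` keeps only the
best placement: fewest mismatches, then leftmost, '+' first); mapped
read counts N_i always count distinct reads.

Depth normalization follows library-size scaling to the most deeply
sequenced sample, scale_i = N_max/N_i; a sample with no mapped reads
keeps scale 1 with a warning. Scaling exists purely for comparable
plotting (tracks are exported every 10 bp); presence calling always
uses raw depth and is therefore scale-invariant, which a test asserts.

Presence thresholds are design choices, exposed in `PresenceThresholds`:
each positive control must reach breadth ≥ 0.8 or the sample is
*indeterminate*; the ORF interior is *present* when breadth ≥ 0.8 and
its longest contiguous covered run spans ≥ 0.5 of the interior — an
operational reading of "continuous mapping" that rejects fragmented,
repeat-like coverage while tolerating sparse stochastic gaps.

A geometric caveat: because only full-length placements count, a
position within one read length of a reference region's boundary can
only be covered by reads falling entirely inside the homologous segment
of the sample genome, so expected coverage tapers linearly over ~150 bp
at segment edges. On a 400–500 bp control this taper is a sizable
fraction of the region; at 10× coverage the 0.8-breadth control gate
then fails stochastically in a few percent of samples. The packaged
study condition for end-to-end classification simulations is therefore
the generator's default 20× coverage, where the gate is comfortably
stable; real WGS screens run far deeper still.

## Synthetic data

Backgrounds are i.i.d. nucleotides at a configurable GC fraction (0.45
default, AT-rich as for *Anopheles*); no repeat structure is modelled.
Every genome embeds one endogenous vasa-like locus (both regulatory
regions around a 200 bp spacer) so controls are coverable in all sample
classes; transposase carriers additionally embed the full ORF.
Construct integration happens only at TTAA tetranucleotides with
target-site duplication (TTAA on both flanks), mirroring piggyBac
chemistry; automatically chosen loci are restricted to background
sequence because the emulated strains carry autosomal insertions with
functional loci intact. Reads are single-end 150 bp (paired-end adds
nothing to a coverage screen), drawn uniformly from both strands at
`round(depth·|G|/L)` count, with i.i.d. substitutions (default 0.002
per base, an Illumina-like rate; indels and quality profiles are not
modelled — the identity filter makes the screen insensitive to them,
but real data would need adapter/quality trimming upstream). All
generators are deterministic under their seed.

Progeny follow the minimal hierarchy consistent with per-female
summaries: eggs ~ Poisson(mean), larvae ~ Binomial(eggs, hatch), males
~ Binomial(larvae, m), with m = 0.95 for distorter scenarios and 0.5
under Mendelian segregation. Ct tables shift the target gene by
−log_E(fold) against a strain-independent reference gene, with shared
Gaussian cycle noise (default sd 0.2) and efficiency E fixed at 2.0.

What passing on these data does *not* show: robustness to genomic
repeats, structural variation, contamination, index hopping, or
divergent transposase homologs — the generator contains none of them.

## Statistics

Strain summaries average per-female percentages (hatch %, male %) and
report SEM = s/√n, matching how distortion assays are tabulated;
pooled totals are reported alongside because the sex-ratio test uses
pooled counts. The test is the 1-df goodness-of-fit chi-square against
an expected male fraction (0.5 default), no continuity correction
(counts are large in this design; Yates is available as a flag).
Calibration is asserted empirically: over 10,000 simulated null crosses
of 3,000 pooled offspring, the rejection rate at α = 0.05 lies in
[0.04, 0.06], and power at m = 0.95 with 200 offspring exceeds 0.99.

ΔΔCt quantification averages technical replicates arithmetically,
computes ΔCt per biological replicate, differences strain means against
the calibrator and reports RQ = E^−ΔΔCt; the calibrator's ΔΔCt is set
to exactly 0 so its RQ is exactly 1. Strain comparisons are unpaired
t-tests on ΔCt (approximately normal on the cycle scale) rather than on
RQ; equal-variance by default with Welch as an option, and a (0, 1)
shortcut for the degenerate all-identical case. Efficiency is fixed at
2.0; standard-curve estimation and multi-reference normalization are
out of scope.

## Genotyping

Primer sites are exact string matches (the assays target their own
construct and genome); a mismatch allowance exists but defaults off.
Amplicons are all (forward-on-plus, reverse-on-minus) site pairs with
positive length ≤ max_product (default 5,000 bp, a typical ceiling for
the polymerase class used in such assays); duplex reactions are
modelled as independent simplex predictions. The genotype logic is:
empty-site failure on both homologs ⇒ *failed*; marker plus all
junctions ⇒ *transgenic_at_locus*; marker without some junction ⇒
*discordant* (candidate remobilization); otherwise *non_transgenic*.
Calls are invariant to which homolog carries the insertion. Junction
primers are designed from the simulated genome's flanks (60 bp offset,
21-mers), since the real locus flanks are not public.

## Translocation model

The karyotype is a segment multiset over four elements; validity
requires the translocated pair to jointly carry exactly the normal
pair's segments. Only alternate and adjacent-1 segregation are
enumerated — the two modes relevant to the semi-sterility argument;
adjacent-2 and 3:1 nondisjunction are excluded by design but the mode
table is extensible. Balance is decided by comparing a gamete class's
segment multiset to the haploid complement (brute-force accounting, no
shortcuts). `fraction_balanced` is the weight-average of balanced
classes per mode: equal weights give 0.5; the weights are user-settable
to encode empirical sterility figures, which are inputs here, not
derived quantities. The pathway checklist is a strict conjunction of
the three requirements — no probabilistic combination rule is imposed
beyond it.

## Problem sizes and determinism

Defaults keep every analysis interactive on one CPU: 2.7 kb reference,
~5–11 kb genomes, hundreds of reads per sample, 162-individual cohorts,
10,000-replicate calibration runs. All randomness flows through
`numpy.random.default_rng` seeds carried in parameter objects; derived
seeds stay below 2^31. Interfaces exchange only plain-text formats
(FASTA/FASTQ/TSV/CSV/JSON).
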