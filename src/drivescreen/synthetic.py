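"""Synthetic inputs for the surveillance pipeline.

Everything downstream consumes — annotated references, genomes with or
without the transgenic construct and a transposase source, sequencing
reads, per-female progeny tables and qPCR Ct tables — can be fabricated
here under explicit parameters and a mandatory seed.

The reference pair mirrors the anatomy of a piggyBac transformation
system: a *helper*-style reference carrying the complete transposase
open reading frame (ORF) between germline (vasa-type) regulatory
regions that double as internal positive controls, and a
*construct*-style reference whose left/right arms carry the inverted
terminal repeats (ITRs) plus only the terminal fragments of that ORF.
The part of the ORF present on neither arm — the "ORF interior" — is
what distinguishes a genuine transposase source from construct-derived
reads, and is recorded as a named sub-interval of the helper's ORF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "REGION_ROLES",
    "RegionAnnotation",
    "ReferenceMap",
    "ReferenceConfig",
    "GenomeSpec",
    "ReadSimParams",
    "CrossSimParams",
    "QpcrSimParams",
    "make_reference_maps",
    "random_sequence",
    "reverse_complement",
    "find_ttaa_sites",
    "insert_construct",
    "build_genome",
    "simulate_reads",
    "simulate_sample_classes",
    "simulate_progeny",
    "simulate_ct",
    "simulate_stability_cohort",
]

REGION_ROLES = frozenset(
    {"positive_control", "query_orf", "construct_arm", "marker", "cassette", "other"}
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RegionAnnotation:
    """A named, role-tagged interval on a reference (0-based half-open)."""

    name: str
    role: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.role not in REGION_ROLES:
            raise ValueError(f"unknown region role {self.role!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"region {self.name!r}: require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceMap:
    """An annotated reference sequence.

    ``regions`` are sorted and non-overlapping.  ``named_intervals``
    holds auxiliary sub-intervals that may nest inside a region — in
    particular ``"orf_interior"``, the ORF portion absent from the
    construct arms.
    """

    identifier: str
    sequence: str
    regions: list[RegionAnnotation]
    named_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        self.regions = sorted(self.regions, key=lambda r: r.start)
        prev_end = 0
        for r in self.regions:
            if r.end > n:
                raise ValueError(f"region {r.name!r} exceeds reference length {n}")
            if r.start < prev_end:
                raise ValueError(f"region {r.name!r} overlaps a preceding region")
            prev_end = r.end
        for name, (s, e) in self.named_intervals.items():
            if not (0 <= s < e <= n):
                raise ValueError(f"named interval {name!r} out of bounds")

    def __len__(self) -> int:
        return len(self.sequence)

    def regions_with_role(self, role: str) -> list[RegionAnnotation]:
        return [r for r in self.regions if r.role == role]

    def region(self, name: str) -> RegionAnnotation:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)


def validate_helper(ref: ReferenceMap) -> None:
    """A helper-style map needs >=1 positive control and exactly one query ORF."""
    if len(ref.regions_with_role("positive_control")) < 1:
        raise ValueError("helper reference lacks a positive_control region")
    if len(ref.regions_with_role("query_orf")) != 1:
        raise ValueError("helper reference must carry exactly one query_orf region")
    if "orf_interior" not in ref.named_intervals:
        raise ValueError("helper reference lacks the orf_interior named interval")


def random_sequence(length: int, gc_fraction: float, rng: np.random.Generator) -> str:
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(bases)


@dataclass(frozen=True)
class ReferenceConfig:
    """Segment lengths (bp) for the helper / construct reference pair.

    ``orf_in_arm_len`` bases from each end of the transposase ORF are
    carried on the corresponding construct arm; the rest of the arm is
    ITR-like sequence.  The ORF interior (absent from both arms) must be
    non-empty.
    """

    vasa5_len: int = 500
    orf_len: int = 1800
    vasa3_len: int = 400
    arm_len: int = 700
    marker_len: int = 600
    cassette_len: int = 3000
    orf_in_arm_len: int = 450
    gc_fraction: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vasa5_len", "orf_len", "vasa3_len", "arm_len", "marker_len", "cassette_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.orf_in_arm_len <= 0 or self.orf_in_arm_len >= self.arm_len:
            raise ValueError("orf_in_arm_len must be positive and smaller than arm_len")
        if self.orf_len - 2 * self.orf_in_arm_len <= 0:
            raise ValueError("degenerate geometry: ORF interior would be empty")


def make_reference_maps(config: ReferenceConfig) -> tuple[ReferenceMap, ReferenceMap]:
    """Build the (helper, construct) reference pair.

    helper   = vasa 5' control + full ORF + vasa 3' control
    construct = left arm (ITR + 5' ORF fragment) + marker + cassette
                + right arm (3' ORF fragment + ITR)

    The construct arms' ORF content is copied verbatim from the helper
    ORF ends, so construct-derived reads map only to the ORF ends and
    the interior stays dark unless a real transposase source is present.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction

    vasa5 = random_sequence(config.vasa5_len, gc, rng)
    orf = random_sequence(config.orf_len, gc, rng)
    vasa3 = random_sequence(config.vasa3_len, gc, rng)

    helper = ReferenceMap(
        identifier="helper_plasmid",
        sequence=vasa5 + orf + vasa3,
        regions=[
            RegionAnnotation("vasa5_regulatory", "positive_control", 0, config.vasa5_len),
            RegionAnnotation(
                "pb_orf", "query_orf", config.vasa5_len, config.vasa5_len + config.orf_len
            ),
            RegionAnnotation(
                "vasa3_regulatory",
                "positive_control",
                config.vasa5_len + config.orf_len,
                config.vasa5_len + config.orf_len + config.vasa3_len,
            ),
        ],
        named_intervals={
            "orf_interior": (
                config.vasa5_len + config.orf_in_arm_len,
                config.vasa5_len + config.orf_len - config.orf_in_arm_len,
            )
        },
    )

    itr_len = config.arm_len - config.orf_in_arm_len
    itr_left = random_sequence(itr_len, gc, rng)
    itr_right = random_sequence(itr_len, gc, rng)
    orf_left = orf[: config.orf_in_arm_len]
    orf_right = orf[-config.orf_in_arm_len :]
    marker = random_sequence(config.marker_len, gc, rng)
    cassette = random_sequence(config.cassette_len, gc, rng)

    a, m, c = config.arm_len, config.marker_len, config.cassette_len
    construct = ReferenceMap(
        identifier="transformation_construct",
        sequence=itr_left + orf_left + marker + cassette + orf_right + itr_right,
        regions=[
            RegionAnnotation("pbacL", "construct_arm", 0, a),
            RegionAnnotation("marker", "marker", a, a + m),
            RegionAnnotation("cassette", "cassette", a + m, a + m + c),
            RegionAnnotation("pbacR", "construct_arm", a + m + c, 2 * a + m + c),
        ],
    )
    validate_helper(helper)
    return helper, construct


def find_ttaa_sites(sequence: str) -> list[int]:
    """All 0-based start positions of the piggyBac TTAA target site."""
    sites, pos = [], sequence.find("TTAA")
    while pos != -1:
        sites.append(pos)
        pos = sequence.find("TTAA", pos + 1)
    return sites


def insert_construct(background: str, construct: ReferenceMap | str, locus: int) -> str:
    """Integrate the construct at a TTAA site with target-site duplication.

    piggyBac integrates exclusively at TTAA and duplicates it, so the
    product carries TTAA on both flanks of the insert and is exactly
    ``len(background) + len(construct) + 4`` bp long.
    """
    seq = construct.sequence if isinstance(construct, ReferenceMap) else construct
    if not 0 <= locus <= len(background) - 4:
        raise ValueError(f"locus {locus} outside background")
    site = background[locus : locus + 4]
    if site != "TTAA":
        raise ValueError(
            f"invalid piggyBac target site at {locus}: expected TTAA, found {site!r}"
        )
    return background[: locus + 4] + seq + "TTAA" + background[locus + 4 :]


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for one diploid-haploid-agnostic sample genome.

    The genome always carries an endogenous vasa-like locus (copies of
    the helper's regulatory regions separated by a short coding spacer),
    so positive controls are coverable in every sample class.
    """

    background_length: int = 6000
    gc_fraction: float = 0.45
    insertions: tuple[tuple[ReferenceMap, int | None], ...] = ()
    carries_transposase: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        loci = [loc for _, loc in self.insertions if loc is not None]
        if len(set(loci)) != len(loci):
            raise ValueError("insertion loci must be distinct")
        for loc in loci:
            if not 0 <= loc < self.background_length:
                raise ValueError(f"locus {loc} outside background")


def build_genome(spec: GenomeSpec, helper: ReferenceMap) -> str:
    """Assemble a sample genome from a spec.

    Layout: random background, the endogenous vasa locus (helper
    regulatory sequences around a 200 bp spacer), more background, the
    complete transposase ORF if ``carries_transposase``, then construct
    insertions applied at TTAA sites (given locus, or drawn from the
    existing TTAA occurrences when the spec leaves it to the generator).
    """
    rng = np.random.default_rng(spec.seed)
    vasa5 = next(r for r in helper.regions if r.name == "vasa5_regulatory")
    vasa3 = next(r for r in helper.regions if r.name == "vasa3_regulatory")
    orf = helper.regions_with_role("query_orf")[0]

    third = spec.background_length // 3
    parts = [
        random_sequence(third, spec.gc_fraction, rng),
        helper.sequence[vasa5.start : vasa5.end],
        random_sequence(200, spec.gc_fraction, rng),
        helper.sequence[vasa3.start : vasa3.end],
        random_sequence(third, spec.gc_fraction, rng),
    ]
    if spec.carries_transposase:
        parts.append(helper.sequence[orf.start : orf.end])
        parts.append(random_sequence(spec.background_length - 2 * third, spec.gc_fraction, rng))
    genome = "".join(parts)

    # functional loci (endogenous vasa copies, transposase ORF) stay intact:
    # the emulated strains carry autosomal insertions, so auto-chosen TTAA
    # loci are restricted to background sequence
    protected: list[tuple[int, int]] = []
    offset = len(parts[0])
    protected.append((offset, offset + vasa5.length))  # vasa5 copy
    offset += vasa5.length + 200
    protected.append((offset, offset + vasa3.length))  # vasa3 copy
    if spec.carries_transposase:
        orf_start = len(genome) - len(parts[-1]) - orf.length
        protected.append((orf_start, orf_start + orf.length))

    for construct, locus in spec.insertions:
        if locus is None:
            sites = [
                s
                for s in find_ttaa_sites(genome)
                if not any(s < e and s + 4 > b for b, e in protected)
            ]
            if not sites:
                raise ValueError("no TTAA target site available in background")
            locus = int(sites[rng.integers(len(sites))])
        genome = insert_construct(genome, construct, locus)
        shift = (len(construct) if isinstance(construct, ReferenceMap) else len(construct)) + 4
        protected = [(b + shift, e + shift) if b >= locus else (b, e) for b, e in protected]
    return genome


@dataclass(frozen=True)
class ReadSimParams:
    """Single-end read simulation: uniform start, both strands, i.i.d. substitutions."""

    read_length: int = 150
    mean_depth: float = 20.0
    substitution_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")
        if not 0.0 <= self.substitution_rate <= 0.05:
            raise ValueError("substitution_rate must lie in [0, 0.05]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_reads(genome: str, params: ReadSimParams) -> list[tuple[str, str]]:
    """Draw ``round(mean_depth * len(genome) / read_length)`` error-bearing reads.

    Returns ``(read_id, sequence)`` pairs; byte-identical output for a
    fixed seed.  Substituted bases are forced to differ from the
    template base.
    """
    L, rl = len(genome), params.read_length
    if L < rl:
        raise ValueError("genome shorter than read length")
    n_reads = int(round(params.mean_depth * L / rl))
    rng = np.random.default_rng(params.seed)
    starts = rng.integers(0, L - rl + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)

    garr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        window = garr[starts[i] : starts[i] + rl].copy()
        if params.substitution_rate > 0:
            hit = rng.random(rl) < params.substitution_rate
            n_hit = int(hit.sum())
            if n_hit:
                # offset 1..3 from the template base, cycling through ACGT
                idx = np.searchsorted(_BASES, window[hit])
                window[hit] = _BASES[(idx + rng.integers(1, 4, size=n_hit)) % 4]
        seq = window.tobytes().decode("ascii")
        if strands[i] == 1:
            seq = reverse_complement(seq)
        reads.append((f"read_{i:06d}", seq))
    return reads


def simulate_sample_classes(
    config: ReferenceConfig,
    read_params: ReadSimParams,
    background_length: int = 6000,
    seed: int = 0,
) -> tuple[ReferenceMap, dict[str, list[tuple[str, str]]]]:
    """One seeded trio of read sets: background-only, construct-carrying,
    transposase-carrying, all sharing one helper reference.

    Emulates the three WGS sample classes the screen must separate: a
    wild-type colony genome, a transgenic strain carrying the immobile
    construct, and a hypothetical genome harbouring an intact
    transposase gene.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    helper, construct = make_reference_maps(replace(config, seed=sub()))

    specs = {
        "background_only": GenomeSpec(background_length, config.gc_fraction, (), False, sub()),
        "construct_only": GenomeSpec(
            background_length, config.gc_fraction, ((construct, None),), False, sub()
        ),
        "transposase": GenomeSpec(background_length, config.gc_fraction, (), True, sub()),
    }
    reads = {
        name: simulate_reads(build_genome(spec, helper), replace(read_params, seed=sub()))
        for name, spec in specs.items()
    }
    return helper, reads


@dataclass(frozen=True)
class CrossSimParams:
    """Per-female progeny model: eggs ~ Poisson, larvae ~ Binomial(eggs, hatch),
    males ~ Binomial(larvae, male_fraction)."""

    n_females: int = 20
    mean_eggs: float = 100.0
    hatch_prob: float = 0.85
    male_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hatch_prob", "male_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_females < 1 or self.mean_eggs < 0:
            raise ValueError("need n_females >= 1 and mean_eggs >= 0")


def simulate_progeny(params: CrossSimParams, strain: str = "strain"):
    """Per-female progeny counts as a DataFrame of cross records."""
    import pandas as pd

    rng = np.random.default_rng(params.seed)
    eggs = rng.poisson(params.mean_eggs, size=params.n_females)
    larvae = rng.binomial(eggs, params.hatch_prob)
    males = rng.binomial(larvae, params.male_fraction)
    return pd.DataFrame(
        {
            "female_id": [f"F{i + 1:03d}" for i in range(params.n_females)],
            "strain": strain,
            "eggs": eggs,
            "larvae": larvae,
            "males": males,
            "females": larvae - males,
        }
    )


@dataclass(frozen=True)
class QpcrSimParams:
    """Ct generator: target Ct shifted by -log_E(fold) vs the calibrator,
    reference gene independent of strain, shared Gaussian cycle noise."""

    amplification_efficiency: float = 2.0
    ct_noise_sd: float = 0.2
    n_replicates: int = 2
    n_technical: int = 2
    base_ct_target: float = 28.0
    base_ct_reference: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1.0 < self.amplification_efficiency <= 2.0:
            raise ValueError("amplification efficiency must lie in (1, 2]")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.n_replicates < 1 or self.n_technical < 1:
            raise ValueError("replicate counts must be >= 1")


def simulate_ct(params: QpcrSimParams, fold_changes: dict[str, float]):
    """Ct table (strain, gene, bio/tech replicate, Ct) for the given strains.

    ``fold_changes`` maps strain -> true expression fold relative to the
    calibrator (which should be included with fold 1.0).
    """
    import pandas as pd

    for strain, f in fold_changes.items():
        if f <= 0:
            raise ValueError(f"fold change for {strain!r} must be positive")
    rng = np.random.default_rng(params.seed)
    E = params.amplification_efficiency
    rows = []
    for strain, f in fold_changes.items():
        shift = -math.log(f) / math.log(E)
        for b in range(1, params.n_replicates + 1):
            for t in range(1, params.n_technical + 1):
                rows.append(
                    (strain, "target", b, t,
                     params.base_ct_target + shift + rng.normal(0, params.ct_noise_sd))
                )
                rows.append(
                    (strain, "reference", b, t,
                     params.base_ct_reference + rng.normal(0, params.ct_noise_sd))
                )
    return pd.DataFrame(rows, columns=["strain", "gene", "bio_rep", "tech_rep", "ct"])


def simulate_stability_cohort(
    n_individuals: int,
    remobilization_prob: float = 0.0,
    seed: int = 0,
    config: ReferenceConfig | None = None,
    background_length: int = 6000,
):
    """Heterozygous cohort for the insertion-stability assay.

    Every individual carries the construct at the canonical locus on one
    homolog (wild-type on the other); with ``remobilization_prob`` the
    insertion is moved to a different TTAA site instead, emulating a
    transposase-mediated jump.  Returns ``(wild_genome, construct,
    locus, individuals)`` where individuals maps id -> (homolog_a,
    homolog_b, truly_at_locus).
    """
    if not 0.0 <= remobilization_prob <= 1.0:
        raise ValueError("remobilization_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cfg = replace(config or ReferenceConfig(), seed=int(rng.integers(2**31 - 1)))
    helper, construct = make_reference_maps(cfg)
    wild = build_genome(
        GenomeSpec(background_length, cfg.gc_fraction, (), False, int(rng.integers(2**31 - 1))),
        helper,
    )
    sites = find_ttaa_sites(wild)
    if len(sites) < 2:
        raise ValueError("background offers too few TTAA sites")
    locus = int(sites[len(sites) // 2])

    individuals: dict[str, tuple[str, str, bool]] = {}
    for i in range(n_individuals):
        moved = bool(rng.random() < remobilization_prob)
        if moved:
            alt = locus
            while alt == locus:
                alt = int(sites[rng.integers(len(sites))])
            carrier = insert_construct(wild, construct, alt)
        else:
            carrier = insert_construct(wild, construct, locus)
        individuals[f"ind_{i + 1:03d}"] = (carrier, wild, not moved)
    return wild, construct, locus, individuals
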