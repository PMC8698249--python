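"""In-silico PCR genotyping of the transgene insertion site.

Reproduces the logic of the bench stability assay: three reaction
classes per individual — the wild-type *empty site* spanning the
integration locus (a universal positive control, since it amplifies
from the non-transgenic homolog of any heterozygote and from both
homologs of a wild type), the *internal marker* inside the construct,
and *junction* reactions pairing a genomic flank primer with a
construct-arm primer.  An individual whose marker and junctions all
amplify carries the transgene at the expected locus; a marker without
its junctions flags a candidate remobilization event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .synthetic import ReferenceMap, reverse_complement

__all__ = [
    "Primer",
    "PrimerAssay",
    "AmpliconPrediction",
    "GenotypeCall",
    "find_primer_sites",
    "predict_amplicons",
    "genotype_individual",
    "summarize_cohort",
    "design_locus_assays",
]

ASSAY_ROLES = ("empty_site", "internal_marker", "junction_up", "junction_down")


@dataclass(frozen=True)
class Primer:
    """A PCR primer, written 5'->3'."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 15:
            raise ValueError(f"primer {self.name!r}: need >= 15 nt")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"primer {self.name!r}: alphabet must be A/C/G/T")


@dataclass(frozen=True)
class PrimerAssay:
    forward: Primer
    reverse: Primer
    role: str
    max_product: int = 5000

    def __post_init__(self) -> None:
        if self.role not in ASSAY_ROLES:
            raise ValueError(f"unknown assay role {self.role!r}")
        if self.max_product < 1:
            raise ValueError("max_product must be positive")


@dataclass(frozen=True)
class AmpliconPrediction:
    role: str
    products: tuple[tuple[int, int, int], ...]  # (start, end, length), 0-based half-open

    @property
    def amplifies(self) -> bool:
        return len(self.products) > 0


def find_primer_sites(
    primer: Primer, genome: str, max_mismatches: int = 0
) -> list[tuple[int, str]]:
    """Binding sites of a primer: + strand matches of the primer itself,
    - strand matches of its reverse complement (position = leftmost
    coordinate of the match).  Exact by default; an optional mismatch
    allowance falls back to a full scan."""
    if not genome:
        raise ValueError("genome is empty")
    sites: list[tuple[int, str]] = []
    for strand, probe in (("+", primer.sequence), ("-", reverse_complement(primer.sequence))):
        if max_mismatches == 0:
            pos = genome.find(probe)
            while pos != -1:
                sites.append((pos, strand))
                pos = genome.find(probe, pos + 1)
        else:
            k = len(probe)
            for pos in range(len(genome) - k + 1):
                window = genome[pos : pos + k]
                if sum(a != b for a, b in zip(window, probe)) <= max_mismatches:
                    sites.append((pos, strand))
    sites.sort(key=lambda s: (s[0], s[1]))
    return sites


def predict_amplicons(
    assay: PrimerAssay, genome: str, max_mismatches: int = 0
) -> AmpliconPrediction:
    """All products from (forward on +, reverse on -) site pairs.

    A product runs from the forward primer's 5' position to the reverse
    primer's 3' end (the right edge of the - strand match) and must be
    positive in length and no longer than ``max_product``.
    """
    fwd_sites = [p for p, s in find_primer_sites(assay.forward, genome, max_mismatches) if s == "+"]
    rev_sites = [p for p, s in find_primer_sites(assay.reverse, genome, max_mismatches) if s == "-"]
    rev_len = len(assay.reverse.sequence)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r + rev_len
            length = end - f
            if 0 < length <= assay.max_product:
                products.append((f, end, length))
    return AmpliconPrediction(assay.role, tuple(sorted(products)))


@dataclass(frozen=True)
class GenotypeCall:
    individual_id: str
    status: str  # transgenic_at_locus / non_transgenic / discordant / failed
    assay_outcomes: Mapping[str, bool] = field(default_factory=dict)


def genotype_individual(
    assays: Sequence[PrimerAssay],
    homologs: tuple[str, str],
    individual_id: str = "individual",
    max_mismatches: int = 0,
) -> GenotypeCall:
    """Call one individual from its pair of homologous sequences.

    An assay counts as amplifying if it yields a product on either
    homolog.  Status logic:

    * ``failed`` — the universal empty-site control amplifies from
      neither homolog (reaction failure, no call possible);
    * ``transgenic_at_locus`` — internal marker and every junction
      assay amplify;
    * ``discordant`` — marker amplifies but some junction does not
      (construct present somewhere other than the expected locus);
    * ``non_transgenic`` — marker silent, empty site amplifies.
    """
    roles = {a.role for a in assays}
    if "empty_site" not in roles or "internal_marker" not in roles:
        raise ValueError("assays must include empty_site and internal_marker")
    if not roles & {"junction_up", "junction_down"}:
        raise ValueError("assays must include at least one junction reaction")

    outcomes: dict[str, bool] = {}
    for assay in assays:
        hit = any(predict_amplicons(assay, h, max_mismatches).amplifies for h in homologs)
        outcomes[assay.role] = outcomes.get(assay.role, False) or hit

    junctions_ok = all(v for k, v in outcomes.items() if k.startswith("junction"))
    if not outcomes["empty_site"]:
        status = "failed"
    elif outcomes["internal_marker"]:
        status = "transgenic_at_locus" if junctions_ok else "discordant"
    else:
        status = "non_transgenic"
    return GenotypeCall(individual_id, status, outcomes)


def summarize_cohort(calls: Iterable[GenotypeCall]) -> dict:
    """Status counts plus insertion-site concordance among transgenics.

    concordance = transgenic_at_locus / (transgenic_at_locus + discordant);
    a cohort in which every transgenic sits at the expected locus scores
    1.0 (the pattern a fully stable insertion shows, e.g. 162/162).
    """
    calls = list(calls)
    if not calls:
        raise ValueError("empty cohort")
    counts = {s: 0 for s in ("transgenic_at_locus", "non_transgenic", "discordant", "failed")}
    for c in calls:
        counts[c.status] += 1
    denom = counts["transgenic_at_locus"] + counts["discordant"]
    return {
        "n": len(calls),
        "counts": counts,
        "concordance": counts["transgenic_at_locus"] / denom if denom else float("nan"),
    }


def design_locus_assays(
    wild_genome: str,
    construct: ReferenceMap,
    locus: int,
    primer_len: int = 21,
    flank_gap: int = 40,
    max_product: int = 5000,
) -> list[PrimerAssay]:
    """Derive the four stability assays for a known TTAA integration locus.

    Primers are taken verbatim from the wild-type flanks and from the
    construct (marker interior and arm termini), so they are exact
    matches by construction:

    * empty_site — flank-F x flank-R across the locus (short on the
      wild-type molecule, pushed past ``max_product`` by an insertion);
    * internal_marker — inside the construct's marker region;
    * junction_up — upstream flank-F x left-arm reverse primer;
    * junction_down — right-arm forward primer x downstream flank-R.
    """
    k = primer_len
    up_start = locus - flank_gap - k
    down_end = locus + 4 + flank_gap + k
    if up_start < 0 or down_end > len(wild_genome):
        raise ValueError("locus too close to the genome edge for flanking primers")

    flank_f = Primer("flankF", wild_genome[up_start : up_start + k])
    flank_r = Primer("flankR", reverse_complement(wild_genome[down_end - k : down_end]))

    marker = construct.regions_with_role("marker")[0]
    mseq = construct.sequence[marker.start : marker.end]
    mid = len(mseq) // 2
    marker_f = Primer("markerF", mseq[mid - k : mid])
    marker_r = Primer("markerR", reverse_complement(mseq[mid + 60 : mid + 60 + k]))

    arms = construct.regions_with_role("construct_arm")
    left, right = arms[0], arms[-1]
    left_r = Primer(
        "armL_R", reverse_complement(construct.sequence[left.start + 30 : left.start + 30 + k])
    )
    right_f = Primer("armR_F", construct.sequence[right.end - 30 - k : right.end - 30])

    return [
        PrimerAssay(flank_f, flank_r, "empty_site", max_product),
        PrimerAssay(marker_f, marker_r, "internal_marker", max_product),
        PrimerAssay(flank_f, left_r, "junction_up", max_product),
        PrimerAssay(right_f, flank_r, "junction_down", max_product),
    ]
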