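"""Gamete balance of reciprocal autosome-Y translocations, and the
driving-Y pathway checklist.

A reciprocal translocation heterozygote male carries four meiotic
elements: the normal autosome A, the normal Y, and the two translocated
products A^Y and Y^A that exchanged distal segments.  At meiosis I the
quadrivalent resolves mainly by *alternate* segregation (A with Y, A^Y
with Y^A — both gamete classes carry a full haploid segment complement
and are balanced) or by *adjacent-1* segregation (homologous
centromeres separate but translocated and normal elements co-assort:
A with Y^A, A^Y with Y — every class carries a duplication and a
deficiency and is unbalanced).  With the two modes equally frequent,
half of all gametes — hence half the offspring of a translocation
male — are genetically balanced: the classical semi-sterility of
translocation heterozygotes.

The pathway checklist encodes the three jointly necessary requirements
for an autosomal X-shredder to become a driving Y: physical linkage to
the Y, faithful expression from its new Y position during late
spermatogenesis, and no prohibitive fitness cost to carrier males.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "TranslocationKaryotype",
    "GameteClass",
    "SegregationOutcome",
    "PathwayAssessment",
    "enumerate_gametes",
    "fraction_balanced",
    "assess_pathway",
]

SEGREGATION_MODES = ("alternate", "adjacent_1")


@dataclass(frozen=True)
class TranslocationKaryotype:
    """Segment content of the four elements of a translocation heterozygote.

    Defaults model an autosome of segments (A1, A2) and a Y of (Y1, Y2)
    that exchanged their distal segments: A^Y = (A1, Y2), Y^A = (Y1, A2).
    """

    autosome: tuple[str, ...] = ("A1", "A2")
    y_chromosome: tuple[str, ...] = ("Y1", "Y2")
    translocated_autosome: tuple[str, ...] = ("A1", "Y2")  # A^Y
    translocated_y: tuple[str, ...] = ("Y1", "A2")  # Y^A

    def __post_init__(self) -> None:
        normal = Counter(self.autosome) + Counter(self.y_chromosome)
        translocated = Counter(self.translocated_autosome) + Counter(self.translocated_y)
        if normal != translocated:
            raise ValueError(
                "malformed karyotype: translocated elements must jointly carry "
                "exactly the segments of the normal autosome + Y"
            )

    @property
    def haploid_complement(self) -> Counter:
        return Counter(self.autosome) + Counter(self.y_chromosome)


@dataclass(frozen=True)
class GameteClass:
    elements: tuple[str, str]
    segments: tuple[str, ...]
    balanced: bool


@dataclass(frozen=True)
class SegregationOutcome:
    mode: str
    gamete_classes: tuple[GameteClass, GameteClass]


def _gamete(karyotype: TranslocationKaryotype, names: tuple[str, str]) -> GameteClass:
    content = {
        "A": karyotype.autosome,
        "Y": karyotype.y_chromosome,
        "A^Y": karyotype.translocated_autosome,
        "Y^A": karyotype.translocated_y,
    }
    segments: list[str] = []
    for n in names:
        segments.extend(content[n])
    balanced = Counter(segments) == karyotype.haploid_complement
    return GameteClass(names, tuple(segments), balanced)


def enumerate_gametes(
    karyotype: TranslocationKaryotype, mode: str
) -> SegregationOutcome:
    """The two reciprocal gamete classes a segregation mode produces.

    alternate  -> {A, Y} and {A^Y, Y^A}; adjacent_1 -> {A, Y^A} and
    {A^Y, Y}.  Each class is flagged balanced iff its segment multiset
    equals one full haploid complement.
    """
    pairs = {
        "alternate": (("A", "Y"), ("A^Y", "Y^A")),
        "adjacent_1": (("A", "Y^A"), ("A^Y", "Y")),
    }
    if mode not in pairs:
        raise ValueError(f"unknown segregation mode {mode!r}; choose from {SEGREGATION_MODES}")
    a, b = pairs[mode]
    return SegregationOutcome(mode, (_gamete(karyotype, a), _gamete(karyotype, b)))


def fraction_balanced(
    mode_weights: Mapping[str, float],
    karyotype: TranslocationKaryotype | None = None,
) -> float:
    """Weighted fraction of balanced gamete classes across segregation modes.

    With equal alternate / adjacent-1 weights this is 0.5: only half of
    a translocation male's offspring are genetically balanced.
    """
    karyotype = karyotype or TranslocationKaryotype()
    total = 0.0
    balanced = 0.0
    for mode, w in mode_weights.items():
        if w < 0:
            raise ValueError("mode weights must be non-negative")
        outcome = enumerate_gametes(karyotype, mode)
        total += w
        balanced += w * sum(g.balanced for g in outcome.gamete_classes) / len(
            outcome.gamete_classes
        )
    if total == 0:
        raise ValueError("mode weights must not all be zero")
    return balanced / total


@dataclass(frozen=True)
class PathwayAssessment:
    linkage_established: bool
    expressed_on_y: bool
    fitness_viable: bool
    feasible: bool
    failed_requirements: tuple[str, ...] = field(default_factory=tuple)


def assess_pathway(
    linkage_established: bool,
    expressed_on_y: bool,
    fitness_viable: bool,
) -> PathwayAssessment:
    """Conjunction of the three driving-Y requirements, reporting which fail.

    1. the autosomal transgene becomes physically Y-linked;
    2. it is expressed from the Y during late spermatogenesis;
    3. Y-linkage imposes no prohibitive male fitness/viability cost.
    """
    failed = []
    if not linkage_established:
        failed.append("1: transgene not linked to the Y chromosome")
    if not expressed_on_y:
        failed.append("2: no expression from the Y during spermatogenesis")
    if not fitness_viable:
        failed.append("3: prohibitive male fitness cost")
    return PathwayAssessment(
        linkage_established=linkage_established,
        expressed_on_y=expressed_on_y,
        fitness_viable=fitness_viable,
        feasible=not failed,
        failed_requirements=tuple(failed),
    )
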