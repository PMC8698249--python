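"""WGS screening for a mobilizing transposase gene.

The screen asks one question per sample: do the reads contain the
complete transposase open reading frame?  Reads are mapped to an
annotated reference carrying the ORF between endogenous single-copy
positive-control regions; an alignment is kept only if it covers the
entire read at >= 98% identity (<= floor(0.02 * L) mismatches on an
ungapped placement).  Presence of the ORF is then judged from raw
coverage of the *ORF interior* — the part of the ORF absent from the
construct's terminal arms — with the positive controls gating the call:
a sample whose controls are not covered yields "indeterminate" rather
than a spurious "absent".

Normalization (library-size scaling to the most deeply sequenced
sample) affects only the exported depth tracks used for plotting;
presence calls always use raw depth, so they are scale-invariant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .synthetic import ReferenceMap, RegionAnnotation, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "ReadAlignment",
    "DepthTrack",
    "RegionCoverageSummary",
    "PresenceThresholds",
    "PresenceCall",
    "align_full_length",
    "depth_from_alignments",
    "normalize_tracks",
    "bin_track",
    "summarize_region",
    "call_presence",
    "screen_sample",
    "run_screen",
]


@dataclass(frozen=True)
class ReadAlignment:
    """One ungapped full-read-length placement on the reference."""

    read_id: str
    reference_id: str
    start: int
    strand: str  # '+' or '-'
    mismatches: int
    read_length: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _chunk_bounds(length: int, n_chunks: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, length, n_chunks + 1).astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_chunks)]


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    pos = haystack.find(needle)
    while pos != -1:
        yield pos
        pos = haystack.find(needle, pos + 1)


def align_full_length(
    reads: Iterable[tuple[str, str]],
    reference: ReferenceMap | str,
    max_mismatch_fraction: float = 0.02,
    reference_id: str | None = None,
) -> list[ReadAlignment]:
    """All full-length placements of each read at >= (1 - f) identity.

    Every (position, strand) placement whose Hamming distance over the
    whole read is <= floor(f * read_length) is reported; ambiguous (N)
    bases always count as mismatches.  Multi-mapping reads yield one
    alignment per placement.  Reads longer than the reference are
    skipped with a warning.

    Exactness: a placement with at most m mismatches must contain an
    exactly matching read chunk once the read is split into m + 1
    pieces (pigeonhole), so exact chunk lookup followed by full Hamming
    verification finds precisely the placements an exhaustive
    offset-by-offset scan would.
    """
    if isinstance(reference, ReferenceMap):
        ref_seq = reference.sequence
        ref_id = reference.identifier
    else:
        ref_seq = reference
        ref_id = reference_id or "reference"
    ref_arr = _encode(ref_seq)
    ref_len = len(ref_seq)

    out: list[ReadAlignment] = []
    for read_id, seq in reads:
        if not seq:
            raise ValueError(f"read {read_id!r} is empty")
        L = len(seq)
        if L > ref_len:
            logger.warning("read %s (%d bp) longer than reference (%d bp); skipped",
                           read_id, L, ref_len)
            continue
        budget = int(np.floor(max_mismatch_fraction * L))
        bounds = _chunk_bounds(L, budget + 1)
        for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
            arr = _encode(oriented)
            candidates: set[int] = set()
            for s, e in bounds:
                chunk = oriented[s:e]
                if not chunk or "N" in chunk:
                    continue
                for hit in _find_all(ref_seq, chunk):
                    start = hit - s
                    if 0 <= start <= ref_len - L:
                        candidates.add(start)
            for start in sorted(candidates):
                mm = int(np.count_nonzero(ref_arr[start : start + L] != arr))
                if mm <= budget:
                    out.append(ReadAlignment(read_id, ref_id, start, strand, mm, L))
    return out


@dataclass
class DepthTrack:
    """Per-position read depth for one sample on one reference."""

    sample_id: str
    reference_id: str
    depth: np.ndarray  # raw integer counts
    total_mapped_reads: int
    scale_factor: float = 1.0

    @property
    def scaled(self) -> np.ndarray:
        return self.depth * self.scale_factor


def depth_from_alignments(
    alignments: Sequence[ReadAlignment],
    reference: ReferenceMap | int,
    sample_id: str = "sample",
    multimap: str = "per_placement",
) -> DepthTrack:
    """Pile alignments into a depth track.

    ``multimap='per_placement'`` (default) adds one depth unit per
    reported placement, mirroring a keep-many-alignments mapping;
    ``'per_read'`` keeps only each read's best placement (fewest
    mismatches, then leftmost, '+' before '-').  ``total_mapped_reads``
    counts distinct reads either way.
    """
    if isinstance(reference, ReferenceMap):
        ref_len, ref_id = len(reference), reference.identifier
    else:
        ref_len, ref_id = int(reference), "reference"
    if multimap not in ("per_placement", "per_read"):
        raise ValueError("multimap must be 'per_placement' or 'per_read'")
    for a in alignments:
        if a.reference_id != ref_id and isinstance(reference, ReferenceMap):
            raise ValueError(f"alignment of {a.read_id} is on {a.reference_id}, not {ref_id}")

    if multimap == "per_read":
        best: dict[str, ReadAlignment] = {}
        for a in alignments:
            key = (a.mismatches, a.start, 0 if a.strand == "+" else 1)
            cur = best.get(a.read_id)
            if cur is None or key < (cur.mismatches, cur.start, 0 if cur.strand == "+" else 1):
                best[a.read_id] = a
        alignments = list(best.values())

    diff = np.zeros(ref_len + 1, dtype=np.int64)
    for a in alignments:
        diff[a.start] += 1
        diff[a.start + a.read_length] -= 1
    depth = np.cumsum(diff[:-1])
    n_reads = len({a.read_id for a in alignments})
    return DepthTrack(sample_id, ref_id, depth, n_reads)


def normalize_tracks(tracks: Sequence[DepthTrack]) -> list[DepthTrack]:
    """Library-size scaling to the most deeply sequenced sample.

    scale_factor_i = N_max / N_i with N_i the sample's mapped-read
    count; samples with no mapped reads keep scale 1 (with a warning).
    Raw depths are untouched — only ``scaled`` changes.
    """
    if not tracks:
        raise ValueError("need at least one track")
    n_max = max(t.total_mapped_reads for t in tracks)
    out = []
    for t in tracks:
        if t.total_mapped_reads == 0:
            logger.warning("sample %s has no mapped reads; scale factor left at 1", t.sample_id)
            scale = 1.0
        else:
            scale = n_max / t.total_mapped_reads
        out.append(DepthTrack(t.sample_id, t.reference_id, t.depth, t.total_mapped_reads, scale))
    return out


def bin_track(track: DepthTrack, step: int = 10) -> list[tuple[int, float]]:
    """Scaled depth sampled every ``step`` positions (for plotting only)."""
    if step < 1:
        raise ValueError("step must be >= 1")
    scaled = track.scaled
    return [(p, float(scaled[p])) for p in range(0, len(scaled), step)]


@dataclass(frozen=True)
class RegionCoverageSummary:
    """Raw-depth coverage of one region: breadth, mean depth, longest covered run."""

    region_name: str
    breadth: float
    mean_depth: float
    longest_run: int
    length: int


def summarize_region(track: DepthTrack, region: RegionAnnotation) -> RegionCoverageSummary:
    if region.end > len(track.depth):
        raise ValueError(f"region {region.name!r} outside reference")
    window = track.depth[region.start : region.end]
    covered = window >= 1
    longest = run = 0
    for c in covered:
        run = run + 1 if c else 0
        longest = max(longest, run)
    return RegionCoverageSummary(
        region_name=region.name,
        breadth=float(covered.mean()),
        mean_depth=float(window.mean()),
        longest_run=int(longest),
        length=region.length,
    )


@dataclass(frozen=True)
class PresenceThresholds:
    """Gates for presence calling (all on raw coverage).

    control_breadth: minimum breadth on every positive-control region
    for the sample to be callable at all.  orf_breadth / orf_run_fraction:
    the ORF interior is "present" when its breadth reaches orf_breadth
    AND its longest contiguous covered run reaches orf_run_fraction of
    the interior length — the operational reading of "continuous
    mapping" across the query.
    """

    control_breadth: float = 0.8
    orf_breadth: float = 0.8
    orf_run_fraction: float = 0.5


@dataclass(frozen=True)
class PresenceCall:
    sample_id: str
    target: str
    status: str  # present / absent / indeterminate
    evidence: dict = field(default_factory=dict)


def call_presence(
    summaries: Mapping[str, RegionCoverageSummary],
    reference: ReferenceMap,
    thresholds: PresenceThresholds = PresenceThresholds(),
    sample_id: str = "sample",
) -> PresenceCall:
    """Verdict for the query ORF from per-region coverage summaries.

    ``summaries`` must contain every positive-control region and the
    ``orf_interior`` interval.  A failed control makes the sample
    indeterminate regardless of the interior signal.
    """
    if "orf_interior" not in summaries:
        raise ValueError("missing ORF-interior coverage summary")
    controls = reference.regions_with_role("positive_control")
    evidence: dict = {"thresholds": thresholds.__dict__.copy(), "controls": {}}

    controls_ok = True
    for region in controls:
        if region.name not in summaries:
            raise ValueError(f"missing summary for positive control {region.name!r}")
        s = summaries[region.name]
        ok = s.breadth >= thresholds.control_breadth
        evidence["controls"][region.name] = {"breadth": s.breadth, "passed": ok}
        controls_ok = controls_ok and ok

    interior = summaries["orf_interior"]
    evidence["orf_interior"] = {
        "breadth": interior.breadth,
        "longest_run": interior.longest_run,
        "length": interior.length,
        "mean_depth": interior.mean_depth,
    }
    if not controls_ok:
        status = "indeterminate"
    elif (
        interior.breadth >= thresholds.orf_breadth
        and interior.longest_run >= thresholds.orf_run_fraction * interior.length
    ):
        status = "present"
    else:
        status = "absent"
    return PresenceCall(sample_id, "orf_interior", status, evidence)


def _interior_region(reference: ReferenceMap) -> RegionAnnotation:
    try:
        s, e = reference.named_intervals["orf_interior"]
    except KeyError as exc:
        raise ValueError("reference lacks an orf_interior annotation") from exc
    return RegionAnnotation("orf_interior", "other", s, e)


def screen_sample(
    reads: Iterable[tuple[str, str]],
    reference: ReferenceMap,
    thresholds: PresenceThresholds = PresenceThresholds(),
    sample_id: str = "sample",
    max_mismatch_fraction: float = 0.02,
    multimap: str = "per_placement",
) -> tuple[DepthTrack, PresenceCall]:
    """Map one sample's reads and call ORF presence."""
    alignments = align_full_length(reads, reference, max_mismatch_fraction)
    track = depth_from_alignments(alignments, reference, sample_id, multimap)
    summaries = {r.name: summarize_region(track, r) for r in reference.regions}
    summaries["orf_interior"] = summarize_region(track, _interior_region(reference))
    return track, call_presence(summaries, reference, thresholds, sample_id)


def run_screen(
    samples: Mapping[str, Iterable[tuple[str, str]]],
    reference: ReferenceMap,
    out_dir: str | Path | None = None,
    thresholds: PresenceThresholds = PresenceThresholds(),
    max_mismatch_fraction: float = 0.02,
    bin_step: int = 10,
    multimap: str = "per_placement",
) -> tuple[list[DepthTrack], dict[str, PresenceCall]]:
    """Screen a cohort: per-sample calls plus normalized, binned depth tracks.

    When ``out_dir`` is given, writes ``depth_binned.tsv`` (sample,
    position, scaled depth), ``presence_calls.json`` and ``screen.log``
    (thresholds and scale factors).
    """
    tracks, calls = [], {}
    for sample_id, reads in samples.items():
        track, call = screen_sample(
            reads, reference, thresholds, sample_id, max_mismatch_fraction, multimap
        )
        tracks.append(track)
        calls[sample_id] = call
    tracks = normalize_tracks(tracks)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "depth_binned.tsv", "w") as fh:
            fh.write("sample\tposition\tdepth\n")
            for t in tracks:
                for pos, d in bin_track(t, bin_step):
                    fh.write(f"{t.sample_id}\t{pos}\t{d:.4f}\n")
        with open(out / "presence_calls.json", "w") as fh:
            json.dump(
                {s: {"status": c.status, "target": c.target, "evidence": c.evidence}
                 for s, c in calls.items()},
                fh, indent=2,
            )
        with open(out / "screen.log", "w") as fh:
            fh.write(f"reference\t{reference.identifier}\n")
            fh.write(f"max_mismatch_fraction\t{max_mismatch_fraction}\n")
            for k, v in thresholds.__dict__.items():
                fh.write(f"threshold.{k}\t{v}\n")
            for t in tracks:
                fh.write(
                    f"sample\t{t.sample_id}\tmapped_reads\t{t.total_mapped_reads}"
                    f"\tscale_factor\t{t.scale_factor:.6f}\n"
                )
    return tracks, calls
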