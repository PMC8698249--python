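"""Aligner, depth tracks, normalization and presence calling."""

import numpy as np
import pytest

from drivescreen import (
    GenomeSpec,
    PresenceThresholds,
    ReadSimParams,
    ReferenceConfig,
    RegionAnnotation,
    align_full_length,
    bin_track,
    build_genome,
    call_presence,
    depth_from_alignments,
    normalize_tracks,
    reverse_complement,
    screen_sample,
    simulate_reads,
    simulate_sample_classes,
    summarize_region,
)
from drivescreen.screen import DepthTrack

from conftest import brute_force_alignments, mutate_read


class TestAligner:
    def test_empty_read_set(self, helper_map):
        assert align_full_length([], helper_map) == []

    def test_exact_substring_maps_once_per_strand_input(self, helper_map):
        read = helper_map.sequence[100:250]
        hits = align_full_length([("r1", read)], helper_map)
        assert [(h.start, h.strand, h.mismatches) for h in hits] == [(100, "+", 0)]
        rc_hits = align_full_length([("r2", reverse_complement(read))], helper_map)
        assert [(h.start, h.strand, h.mismatches) for h in rc_hits] == [(100, "-", 0)]

    def test_three_substitutions_kept_four_rejected(self, helper_map, rng):
        """floor(0.02 * 150) = 3 is the mismatch budget on 150 bp reads."""
        window = helper_map.sequence[400:550]
        pos4 = rng.choice(150, size=4, replace=False)
        read3 = mutate_read(window, pos4[:3], rng)
        read4 = mutate_read(window, pos4, rng)
        kept = align_full_length([("r3", read3)], helper_map)
        assert [(h.start, h.mismatches) for h in kept] == [(400, 3)]
        assert align_full_length([("r4", read4)], helper_map) == []

    def test_n_bases_count_as_mismatches(self, helper_map):
        window = helper_map.sequence[200:350]
        read = "NNNN" + window[4:]
        assert align_full_length([("rn", read)], helper_map) == []
        read3n = "NNN" + window[3:]
        hits = align_full_length([("rn3", read3n)], helper_map)
        assert [(h.start, h.mismatches) for h in hits] == [(200, 3)]

    def test_read_longer_than_reference_skipped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="drivescreen.screen"):
            hits = align_full_length([("long", "ACGT" * 50)], "ACGTACGTACGT")
        assert hits == [] and "skipped" in caplog.text

    def test_multiple_placements_all_reported(self):
        ref = ("TTACGGATTGCGTAGCATTCGATCGTAGCTAGCATGCTTCAGGCATCAGT" * 2) + "GGTT"
        read = ref[0:50]
        hits = align_full_length([("dup", read)], ref, max_mismatch_fraction=0.02)
        assert {(h.start, h.strand) for h in hits} == {(0, "+"), (50, "+")}

    def test_matches_exhaustive_oracle_on_mutated_reads(self, rng):
        """Seeded pigeonhole search returns exactly the placements an
        exhaustive Hamming scan over all offsets and both strands finds."""
        from drivescreen.synthetic import random_sequence

        ref = random_sequence(1_500, 0.5, rng)
        reads = []
        for i in range(120):
            start = int(rng.integers(0, 1_500 - 100 + 1))
            window = ref[start : start + 100]
            n_mut = int(rng.integers(0, 4))  # budget floor(0.02*100) = 2
            read = mutate_read(window, rng.choice(100, n_mut, replace=False), rng)
            if rng.integers(2):
                read = reverse_complement(read)
            reads.append((f"r{i}", read))
        got = {
            (h.read_id, h.start, h.strand, h.mismatches)
            for h in align_full_length(reads, ref, reference_id="ref")
        }
        assert got == brute_force_alignments(reads, ref)


class TestDepth:
    def test_no_alignments_gives_zero_track(self, helper_map):
        track = depth_from_alignments([], helper_map)
        assert track.total_mapped_reads == 0 and track.depth.sum() == 0

    def test_depth_conservation(self, helper_map, rng):
        """Sum of depth equals the sum of aligned read lengths, overlapping
        or not (position-wise recount)."""
        reads = simulate_reads(helper_map.sequence, ReadSimParams(150, 5.0, 0.0, seed=12))
        aln = align_full_length(reads, helper_map)
        track = depth_from_alignments(aln, helper_map)
        assert track.depth.sum() == sum(a.read_length for a in aln)
        # independent position-wise recount
        recount = np.zeros(len(helper_map), dtype=int)
        for a in aln:
            recount[a.start : a.start + a.read_length] += 1
        assert np.array_equal(track.depth, recount)

    def test_disjoint_alignments_sum_to_total_read_length(self, helper_map):
        reads = [("a", helper_map.sequence[0:150]), ("b", helper_map.sequence[300:450])]
        track = depth_from_alignments(align_full_length(reads, helper_map), helper_map)
        assert track.depth.sum() == 300 and track.total_mapped_reads == 2

    def test_per_read_mode_counts_each_read_once(self):
        ref = "AGCTTAGGCTAGCGATCGATCCGGATTACGCTAGGCTAACGGATCGATTA" * 2
        read = ref[:50]  # maps at 0 and 50
        aln = align_full_length([("dup", read)], ref)
        per_placement = depth_from_alignments(aln, len(ref))
        per_read = depth_from_alignments(aln, len(ref), multimap="per_read")
        assert per_placement.depth.sum() == 100
        assert per_read.depth.sum() == 50
        assert per_placement.total_mapped_reads == per_read.total_mapped_reads == 1


class TestNormalization:
    def test_single_sample_unchanged(self, helper_map):
        t = DepthTrack("s", helper_map.identifier, np.ones(10, dtype=int), 10)
        (n,) = normalize_tracks([t])
        assert n.scale_factor == 1.0 and np.array_equal(n.scaled, t.depth)

    def test_half_sized_library_doubled(self):
        a = DepthTrack("a", "ref", np.full(10, 4), 100)
        b = DepthTrack("b", "ref", np.full(10, 4), 50)
        na, nb = normalize_tracks([a, b])
        assert na.scale_factor == 1.0 and nb.scale_factor == 2.0
        assert np.array_equal(nb.scaled, np.full(10, 8.0))

    def test_empty_track_keeps_scale_one(self, caplog):
        import logging

        a = DepthTrack("a", "ref", np.full(10, 4), 100)
        z = DepthTrack("z", "ref", np.zeros(10, dtype=int), 0)
        with caplog.at_level(logging.WARNING, logger="drivescreen.screen"):
            _, nz = normalize_tracks([a, z])
        assert nz.scale_factor == 1.0 and nz.scaled.sum() == 0


class TestBinning:
    def test_step_one_is_identity(self):
        t = DepthTrack("s", "ref", np.arange(25), 5)
        assert [d for _, d in bin_track(t, 1)] == list(map(float, range(25)))

    def test_point_count_and_subsequence(self):
        t = DepthTrack("s", "ref", np.arange(100), 7, scale_factor=2.0)
        pts = bin_track(t, 10)
        assert len(pts) == 10
        scaled = t.scaled
        assert all(scaled[p] == d for p, d in pts)


class TestRegionSummary:
    def test_zero_track(self):
        t = DepthTrack("s", "ref", np.zeros(100, dtype=int), 0)
        s = summarize_region(t, RegionAnnotation("r", "other", 10, 60))
        assert s.breadth == 0.0 and s.longest_run == 0 and s.mean_depth == 0.0

    def test_fully_covered_region(self):
        t = DepthTrack("s", "ref", np.full(100, 3), 10)
        s = summarize_region(t, RegionAnnotation("r", "other", 20, 70))
        assert (s.breadth, s.mean_depth, s.longest_run) == (1.0, 3.0, 50)

    def test_half_covered_single_block(self):
        depth = np.zeros(100, dtype=int)
        depth[10:35] = 2
        t = DepthTrack("s", "ref", depth, 5)
        s = summarize_region(t, RegionAnnotation("r", "other", 10, 60))
        assert s.breadth == 0.5 and s.longest_run == 25


class TestPresence:
    def _summaries(self, helper_map, depth):
        t = DepthTrack("s", helper_map.identifier, depth, int(depth.sum() // 150) or 1)
        s, e = helper_map.named_intervals["orf_interior"]
        out = {r.name: summarize_region(t, r) for r in helper_map.regions}
        out["orf_interior"] = summarize_region(t, RegionAnnotation("orf_interior", "other", s, e))
        return out

    def test_failed_controls_give_indeterminate(self, helper_map):
        depth = np.zeros(len(helper_map), dtype=int)
        s, e = helper_map.named_intervals["orf_interior"]
        depth[s:e] = 10  # ORF lit up but controls dark
        call = call_presence(self._summaries(helper_map, depth), helper_map)
        assert call.status == "indeterminate"

    def test_covered_controls_and_dark_interior_give_absent(self, helper_map):
        depth = np.full(len(helper_map), 5)
        s, e = helper_map.named_intervals["orf_interior"]
        depth[s:e] = 0
        call = call_presence(self._summaries(helper_map, depth), helper_map)
        assert call.status == "absent"
        assert call.evidence["orf_interior"]["breadth"] == 0.0

    def test_full_coverage_gives_present(self, helper_map):
        call = call_presence(
            self._summaries(helper_map, np.full(len(helper_map), 8)), helper_map
        )
        assert call.status == "present"

    def test_fragmented_interior_coverage_is_not_continuous_mapping(self, helper_map):
        """High breadth alone is not enough: the presence rule demands a
        long contiguous run, so alternating gaps stay 'absent'."""
        depth = np.full(len(helper_map), 5)
        s, e = helper_map.named_intervals["orf_interior"]
        depth[s:e] = 0
        depth[s:e:2] = 9  # 50% breadth, runs of length 1
        call = call_presence(self._summaries(helper_map, depth), helper_map)
        assert call.status == "absent"

    def test_missing_interior_summary_is_an_error(self, helper_map):
        summaries = self._summaries(helper_map, np.full(len(helper_map), 8))
        del summaries["orf_interior"]
        with pytest.raises(ValueError, match="interior"):
            call_presence(summaries, helper_map)


class TestEndToEnd:
    def test_three_sample_classes_separate(self):
        helper, reads = simulate_sample_classes(
            ReferenceConfig(seed=1), ReadSimParams(mean_depth=12, seed=2), seed=3
        )
        calls = {name: screen_sample(r, helper, sample_id=name)[1] for name, r in reads.items()}
        assert calls["transposase"].status == "present"
        assert calls["construct_only"].status == "absent"
        assert calls["background_only"].status == "absent"

    def test_monotonicity_adding_reads_never_loses_presence(self, helper_map):
        spec = GenomeSpec(carries_transposase=True, seed=5)
        genome = build_genome(spec, helper_map)
        reads = simulate_reads(genome, ReadSimParams(150, 12.0, 0.002, seed=6))
        extra = simulate_reads(genome, ReadSimParams(150, 4.0, 0.002, seed=7))
        extra = [(f"x_{rid}", s) for rid, s in extra]
        track1, call1 = screen_sample(reads, helper_map)
        track2, call2 = screen_sample(reads + extra, helper_map)
        assert call1.status == "present" and call2.status == "present"
        assert np.all(track2.depth >= track1.depth)

    def test_presence_calls_invariant_under_normalization(self):
        """Calling uses raw depth, so scaling cannot flip a verdict."""
        helper, reads = simulate_sample_classes(
            ReferenceConfig(seed=9), ReadSimParams(mean_depth=12, seed=10), seed=11
        )
        tracks, calls = [], {}
        for name, r in reads.items():
            t, c = screen_sample(r, helper, sample_id=name)
            tracks.append(t)
            calls[name] = c.status
        assert set(calls.values()) == {"present", "absent"}
        for scaled in normalize_tracks(tracks):
            s, e = helper.named_intervals["orf_interior"]
            region = RegionAnnotation("orf_interior", "other", s, e)
            summaries = {r.name: summarize_region(scaled, r) for r in helper.regions}
            summaries["orf_interior"] = summarize_region(scaled, region)
            recall = call_presence(summaries, helper, sample_id=scaled.sample_id)
            assert recall.status == calls[scaled.sample_id]
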