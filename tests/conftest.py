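"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view

from drivescreen import ReadSimParams, ReferenceConfig, make_reference_maps, reverse_complement


@pytest.fixture(scope="session")
def reference_pair():
    """Deterministic helper/construct pair with the default anatomy."""
    return make_reference_maps(ReferenceConfig(seed=42))


@pytest.fixture(scope="session")
def helper_map(reference_pair):
    return reference_pair[0]


@pytest.fixture(scope="session")
def construct_map(reference_pair):
    return reference_pair[1]


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


def brute_force_alignments(reads, reference: str, max_mismatch_fraction: float = 0.02):
    """Exhaustive sliding-window Hamming scan over all offsets and both strands.

    Independent oracle for the seeded aligner: returns the full set of
    (read_id, start, strand, mismatches) placements within budget.
    """
    ref_arr = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    out = set()
    for read_id, seq in reads:
        L = len(seq)
        if L > len(reference):
            continue
        budget = int(np.floor(max_mismatch_fraction * L))
        windows = sliding_window_view(ref_arr, L)
        for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
            arr = np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)
            mm = (windows != arr).sum(axis=1)
            for start in np.nonzero(mm <= budget)[0]:
                out.add((read_id, int(start), strand, int(mm[start])))
    return out


def mutate_read(seq: str, positions, rng) -> str:
    """Substitute the given positions with a different base each."""
    bases = "ACGT"
    out = list(seq)
    for p in positions:
        choices = [b for b in bases if b != out[p]]
        out[p] = choices[rng.integers(3)]
    return "".join(out)


@pytest.fixture(scope="session")
def read_params():
    return ReadSimParams(read_length=150, mean_depth=10.0, substitution_rate=0.002, seed=0)
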