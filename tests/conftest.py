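"""Shared fixtures and independent oracles for the test suite."""

from math import comb

import numpy as np
import pytest

from misincmap import AlignedRead, ReferenceSequence
from misincmap.pileup import clip_read, collapse_duplicates


def mk_read(
    seq_id="chrT",
    start=0,
    bases="ACGT",
    strand="+",
    umi=None,
    read_id="r",
    replicate_id="rep01",
    offsets=None,
):
    """Contiguous aligned read unless explicit offsets are given."""
    if offsets is None:
        offsets = np.arange(len(bases))
    return AlignedRead(
        read_id=read_id,
        seq_id=seq_id,
        start=start,
        strand=strand,
        offsets=np.asarray(offsets, dtype=np.int64),
        bases=bases,
        umi=umi,
        replicate_id=replicate_id,
    )


def brute_force_pileup(reads, reference: ReferenceSequence, config):
    """Independent per-position tally by nested loops (the pileup oracle)."""
    if config.collapse_duplicates:
        reads = collapse_duplicates(reads)
    if config.end_clip:
        reads = [clip_read(r, config.end_clip) for r in reads]
    reads = [r for r in reads if r.n_aligned > 0]
    counts: dict[int, dict[str, int]] = {}
    for read in reads:
        mismatches = 0
        for off, base in read.aligned_bases:
            if base != "N" and reference.sequence[read.start + off] != base:
                mismatches += 1
        if mismatches > config.max_mismatches_per_read:
            continue
        for off, base in read.aligned_bases:
            if base == "N":
                continue
            col = counts.setdefault(read.start + off, {b: 0 for b in "ACGT"})
            col[base] += 1
    return counts


def hypergeom_fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p by exact enumeration over tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    denom = comb(n, c1)

    def pmf(k):
        return comb(r1, k) * comb(r2, c1 - k) / denom

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
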