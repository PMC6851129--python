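"""Per-replicate pileup construction: duplicate collapsing, end clipping,
per-read mismatch cap, and per-position base counting.

A pileup column records, for one reference position, how many deduplicated
reads carried each of A/C/G/T there. N bases are ignored; deletions create no
count at the deleted position. Columns with zero depth are never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import BASES, AlignedRead, ReferenceSequence, encode_bases


@dataclass
class PileupConfig:
    """Knobs reproducing the upstream alignment conventions.

    ``end_clip`` removes that many aligned bases from each read end before
    counting (Illumina read ends are error-prone). ``max_mismatches_per_read``
    discards reads exceeding the aligner's mismatch ceiling, re-applied here
    as a post hoc filter since alignment itself is upstream of this tool.
    """

    end_clip: int = 10
    max_mismatches_per_read: int = 1
    collapse_duplicates: bool = True
    strand_aware: bool = True

    def __post_init__(self):
        if self.end_clip < 0 or self.max_mismatches_per_read < 0:
            raise ValueError("end_clip and max_mismatches_per_read must be >= 0")


@dataclass
class PileupColumn:
    seq_id: str
    position: int
    ref_base: str
    counts: dict = field(default_factory=lambda: {b: 0 for b in BASES})

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def mismatch_count(self) -> int:
        return self.depth - self.counts.get(self.ref_base, 0)


class ReplicatePileup:
    """Sparse per-position base counts for one replicate.

    Internally dense (L, 4) count arrays per contig for speed; the column view
    exposes only positions with non-zero depth.
    """

    def __init__(self, replicate_id: str, references: dict[str, ReferenceSequence]):
        self.replicate_id = replicate_id
        self.references = references
        self._counts: dict[str, np.ndarray] = {}

    def counts_array(self, seq_id: str) -> np.ndarray:
        """(L, 4) int64 array of base counts for a contig (zeros if uncovered)."""
        if seq_id not in self._counts:
            L = len(self.references[seq_id])
            return np.zeros((L, 4), dtype=np.int64)
        return self._counts[seq_id]

    def add_counts(self, seq_id: str, counts: np.ndarray) -> None:
        if seq_id in self._counts:
            self._counts[seq_id] += counts
        else:
            self._counts[seq_id] = counts

    def column(self, seq_id: str, position: int) -> PileupColumn | None:
        arr = self._counts.get(seq_id)
        if arr is None or arr[position].sum() == 0:
            return None
        return PileupColumn(
            seq_id=seq_id,
            position=position,
            ref_base=self.references[seq_id].sequence[position],
            counts={b: int(arr[position, i]) for i, b in enumerate(BASES)},
        )

    def __iter__(self):
        for seq_id in sorted(self._counts):
            arr = self._counts[seq_id]
            for pos in np.nonzero(arr.sum(axis=1))[0]:
                yield self.column(seq_id, int(pos))

    @property
    def columns(self) -> dict[tuple[str, int], PileupColumn]:
        return {(c.seq_id, c.position): c for c in self}

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: seq_id, 1-based position, ref base, A/C/G/T counts."""
        rows = [
            {
                "seq_id": c.seq_id,
                "position": c.position + 1,
                "ref_base": c.ref_base,
                **c.counts,
            }
            for c in self
        ]
        return pd.DataFrame(rows, columns=["seq_id", "position", "ref_base", *BASES])


def collapse_duplicates(reads: list[AlignedRead]) -> list[AlignedRead]:
    """Collapse PCR duplicates, keeping the first read per molecule key.

    With a UMI the key is (seq_id, start, strand, umi); without, identical
    placement and base string must match: (seq_id, start, strand, length,
    bases).
    """
    seen = set()
    kept = []
    for read in reads:
        if read.umi is not None:
            key = (read.seq_id, read.start, read.strand, read.umi)
        else:
            key = (read.seq_id, read.start, read.strand, read.n_aligned, read.bases)
        if key not in seen:
            seen.add(key)
            kept.append(read)
    return kept


def clip_read(read: AlignedRead, end_clip: int) -> AlignedRead:
    """Drop the first and last ``end_clip`` aligned bases of a read.

    Reads with <= 2 * end_clip aligned bases come back empty and are dropped
    downstream.
    """
    if end_clip == 0:
        return read
    n = read.n_aligned
    if n <= 2 * end_clip:
        return replace(read, offsets=read.offsets[:0], bases="")
    return replace(
        read,
        offsets=read.offsets[end_clip : n - end_clip],
        bases=read.bases[end_clip : n - end_clip],
    )


def build_pileup(
    reads: list[AlignedRead],
    reference: ReferenceSequence | list[ReferenceSequence] | dict[str, ReferenceSequence],
    config: PileupConfig | None = None,
    replicate_id: str | None = None,
) -> ReplicatePileup:
    """Count base frequencies per reference position for one replicate.

    Pipeline: collapse duplicates -> end-clip -> discard reads with more than
    ``max_mismatches_per_read`` mismatches versus the reference -> accumulate
    counts. N bases contribute nothing.
    """
    config = config or PileupConfig()
    refs = _as_ref_dict(reference)
    if replicate_id is None:
        replicate_id = reads[0].replicate_id if reads else ""

    if config.collapse_duplicates:
        reads = collapse_duplicates(reads)
    if config.end_clip:
        reads = [clip_read(r, config.end_clip) for r in reads]
    reads = [r for r in reads if r.n_aligned > 0]

    pileup = ReplicatePileup(replicate_id, refs)
    by_seq: dict[str, list[AlignedRead]] = {}
    for read in reads:
        if read.seq_id not in refs:
            raise KeyError(f"read {read.read_id} on unknown sequence {read.seq_id!r}")
        by_seq.setdefault(read.seq_id, []).append(read)

    for seq_id, seq_reads in by_seq.items():
        ref = refs[seq_id]
        L = len(ref)
        ref_codes = ref.codes()
        lens = np.array([r.n_aligned for r in seq_reads])
        contiguous = all(
            int(r.offsets[-1]) - int(r.offsets[0]) == r.n_aligned - 1
            for r in seq_reads
        )
        if contiguous:
            # positions = repeat(first_position, len) + within-read ranges
            firsts = np.array([r.start + int(r.offsets[0]) for r in seq_reads])
            total = int(lens.sum())
            within = np.arange(total) - np.repeat(
                np.concatenate(([0], np.cumsum(lens)[:-1])), lens
            )
            pos = np.repeat(firsts, lens) + within
        else:
            pos = np.concatenate([r.positions() for r in seq_reads])
        if pos.max() >= L:
            raise ValueError(f"read extends past end of reference {seq_id!r}")
        codes = encode_bases("".join(r.bases for r in seq_reads))
        read_idx = np.repeat(np.arange(len(seq_reads)), lens)

        real = codes < 4  # drop Ns from both mismatch counting and tallies
        mismatch = real & (codes != ref_codes[pos])
        per_read_mm = np.bincount(read_idx[mismatch], minlength=len(seq_reads))
        keep_read = per_read_mm <= config.max_mismatches_per_read

        keep = real & keep_read[read_idx]
        flat = pos[keep] * 4 + codes[keep]
        counts = np.bincount(flat, minlength=L * 4).reshape(L, 4)
        pileup.add_counts(seq_id, counts)
    return pileup


def combine_counts(
    pileups: list[ReplicatePileup],
) -> tuple[dict[str, np.ndarray], dict[str, ReferenceSequence]]:
    """Sum count arrays across replicates; also return the merged reference map."""
    refs: dict[str, ReferenceSequence] = {}
    combined: dict[str, np.ndarray] = {}
    for pu in pileups:
        refs.update(pu.references)
    for seq_id, ref in refs.items():
        total = np.zeros((len(ref), 4), dtype=np.int64)
        for pu in pileups:
            total += pu.counts_array(seq_id)
        combined[seq_id] = total
    return combined, refs


def _as_ref_dict(reference) -> dict[str, ReferenceSequence]:
    if isinstance(reference, ReferenceSequence):
        return {reference.seq_id: reference}
    if isinstance(reference, dict):
        return reference
    return {r.seq_id: r for r in reference}
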