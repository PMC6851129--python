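"""Truncation-signature analytics for miCLIP libraries.

Reverse transcription aborts at an antibody-RNA adduct, so the 5' ends of
miCLIP reads pinpoint crosslink sites. Around transcription-start sites (TSS)
this separates two hypotheses: plain RNA-seq reads terminate at offset 0
(simply the end of the transcript), whereas cap-bound antibody crosslinks push
terminations to offsets 0/+1 and occasionally further downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AlignedRead, TranscriptAnnotation

logger = logging.getLogger(__name__)

N_OFFSETS = 5  # terminations counted at TSS offsets 0..+4


@dataclass
class TerminationProfile:
    transcript_id: str
    tss: int
    counts_by_offset: dict
    tss_depth_miclip: int
    tss_depth_rnaseq: int

    def fractions(self) -> np.ndarray:
        counts = np.array([self.counts_by_offset.get(k, 0) for k in range(N_OFFSETS)], float)
        total = counts.sum()
        return counts / total if total > 0 else counts

    def modal_offset(self) -> int:
        counts = [self.counts_by_offset.get(k, 0) for k in range(N_OFFSETS)]
        return int(np.argmax(counts))


@dataclass
class Cluster:
    """Maximal interval of transitively overlapping same-strand unique reads."""

    seq_id: str
    start: int
    end: int
    strand: str
    score: int  # maximum number of stacked overlapping reads

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("cluster start must precede end")
        if self.score < 1:
            raise ValueError("cluster score must be >= 1")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, seq_id: str, position: int) -> bool:
        return seq_id == self.seq_id and self.start <= position < self.end


@dataclass
class MetageneProfile:
    """miCLIP/RNA-seq density ratio over 30 bins per region (5'UTR, CDS, 3'UTR)."""

    values: np.ndarray  # 90 values; NaN where RNA-seq density is zero
    item_counts: np.ndarray
    rnaseq_counts: np.ndarray
    bins_per_region: int = 30

    REGIONS = ("5'UTR", "CDS", "3'UTR")


@dataclass
class EnrichmentResult:
    table: np.ndarray  # rows: A-start / non-A-start; cols: overlapping / not
    fraction_overlap: float
    fraction_background: float
    odds_ratio: float
    p_value: float


# ---------------------------------------------------------------------------


def _tss_coverage(reads_by_seq: dict, annot: TranscriptAnnotation) -> int:
    """Unique reads covering the TSS position."""
    n = 0
    for read in reads_by_seq.get((annot.seq_id, annot.strand), []):
        if read.start <= annot.tss < read.end:
            n += 1
    return n


def _group_reads(reads: list[AlignedRead]) -> dict:
    grouped: dict[tuple[str, str], list[AlignedRead]] = {}
    for read in reads:
        grouped.setdefault((read.seq_id, read.strand), []).append(read)
    return grouped


def termination_profiles(
    miclip_reads: list[AlignedRead],
    rnaseq_reads: list[AlignedRead],
    annotations: list[TranscriptAnnotation],
    min_tss_coverage: int = 5,
) -> tuple[list[TerminationProfile], pd.DataFrame]:
    """Count miCLIP read 5' ends at offsets 0..+4 from each eligible TSS.

    A TSS is eligible when at least ``min_tss_coverage`` unique reads cover
    the TSS position in *both* the miCLIP and the RNA-seq library. The
    aggregate gives each TSS equal weight: per-offset mean fraction across
    TSSs with its SEM.
    """
    mi = _group_reads(miclip_reads)
    rna = _group_reads(rnaseq_reads)
    profiles = []
    for annot in annotations:
        depth_mi = _tss_coverage(mi, annot)
        depth_rna = _tss_coverage(rna, annot)
        if depth_mi < min_tss_coverage or depth_rna < min_tss_coverage:
            continue
        sign = 1 if annot.strand == "+" else -1
        counts = {k: 0 for k in range(N_OFFSETS)}
        for read in mi.get((annot.seq_id, annot.strand), []):
            offset = sign * (read.five_prime_end() - annot.tss)
            if 0 <= offset < N_OFFSETS:
                counts[offset] += 1
        profiles.append(
            TerminationProfile(
                transcript_id=annot.transcript_id,
                tss=annot.tss,
                counts_by_offset=counts,
                tss_depth_miclip=depth_mi,
                tss_depth_rnaseq=depth_rna,
            )
        )
    if not profiles:
        logger.warning("no TSS passed the coverage filter (min %d)", min_tss_coverage)
        aggregate = pd.DataFrame(columns=["offset", "mean_fraction", "sem", "n_tss"])
        return profiles, aggregate

    fractions = np.array([p.fractions() for p in profiles if sum(p.counts_by_offset.values()) > 0])
    n = len(fractions)
    mean = fractions.mean(axis=0)
    sem = fractions.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(N_OFFSETS)
    aggregate = pd.DataFrame(
        {"offset": np.arange(N_OFFSETS), "mean_fraction": mean, "sem": sem, "n_tss": n}
    )
    return profiles, aggregate


# ---------------------------------------------------------------------------


def call_clusters(reads: list[AlignedRead], min_score: int = 20) -> list[Cluster]:
    """Merge same-strand overlapping unique reads into scored clusters.

    Overlapping reads merge transitively into maximal intervals; the cluster
    score is the maximum per-position stacked read depth within the interval.
    Clusters scoring below ``min_score`` are dropped. Order-invariant.
    """
    clusters = []
    for (seq_id, strand), group in _group_reads(reads).items():
        spans = sorted((r.start, r.end) for r in group if r.end > r.start)
        if not spans:
            continue
        cur_start, cur_end = spans[0]
        merged = []
        for start, end in spans[1:]:
            if start < cur_end:  # overlap (half-open intervals)
                cur_end = max(cur_end, end)
            else:
                merged.append((cur_start, cur_end))
                cur_start, cur_end = start, end
        merged.append((cur_start, cur_end))

        for start, end in merged:
            inside = [(s, e) for s, e in spans if s >= start and e <= end]
            diff = np.zeros(end - start + 1, dtype=np.int64)
            for s, e in inside:
                diff[s - start] += 1
                diff[e - start] -= 1
            score = int(np.cumsum(diff).max())
            if score >= min_score:
                clusters.append(Cluster(seq_id, start, end, strand, score))
    clusters.sort(key=lambda c: (c.seq_id, c.start))
    return clusters


# ---------------------------------------------------------------------------


def _scaled_bin(
    annot: TranscriptAnnotation, position: int, bins_per_region: int
) -> int | None:
    """Map a position to one of 3 * bins_per_region metagene bins, 5'->3'."""
    regions_fw = [
        (annot.tx_start, annot.cds_start),
        (annot.cds_start, annot.cds_end),
        (annot.cds_end, annot.tx_end),
    ]
    if annot.strand == "+":
        regions = regions_fw
    else:
        regions = regions_fw[::-1]
    for idx, (start, end) in enumerate(regions):
        if start <= position < end:
            if annot.strand == "+":
                frac = (position - start) / (end - start)
            else:
                frac = (end - 1 - position) / (end - start)
            b = min(int(frac * bins_per_region), bins_per_region - 1)
            return idx * bins_per_region + b
    return None


def metagene(
    items,
    annotations: list[TranscriptAnnotation],
    rnaseq_reads: list[AlignedRead],
    bins_per_region: int = 30,
) -> MetageneProfile:
    """Transcript-scaled miCLIP density normalized to RNA-seq density.

    ``items`` may be clusters or reads; each item's midpoint lands in one of
    30 bins per region (5'UTR, CDS, 3'UTR). Bin values are the ratio of
    miCLIP density (fraction of items) to RNA-seq read-midpoint density;
    bins with zero RNA-seq density are NaN (missing), not infinite.
    Transcripts lacking any of the three regions are skipped.
    """
    n_bins = 3 * bins_per_region
    usable = [
        a
        for a in annotations
        if a.tx_start < a.cds_start and a.cds_start < a.cds_end and a.cds_end < a.tx_end
    ]

    def tally(midpoints) -> np.ndarray:
        counts = np.zeros(n_bins, dtype=np.int64)
        for seq_id, pos in midpoints:
            for annot in usable:
                if annot.seq_id == seq_id and annot.tx_start <= pos < annot.tx_end:
                    b = _scaled_bin(annot, pos, bins_per_region)
                    if b is not None:
                        counts[b] += 1
                    break
        return counts

    item_mid = [
        (it.seq_id, it.midpoint) if isinstance(it, Cluster) else (it.seq_id, (it.start + it.end) // 2)
        for it in items
    ]
    rna_mid = [(r.seq_id, (r.start + r.end) // 2) for r in rnaseq_reads]
    item_counts = tally(item_mid)
    rna_counts = tally(rna_mid)

    if item_counts.sum() == 0:
        values = np.zeros(n_bins)
    else:
        item_density = item_counts / item_counts.sum()
        rna_density = (
            rna_counts / rna_counts.sum() if rna_counts.sum() else np.zeros(n_bins)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(rna_density > 0, item_density / np.maximum(rna_density, 1e-300), np.nan)
    return MetageneProfile(
        values=values,
        item_counts=item_counts,
        rnaseq_counts=rna_counts,
        bins_per_region=bins_per_region,
    )


# ---------------------------------------------------------------------------


def fisher_exact_two_sided(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table -> (odds ratio, p)."""
    odds, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)


def tss_start_enrichment(
    clusters: list[Cluster], annotations: list[TranscriptAnnotation]
) -> EnrichmentResult:
    """Are adenosine-start TSSs over-represented among cluster-overlapping TSSs?

    Builds the 2x2 table {start A vs not} x {TSS overlapping a cluster vs
    not} over the full TSS catalog and applies a two-sided Fisher's exact
    test. Degenerate margins report p = 1 with a warning.
    """
    a_ov = a_no = o_ov = o_no = 0
    for annot in annotations:
        overlaps = any(
            c.contains(annot.seq_id, annot.tss) and c.strand == annot.strand
            for c in clusters
        )
        is_a = annot.start_nucleotide == "A"
        if is_a and overlaps:
            a_ov += 1
        elif is_a:
            a_no += 1
        elif overlaps:
            o_ov += 1
        else:
            o_no += 1
    table = np.array([[a_ov, a_no], [o_ov, o_no]], dtype=np.int64)
    n = table.sum()
    n_overlap = a_ov + o_ov
    fraction_overlap = a_ov / n_overlap if n_overlap else 0.0
    fraction_background = (a_ov + a_no) / n if n else 0.0
    if 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
        warnings.warn("degenerate 2x2 margins; Fisher test uninformative (p = 1)")
        return EnrichmentResult(table, fraction_overlap, fraction_background, np.nan, 1.0)
    odds, p = fisher_exact_two_sided(table)
    return EnrichmentResult(table, fraction_overlap, fraction_background, odds, p)
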