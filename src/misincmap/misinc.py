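"""Candidate hard-stop modification sites from multi-replicate pileups.

The filter chain distinguishes modification-induced misincorporations from
sequencing error, genomic variants and A-to-I editing:

1.  combined read depth across replicates >= ``min_combined_depth``
    (deep coverage so a low read-through modification still leaves evidence);
2.  combined misincorporation rate >= ``min_rate``;
3.  detection (own depth and rate gates) in at least
    ``min_replicate_fraction`` of the replicates — sequencing errors do not
    replicate across libraries;
4.  positions in the variant mask (genomic variants, dbSNP) are never
    analyzed;
5.  *high-confidence* additionally requires misincorporation heterogeneity —
    a minority-mismatch fraction >= ``min_heterogeneity`` — because hard-stop
    nucleotides scatter reads over all three alternative bases while A→G
    editing and unmasked heterozygous alleles produce a single pure class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import BASES, VariantMask
from .pileup import PileupColumn, ReplicatePileup, combine_counts


@dataclass
class FilterConfig:
    min_combined_depth: int = 500
    min_rate: float = 0.01
    min_replicate_fraction: float = 0.5
    min_heterogeneity: float = 0.05
    per_replicate_min_depth: int = 20
    per_replicate_min_rate: float = 0.01

    def __post_init__(self):
        for name in ("min_rate", "min_replicate_fraction", "min_heterogeneity", "per_replicate_min_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_combined_depth < 1 or self.per_replicate_min_depth < 1:
            raise ValueError("depth thresholds must be >= 1")


@dataclass
class CandidateSite:
    """One position passing the depth/rate/replication filters."""

    seq_id: str
    position: int  # 0-based
    ref_base: str
    combined_counts: dict
    replicates_detected: int
    n_replicates: int
    high_confidence: bool = False

    @property
    def combined_depth(self) -> int:
        return sum(self.combined_counts.values())

    @property
    def combined_rate(self) -> float:
        depth = self.combined_depth
        return (depth - self.combined_counts.get(self.ref_base, 0)) / depth

    @property
    def heterogeneity(self) -> float:
        mism = {b: c for b, c in self.combined_counts.items() if b != self.ref_base}
        total = sum(mism.values())
        if total == 0:
            return 0.0
        return 1.0 - max(mism.values()) / total


@dataclass
class ReadthroughEstimate:
    seq_id: str
    position: int
    site_depth: int
    flank_depth: float
    readthrough_rate: float


def misincorporation_rate(column: PileupColumn) -> float:
    """Fraction of covering reads whose base differs from the reference."""
    depth = column.depth
    if depth == 0:
        raise ValueError("misincorporation rate undefined at zero depth")
    return (depth - column.counts.get(column.ref_base, 0)) / depth


def heterogeneity_fraction(column: PileupColumn) -> float:
    """Minority-mismatch fraction: 1 - modal mismatch count / total mismatches.

    Ties on the modal base are broken A<C<G<T; the result is tie-break
    invariant since only the modal *count* enters.
    """
    mism = {b: c for b, c in column.counts.items() if b != column.ref_base}
    total = sum(mism.values())
    if total == 0:
        raise ValueError("heterogeneity undefined with zero mismatches")
    modal = max(mism.values())
    return 1.0 - modal / total


def replicate_detects(column: PileupColumn, config: FilterConfig) -> bool:
    """Does one replicate's column independently support a misincorporation?"""
    depth = column.depth
    if depth < config.per_replicate_min_depth:
        return False
    return misincorporation_rate(column) >= config.per_replicate_min_rate


def call_candidate_sites(
    pileups: list[ReplicatePileup],
    mask: VariantMask | None,
    reference=None,
    config: FilterConfig | None = None,
) -> list[CandidateSite]:
    """Run the full filter chain over every covered, unmasked position.

    Counts are summed across replicates; per-replicate detection uses each
    replicate's own column. Reference-N positions are skipped. Output is
    sorted by (seq_id, position).
    """
    if not pileups:
        raise ValueError("at least one replicate pileup required")
    config = config or FilterConfig()
    mask = mask or VariantMask()
    n_rep = len(pileups)
    combined, refs = combine_counts(pileups)

    sites: list[CandidateSite] = []
    for seq_id in sorted(combined):
        counts = combined[seq_id]
        ref_codes = refs[seq_id].codes()
        L = len(ref_codes)
        depth = counts.sum(axis=1)
        safe_codes = np.minimum(ref_codes, 3).astype(np.int64)
        ref_count = counts[np.arange(L), safe_codes]
        mism = depth - ref_count
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(depth > 0, mism / np.maximum(depth, 1), 0.0)

        ok = (
            (ref_codes < 4)
            & (depth >= config.min_combined_depth)
            & (rate >= config.min_rate)
        )
        masked = mask.positions_on(seq_id)
        if masked.size:
            masked = masked[masked < L]
            ok[masked] = False
        if not ok.any():
            continue

        detected = np.zeros(L, dtype=np.int64)
        for pu in pileups:
            arr = pu.counts_array(seq_id)
            d = arr.sum(axis=1)
            rc = arr[np.arange(L), safe_codes]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(d > 0, (d - rc) / np.maximum(d, 1), 0.0)
            detected += (d >= config.per_replicate_min_depth) & (
                r >= config.per_replicate_min_rate
            )
        ok &= detected / n_rep >= config.min_replicate_fraction

        for pos in np.nonzero(ok)[0]:
            pos = int(pos)
            site = CandidateSite(
                seq_id=seq_id,
                position=pos,
                ref_base=BASES[ref_codes[pos]],
                combined_counts={b: int(counts[pos, i]) for i, b in enumerate(BASES)},
                replicates_detected=int(detected[pos]),
                n_replicates=n_rep,
            )
            site.high_confidence = site.heterogeneity >= config.min_heterogeneity
            sites.append(site)
    return sites


def estimate_readthrough(
    pileup: ReplicatePileup | list[ReplicatePileup],
    seq_id: str,
    position: int,
    flank_window: int = 20,
    strand: str = "+",
) -> ReadthroughEstimate:
    """Read-through rate at a hard-stop site from the coverage drop.

    Truncated cDNAs never cover the modified position but do cover the
    3' flank (they terminate with their 5' end just downstream), so
    depth(site) / median depth over the ``flank_window`` positions
    immediately 3' of the site estimates the fraction of reverse
    transcription events that traversed the stop. Clipped to [0, 1].
    """
    pileups = pileup if isinstance(pileup, list) else [pileup]
    combined, refs = combine_counts(pileups)
    if seq_id not in combined:
        raise KeyError(f"no coverage on {seq_id!r}")
    depth = combined[seq_id].sum(axis=1)
    L = len(depth)
    if strand == "+":
        flank = depth[position + 1 : min(L, position + 1 + flank_window)]
    else:
        flank = depth[max(0, position - flank_window) : position]
    if flank.size == 0 or np.median(flank) <= 0:
        raise ValueError(f"zero flank coverage 3' of {seq_id}:{position}")
    flank_depth = float(np.median(flank))
    rate = float(np.clip(depth[position] / flank_depth, 0.0, 1.0))
    return ReadthroughEstimate(
        seq_id=seq_id,
        position=position,
        site_depth=int(depth[position]),
        flank_depth=flank_depth,
        readthrough_rate=rate,
    )
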