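"""Readers/writers for the formats the suite touches, and the shared domain types.

Internal coordinates are 0-based, half-open everywhere. SAM and VCF inputs are
converted on read; tabular outputs print 1-based positions. Strand-aware
handling follows stranded library protocols: a read's bases are stored in
forward reference orientation (as in SAM), and strand is carried alongside for
5'-end and duplicate-collapse logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# byte -> base code; A,C,G,T -> 0..3, N -> 4, everything else -> 255
_BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _BASE_CODES[ord(_b)] = _i
    _BASE_CODES[ord(_b.lower())] = _i
_BASE_CODES[ord("N")] = 4
_BASE_CODES[ord("n")] = 4


def encode_bases(seq: str) -> np.ndarray:
    """Encode a base string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    codes = _BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"invalid base {bad!r} in sequence")
    return codes


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference contig: uppercase DNA over {A,C,G,T,N}."""

    seq_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.seq_id!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())
        encode_bases(self.sequence)  # validates alphabet

    def __len__(self) -> int:
        return len(self.sequence)

    def codes(self) -> np.ndarray:
        return encode_bases(self.sequence)


@dataclass(slots=True)
class AlignedRead:
    """One uniquely-mapped (and possibly UMI-tagged) read.

    ``offsets`` are reference offsets relative to ``start`` (strictly
    increasing); ``bases`` is the matching read base per offset, stored in
    forward reference orientation as in SAM.
    """

    read_id: str
    seq_id: str
    start: int
    strand: str
    offsets: np.ndarray
    bases: str
    umi: str | None = None
    replicate_id: str = ""

    def __post_init__(self):
        o = self.offsets
        if not isinstance(o, np.ndarray) or o.dtype != np.int64:
            o = np.asarray(o, dtype=np.int64)
            self.offsets = o
        if len(o) != len(self.bases):
            raise ValueError("offsets and bases length mismatch")
        if self.start < 0:
            raise ValueError("negative start")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        # contiguous offsets (the common case) are trivially increasing
        if len(o) > 1 and int(o[-1]) - int(o[0]) != len(o) - 1:
            if not (np.diff(o) > 0).all():
                raise ValueError("aligned offsets must be strictly increasing")

    @property
    def aligned_bases(self) -> list[tuple[int, str]]:
        return list(zip(self.offsets.tolist(), self.bases))

    @property
    def n_aligned(self) -> int:
        return len(self.bases)

    @property
    def end(self) -> int:
        """One past the rightmost aligned reference position."""
        if len(self.offsets) == 0:
            return self.start
        return self.start + int(self.offsets[-1]) + 1

    def five_prime_end(self) -> int:
        """Reference position of the read 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    def positions(self) -> np.ndarray:
        return self.start + self.offsets


@dataclass
class VariantMask:
    """Set of (seq_id, 0-based position) excluded from analysis (SNPs/variants)."""

    positions: set[tuple[str, int]] = field(default_factory=set)

    def __contains__(self, item) -> bool:
        return item in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    def union(self, other: "VariantMask") -> "VariantMask":
        return VariantMask(self.positions | other.positions)

    def positions_on(self, seq_id: str) -> np.ndarray:
        pos = [p for s, p in self.positions if s == seq_id]
        return np.array(sorted(pos), dtype=np.int64)


@dataclass
class TranscriptAnnotation:
    """One transcript with TSS, CDS and UTR boundaries (0-based, half-open)."""

    transcript_id: str
    seq_id: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    start_nucleotide: str = "N"
    tss_categories: frozenset = frozenset()

    def __post_init__(self):
        if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
            raise ValueError(
                f"{self.transcript_id}: require tx_start <= cds_start < cds_end <= tx_end"
            )
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        self.tss_categories = frozenset(self.tss_categories)

    @property
    def tss(self) -> int:
        """First transcribed position: tx_start on +, tx_end - 1 on -."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    def utr5(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.tx_start, self.cds_start
        return self.cds_end, self.tx_end

    def utr3(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.cds_end, self.tx_end
        return self.tx_start, self.cds_start


# ---------------------------------------------------------------------------
# FASTA


def read_reference(path) -> list[ReferenceSequence]:
    """Read a FASTA file into uppercase reference sequences (N allowed)."""
    with open(path) as handle:
        first = handle.read(1)
        if not first:
            raise ValueError(f"{path}: empty FASTA file")
        if first != ">":
            raise ValueError(f"{path}: malformed FASTA, line 1 does not start with '>'")
    records = [
        ReferenceSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_reference(seqs: list[ReferenceSequence], path, width: int = 70) -> None:
    with open(path, "w") as out:
        for ref in seqs:
            out.write(f">{ref.seq_id}\n")
            for i in range(0, len(ref.sequence), width):
                out.write(ref.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM


def read_alignments(path, replicate_id: str, umi_delimiter: str = "_") -> list[AlignedRead]:
    """Read a SAM file into AlignedRead records.

    Unmapped, secondary and supplementary records are skipped. Per-base
    reference offsets come from the CIGAR (M/=/X consume both, I consumes the
    read, D/N the reference, S the read only). A UMI is taken from the read
    name suffix after the last ``umi_delimiter`` when present.
    """
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigartuples is None:
                raise ValueError(f"{rec.query_name}: mapped read without CIGAR")
            seq = rec.query_sequence or ""
            offsets, bases = _cigar_walk(rec.cigartuples, seq, rec.query_name)
            name = rec.query_name
            umi = None
            if umi_delimiter and umi_delimiter in name:
                name, umi = name.rsplit(umi_delimiter, 1)
            reads.append(
                AlignedRead(
                    read_id=name,
                    seq_id=rec.reference_name,
                    start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    offsets=np.array(offsets, dtype=np.int64),
                    bases="".join(bases),
                    umi=umi,
                    replicate_id=replicate_id,
                )
            )
    return reads


_CONSUME_BOTH = {0, 7, 8}  # M, =, X
_CONSUME_READ = {1, 4}  # I, S
_CONSUME_REF = {2, 3}  # D, N


def _cigar_walk(cigartuples, seq: str, name: str):
    offsets, bases = [], []
    qpos = rpos = 0
    for op, length in cigartuples:
        if op in _CONSUME_BOTH:
            for k in range(length):
                offsets.append(rpos + k)
                bases.append(seq[qpos + k])
            qpos += length
            rpos += length
        elif op in _CONSUME_READ:
            qpos += length
        elif op in _CONSUME_REF:
            rpos += length
        elif op in (5, 6):  # H, P consume neither
            continue
        else:
            raise ValueError(f"{name}: unsupported CIGAR op {op}")
    return offsets, bases


def write_alignments(
    reads: list[AlignedRead],
    references: list[ReferenceSequence],
    path,
    umi_delimiter: str = "_",
) -> None:
    """Write reads as plain-text SAM (CIGAR rebuilt from aligned offsets)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r.seq_id, "LN": len(r)} for r in references],
    }
    tid = {r.seq_id: i for i, r in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            rec = pysam.AlignedSegment(out.header)
            name = read.read_id
            if read.umi is not None:
                name = f"{name}{umi_delimiter}{read.umi}"
            rec.query_name = name
            rec.flag = 16 if read.strand == "-" else 0
            rec.reference_id = tid[read.seq_id]
            rec.reference_start = read.start
            rec.mapping_quality = 255
            rec.cigarstring = _offsets_to_cigar(read.offsets)
            rec.query_sequence = read.bases
            out.write(rec)


def _offsets_to_cigar(offsets: np.ndarray) -> str:
    if len(offsets) == 0:
        return "*"
    parts = []
    run_start = 0
    for i in range(1, len(offsets)):
        gap = int(offsets[i] - offsets[i - 1])
        if gap > 1:
            parts.append(f"{i - run_start}M{gap - 1}D")
            run_start = i
    parts.append(f"{len(offsets) - run_start}M")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Variant masks (VCF + BED)


def read_variant_mask(paths) -> VariantMask:
    """Union of masked positions from VCF (1-based) and/or BED (0-based) files.

    Multi-nucleotide VCF REF alleles expand to every covered position. File
    type is chosen by extension (.bed -> BED, otherwise VCF).
    """
    positions: set[tuple[str, int]] = set()
    for path in paths:
        if str(path).lower().endswith(".bed"):
            positions |= _read_bed_positions(path)
        else:
            positions |= _read_vcf_positions(path)
    return VariantMask(positions)


def _read_vcf_positions(path) -> set[tuple[str, int]]:
    positions = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for p in range(rec.start, rec.start + len(rec.ref or "N")):
                positions.add((rec.chrom, p))
    return positions


def _read_bed_positions(path) -> set[tuple[str, int]]:
    positions = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with < 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            positions.update((chrom, p) for p in range(start, end))
    return positions


def read_bed_position_set(path) -> set[tuple[str, int]]:
    """Read a BED file as a set of single positions (every covered base)."""
    return _read_bed_positions(path)


def write_bed_positions(positions, path, name: str = ".") -> None:
    with open(path, "w") as out:
        for seq_id, pos in sorted(positions):
            out.write(f"{seq_id}\t{pos}\t{pos + 1}\t{name}\t0\t+\n")


# ---------------------------------------------------------------------------
# Candidate-site tables

SITE_COLUMNS = [
    "seq_id",
    "position",  # 1-based in the file
    "ref_base",
    "combined_depth",
    "combined_rate",
    "replicates_detected",
    "n_replicates",
    "heterogeneity",
    "high_confidence",
    "count_A",
    "count_C",
    "count_G",
    "count_T",
]


def write_sites(sites, path, bed_path=None) -> None:
    """Write candidate sites as a TSV (1-based positions); optional BED6.

    The BED score is round(1000 * combined misincorporation rate).
    """
    rows = []
    for s in sites:
        rows.append(
            {
                "seq_id": s.seq_id,
                "position": s.position + 1,
                "ref_base": s.ref_base,
                "combined_depth": s.combined_depth,
                "combined_rate": s.combined_rate,
                "replicates_detected": s.replicates_detected,
                "n_replicates": s.n_replicates,
                "heterogeneity": s.heterogeneity,
                "high_confidence": s.high_confidence,
                **{f"count_{b}": s.combined_counts[b] for b in BASES},
            }
        )
    frame = pd.DataFrame(rows, columns=SITE_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as out:
            for s in sites:
                score = int(round(1000 * s.combined_rate))
                out.write(
                    f"{s.seq_id}\t{s.position}\t{s.position + 1}\t"
                    f"site_{s.seq_id}_{s.position + 1}\t{score}\t+\n"
                )


def read_sites(path):
    """Read a candidate-site TSV back (positions converted to 0-based)."""
    from .misinc import CandidateSite  # local import to avoid a cycle

    frame = pd.read_csv(path, sep="\t")
    sites = []
    for row in frame.itertuples(index=False):
        sites.append(
            CandidateSite(
                seq_id=row.seq_id,
                position=int(row.position) - 1,
                ref_base=row.ref_base,
                combined_counts={b: int(getattr(row, f"count_{b}")) for b in BASES},
                replicates_detected=int(row.replicates_detected),
                n_replicates=int(row.n_replicates),
                high_confidence=bool(row.high_confidence),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Transcript annotations (BED-like TSV)

ANNOTATION_COLUMNS = [
    "transcript_id",
    "seq_id",
    "strand",
    "tx_start",
    "tx_end",
    "cds_start",
    "cds_end",
    "start_nucleotide",
    "tss_categories",
]


def write_annotations(annotations, path) -> None:
    rows = [
        {
            "transcript_id": a.transcript_id,
            "seq_id": a.seq_id,
            "strand": a.strand,
            "tx_start": a.tx_start,
            "tx_end": a.tx_end,
            "cds_start": a.cds_start,
            "cds_end": a.cds_end,
            "start_nucleotide": a.start_nucleotide,
            "tss_categories": ",".join(sorted(a.tss_categories)),
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list[TranscriptAnnotation]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in frame.itertuples(index=False):
        cats = frozenset(c for c in str(row.tss_categories).split(",") if c)
        out.append(
            TranscriptAnnotation(
                transcript_id=row.transcript_id,
                seq_id=row.seq_id,
                strand=row.strand,
                tx_start=int(row.tx_start),
                tx_end=int(row.tx_end),
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                start_nucleotide=row.start_nucleotide,
                tss_categories=cats,
            )
        )
    return out
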