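"""Curation of external-style m1A site lists and their TSS-overlap accounting.

A published site list typically needs cleanup before comparison against
transcription-start catalogs: entries with retired or missing gene
identifiers, entries whose genomic coordinate is not an adenosine, and
duplicate coordinates arising from transcript isoforms of the same gene. The
curated survivors are then intersected with annotated and experimentally
inferred (CAGE / m6Am-cap) TSS sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SiteRecord:
    site_id: str
    gene_id: str | None
    seq_id: str
    genomic_position: int  # 0-based
    nucleotide: str
    transcript_id: str = ""

    def __post_init__(self):
        if self.genomic_position < 0:
            raise ValueError("negative genomic position")
        object.__setattr__(self, "nucleotide", self.nucleotide.upper())


@dataclass
class CurationReport:
    n_input: int
    n_missing_gene: int
    n_non_adenosine: int
    n_duplicate: int
    kept: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return self.n_missing_gene + self.n_non_adenosine + self.n_duplicate

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed


@dataclass
class TssOverlapReport:
    n_sites: int
    n_annotated_tss: int
    n_cage_m6am: int
    n_union: int

    @property
    def n_internal(self) -> int:
        return self.n_sites - self.n_union


def curate(records: list[SiteRecord], valid_gene_ids: set[str]) -> CurationReport:
    """Filter a site list: invalid gene -> non-adenosine -> coordinate duplicate.

    Filters apply in that order, so each record is tallied against the first
    filter it fails. Among survivors of the first two filters, only the first
    record per (seq_id, genomic_position) is kept.
    """
    n_missing_gene = n_non_a = n_dup = 0
    seen: set[tuple[str, int]] = set()
    kept: list[SiteRecord] = []
    for rec in records:
        if not rec.gene_id or rec.gene_id not in valid_gene_ids:
            n_missing_gene += 1
            continue
        if rec.nucleotide != "A":
            n_non_a += 1
            continue
        coord = (rec.seq_id, rec.genomic_position)
        if coord in seen:
            n_dup += 1
            continue
        seen.add(coord)
        kept.append(rec)
    return CurationReport(
        n_input=len(records),
        n_missing_gene=n_missing_gene,
        n_non_adenosine=n_non_a,
        n_duplicate=n_dup,
        kept=kept,
    )


def tss_overlap(
    kept: list[SiteRecord],
    annotated_tss: set[tuple[str, int]],
    cage_m6am_tss: set[tuple[str, int]],
    tolerance: int = 0,
) -> TssOverlapReport:
    """Count curated sites at annotated and/or CAGE/m6Am-inferred TSSs.

    A site matches a TSS set when some set member on the same sequence lies
    within ``tolerance`` nucleotides; the union counts sites matching either
    set (each site once).
    """

    def matches(rec: SiteRecord, tss_set) -> bool:
        if tolerance == 0:
            return (rec.seq_id, rec.genomic_position) in tss_set
        return any(
            s == rec.seq_id and abs(p - rec.genomic_position) <= tolerance
            for s, p in tss_set
        )

    n_annot = n_cage = n_union = 0
    for rec in kept:
        in_annot = matches(rec, annotated_tss)
        in_cage = matches(rec, cage_m6am_tss)
        n_annot += in_annot
        n_cage += in_cage
        n_union += in_annot or in_cage
    return TssOverlapReport(
        n_sites=len(kept),
        n_annotated_tss=n_annot,
        n_cage_m6am=n_cage,
        n_union=n_union,
    )


# ---------------------------------------------------------------------------
# Canonical fixture: a synthetic site list with a known defect structure.

FIXTURE_SEQ = "chrF"
FIXTURE_N_KEPT = 352
FIXTURE_N_INVALID_GENE = 3
FIXTURE_N_NON_A = 37
FIXTURE_N_DUPLICATE = 82
FIXTURE_N_ANNOTATED = 19
FIXTURE_N_CAGE = 134
FIXTURE_N_BOTH = 13


def make_curation_fixture(seed: int = 0):
    """Synthetic 474-record site list with a fixed defect composition.

    Returns (records, valid_gene_ids, annotated_tss, cage_m6am_tss). The list
    carries 352 clean unique adenosine sites plus three disjoint defect
    classes: 3 records with missing/unknown gene identifiers, 37 records at
    non-adenosine nucleotides, and 82 records duplicating a clean site's
    genomic coordinate. Of the clean sites, 19 sit at annotated TSSs and 134
    at CAGE/m6Am-inferred TSSs, 13 of them in both sets (union 140).
    Deterministic for a given seed (only the shuffle order varies).
    """
    rng = np.random.default_rng(seed)
    clean = [
        SiteRecord(
            site_id=f"S{i:04d}",
            gene_id=f"GENE{i:04d}",
            seq_id=FIXTURE_SEQ,
            genomic_position=1000 + 10 * i,
            nucleotide="A",
            transcript_id=f"NM_{i:06d}",
        )
        for i in range(FIXTURE_N_KEPT)
    ]
    valid_gene_ids = {rec.gene_id for rec in clean}

    # annotated TSS = clean sites 0..18; CAGE/m6Am = clean sites 6..139
    annotated_tss = {
        (r.seq_id, r.genomic_position) for r in clean[:FIXTURE_N_ANNOTATED]
    }
    cage_start = FIXTURE_N_ANNOTATED - FIXTURE_N_BOTH
    cage_m6am_tss = {
        (r.seq_id, r.genomic_position)
        for r in clean[cage_start : cage_start + FIXTURE_N_CAGE]
    }

    records = list(clean)
    for i in range(FIXTURE_N_INVALID_GENE):
        records.append(
            SiteRecord(
                site_id=f"BADGENE{i}",
                gene_id=None if i == 0 else f"RETIRED{i}",
                seq_id=FIXTURE_SEQ,
                genomic_position=100 + 10 * i,  # off the clean coordinate grid
                nucleotide="A",
            )
        )
    for i in range(FIXTURE_N_NON_A):
        records.append(
            SiteRecord(
                site_id=f"NONA{i:03d}",
                gene_id=f"GENE{i:04d}",
                seq_id=FIXTURE_SEQ,
                genomic_position=200000 + 10 * i,
                nucleotide="CGT"[i % 3],
            )
        )
    dup_of = rng.choice(FIXTURE_N_KEPT, size=FIXTURE_N_DUPLICATE, replace=True)
    for i, j in enumerate(dup_of):
        src = clean[int(j)]
        records.append(
            SiteRecord(
                site_id=f"DUP{i:03d}",
                gene_id=src.gene_id,
                seq_id=src.seq_id,
                genomic_position=src.genomic_position,
                nucleotide="A",
                transcript_id=f"NM_ALT{i:04d}",
            )
        )
    # shuffle defect records among themselves but keep each duplicate after
    # its clean original so "first per coordinate" keeps the clean record
    tail = records[FIXTURE_N_KEPT:]
    rng.shuffle(tail)
    records = records[:FIXTURE_N_KEPT] + tail
    return records, valid_gene_ids, annotated_tss, cage_m6am_tss


# ---------------------------------------------------------------------------
# Site-list TSV / gene-list IO

SITE_RECORD_COLUMNS = [
    "site_id",
    "gene_id",
    "seq_id",
    "position",  # 1-based in the file
    "nucleotide",
    "transcript_id",
]


def write_site_records(records: list[SiteRecord], path) -> None:
    rows = [
        {
            "site_id": r.site_id,
            "gene_id": r.gene_id or "",
            "seq_id": r.seq_id,
            "position": r.genomic_position + 1,
            "nucleotide": r.nucleotide,
            "transcript_id": r.transcript_id,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SITE_RECORD_COLUMNS).to_csv(path, sep="\t", index=False)


def read_site_records(path) -> list[SiteRecord]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    return [
        SiteRecord(
            site_id=row.site_id,
            gene_id=row.gene_id or None,
            seq_id=row.seq_id,
            genomic_position=int(row.position) - 1,
            nucleotide=row.nucleotide,
            transcript_id=row.transcript_id,
        )
        for row in frame.itertuples(index=False)
    ]


def write_gene_list(gene_ids, path) -> None:
    with open(path, "w") as out:
        for gid in sorted(gene_ids):
            out.write(gid + "\n")


def read_gene_list(path) -> set[str]:
    with open(path) as handle:
        return {line.strip() for line in handle if line.strip()}
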