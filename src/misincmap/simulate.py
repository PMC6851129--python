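"""Seeded read simulator with planted hard-stop modifications.

Emulates the generative process behind misincorporation mapping and miCLIP:
transcripts are fragmented (the 5'-terminal fragment always starts at the
TSS), fragments are reverse transcribed 3'->5', and at a modified template
position the reverse transcriptase either terminates (the cDNA — and hence
the read 5' end — begins at the position immediately 3' of the modification)
or reads through, usually leaving a misincorporation drawn from an A→T-major
spectrum. Uniform sequencing error, PCR duplication with UMIs, heterozygous
and homozygous SNPs, and homogeneous A→G editing decoys complete the picture.
In miCLIP mode, antibody crosslinks at the cap cause terminations at small
positive offsets from the TSS instead.

Truncated cDNAs are retained as reads: both protocols clone them, and they
are what makes termination analysis possible (and what depletes coverage 5'
of a hard stop).

All randomness flows from integer-seeded numpy Generators, so a fixed seed
reproduces every read bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    AlignedRead,
    ReferenceSequence,
    TranscriptAnnotation,
)

BASES = "ACGT"


@dataclass(frozen=True)
class PlantedSite:
    """A hard-stop modification planted on an adenosine."""

    seq_id: str
    position: int
    stoichiometry: float  # fraction of molecules modified at this position
    readthrough: float  # P(RT traverses | modified)
    misinc_given_readthrough: float
    spectrum: tuple = (("T", 0.8), ("G", 0.1), ("C", 0.1))


@dataclass(frozen=True)
class SnpSite:
    seq_id: str
    position: int
    ref: str
    alt: str
    genotype: str  # 'het' or 'hom'


@dataclass(frozen=True)
class EditingSite:
    """Homogeneous single-class A→G editing decoy."""

    seq_id: str
    position: int
    rate: float


@dataclass(frozen=True)
class CrosslinkSite:
    seq_id: str
    position: int


@dataclass
class SimulationTruth:
    sites: list = field(default_factory=list)
    snps: list = field(default_factory=list)
    editing: list = field(default_factory=list)
    crosslinks: list = field(default_factory=list)

    def special_positions(self, seq_id: str) -> set[int]:
        out = set()
        for group in (self.sites, self.snps, self.editing):
            out |= {x.position for x in group if x.seq_id == seq_id}
        return out


@dataclass
class SimulationConfig:
    """Generative parameters; the defaults mirror the conditions the method
    was designed for: 20 replicates of 50 nt reads from ~250 nt inserts,
    ~20% average stoichiometry, 20–30% read-through with mostly A→T
    misincorporations, and low uniform sequencing error."""

    n_transcripts: int = 1
    transcript_length: int = 800
    n_replicates: int = 20
    reads_per_replicate: int = 7200  # molecules per replicate before PCR
    read_length: int = 50
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 30.0
    n_planted_sites: int = 5
    stoichiometry: float | tuple = (0.1, 0.5)
    readthrough: float = 0.25
    misinc_given_readthrough: float = 0.9
    spectrum: tuple = (("T", 0.8), ("G", 0.1), ("C", 0.1))
    sequencing_error: float = 0.001
    pcr_duplication_rate: float = 0.2
    n_het_snps: int = 2
    n_hom_snps: int = 2
    n_editing_sites: int = 2
    editing_rate: float = 0.2
    a_start_fraction: float = 0.85
    crosslink_offset_weights: tuple = ((0, 0.35), (1, 0.40), (2, 0.08), (3, 0.05))
    miclip_background: float = 0.05
    # crosslink only adenosine-start caps (cap-cross-reactive antibody model)
    crosslink_a_start_only: bool = False
    dimroth_loss: float = 0.0  # stoichiometry lost to m1A->m6A conversion
    min_read_length: int = 20
    umi_length: int = 10
    site_margin: int = 40
    min_separation: int = 50  # > read span, so no read covers two special sites
    abundance: tuple | None = None  # per-transcript weights; uniform if None
    seed: int = 0

    def __post_init__(self):
        probs = [
            self.readthrough,
            self.misinc_given_readthrough,
            self.sequencing_error,
            self.pcr_duplication_rate,
            self.editing_rate,
            self.a_start_fraction,
            self.miclip_background,
            self.dimroth_loss,
        ]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if abs(sum(w for _, w in self.spectrum) - 1.0) > 1e-9:
            raise ValueError("spectrum weights must sum to 1")
        if self.transcript_length < 300:
            raise ValueError("transcript_length must be >= 300")
        if self.transcript_length < self.fragment_length_mean:
            raise ValueError("transcript_length below the fragment length floor")


def expected_mismatch_rate(s: float, r: float, m: float) -> float:
    """Closed-form mismatch fraction among reads covering a planted site.

    Truncated cDNAs never cover the site, so the covering reads split into
    unmodified templates (weight 1 - s) and read-through events (weight
    s * r), of which a fraction m carry a misincorporation:

        rate = s * r * m / (s * r + (1 - s))
    """
    for p in (s, r, m):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    denom = s * r + (1.0 - s)
    if denom <= 0.0:
        raise ValueError("degenerate denominator: no reads ever cover the site")
    return s * r * m / denom


# ---------------------------------------------------------------------------


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[ReferenceSequence], list[TranscriptAnnotation], SimulationTruth]:
    """Generate transcripts (one contig each, + strand), annotations and truth.

    Planted modifications, SNPs and editing decoys are forced onto adenosines
    at mutually separated interior positions so no read can span two special
    positions. Each TSS carries a crosslink site (used only in miCLIP mode).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    refs, annotations = [], []
    truth = SimulationTruth()

    L = config.transcript_length
    sites_per_tx = _round_robin(config.n_planted_sites, config.n_transcripts)
    het_per_tx = _round_robin(config.n_het_snps, config.n_transcripts)
    hom_per_tx = _round_robin(config.n_hom_snps, config.n_transcripts)
    edit_per_tx = _round_robin(config.n_editing_sites, config.n_transcripts)

    for i in range(config.n_transcripts):
        seq_id = f"tx{i:04d}"
        codes = rng.integers(0, 4, size=L)
        seq = list("".join(BASES[c] for c in codes))
        if rng.random() < config.a_start_fraction:
            seq[0] = "A"
        elif seq[0] == "A":
            seq[0] = "CGT"[rng.integers(0, 3)]

        n_special = sites_per_tx[i] + het_per_tx[i] + hom_per_tx[i] + edit_per_tx[i]
        positions = _pick_separated_positions(
            rng, L, n_special, config.site_margin, config.min_separation
        )
        for p in positions:
            seq[p] = "A"
        cursor = 0
        for _ in range(sites_per_tx[i]):
            s = (
                float(rng.uniform(*config.stoichiometry))
                if isinstance(config.stoichiometry, tuple)
                else float(config.stoichiometry)
            )
            truth.sites.append(
                PlantedSite(
                    seq_id=seq_id,
                    position=positions[cursor],
                    stoichiometry=s,
                    readthrough=config.readthrough,
                    misinc_given_readthrough=config.misinc_given_readthrough,
                    spectrum=config.spectrum,
                )
            )
            cursor += 1
        for genotype, count in (("het", het_per_tx[i]), ("hom", hom_per_tx[i])):
            for _ in range(count):
                truth.snps.append(
                    SnpSite(seq_id, positions[cursor], "A", "G", genotype)
                )
                cursor += 1
        for _ in range(edit_per_tx[i]):
            truth.editing.append(
                EditingSite(seq_id, positions[cursor], config.editing_rate)
            )
            cursor += 1
        if not config.crosslink_a_start_only or seq[0] == "A":
            truth.crosslinks.append(CrosslinkSite(seq_id, 0))

        sequence = "".join(seq)
        refs.append(ReferenceSequence(seq_id, sequence))
        cds_start = max(1, int(round(0.3 * L)))
        cds_end = min(L - 1, int(round(0.8 * L)))
        annotations.append(
            TranscriptAnnotation(
                transcript_id=f"T{i:04d}",
                seq_id=seq_id,
                strand="+",
                tx_start=0,
                tx_end=L,
                cds_start=cds_start,
                cds_end=cds_end,
                start_nucleotide=sequence[0],
                tss_categories=frozenset({"refseq"}),
            )
        )
    return refs, annotations, truth


def _round_robin(total: int, n_bins: int) -> list[int]:
    if n_bins == 0:
        return []
    base, extra = divmod(total, n_bins)
    return [base + (1 if i < extra else 0) for i in range(n_bins)]


def _pick_separated_positions(rng, L, n, margin, min_sep) -> list[int]:
    """Random interior positions with pairwise separation >= min_sep
    (stars-and-bars: sorted draws plus fixed spacing, then shuffled)."""
    lo, hi = margin, L - margin
    if n == 0:
        return []
    slack = (hi - lo - 1) - (n - 1) * min_sep
    if slack < 0:
        raise ValueError(
            f"cannot place {n} positions with separation {min_sep} in [{lo}, {hi})"
        )
    draws = np.sort(rng.integers(0, slack + 1, size=n))
    pos = lo + draws + np.arange(n) * min_sep
    return [int(p) for p in rng.permutation(pos)]


# ---------------------------------------------------------------------------


def simulate_reads(
    references: list[ReferenceSequence],
    truth: SimulationTruth,
    mode: str,
    replicate_id: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[AlignedRead]:
    """Simulate one replicate's reads in ``rnaseq`` or ``miclip`` mode."""
    if mode not in ("rnaseq", "miclip"):
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        tag = zlib.crc32(f"{mode}:{replicate_id}".encode()) % (2**31)
        rng = np.random.default_rng([config.seed, tag])

    n_tx = len(references)
    weights = (
        np.asarray(config.abundance, dtype=float)
        if config.abundance is not None
        else np.ones(n_tx)
    )
    weights = weights / weights.sum()
    per_tx = rng.multinomial(config.reads_per_replicate, weights)

    reads: list[AlignedRead] = []
    serial = 0
    shared_offsets = np.arange(config.read_length + 1)
    for ref, n_mol in zip(references, per_tx):
        if n_mol == 0:
            continue
        serial = _simulate_transcript(
            ref, truth, mode, replicate_id, config, rng, int(n_mol), reads, serial,
            shared_offsets,
        )
    return reads


def _simulate_transcript(
    ref, truth, mode, replicate_id, config, rng, n, reads, serial, shared_offsets
):
    L = len(ref)
    seq = ref.sequence
    read_len = config.read_length

    # --- fragmentation ------------------------------------------------
    crosslinks = sorted(
        (c.position for c in truth.crosslinks if c.seq_id == ref.seq_id), reverse=True
    )
    if mode == "miclip" and not crosslinks:
        # immunoprecipitation washes away uncrosslinked transcripts; only a
        # small nonspecific background survives
        n = int(round(n * config.miclip_background))
        if n == 0:
            return serial
    if mode == "miclip" and crosslinks:
        # immunoprecipitation keeps crosslink-containing fragments (the
        # 5'-terminal one for a cap crosslink) plus a small background
        is_ip = rng.random(n) >= config.miclip_background
        start = np.zeros(n, dtype=np.int64)  # IP'd cap fragments start at the TSS
        bg = ~is_ip
        start[bg] = _random_starts(rng, int(bg.sum()), L, read_len, config)
    else:
        is_ip = np.zeros(n, dtype=bool)
        start = _random_starts(rng, n, L, read_len, config)

    frag_len = np.rint(
        rng.normal(config.fragment_length_mean, config.fragment_length_sd, size=n)
    ).astype(np.int64)
    frag_len = np.clip(frag_len, read_len, None)
    frag_end = np.minimum(start + frag_len, L)

    # --- reverse transcription: hard stops ----------------------------
    stop = start.copy()
    overrides: dict[int, list[tuple[int, str]]] = {}

    tx_sites = sorted(
        (s for s in truth.sites if s.seq_id == ref.seq_id),
        key=lambda s: -s.position,
    )
    for site in tx_sites:
        p = site.position
        s_eff = site.stoichiometry * (1.0 - config.dimroth_loss)
        reached = (frag_end > p) & (stop <= p)
        modified = reached & (rng.random(n) < s_eff)
        terminate = modified & (rng.random(n) >= site.readthrough)
        stop[terminate] = p + 1
        misinc = (
            modified
            & ~terminate
            & (rng.random(n) < site.misinc_given_readthrough)
        )
        idx = np.nonzero(misinc)[0]
        if idx.size:
            alts = [b for b, _ in site.spectrum]
            w = np.array([w for _, w in site.spectrum])
            picks = rng.choice(len(alts), size=idx.size, p=w / w.sum())
            for i, k in zip(idx, picks):
                overrides.setdefault(int(i), []).append((p, alts[int(k)]))

    if mode == "miclip" and crosslinks:
        # residual probability mass (1 - sum of weights) is read-through
        offs = np.array([o for o, _ in config.crosslink_offset_weights])
        w = np.array([w for _, w in config.crosslink_offset_weights])
        for c in crosslinks:
            hit = is_ip & (start <= c) & (frag_end > c) & (stop <= c)
            idx = np.nonzero(hit)[0]
            if idx.size == 0:
                continue
            draw = rng.random(idx.size)
            cum = np.cumsum(w)
            cat = np.searchsorted(cum, draw)  # == len(w) means read-through
            stopped = cat < len(w)
            stop[idx[stopped]] = c + offs[cat[stopped]]

    # --- genomic decoys ------------------------------------------------
    for snp in truth.snps:
        if snp.seq_id != ref.seq_id:
            continue
        p_alt = 0.5 if snp.genotype == "het" else 1.0
        carrier = rng.random(n) < p_alt
        for i in np.nonzero(carrier)[0]:
            overrides.setdefault(int(i), []).append((snp.position, snp.alt))
    for ed in truth.editing:
        if ed.seq_id != ref.seq_id:
            continue
        edited = rng.random(n) < ed.rate
        for i in np.nonzero(edited)[0]:
            overrides.setdefault(int(i), []).append((ed.position, "G"))

    # --- emit reads (with PCR duplicates and per-copy sequencing error)
    stop = np.maximum(stop, start)
    read_end = np.minimum(stop + read_len, frag_end)
    length = read_end - stop
    keep_idx = np.nonzero(length >= config.min_read_length)[0]
    n_copies = 1 + (
        rng.geometric(1.0 - config.pcr_duplication_rate, size=keep_idx.size) - 1
    )
    umis = _random_umis(rng, n, config.umi_length)
    # independent sequencing errors for every emitted PCR copy
    copy_lens = np.repeat(length[keep_idx], n_copies)
    err_counts = (
        rng.binomial(copy_lens, config.sequencing_error)
        if config.sequencing_error > 0
        else np.zeros(copy_lens.size, dtype=np.int64)
    )

    copy_no = 0
    for j, i in enumerate(keep_idx):
        i = int(i)
        lo, hi = int(stop[i]), int(read_end[i])
        template = seq[lo:hi]
        ovr = [(p - lo, b) for p, b in overrides.get(i, []) if lo <= p < hi]
        if ovr:
            chars = list(template)
            for off, b in ovr:
                chars[off] = b
            template = "".join(chars)
        for _copy in range(int(n_copies[j])):
            k = int(err_counts[copy_no])
            copy_no += 1
            bases = _apply_errors(rng, template, k) if k else template
            reads.append(
                AlignedRead(
                    read_id=f"{replicate_id}.{serial}",
                    seq_id=ref.seq_id,
                    start=lo,
                    strand="+",
                    offsets=shared_offsets[: hi - lo],
                    bases=bases,
                    umi=umis[i],
                    replicate_id=replicate_id,
                )
            )
            serial += 1
    return serial


def _random_starts(rng, n, L, read_len, config):
    """Fragment starts: the 5'-terminal fragment (start 0) appears with the
    probability a ~fragment-sized piece has of being first; other fragments
    start uniformly downstream."""
    p5 = min(1.0, config.fragment_length_mean / L)
    first = rng.random(n) < p5
    hi = max(2, L - read_len)
    start = rng.integers(1, hi, size=n)
    start[first] = 0
    return start


_UMI_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_umis(rng, n, k) -> list[str]:
    codes = rng.integers(0, 4, size=(n, k))
    flat = _UMI_ASCII[codes].tobytes().decode("ascii")
    return [flat[i * k : (i + 1) * k] for i in range(n)]


def _apply_errors(rng, template: str, k: int) -> str:
    """Misread ``k`` random positions, each to a uniformly chosen other base."""
    chars = list(template)
    pos = rng.choice(len(chars), size=min(k, len(chars)), replace=False)
    for p in pos:
        old = chars[int(p)]
        alts = [b for b in BASES if b != old]
        chars[int(p)] = alts[int(rng.integers(0, 3))]
    return "".join(chars)


# ---------------------------------------------------------------------------


def simulate_experiment(
    config: SimulationConfig, mode: str = "rnaseq"
) -> tuple[
    list[ReferenceSequence],
    list[TranscriptAnnotation],
    SimulationTruth,
    dict[str, list[AlignedRead]],
]:
    """Reference + annotations + truth + one read list per replicate."""
    refs, annotations, truth = simulate_reference(config)
    reads_by_rep = {}
    for r in range(config.n_replicates):
        rep_id = f"rep{r + 1:02d}"
        reads_by_rep[rep_id] = simulate_reads(
            refs, truth, mode, rep_id, config
        )
    return refs, annotations, truth, reads_by_rep
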