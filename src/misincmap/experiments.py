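"""Reproducible in-silico validation experiments.

Each function runs one self-contained simulate -> analyze experiment and
returns plain numbers: planted-site recovery under the default study
conditions, convergence of the observed mismatch rate to its closed form,
read-through estimation at a full-stoichiometry hard stop, the
RNA-seq/miCLIP termination-offset contrast at transcription-start sites,
and the A-start TSS enrichment test. The test suite and the acceptance
script both drive these.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import VariantMask
from .miclip import call_clusters, termination_profiles, tss_start_enrichment
from .misinc import FilterConfig, call_candidate_sites, estimate_readthrough
from .pileup import PileupConfig, build_pileup
from .simulate import SimulationConfig, expected_mismatch_rate, simulate_experiment


def recover_planted_sites(
    seed: int,
    config: SimulationConfig | None = None,
    filter_config: FilterConfig | None = None,
    pileup_config: PileupConfig | None = None,
) -> dict:
    """One full misincorporation-mapping round on a simulated genome.

    SNP truth positions form the variant mask (as genomic variants would).
    Returns recovery statistics: high-confidence detection of planted sites,
    false positives among error-only adenosines, mask and editing-decoy
    behaviour, and the minimum combined covering depth over planted sites.
    """
    config = config or SimulationConfig(seed=seed)
    if config.seed != seed:
        config = dataclasses.replace(config, seed=seed)
    filter_config = filter_config or FilterConfig()
    pileup_config = pileup_config or PileupConfig()

    refs, _, truth, reads_by_rep = simulate_experiment(config)
    pileups = [build_pileup(r, refs, pileup_config) for r in reads_by_rep.values()]
    mask = VariantMask({(s.seq_id, s.position) for s in truth.snps})
    sites = call_candidate_sites(pileups, mask, refs, filter_config)

    called = {(s.seq_id, s.position) for s in sites}
    called_hc = {(s.seq_id, s.position) for s in sites if s.high_confidence}
    planted = {(s.seq_id, s.position) for s in truth.sites}
    editing = {(s.seq_id, s.position) for s in truth.editing}

    # error-only adenosines: covered deep enough to have been callable, not
    # planted / SNP / editing / masked
    n_error_only = 0
    fp = 0
    depth_by_seq = {}
    for ref in refs:
        total = np.zeros((len(ref), 4), dtype=np.int64)
        for pu in pileups:
            total += pu.counts_array(ref.seq_id)
        depth_by_seq[ref.seq_id] = total.sum(axis=1)
        special = truth.special_positions(ref.seq_id)
        for pos in np.nonzero(
            depth_by_seq[ref.seq_id] >= filter_config.min_combined_depth
        )[0]:
            pos = int(pos)
            if ref.sequence[pos] != "A" or pos in special:
                continue
            n_error_only += 1
            if (ref.seq_id, pos) in called:
                fp += 1

    min_site_depth = min(
        int(depth_by_seq[s.seq_id][s.position]) for s in truth.sites
    )
    return {
        "n_planted": len(planted),
        "n_detected_hc": len(planted & called_hc),
        "n_error_only_adenosines": n_error_only,
        "n_false_positives": fp,
        "n_masked_called": len(called & mask.positions),
        "n_editing_high_confidence": len(editing & called_hc),
        "min_planted_site_depth": min_site_depth,
    }


def mismatch_rate_error(seed: int, stoichiometry: float = 0.2) -> dict:
    """Observed vs closed-form mismatch rate at one deeply covered site.

    Sized so the combined covering depth at the planted site is ~10^4;
    unclipped pileups keep every aligned base in the tally. Short fragments
    and no PCR duplication concentrate coverage — the rate among covering
    reads does not depend on either.
    """
    config = SimulationConfig(
        seed=seed,
        n_planted_sites=1,
        stoichiometry=stoichiometry,
        n_het_snps=0,
        n_hom_snps=0,
        n_editing_sites=0,
        n_replicates=2,
        reads_per_replicate=96_000,
        fragment_length_mean=60.0,
        fragment_length_sd=5.0,
        pcr_duplication_rate=0.0,
    )
    refs, _, truth, reads_by_rep = simulate_experiment(config)
    pconfig = PileupConfig(end_clip=0)
    total = np.zeros((len(refs[0]), 4), dtype=np.int64)
    for rep_reads in reads_by_rep.values():
        total += build_pileup(rep_reads, refs, pconfig).counts_array(refs[0].seq_id)
    site = truth.sites[0]
    depth = int(total[site.position].sum())
    rate = (depth - int(total[site.position, 0])) / depth  # sites sit on A
    expected = expected_mismatch_rate(
        site.stoichiometry, site.readthrough, site.misinc_given_readthrough
    )
    return {"observed": rate, "expected": expected, "depth": depth}


def readthrough_recovery(seed: int, readthrough: float = 0.15) -> dict:
    """Estimate read-through at a full-stoichiometry hard stop.

    Uses fully-sequenced fragments (fragment length = read length) so column
    depth counts molecule passage — the flank-ratio estimator's regime — and
    unclipped pileups so truncated reads cover the near flank.
    """
    config = SimulationConfig(
        seed=seed,
        n_planted_sites=1,
        stoichiometry=1.0,
        readthrough=readthrough,
        n_het_snps=0,
        n_hom_snps=0,
        n_editing_sites=0,
        reads_per_replicate=2500,
        fragment_length_mean=50.0,
        fragment_length_sd=0.0,
        min_read_length=5,  # keep short truncated reads: they carry the flank
    )
    refs, _, truth, reads_by_rep = simulate_experiment(config)
    pconfig = PileupConfig(end_clip=0)
    pileups = [build_pileup(r, refs, pconfig) for r in reads_by_rep.values()]
    site = truth.sites[0]
    est = estimate_readthrough(pileups, site.seq_id, site.position)
    return {"estimate": est.readthrough_rate, "true_readthrough": readthrough}


def _tss_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_transcripts=30,
        transcript_length=400,
        n_planted_sites=0,
        n_het_snps=0,
        n_hom_snps=0,
        n_editing_sites=0,
        n_replicates=2,
        reads_per_replicate=4000,
    )


def termination_contrast(seed: int, min_tss_coverage: int = 5) -> dict:
    """RNA-seq vs miCLIP termination signature at transcription-start sites.

    RNA-seq read 5' ends mark the transcript end (offset 0); miCLIP reads
    truncate at the antibody adduct (offsets 0/+1, some further downstream).
    """
    config = _tss_config(seed)
    _, annotations, _, rna_by_rep = simulate_experiment(config, mode="rnaseq")
    refs, _, _, mi_by_rep = simulate_experiment(config, mode="miclip")
    rna = [r for reads in rna_by_rep.values() for r in reads]
    mi = [r for reads in mi_by_rep.values() for r in reads]

    rna_profiles, _ = termination_profiles(rna, rna, annotations, min_tss_coverage)
    mi_profiles, mi_aggregate = termination_profiles(mi, rna, annotations, min_tss_coverage)

    modal0 = sum(p.modal_offset() == 0 for p in rna_profiles)
    offsets01 = float(mi_aggregate.mean_fraction.iloc[:2].sum())
    return {
        "n_tss_rnaseq": len(rna_profiles),
        "rnaseq_modal_offset0_fraction": modal0 / len(rna_profiles) if rna_profiles else float("nan"),
        "n_tss_miclip": len(mi_profiles),
        "miclip_offsets01_fraction": offsets01,
    }


def tss_enrichment_experiment(seed: int, a_start_fraction: float = 0.33) -> dict:
    """A-start enrichment among cluster-overlapping TSSs for a cap-binding
    antibody model (crosslinks only at adenosine-start caps)."""
    config = dataclasses.replace(
        _tss_config(seed),
        n_transcripts=60,
        a_start_fraction=a_start_fraction,
        crosslink_a_start_only=True,
    )
    refs, annotations, _, mi_by_rep = simulate_experiment(config, mode="miclip")
    mi = [r for reads in mi_by_rep.values() for r in reads]
    clusters = call_clusters(mi, min_score=20)
    res = tss_start_enrichment(clusters, annotations)
    return {
        "fraction_overlap": res.fraction_overlap,
        "fraction_background": res.fraction_background,
        "odds_ratio": res.odds_ratio,
        "p_value": res.p_value,
        "n_clusters": len(clusters),
    }
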