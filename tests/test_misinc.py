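"""Filter-chain semantics: rates, heterogeneity, replication, masking,
decoy rejection and read-through estimation."""

import dataclasses

import numpy as np
import pytest

from misincmap import (
    FilterConfig,
    PileupConfig,
    ReferenceSequence,
    SimulationConfig,
    VariantMask,
    build_pileup,
    call_candidate_sites,
    estimate_readthrough,
    heterogeneity_fraction,
    misincorporation_rate,
    replicate_detects,
    simulate_experiment,
)
from misincmap.pileup import PileupColumn, ReplicatePileup


def _column(ref_base="A", **counts):
    full = {b: counts.get(b, 0) for b in "ACGT"}
    return PileupColumn("chrT", 0, ref_base, full)


def _pileup_from_counts(replicate_id, ref, counts_by_pos):
    """Build a ReplicatePileup directly from {position: {base: count}}."""
    pu = ReplicatePileup(replicate_id, {ref.seq_id: ref})
    arr = np.zeros((len(ref), 4), dtype=np.int64)
    for pos, counts in counts_by_pos.items():
        for base, count in counts.items():
            arr[pos, "ACGT".index(base)] = count
    pu.add_counts(ref.seq_id, arr)
    return pu


class TestRate:
    def test_partial_mismatch(self):
        assert misincorporation_rate(_column(A=930, T=70)) == pytest.approx(0.07)

    def test_no_mismatch(self):
        assert misincorporation_rate(_column(A=500)) == 0.0

    def test_full_mismatch(self):
        assert misincorporation_rate(_column(T=10)) == 1.0

    def test_zero_depth_is_an_error(self):
        with pytest.raises(ValueError):
            misincorporation_rate(_column())


class TestHeterogeneity:
    def test_minority_fraction(self):
        assert heterogeneity_fraction(_column(T=90, G=6, C=4)) == pytest.approx(0.10)

    def test_single_class_is_homogeneous(self):
        # the A->I editing signature: all mismatches to one base
        assert heterogeneity_fraction(_column(G=100)) == 0.0

    def test_below_default_threshold(self):
        assert heterogeneity_fraction(_column(T=97, G=2, C=1)) == pytest.approx(0.03)

    def test_reference_reads_do_not_count(self):
        assert heterogeneity_fraction(_column(A=1000, T=90, G=10)) == pytest.approx(0.10)

    def test_zero_mismatches_is_an_error(self):
        with pytest.raises(ValueError):
            heterogeneity_fraction(_column(A=100))


class TestReplicateDetects:
    def test_detected(self):
        assert replicate_detects(_column(A=95, T=5), FilterConfig())

    def test_depth_gate(self):
        assert not replicate_detects(_column(A=5, T=5), FilterConfig())

    def test_rate_gate(self):
        assert not replicate_detects(_column(A=995, T=5), FilterConfig(per_replicate_min_rate=0.01))


class TestCallSites:
    REF = ReferenceSequence("chrT", "C" * 10 + "A" + "C" * 10)
    SITE = 10

    def _replicates(self, n_rep=20, depth=50, mism=None, rng=None):
        """n_rep replicate pileups with given per-replicate counts at SITE."""
        mism = mism or {}
        pileups = []
        for i in range(n_rep):
            counts = {"A": depth - sum(mism.values()), **mism}
            pileups.append(
                _pileup_from_counts(f"rep{i:02d}", self.REF, {self.SITE: counts})
            )
        return pileups

    def test_planted_site_with_heterogeneous_spectrum_is_high_confidence(self, rng):
        # expected combined rate s*r*m/(s*r + 1 - s) ~ 0.043 for s=0.2, r=0.2, m=0.9
        s, r, m = 0.2, 0.2, 0.9
        p_mismatch = s * r * m / (s * r + 1 - s)
        pileups = []
        for i in range(20):
            depth = 50
            n_mm = rng.binomial(depth, p_mismatch)
            split = rng.multinomial(n_mm, [0.8, 0.1, 0.1])
            counts = {"A": depth - n_mm, "T": split[0], "G": split[1], "C": split[2]}
            pileups.append(_pileup_from_counts(f"r{i}", self.REF, {self.SITE: counts}))
        config = FilterConfig(min_combined_depth=500)
        sites = call_candidate_sites(pileups, None, config=config)
        assert [s_.position for s_ in sites] == [self.SITE]
        site = sites[0]
        assert site.high_confidence
        assert site.combined_rate == pytest.approx(p_mismatch, abs=0.02)
        assert site.combined_depth == 1000

    def test_masked_position_absent(self):
        pileups = self._replicates(mism={"T": 5})
        mask = VariantMask({("chrT", self.SITE)})
        assert call_candidate_sites(pileups, mask) == []

    def test_heterozygous_snp_decoy_fails_heterogeneity(self, rng):
        # ~50% pure A->G from allele sampling: passes depth/rate/replication
        pileups = []
        for i in range(20):
            n_alt = rng.binomial(50, 0.5)
            pileups.append(
                _pileup_from_counts(
                    f"r{i}", self.REF, {self.SITE: {"A": 50 - n_alt, "G": n_alt}}
                )
            )
        (site,) = call_candidate_sites(pileups, None)
        assert site.combined_rate > 0.4
        assert site.heterogeneity < 0.05
        assert not site.high_confidence

    def test_insufficient_replication_rejected(self):
        # signal in 8/20 replicates only
        pileups = self._replicates(n_rep=8, mism={"T": 5})
        pileups += self._replicates(n_rep=12, mism={})[:12]
        for i, pu in enumerate(pileups):
            pu.replicate_id = f"rep{i:02d}"
        assert call_candidate_sites(pileups, None) == []

    def test_reference_n_positions_skipped(self):
        ref = ReferenceSequence("chrT", "C" * 10 + "N" + "C" * 10)
        pileups = [
            _pileup_from_counts(f"r{i}", ref, {10: {"A": 25, "T": 25}})
            for i in range(20)
        ]
        assert call_candidate_sites(pileups, None) == []

    def test_combined_counts_conserve_replicate_sums(self):
        pileups = self._replicates(mism={"T": 3, "G": 1})
        (site,) = call_candidate_sites(pileups, None)
        assert site.combined_counts == {"A": 46 * 20, "C": 0, "G": 20, "T": 60}

    def test_output_sorted(self):
        ref = ReferenceSequence("chrT", "A" * 30)
        counts = {p: {"A": 40, "T": 10} for p in (20, 5, 12)}
        pileups = [_pileup_from_counts(f"r{i}", ref, counts) for i in range(20)]
        sites = call_candidate_sites(pileups, None, config=FilterConfig(min_combined_depth=100))
        assert [s.position for s in sites] == [5, 12, 20]


THRESHOLD_FIELDS = [
    "min_combined_depth",
    "min_rate",
    "min_replicate_fraction",
    "min_heterogeneity",
    "per_replicate_min_depth",
    "per_replicate_min_rate",
]


def _random_config(rng):
    return FilterConfig(
        min_combined_depth=int(rng.integers(1, 800)),
        min_rate=float(rng.uniform(0, 0.1)),
        min_replicate_fraction=float(rng.uniform(0, 1)),
        min_heterogeneity=float(rng.uniform(0, 0.3)),
        per_replicate_min_depth=int(rng.integers(1, 40)),
        per_replicate_min_rate=float(rng.uniform(0, 0.1)),
    )


def _raise_field(config, name, rng):
    if name == "min_combined_depth":
        return dataclasses.replace(config, min_combined_depth=config.min_combined_depth + int(rng.integers(1, 300)))
    if name == "per_replicate_min_depth":
        return dataclasses.replace(config, per_replicate_min_depth=config.per_replicate_min_depth + int(rng.integers(1, 20)))
    value = getattr(config, name)
    return dataclasses.replace(config, **{name: min(1.0, value + float(rng.uniform(0.01, 0.3)))})


def test_threshold_monotonicity(rng):
    """Raising any threshold never adds a site (nor a high-confidence site)."""
    config = SimulationConfig(seed=7, n_replicates=6, reads_per_replicate=1200)
    refs, _, truth, reads = simulate_experiment(config)
    pileups = [build_pileup(r, refs) for r in reads.values()]
    for _ in range(25):
        base = _random_config(rng)
        raised = _raise_field(base, THRESHOLD_FIELDS[int(rng.integers(0, 6))], rng)
        before = call_candidate_sites(pileups, None, config=base)
        after = call_candidate_sites(pileups, None, config=raised)
        key = lambda sites: {(s.seq_id, s.position) for s in sites}
        hc = lambda sites: {(s.seq_id, s.position) for s in sites if s.high_confidence}
        assert key(after) <= key(before)
        assert hc(after) <= hc(before)


class TestReadthrough:
    def _uniform_pileup(self, site_depth, flank_depth, L=60, site=20):
        ref = ReferenceSequence("chrT", "A" * L)
        counts = {p: {"A": flank_depth} for p in range(L)}
        counts[site] = {"A": site_depth}
        return _pileup_from_counts("r0", ref, counts), site

    def test_fifteen_percent(self):
        pu, site = self._uniform_pileup(15, 100)
        est = estimate_readthrough(pu, "chrT", site)
        assert est.readthrough_rate == pytest.approx(0.15)
        assert est.site_depth == 15
        assert est.flank_depth == 100

    def test_no_hard_stop_gives_one(self):
        pu, site = self._uniform_pileup(100, 100)
        assert estimate_readthrough(pu, "chrT", site).readthrough_rate == 1.0

    def test_zero_flank_coverage_is_an_error(self):
        ref = ReferenceSequence("chrT", "A" * 30)
        pu = _pileup_from_counts("r0", ref, {10: {"A": 50}})
        with pytest.raises(ValueError, match="flank"):
            estimate_readthrough(pu, "chrT", 10)

    def test_recovers_simulated_readthrough(self):
        """Full-stoichiometry site with r=0.25: estimate within +/- 0.05."""
        # fully-sequenced fragments (fragment length = read length): depth then
        # directly counts molecule passage, the estimator's assumption
        config = SimulationConfig(
            seed=11,
            n_planted_sites=1,
            stoichiometry=1.0,
            readthrough=0.25,
            n_het_snps=0,
            n_hom_snps=0,
            n_editing_sites=0,
            reads_per_replicate=2500,
            fragment_length_mean=50.0,
            fragment_length_sd=0.0,
            min_read_length=5,
        )
        refs, _, truth, reads = simulate_experiment(config)
        # unclipped pileups: clipping would hollow out the near flank
        pconfig = PileupConfig(end_clip=0)
        pileups = [build_pileup(r, refs, pconfig) for r in reads.values()]
        site = truth.sites[0]
        est = estimate_readthrough(pileups, site.seq_id, site.position)
        assert est.readthrough_rate == pytest.approx(0.25, abs=0.05)
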