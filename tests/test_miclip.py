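"""Termination profiles, cluster calling, metagene and TSS enrichment."""

import numpy as np
import pytest

from misincmap import (
    TranscriptAnnotation,
    call_clusters,
    fisher_exact_two_sided,
    metagene,
    termination_profiles,
    tss_start_enrichment,
)
from misincmap.miclip import Cluster

from conftest import hypergeom_fisher_two_sided, mk_read


def _annot(tss=100, L=300, seq_id="chrT", strand="+", start_nt="A", transcript_id="t1"):
    if strand == "+":
        tx_start, tx_end = tss, tss + L
    else:
        tx_start, tx_end = tss - L + 1, tss + 1
    cds_start = tx_start + L // 3
    cds_end = tx_start + 2 * L // 3
    return TranscriptAnnotation(
        transcript_id, seq_id, strand, tx_start, tx_end, cds_start, cds_end,
        start_nucleotide=start_nt,
    )


def _stack(start, n, length=30, seq_id="chrT", prefix="r"):
    return [
        mk_read(seq_id=seq_id, start=start, bases="A" * length, read_id=f"{prefix}{i}")
        for i in range(n)
    ]


class TestTerminationProfiles:
    def test_counts_read_five_prime_ends_by_offset(self):
        annot = _annot(tss=100)
        ends = [0, 0, 1, 1, 1, 3]
        miclip = [
            mk_read(start=100 + e, bases="A" * 30, read_id=f"m{i}")
            for i, e in enumerate(ends)
        ]
        rnaseq = _stack(95, 6, prefix="n")
        profiles, _ = termination_profiles(miclip, rnaseq, [annot], min_tss_coverage=1)
        (profile,) = profiles
        assert profile.counts_by_offset == {0: 2, 1: 3, 2: 0, 3: 1, 4: 0}

    def test_coverage_gate_excludes_shallow_tss(self):
        annot = _annot(tss=100)
        miclip = _stack(100, 4)  # < 5 at the TSS
        rnaseq = _stack(95, 10, prefix="n")
        profiles, aggregate = termination_profiles(miclip, rnaseq, [annot], min_tss_coverage=5)
        assert profiles == []
        assert aggregate.empty

    def test_gate_applies_to_both_libraries(self):
        annot = _annot(tss=100)
        miclip = _stack(100, 10)
        rnaseq = _stack(95, 4, prefix="n")  # RNA-seq side too shallow
        profiles, _ = termination_profiles(miclip, rnaseq, [annot], min_tss_coverage=5)
        assert profiles == []

    def test_minus_strand_offsets_follow_transcript_orientation(self):
        annot = _annot(tss=199, strand="-")
        # on the minus strand the 5' end is the rightmost aligned base;
        # a read ending at 198 terminates at offset +1
        miclip = [
            mk_read(start=199 - 29, bases="A" * 30, strand="-", read_id=f"m{i}")
            for i in range(3)
        ] + [
            mk_read(start=198 - 29, bases="A" * 30, strand="-", read_id=f"x{i}")
            for i in range(2)
        ]
        rnaseq = [
            mk_read(start=180, bases="A" * 30, strand="-", read_id=f"n{i}")
            for i in range(5)
        ]
        profiles, _ = termination_profiles(miclip, rnaseq, [annot], min_tss_coverage=3)
        (profile,) = profiles
        assert profile.counts_by_offset[0] == 3
        assert profile.counts_by_offset[1] == 2

    def test_counts_conserve_in_window_ends(self):
        annot = _annot(tss=100)
        offsets = [0, 0, 1, 2, 4, 4, 7, -1]  # two fall outside 0..4
        miclip = [
            mk_read(start=100 + o, bases="A" * 30, read_id=f"m{i}")
            for i, o in enumerate(offsets)
        ]
        rnaseq = _stack(95, 10, prefix="n")
        profiles, _ = termination_profiles(miclip, rnaseq, [annot], min_tss_coverage=1)
        assert sum(profiles[0].counts_by_offset.values()) == 6


class TestClusters:
    def test_identical_stack_scores_its_size(self):
        (cluster,) = call_clusters(_stack(50, 25), min_score=20)
        assert (cluster.start, cluster.end, cluster.score) == (50, 80, 25)

    def test_nineteen_stacked_reads_dropped_at_default(self):
        assert call_clusters(_stack(50, 19), min_score=20) == []

    def test_gap_separates_clusters(self):
        reads = _stack(0, 25) + _stack(100, 25, prefix="q")
        clusters = call_clusters(reads, min_score=20)
        assert [(c.start, c.end) for c in clusters] == [(0, 30), (100, 130)]

    def test_transitive_merge_scores_peak_depth_not_total(self):
        # 15 + 15 overlapping stacks: one interval, peak 15+15=30 only where
        # they overlap
        reads = _stack(0, 15) + _stack(20, 15, prefix="q")
        (cluster,) = call_clusters(reads, min_score=20)
        assert (cluster.start, cluster.end) == (0, 50)
        assert cluster.score == 30
        # abutting (non-overlapping) stacks never reach a depth of 20
        reads = _stack(0, 15) + _stack(30, 15, prefix="q")
        assert call_clusters(reads, min_score=20) == []

    def test_order_invariance(self, rng):
        reads = _stack(0, 21) + _stack(25, 22, prefix="q") + _stack(200, 30, prefix="z")
        shuffled = list(reads)
        rng.shuffle(shuffled)
        assert call_clusters(reads) == call_clusters(shuffled)

    def test_strands_do_not_merge(self):
        plus = _stack(0, 25)
        minus = [
            mk_read(start=0, bases="A" * 30, strand="-", read_id=f"m{i}")
            for i in range(25)
        ]
        clusters = call_clusters(plus + minus, min_score=20)
        assert len(clusters) == 2
        assert {c.strand for c in clusters} == {"+", "-"}

    def test_widths_bounded_by_covered_span(self):
        reads = _stack(0, 25) + _stack(40, 25, prefix="q")
        clusters = call_clusters(reads, min_score=1)
        assert sum(c.end - c.start for c in clusters) <= 70


class TestMetagene:
    def test_items_proportional_to_rnaseq_are_flat(self, rng):
        annot = _annot(tss=0, L=300)
        starts = rng.integers(0, 270, size=400)
        reads = [mk_read(start=int(s), bases="A" * 30, read_id=f"r{i}") for i, s in enumerate(starts)]
        profile = metagene(reads, [annot], reads)
        defined = profile.values[~np.isnan(profile.values)]
        assert defined == pytest.approx(np.ones_like(defined))

    def test_clusters_at_tss_land_in_first_utr_bin(self):
        annot = _annot(tss=0, L=300)
        clusters = [Cluster("chrT", 0, 2, "+", 25) for _ in range(10)]
        rnaseq = [mk_read(start=int(s), bases="A" * 30, read_id=f"r{i}") for i, s in enumerate(range(0, 270, 3))]
        profile = metagene(clusters, [annot], rnaseq)
        assert profile.item_counts[0] == 10
        assert profile.item_counts[1:].sum() == 0

    def test_empty_items_give_all_zero_profile(self):
        annot = _annot(tss=0, L=300)
        profile = metagene([], [annot], _stack(0, 5))
        assert (profile.values == 0).all()

    def test_zero_rnaseq_bins_are_missing_not_infinite(self):
        annot = _annot(tss=0, L=300)
        items = [Cluster("chrT", 0, 2, "+", 25)]
        profile = metagene(items, [annot], [])  # no RNA-seq at all
        assert np.isnan(profile.values[0])
        assert not np.isinf(profile.values).any()


class TestEnrichment:
    def _catalog(self, a_ov, a_no, o_ov, o_no):
        annotations = []
        clusters = []
        tss = 0
        for count, start_nt, overlapping in (
            (a_ov, "A", True), (a_no, "A", False), (o_ov, "G", True), (o_no, "G", False),
        ):
            for _ in range(count):
                annotations.append(
                    _annot(tss=tss, L=300, start_nt=start_nt, transcript_id=f"t{tss}")
                )
                if overlapping:
                    clusters.append(Cluster("chrT", tss, tss + 5, "+", 25))
                tss += 1000
        return clusters, annotations

    def test_worked_table(self):
        clusters, annotations = self._catalog(90, 10, 30, 70)
        res = tss_start_enrichment(clusters, annotations)
        assert res.table.tolist() == [[90, 10], [30, 70]]
        assert res.odds_ratio == pytest.approx(21.0)
        assert res.fraction_overlap == pytest.approx(90 / 120)
        assert res.fraction_background == pytest.approx(0.5)
        assert res.p_value == pytest.approx(hypergeom_fisher_two_sided(90, 10, 30, 70), rel=1e-9)

    def test_background_fraction_small_catalog(self):
        _, annotations = self._catalog(0, 1, 0, 2)
        with pytest.warns(UserWarning):
            res = tss_start_enrichment([], annotations)
        assert res.fraction_background == pytest.approx(1 / 3)

    def test_no_clusters_is_degenerate(self):
        _, annotations = self._catalog(0, 5, 0, 5)
        with pytest.warns(UserWarning, match="degenerate"):
            res = tss_start_enrichment([], annotations)
        assert res.fraction_overlap == 0.0
        assert res.p_value == 1.0

    def test_fisher_matches_enumeration_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
                continue
            _, p = fisher_exact_two_sided([[a, b], [c, d]])
            assert p == pytest.approx(hypergeom_fisher_two_sided(a, b, c, d), rel=1e-8)
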