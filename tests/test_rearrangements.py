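"""Locus rearrangement classification, chromothripsis detection, RB1 status."""

import numpy as np
import pytest

from conftest import make_junction, make_snv
from rbwgs.io_formats import CopyNumberProfile, CopyNumberSegment
from rbwgs.rearrangements import (
    breakend_exon_proximity,
    classify_locus_rearrangement,
    count_gene_breakends,
    detect_chromothripsis_like,
    resolve_rb1_status,
)
from rbwgs.synthetic_cohort import (
    SimulationConfig,
    default_rb1_model,
    realise_rb1_mechanism,
    simulate_tumour,
)


def diploid_profile(extra=(), sample_id="S1", karyotype=None):
    segments = []
    if karyotype is not None:
        painted = {s.chrom for s in extra}
        for name in karyotype.names():
            if name not in painted:
                segments.append(
                    CopyNumberSegment(name, 1, karyotype.chrom(name).length, 2, 1)
                )
    segments.extend(extra)
    return CopyNumberProfile(sample_id, 2.0, segments)


class TestCountGeneBreakends:
    def test_complex_intra_fixture_has_three_or_four(self, rb1, karyotype):
        for seed in range(5):
            junctions, _, _ = realise_rb1_mechanism(
                "complex_intra", rb1, seed, karyotype=karyotype
            )
            n, inside = count_gene_breakends(junctions, rb1)
            assert n in (3, 4)
            assert all(rb1.gene_start <= b.pos <= rb1.gene_end for b in inside)

    def test_other_chromosome_junction_contributes_zero(self, rb1):
        j = make_junction("8", 1000, "+", "8", 2000, "-", "deletion")
        assert count_gene_breakends([j], rb1) == (0, [])

    def test_matches_brute_force_membership(self, rb1, karyotype):
        from conftest import random_junctions

        junctions = random_junctions(np.random.default_rng(7), 500, karyotype)
        n, _ = count_gene_breakends(junctions, rb1)
        brute = sum(
            1
            for j in junctions
            for be in (j.breakend_a, j.breakend_b)
            if be.chrom == "13" and rb1.gene_start <= be.pos <= rb1.gene_end
        )
        assert n == brute


class TestExonProximity:
    def test_distance_to_exon_boundary(self, rb1):
        exon_start = rb1.exons[22][0]  # exon 23 in 1-based numbering
        be = make_junction("13", exon_start - 72, "+", "13", exon_start + 10**6, "-", "deletion").breakend_a
        ((_, dist),) = breakend_exon_proximity([be], rb1)
        assert dist == 72

    def test_inside_exon_is_zero(self, rb1):
        s, e = rb1.exons[10]
        be = make_junction("13", (s + e) // 2, "+", "13", e + 10**6, "-", "deletion").breakend_a
        ((idx, dist),) = breakend_exon_proximity([be], rb1)
        assert dist == 0 and idx == 10

    def test_matches_brute_force_min_over_edges(self, rb1):
        rng = np.random.default_rng(13)
        positions = rng.integers(rb1.gene_start, rb1.gene_end, size=200)
        bes = [
            make_junction("13", int(p), "+", "13", rb1.gene_end + 10**6, "-", "deletion").breakend_a
            for p in positions
        ]
        results = breakend_exon_proximity(bes, rb1)
        for be, (_, dist) in zip(bes, results):
            brute = min(
                0 if s <= be.pos <= e else min(abs(be.pos - s), abs(be.pos - e))
                for s, e in rb1.exons
            )
            assert dist == brute


class TestChromothripsisDetection:
    def test_generator_fixture_is_positive(self, rb1, karyotype):
        junctions, patches, _ = realise_rb1_mechanism(
            "chromothripsis_like", rb1, 3, karyotype=karyotype
        )
        extra = [CopyNumberSegment(c, s, e, t, m) for c, s, e, t, m in patches]
        base13 = [
            CopyNumberSegment("13", 1, extra[0].start - 1, 2, 1),
            CopyNumberSegment("13", extra[-1].end + 1, karyotype.chrom("13").length, 2, 1),
        ]
        profile = diploid_profile(tuple(extra + base13), karyotype=karyotype)
        calls = detect_chromothripsis_like(junctions, profile, karyotype)
        positive = [c for c in calls if c.verdict]
        assert len(positive) == 1
        call = positive[0]
        assert "13" in call.chromosomes and len(call.chromosomes) == 3
        assert call.n_breakpoints >= 40
        assert call.n_cn_state_switches >= 10
        assert call.n_distinct_cn_states <= 3

    def test_single_deletion_is_negative(self, karyotype):
        j = make_junction("13", 48_000_000, "+", "13", 49_000_000, "-", "deletion")
        profile = diploid_profile(karyotype=karyotype)
        calls = detect_chromothripsis_like([j], profile, karyotype)
        assert all(not c.verdict for c in calls)

    def test_complex_intra_without_oscillation_is_negative(self, rb1, karyotype):
        junctions, patches, _ = realise_rb1_mechanism(
            "complex_intra", rb1, 11, karyotype=karyotype
        )
        assert patches == []  # monotone copy number by construction
        profile = diploid_profile(karyotype=karyotype)
        calls = detect_chromothripsis_like(junctions, profile, karyotype)
        assert all(not c.verdict for c in calls)

    def test_invariant_to_junction_order(self, rb1, karyotype):
        junctions, patches, _ = realise_rb1_mechanism(
            "chromothripsis_like", rb1, 5, karyotype=karyotype
        )
        extra = [CopyNumberSegment(c, s, e, t, m) for c, s, e, t, m in patches]
        base13 = [
            CopyNumberSegment("13", 1, extra[0].start - 1, 2, 1),
            CopyNumberSegment("13", extra[-1].end + 1, karyotype.chrom("13").length, 2, 1),
        ]
        profile = diploid_profile(tuple(extra + base13), karyotype=karyotype)
        fwd = detect_chromothripsis_like(junctions, profile, karyotype)
        rev = detect_chromothripsis_like(list(reversed(junctions)), profile, karyotype)
        assert fwd == rev


class TestClassifyLocus:
    def test_balanced_translocation_pair_is_simple(self, rb1, karyotype):
        intron2 = rb1.intron(2)
        junctions = [
            make_junction("13", intron2[0] + 5, "+", "16", 3_800_000, "-", "translocation"),
            make_junction("13", intron2[0] + 6, "-", "18", 30_000_000, "+", "translocation"),
        ]
        profile = diploid_profile(karyotype=karyotype)
        call = classify_locus_rearrangement(junctions, profile, rb1)
        assert call.pattern == "simple" and call.transected

    def test_three_in_gene_breakends_with_translocations_is_complex_inter(
        self, rb1, karyotype
    ):
        mid = (rb1.gene_start + rb1.gene_end) // 2
        junctions = [
            make_junction("13", mid, "+", "11", 60_000_000, "-", "translocation"),
            make_junction("13", mid + 100, "-", "11", 61_000_000, "+", "translocation"),
            make_junction("13", mid + 200, "+", "11", 62_000_000, "-", "translocation"),
        ]
        profile = diploid_profile(karyotype=karyotype)
        call = classify_locus_rearrangement(junctions, profile, rb1)
        assert call.pattern == "complex_interchromosomal"
        assert call.n_breakends_in_gene == 3

    def test_no_junctions_is_none(self, rb1, karyotype):
        profile = diploid_profile(karyotype=karyotype)
        call = classify_locus_rearrangement([], profile, rb1)
        assert call.pattern == "none" and not call.transected

    @pytest.mark.parametrize(
        "mechanism,expected",
        [
            ("simple_translocation", "simple"),
            ("complex_intra", "complex_intrachromosomal"),
            ("complex_inter", "complex_interchromosomal"),
            ("chromothripsis_like", "chromothripsis_like"),
        ],
    )
    def test_mechanism_recovery_on_synthetic_tumours(self, mechanism, expected, rb1, karyotype):
        cfg = SimulationConfig(seed=101, n_tumours=3, rb1_mechanisms=(mechanism,) * 3)
        for i in range(3):
            _, _, junctions, profile, _ = simulate_tumour(cfg, i)
            call = classify_locus_rearrangement(junctions, profile, rb1)
            assert call.pattern == expected


class TestResolveRb1Status:
    def test_truncating_snv_plus_loh_confirmed(self, rb1, karyotype):
        snv = make_snv(
            pos=rb1.exons[12][0] + 3, gene="RB1", consequence="nonsense"
        )
        loh = CopyNumberSegment("13", 1, karyotype.chrom("13").length, 2, 0)
        profile = diploid_profile((loh,), karyotype=karyotype)
        status = resolve_rb1_status([snv], [], [], profile, rb1)
        assert (status.allele_1, status.allele_2) == ("truncating_snv", "loh")
        assert status.biallelic_status == "confirmed"

    def test_two_truncating_variants_without_loh_confirmed(self, rb1, karyotype):
        a = make_snv(pos=rb1.exons[5][0] + 1, gene="RB1", consequence="essential_splice")
        b = make_snv(pos=rb1.exons[12][0] + 1, gene="RB1", consequence="nonsense")
        profile = diploid_profile(karyotype=karyotype)
        status = resolve_rb1_status([a, b], [], [], profile, rb1)
        assert status.allele_2 == "truncating_snv"
        assert status.biallelic_status == "confirmed"

    def test_complex_transection_without_loh_unresolved(self, rb1, karyotype):
        junctions, _, _ = realise_rb1_mechanism("complex_intra", rb1, 17, karyotype=karyotype)
        profile = diploid_profile(karyotype=karyotype)
        status = resolve_rb1_status([], [], junctions, profile, rb1)
        assert status.allele_1 == "sv_transection"
        assert status.allele_2 == "not_detected"
        assert status.biallelic_status == "unresolved"

    def test_exon_deletion_detected_as_intragenic(self, rb1, karyotype):
        s, e = rb1.exons[7]
        drop = CopyNumberSegment("13", s - 500, e + 500, 1, 0)
        profile = diploid_profile((drop,), karyotype=karyotype)
        status = resolve_rb1_status([], [], [], profile, rb1)
        assert status.allele_1 == "intragenic_deletion"
        assert status.biallelic_status == "unresolved"

    def test_intronic_cn_noise_is_not_a_deletion(self, rb1, karyotype):
        intron = rb1.intron(5)
        drop = CopyNumberSegment("13", intron[0] + 1, intron[1] - 1, 1, 0)
        profile = diploid_profile((drop,), karyotype=karyotype)
        status = resolve_rb1_status([], [], [], profile, rb1)
        assert status.allele_1 == "not_detected"
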