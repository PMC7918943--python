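"""Ploidy-aware amplification, large-scale/LOH/arm-level copy-number rules."""

import numpy as np
import pytest

from rbwgs.copy_number import (
    ArmEventCall,
    call_arm_events,
    call_large_scale_events,
    classify_amplification,
    cooccurrence_summary,
    focal_amplification_fold,
    loh_over_gene,
)
from rbwgs.io_formats import CopyNumberProfile, CopyNumberSegment, GeneModel


def seg(chrom, start, end, total, minor):
    return CopyNumberSegment(chrom, start, end, total, minor)


def profile(segments, ploidy=2.0, sample_id="S1"):
    return CopyNumberProfile(sample_id, ploidy, segments)


class TestAmplification:
    @pytest.mark.parametrize(
        "total_cn,ploidy,expected",
        [
            (11, 2.0, True),  # MDM4-style focal amplification, 11 copies
            (5, 2.0, True),
            (4, 2.0, False),
            (9, 3.1, True),
            (8, 3.1, False),
            (168, 2.0, True),  # MYCN-style 168-fold
            (5, 2.7, False),  # boundary ploidy uses the WGD rule
            (9, 2.7, True),
        ],
    )
    def test_thresholds(self, total_cn, ploidy, expected):
        s = seg("2", 1, 100, total_cn, 1 if total_cn else 0)
        assert classify_amplification(s, ploidy) is expected

    def test_monotone_in_total_cn(self):
        for ploidy in (2.0, 3.1):
            calls = [
                classify_amplification(seg("1", 1, 10, cn, 0), ploidy)
                for cn in range(13)
            ]
            assert calls == sorted(calls)  # False..False then True..True


class TestLargeScaleEvents:
    def test_ten_mb_gain_diploid(self, karyotype):
        p = profile([seg("1", 30_000_000, 40_000_000, 3, 1)])
        (ev,) = call_large_scale_events(p, karyotype)
        assert ev.gain and not ev.loss

    def test_copy_neutral_loh_is_a_loss(self, karyotype):
        p = profile([seg("1", 30_000_000, 40_000_000, 2, 0)])
        (ev,) = call_large_scale_events(p, karyotype)
        assert ev.loss and ev.copy_neutral_loh and not ev.gain

    def test_small_segment_excluded_from_large_scale(self, karyotype):
        p = profile([seg("1", 30_000_000, 32_000_000, 6, 1)])
        assert call_large_scale_events(p, karyotype) == []
        assert classify_amplification(p.segments[0], 2.0)  # still focal amp

    def test_wgd_gain_threshold(self, karyotype):
        p = profile([seg("1", 30_000_000, 40_000_000, 4, 2)], ploidy=3.2)
        assert call_large_scale_events(p, karyotype) == []
        p = profile([seg("1", 30_000_000, 40_000_000, 5, 2)], ploidy=3.2)
        (ev,) = call_large_scale_events(p, karyotype)
        assert ev.gain

    def test_centromeric_segment_excluded(self, karyotype):
        c = karyotype.chrom("1")
        inside = seg("1", c.centromere_start, c.centromere_end, 6, 1)
        p = profile([inside])
        assert call_large_scale_events(p, karyotype) == []

    def test_split_invariance(self, karyotype):
        """Splitting a >2*min_size segment into halves that each still pass
        the size gate yields the same gained footprint."""
        whole = profile([seg("3", 10_000_000, 30_000_000, 3, 1)])
        mid = 20_000_000
        split = profile(
            [seg("3", 10_000_000, mid, 3, 1), seg("3", mid + 1, 30_000_000, 3, 1)]
        )
        ev_whole = call_large_scale_events(whole, karyotype)
        ev_split = call_large_scale_events(split, karyotype)
        footprint = lambda evs: sorted(
            (e.segment.start, e.segment.end) for e in evs if e.gain
        )
        merged = footprint(ev_split)
        assert merged[0][0] == footprint(ev_whole)[0][0]
        assert merged[-1][1] == footprint(ev_whole)[0][1]
        assert sum(e - s + 1 for s, e in merged) == sum(
            e - s + 1 for s, e in footprint(ev_whole)
        )


class TestLohOverGene:
    def _gene(self):
        return GeneModel("RB1", "13", "+", 48_877_887, 49_056_122, ((48_878_000, 48_878_100),))

    def test_whole_chromosome_loh(self, karyotype):
        p = profile([seg("13", 1, 115_169_878, 2, 0)])
        assert loh_over_gene(p, self._gene()) is True

    def test_partial_minor_allele_breaks_loh(self):
        g = self._gene()
        p = profile(
            [
                seg("13", 1, 48_900_000, 2, 0),
                seg("13", 48_900_001, 115_169_878, 2, 1),
            ]
        )
        assert loh_over_gene(p, g) is False

    def test_uncovered_footprint_errors(self):
        g = self._gene()
        p = profile([seg("13", 1, 48_900_000, 2, 0)])
        with pytest.raises(ValueError, match="not fully covered"):
            loh_over_gene(p, g)

    def test_agrees_with_per_base_oracle_on_random_segmentations(self):
        rng = np.random.default_rng(83)
        g = GeneModel("G", "13", "+", 1000, 2000, ((1100, 1200),))
        for _ in range(50):
            bounds = sorted(rng.choice(np.arange(500, 2500), size=6, replace=False))
            bounds = [1] + [int(b) for b in bounds] + [3000]
            segments = []
            for s, e in zip(bounds, bounds[1:]):
                segments.append(
                    seg("13", s, e - 1, 2, int(rng.integers(0, 2)))
                )
            p = profile(segments)
            # brute-force per-base check over the footprint
            minor_at = {}
            for sg in segments:
                for pos in range(max(sg.start, 1000), min(sg.end, 2000) + 1):
                    minor_at[pos] = sg.minor_cn
            oracle = all(minor_at[pos] == 0 for pos in range(1000, 2001))
            assert loh_over_gene(p, g) is oracle


class TestArmEvents:
    def test_whole_arm_gain_has_fraction_one(self, karyotype):
        c, s, e = karyotype.arm_span("1q")
        p = profile([seg("1", s, e, 3, 1)])
        calls = {a.arm: a for a in call_arm_events(p, karyotype)}
        assert calls["1q"].event == "gain"
        assert calls["1q"].affected_fraction == pytest.approx(1.0, abs=1e-6)

    def test_forty_percent_gain_is_not_called(self, karyotype):
        c, s, e = karyotype.arm_span("1q")
        cut = s + int(0.4 * (e - s))
        p = profile([seg("1", s, cut, 3, 1)])
        calls = {a.arm: a for a in call_arm_events(p, karyotype)}
        assert calls["1q"].event == "none"

    def test_generator_arm_labels_recovered(self, karyotype):
        from rbwgs.synthetic_cohort import SimulationConfig, simulate_tumour

        for i in range(6):
            *_, prof, truth = simulate_tumour(SimulationConfig(seed=31, n_tumours=6), i)
            calls = call_arm_events(prof, karyotype)
            gained = {a.arm for a in calls if a.event == "gain"}
            lost = {a.arm for a in calls if a.event == "loss"}
            assert set(truth.arm_gains) <= gained
            assert set(truth.arm_losses) <= lost


class TestCooccurrence:
    def _calls(self, sample, gained):
        return [
            ArmEventCall(sample, arm, "gain" if arm in gained else "none", 1.0 if arm in gained else 0.0)
            for arm in ("1q", "2p", "6p")
        ]

    def test_nine_of_twenty_triple(self):
        by_sample = {}
        for i in range(9):
            by_sample[f"S{i}"] = self._calls(f"S{i}", {"1q", "2p", "6p"})
        for i in range(9, 20):
            by_sample[f"S{i}"] = self._calls(f"S{i}", set())
        summary = cooccurrence_summary(by_sample)
        assert summary["full_concurrence"] == 9
        assert summary["n_samples"] == 20

    def test_no_gains_all_zero(self):
        summary = cooccurrence_summary({"S0": self._calls("S0", set())})
        assert summary["marginal_gains"] == {"1q": 0, "2p": 0, "6p": 0}
        assert summary["patterns"] == {"none": 1}

    def test_exhaustive_enumeration_matches_brute_force(self):
        """All 2^3 patterns over 8 tumours against direct subset counting."""
        arms = ("1q", "2p", "6p")
        by_sample = {}
        patterns = []
        for i in range(8):
            gained = {a for k, a in enumerate(arms) if (i >> k) & 1}
            patterns.append(frozenset(gained))
            by_sample[f"S{i}"] = self._calls(f"S{i}", gained)
        summary = cooccurrence_summary(by_sample)
        for key, count in summary["patterns"].items():
            want = frozenset() if key == "none" else frozenset(key.split("+"))
            assert count == sum(1 for p in patterns if p == want)
        assert summary["full_concurrence"] == 1


class TestFocalFold:
    def _mycn(self):
        return GeneModel("MYCN", "2", "+", 16_080_683, 16_087_129, ((16_081_000, 16_081_200),), "oncogene")

    def test_168_fold(self):
        p = profile([seg("2", 16_000_000, 16_200_000, 168, 1)])
        assert focal_amplification_fold(p, self._mycn()) == (168, True)

    def test_diploid_gene_not_amplified(self):
        p = profile([seg("2", 1, 50_000_000, 2, 1)])
        assert focal_amplification_fold(p, self._mycn()) == (2, False)

    def test_uncovered_gene_errors(self):
        p = profile([seg("2", 1, 100, 2, 1)])
        with pytest.raises(ValueError, match="MYCN"):
            focal_amplification_fold(p, self._mycn())

    def test_max_overlap_matches_brute_force(self):
        rng = np.random.default_rng(89)
        g = self._mycn()
        for _ in range(30):
            bounds = sorted(
                int(b) for b in rng.choice(np.arange(15_900_000, 16_300_000), 5, replace=False)
            )
            segments = [
                seg("2", s, e - 1, int(rng.integers(0, 12)), 0)
                for s, e in zip([15_800_000] + bounds, bounds + [16_400_000])
            ]
            p = profile(segments)
            brute = max(
                s.total_cn
                for s in segments
                if s.start <= g.gene_end and s.end >= g.gene_start
            )
            assert focal_amplification_fold(p, g)[0] == brute
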