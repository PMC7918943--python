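"""Ploidy-aware copy-number rules on allele-specific segments.

The rules mirror ASCAT-style downstream analysis of a low-burden paediatric
tumour cohort:

* focal amplification: total copy number >= 5 in near-diploid genomes
  (ploidy < 2.7) or >= 9 with whole-genome duplication (ploidy >= 2.7);
* large-scale events: segments > 3 Mb are gains when total copy number
  exceeds 2 (diploid) or 4 (WGD), and losses when the minor allele copy
  number is 0 (LOH; copy-neutral or amplified LOH is flagged distinctly);
* arm-level events: an arm is called gained/lost when qualifying large-scale
  segments cover at least half of the unmasked arm;
* telomere- and centromere-restricted segments are excluded from
  large-scale calls.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import CopyNumberProfile, CopyNumberSegment, GeneModel
from .karyotype import KaryotypeTable

WGD_PLOIDY_CUTOFF = 2.7
DIPLOID_AMP_CN = 5
WGD_AMP_CN = 9
DIPLOID_GAIN_CN = 2  # gain when total_cn exceeds this
WGD_GAIN_CN = 4
MIN_LARGE_SCALE_BP = 3_000_000


def is_wgd(ploidy: float) -> bool:
    # ploidy exactly 2.7 is assigned the WGD rule (conservative amplification calling)
    return ploidy >= WGD_PLOIDY_CUTOFF


def classify_amplification(segment: CopyNumberSegment, ploidy: float) -> bool:
    """Amplified iff total_cn >= 5 (ploidy < 2.7) or >= 9 (ploidy >= 2.7)."""
    threshold = WGD_AMP_CN if is_wgd(ploidy) else DIPLOID_AMP_CN
    return segment.total_cn >= threshold


@dataclass(frozen=True)
class LargeScaleEvent:
    segment: CopyNumberSegment
    gain: bool
    loss: bool
    copy_neutral_loh: bool

    @property
    def labels(self) -> tuple[str, ...]:
        out = []
        if self.gain:
            out.append("gain")
        if self.loss:
            out.append("loss")
        if self.copy_neutral_loh:
            out.append("cn_loh")
        return tuple(out)


def _wholly_masked(segment: CopyNumberSegment, karyotype: KaryotypeTable) -> bool:
    return any(
        segment.start >= s and segment.end <= e
        for s, e in karyotype.masked_regions(segment.chrom)
    )


def call_large_scale_events(
    profile: CopyNumberProfile,
    karyotype: KaryotypeTable,
    min_size: int = MIN_LARGE_SCALE_BP,
) -> list[LargeScaleEvent]:
    """Gains/losses on segments larger than ``min_size`` (default 3 Mb).

    A segment can be both gained and LOH at once (amplified LOH); LOH at
    total_cn >= 2 is additionally flagged copy-neutral/amplified LOH.
    Segments lying wholly inside telomere or centromere masks are excluded.
    """
    gain_cn = WGD_GAIN_CN if is_wgd(profile.ploidy) else DIPLOID_GAIN_CN
    events = []
    for seg in profile.segments:
        if seg.length <= min_size:
            continue
        if seg.chrom in karyotype.chromosomes and _wholly_masked(seg, karyotype):
            continue
        gain = seg.total_cn > gain_cn
        loss = seg.minor_cn == 0
        cn_loh = loss and seg.total_cn >= 2
        if gain or loss:
            events.append(LargeScaleEvent(seg, gain, loss, cn_loh))
    return events


def loh_over_gene(profile: CopyNumberProfile, gene: GeneModel) -> bool:
    """True iff every base of the gene footprint lies in minor_cn = 0 segments.

    Raises when the footprint is not fully covered by segments.
    """
    segs = profile.overlapping(gene.chrom, gene.gene_start, gene.gene_end)
    covered_to = gene.gene_start - 1
    all_loh = True
    for seg in segs:  # profile segments are sorted and non-overlapping
        if seg.start > covered_to + 1:
            raise ValueError(
                f"{gene.symbol} footprint not fully covered by segments "
                f"(gap before {seg.chrom}:{seg.start})"
            )
        covered_to = max(covered_to, seg.end)
        if seg.minor_cn != 0:
            all_loh = False
    if covered_to < gene.gene_end:
        raise ValueError(
            f"{gene.symbol} footprint not fully covered by segments "
            f"(uncovered after {gene.chrom}:{covered_to})"
        )
    return all_loh


@dataclass(frozen=True)
class ArmEventCall:
    sample_id: str
    arm: str
    event: str  # "gain", "loss" or "none"
    affected_fraction: float

    def __post_init__(self):
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError(f"affected fraction {self.affected_fraction} outside [0,1]")


def _overlap_bp(seg: CopyNumberSegment, start: int, end: int) -> int:
    return max(0, min(seg.end, end) - max(seg.start, start) + 1)


def call_arm_events(
    profile: CopyNumberProfile,
    karyotype: KaryotypeTable,
    coverage_fraction: float = 0.5,
    min_size: int = MIN_LARGE_SCALE_BP,
) -> list[ArmEventCall]:
    """Arm gained (lost) iff gained (lost) large-scale segments cover at least
    ``coverage_fraction`` of the unmasked arm."""
    events = call_large_scale_events(profile, karyotype, min_size=min_size)
    calls = []
    for arm in karyotype.arms():
        chrom, start, end = karyotype.unmasked_arm_span(arm)
        arm_len = end - start + 1
        if arm_len <= 0:
            continue
        gained = sum(
            _overlap_bp(ev.segment, start, end)
            for ev in events
            if ev.gain and ev.segment.chrom == chrom
        )
        lost = sum(
            _overlap_bp(ev.segment, start, end)
            for ev in events
            if ev.loss and ev.segment.chrom == chrom
        )
        gain_frac = gained / arm_len
        loss_frac = lost / arm_len
        if gain_frac >= coverage_fraction and gain_frac >= loss_frac:
            calls.append(ArmEventCall(profile.sample_id, arm, "gain", gain_frac))
        elif loss_frac >= coverage_fraction:
            calls.append(ArmEventCall(profile.sample_id, arm, "loss", loss_frac))
        else:
            calls.append(
                ArmEventCall(profile.sample_id, arm, "none", max(gain_frac, loss_frac))
            )
    return calls


def cooccurrence_summary(
    arm_calls_by_sample: dict, arms_of_interest=("1q", "2p", "6p")
) -> dict:
    """Count singleton, exclusive-pair and full-concurrence gain patterns.

    ``arm_calls_by_sample`` maps sample_id -> list of ArmEventCall.  Returns
    counts keyed by pattern (e.g. ``"1q"``, ``"1q+6p"``, ``"1q+2p+6p"``,
    ``"none"``) plus per-arm marginal totals and ``n_samples``.
    """
    arms = tuple(arms_of_interest)
    counts = {arm: 0 for arm in arms}
    pattern_counts: dict[str, int] = {}
    for sample, calls in arm_calls_by_sample.items():
        gained = {c.arm for c in calls if c.event == "gain"}
        present = tuple(a for a in arms if a in gained)
        key = "+".join(present) if present else "none"
        pattern_counts[key] = pattern_counts.get(key, 0) + 1
        for a in present:
            counts[a] += 1
    return {
        "n_samples": len(arm_calls_by_sample),
        "marginal_gains": counts,
        "patterns": pattern_counts,
        "full_concurrence": pattern_counts.get("+".join(arms), 0),
    }


def focal_amplification_fold(
    profile: CopyNumberProfile, gene: GeneModel
) -> tuple[int, bool]:
    """(max total_cn over the gene footprint, amplified?).

    The fold value is reported as the raw maximum total copy number of
    segments overlapping the gene, matching the "N-fold" usage for focal
    oncogene amplifications.
    """
    segs = profile.overlapping(gene.chrom, gene.gene_start, gene.gene_end)
    if not segs:
        raise ValueError(f"{gene.symbol}: no segments cover the gene footprint")
    top = max(segs, key=lambda s: s.total_cn)
    return (top.total_cn, classify_amplification(top, profile.ploidy))
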