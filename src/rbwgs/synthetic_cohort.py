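"""Synthetic tumour-cohort generator with known ground truth.

Emulates the statistical structure of a low-burden paediatric eye-tumour
WGS cohort so that every downstream stage can be tested against known
labels:

* substitution burden grows linearly with age at enucleation
  (``Poisson(a + b * age)``), dominated by clock-like background signatures;
* a treated tumour additionally carries a platinum-chemotherapy signature
  at a configurable fraction, inflating its burden accordingly;
* the *RB1* locus is disrupted by one of six mechanisms spanning the
  complexity continuum (truncating point mutation plus LOH, intragenic
  deletion, simple translocation, complex intra-/interchromosomal
  rearrangement, chromothripsis-like shatter with oscillating copy number);
* recurrent arm-level events (1q+, 2p+, 6p+ with strong co-occurrence,
  16q-) and occasional focal *MYCN* amplification;
* contamination that exercises the stringent filter: population-SNP
  leak-through and sub-0.2-VAF artefacts.

All randomness flows from ``numpy.random.default_rng([seed, tumour_index])``
so each tumour is reproducible in isolation and cohort output is
byte-identical across reruns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from ._channels import CHANNELS_96, channel_mutation
from .io_formats import (
    Breakend,
    CopyNumberProfile,
    CopyNumberSegment,
    GeneModel,
    IndelRecord,
    SignatureSet,
    SnvRecord,
    SvJunction,
    read_gene_models,
    read_signatures,
    write_bedpe,
    write_indel_vcf,
    write_segments,
    write_snv_vcf,
)
from .karyotype import KaryotypeTable, load_default_karyotype
from .mutation_catalogue import PopulationSnpIndex, load_default_snp_index

RB1_MECHANISMS = (
    "point_plus_loh",
    "intragenic_deletion",
    "simple_translocation",
    "complex_intra",
    "complex_inter",
    "chromothripsis_like",
)

_DEFAULT_MECHANISM_PROBS = {
    "point_plus_loh": 0.40,
    "intragenic_deletion": 0.10,
    "simple_translocation": 0.10,
    "complex_intra": 0.15,
    "complex_inter": 0.15,
    "chromothripsis_like": 0.10,
}


def load_default_signatures() -> SignatureSet:
    """Bundled synthetic reference signatures (clock-like pair, platinum, UV)."""
    path = resources.files("rbwgs.data") / "signatures_synthetic.tsv"
    with resources.as_file(path) as p:
        return read_signatures(p)


def load_default_gene_models() -> list[GeneModel]:
    """Bundled synthetic gene-model fixture (RB1, MYCN, MDM4, BCOR, CREBBP, EXT2)."""
    path = resources.files("rbwgs.data") / "gene_models_synthetic.tsv"
    with resources.as_file(path) as p:
        return read_gene_models(p)


def default_rb1_model() -> GeneModel:
    return next(g for g in load_default_gene_models() if g.symbol == "RB1")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the cohort structure the analysis assumes: burden
    ``a + b * age`` months with a = 10, b = 8 (mean ~275 substitutions at the
    cohort's mean age of ~33 months), a clock-like background mixture, one
    chemotherapy-exposed tumour per 20 whose platinum fraction (0.7) lifts
    its burden to ~930, arm-gain marginals 0.60 / 0.55 / 0.70 for 1q / 2p /
    6p with coupling chosen so ~45% of tumours carry all three, 16q loss at
    0.40, and 10 + 30 injected contaminants per tumour.
    """

    seed: int = 0
    n_tumours: int = 20
    ages_months: tuple | None = None  # drawn ~ N(34, 16) truncated at 6 when None
    treated: tuple | None = None  # default: last tumour of a >=10-tumour cohort
    rb1_mechanisms: tuple | None = None  # drawn from _DEFAULT_MECHANISM_PROBS
    mycn_amplified: tuple | None = None  # drawn Bernoulli(0.1) when None
    burden_intercept: float = 10.0
    burden_slope: float = 8.0
    indel_intercept: float = 3.0
    indel_slope: float = 2.0
    signature_mixture: dict = field(
        default_factory=lambda: {"clock_flat": 0.7, "clock_cpg": 0.3}
    )
    platinum_fraction: float = 0.7
    platinum_signature: str = "platinum"
    arm_gain_probabilities: dict = field(
        default_factory=lambda: {"1q": 0.60, "2p": 0.55, "6p": 0.70}
    )
    arm_loss_probabilities: dict = field(default_factory=lambda: {"16q": 0.40})
    arm_coupling: float = 0.57
    n_snp_contaminants: int = 10
    n_low_vaf_artefacts: int = 30
    background_sv_mean: float = 6.0
    n_uv_doublets: int = 0

    def __post_init__(self):
        fracs = list(self.signature_mixture.values())
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("signature mixture fractions must be >= 0 and sum to 1")
        if self.burden_slope < 0:
            raise ValueError("burden slope must be >= 0")
        if not 0 <= self.platinum_fraction < 1:
            raise ValueError("platinum fraction must lie in [0, 1)")
        if not 0 <= self.arm_coupling <= 1:
            raise ValueError("arm coupling must lie in [0, 1]")


@dataclass
class GroundTruth:
    sample_id: str
    tumour_index: int
    age_months: float
    treated: bool
    mechanism: str
    exposures: dict  # signature -> true mixture fraction
    n_substitutions: int  # true somatic substitutions (post-filter expectation)
    n_indels: int
    n_rearrangements: int
    arm_gains: tuple
    arm_losses: tuple
    mycn_amplified: bool
    mycn_cn: int
    expected_biallelic: str
    snp_contaminant_keys: tuple
    low_vaf_keys: tuple


# ---------------------------------------------------------------------------
# low-level helpers

_BASES = "ACGT"


def _random_flanks(rng, ref):
    return _BASES[rng.integers(0, 4)] + ref + _BASES[rng.integers(0, 4)]


def _random_position(rng, karyotype: KaryotypeTable, chrom: str | None = None):
    """Uniform position over the (unmasked) arms of a random chromosome,
    weighted by chromosome length."""
    names = karyotype.names()
    if chrom is None:
        lengths = np.array([karyotype.chrom(n).length for n in names], dtype=float)
        chrom = names[rng.choice(len(names), p=lengths / lengths.sum())]
    c = karyotype.chrom(chrom)
    p_len = max(0, c.p_arm[1] - c.p_arm[0] + 1)
    q_len = max(0, c.q_arm[1] - c.q_arm[0] + 1)
    if rng.random() < p_len / (p_len + q_len):
        lo, hi = c.p_arm
    else:
        lo, hi = c.q_arm
    lo = max(lo, karyotype.telomere_mask + 1)
    hi = min(hi, c.length - karyotype.telomere_mask)
    return chrom, int(rng.integers(lo, hi + 1))


def _truncated_beta_vaf(rng, minimum: float = 0.2) -> float:
    """Clonal diploid VAF ~ Beta(8, 12) (mean 0.4), truncated at the
    stringent-filter threshold so ground-truth labels stay separable."""
    while True:
        v = float(rng.beta(8, 12))
        if v >= minimum:
            return round(v, 6)


def _low_vaf(rng) -> float:
    return round(float(rng.uniform(0.02, 0.195)), 6)


def _paint(segments: list, start: int, end: int, total: int, minor: int) -> list:
    """Paint [start, end] with (total, minor) over a sorted disjoint segment
    list of one chromosome, splitting whatever it overlaps."""
    out = []
    for s0, e0, t0, m0 in segments:
        if e0 < start or s0 > end:
            out.append((s0, e0, t0, m0))
            continue
        if s0 < start:
            out.append((s0, start - 1, t0, m0))
        if e0 > end:
            out.append((end + 1, e0, t0, m0))
    out.append((start, end, total, minor))
    return sorted(out)


class _GenomePainter:
    def __init__(self, karyotype: KaryotypeTable):
        self.karyotype = karyotype
        self.by_chrom = {
            name: [(1, karyotype.chrom(name).length, 2, 1)]
            for name in karyotype.names()
        }

    def paint(self, chrom: str, start: int, end: int, total: int, minor: int):
        self.by_chrom[chrom] = _paint(self.by_chrom[chrom], start, end, total, minor)

    def profile(self, sample_id: str) -> CopyNumberProfile:
        segments = []
        weighted = 0.0
        genome = 0.0
        for chrom in self.by_chrom:
            for s, e, t, m in self.by_chrom[chrom]:
                segments.append(CopyNumberSegment(chrom, s, e, t, m))
                weighted += t * (e - s + 1)
                genome += e - s + 1
        ploidy = round(weighted / genome, 4)
        return CopyNumberProfile(sample_id=sample_id, ploidy=ploidy, segments=segments)


# ---------------------------------------------------------------------------
# RB1 mechanism realisation


def realise_rb1_mechanism(
    mechanism: str,
    gene: GeneModel,
    seed,
    sample_id: str = "sample",
    karyotype: KaryotypeTable | None = None,
):
    """Realise one *RB1*-disruption mechanism.

    Returns ``(junctions, cn_patches, optional_snv)`` where ``cn_patches``
    is a list of ``(chrom, start, end, total_cn, minor_cn)`` to be painted
    over a diploid baseline.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if karyotype is None:
        karyotype = load_default_karyotype()
    if mechanism not in RB1_MECHANISMS:
        raise ValueError(f"unknown RB1 mechanism {mechanism!r}")
    ex = gene.exons
    chrom = gene.chrom
    junctions: list[SvJunction] = []
    patches: list[tuple] = []
    snv = None

    def intron_pos(i: int) -> int:
        lo, hi = ex[i - 1][1] + 1, ex[i][0] - 1
        return int(rng.integers(lo, hi + 1))

    def intra(pos1, pos2) -> SvJunction:
        a, b = sorted((int(pos1), int(pos2)))
        orient = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")][rng.integers(0, 4)]
        cls = {
            ("+", "-"): "deletion",
            ("-", "+"): "tandem_duplication",
            ("+", "+"): "inversion",
            ("-", "-"): "inversion",
        }[orient]
        return SvJunction(
            sample_id, Breakend(chrom, a, orient[0]), Breakend(chrom, b, orient[1]), cls
        )

    def transloc(pos13, partner_chrom, partner_pos) -> SvJunction:
        return SvJunction(
            sample_id,
            Breakend(chrom, int(pos13), "+-"[rng.integers(0, 2)]),
            Breakend(partner_chrom, int(partner_pos), "+-"[rng.integers(0, 2)]),
            "translocation",
        )

    if mechanism == "point_plus_loh":
        exon = ex[rng.integers(0, len(ex))]
        pos = int(rng.integers(exon[0], exon[1] + 1))
        ref = "C"
        alt = "T"
        consequence = ["nonsense", "frameshift", "essential_splice"][rng.integers(0, 3)]
        snv = SnvRecord(
            sample_id=sample_id,
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            vaf=_truncated_beta_vaf(rng),
            context=_random_flanks(rng, ref),
            gene=gene.symbol,
            consequence=consequence,
        )
        # copy-neutral LOH across the gene and 1 Mb of flank
        patches.append(
            (chrom, gene.gene_start - 1_000_000, gene.gene_end + 1_000_000, 2, 0)
        )

    elif mechanism == "intragenic_deletion":
        i = int(rng.integers(1, len(ex) - 5))
        j = i + int(rng.integers(0, 4))  # delete exons i..j (0-based)
        del_start = int(rng.integers(ex[i - 1][1] + 1, ex[i][0]))
        del_end = int(rng.integers(ex[j][1] + 1, ex[j + 1][0]))
        junctions.append(
            SvJunction(
                sample_id,
                Breakend(chrom, del_start, "+"),
                Breakend(chrom, del_end, "-"),
                "deletion",
            )
        )
        patches.append((chrom, del_start, del_end, 1, 0))

    elif mechanism == "simple_translocation":
        n = int(rng.integers(1, 3))
        partners = ["16", "18"]
        for k in range(n):
            partner = partners[k % 2]
            _, ppos = _random_position(rng, karyotype, partner)
            junctions.append(transloc(intron_pos(2), partner, ppos))

    elif mechanism == "complex_intra":
        k_in = int(rng.integers(3, 5))  # 3-4 breakends inside the gene
        n_total = int(rng.integers(7, 33))  # 14-64 breakends on chr13
        lo = max(karyotype.chrom(chrom).q_arm[0], gene.gene_start - 15_000_000)
        hi = min(karyotype.chrom(chrom).length - 100_000, gene.gene_end + 15_000_000)

        def outside_pos():
            while True:
                p = int(rng.integers(lo, hi + 1))
                if not (gene.gene_start <= p <= gene.gene_end):
                    return p

        for _ in range(k_in):
            gpos = int(rng.integers(gene.gene_start, gene.gene_end + 1))
            junctions.append(intra(gpos, outside_pos()))
        for _ in range(n_total - k_in):
            junctions.append(intra(outside_pos(), outside_pos()))

    elif mechanism == "complex_inter":
        partner = "2"
        k_in = int(rng.integers(2, 4))
        in_gene = [int(rng.integers(gene.gene_start, gene.gene_end + 1)) for _ in range(k_in)]
        for gpos in in_gene[:2]:
            _, ppos = _random_position(rng, karyotype, partner)
            junctions.append(transloc(gpos, partner, ppos))
        lo = gene.gene_start - 5_000_000
        hi = gene.gene_end + 5_000_000
        extra_in = in_gene[2:]  # possible third in-gene breakend via an intra junction
        for k in range(2):
            p1 = extra_in.pop() if extra_in else int(rng.integers(lo, gene.gene_start - 1))
            p2 = int(rng.integers(gene.gene_end + 1, hi))
            junctions.append(intra(p1, p2))

    elif mechanism == "chromothripsis_like":
        partners = ["8", "14"]
        q_start = karyotype.chrom(chrom).q_arm[0]
        ws = max(q_start + 1_000_000, gene.gene_start - 20_000_000)
        we = min(karyotype.chrom(chrom).length - 1_000_000, gene.gene_end + 20_000_000)
        # oscillating copy number: alternate between totals 2 and 3
        n_seg = 14
        cuts: set[int] = set()
        while len(cuts) < n_seg - 1:
            cuts.add(int(rng.integers(ws + 1, we)))
        bounds = [ws] + sorted(cuts) + [we]
        for k in range(n_seg):
            total = 3 if k % 2 == 0 else 2
            patches.append((chrom, bounds[k], bounds[k + 1] - 1, total, 1))
        # clustered intrachromosomal junctions, some transecting the gene
        k_in = int(rng.integers(2, 4))
        for _ in range(k_in):
            gpos = int(rng.integers(gene.gene_start, gene.gene_end + 1))
            junctions.append(intra(gpos, int(rng.integers(ws, we + 1))))
        for _ in range(18 - k_in):
            junctions.append(intra(int(rng.integers(ws, we + 1)), int(rng.integers(ws, we + 1))))
        for partner in partners:
            for _ in range(2):
                _, ppos = _random_position(rng, karyotype, partner)
                junctions.append(transloc(int(rng.integers(ws, we + 1)), partner, ppos))
            p1, p2 = sorted(
                int(_random_position(rng, karyotype, partner)[1]) for _ in range(2)
            )
            if p1 != p2:
                junctions.append(
                    SvJunction(
                        sample_id,
                        Breakend(partner, p1, "+"),
                        Breakend(partner, p2, "-"),
                        "deletion",
                    )
                )

    return junctions, patches, snv


_EXPECTED_BIALLELIC = {
    "point_plus_loh": "confirmed",
    "intragenic_deletion": "unresolved",
    "simple_translocation": "unresolved",
    "complex_intra": "unresolved",
    "complex_inter": "unresolved",
    "chromothripsis_like": "unresolved",
}


# ---------------------------------------------------------------------------
# per-tumour simulation


def _effective_mixture(config: SimulationConfig, treated: bool) -> dict:
    if not treated or config.platinum_fraction == 0:
        return dict(config.signature_mixture)
    f = config.platinum_fraction
    mix = {name: frac * (1 - f) for name, frac in config.signature_mixture.items()}
    mix[config.platinum_signature] = mix.get(config.platinum_signature, 0.0) + f
    return mix


def _draw_arm_events(rng, config: SimulationConfig):
    """Coupled arm gains: with probability ``arm_coupling`` one shared
    Bernoulli drives all gain arms (their probability averaged), otherwise
    the arms draw independently.  Coupling 1 makes the gains all-or-none."""
    gains = []
    arms = sorted(config.arm_gain_probabilities)
    probs = [config.arm_gain_probabilities[a] for a in arms]
    if rng.random() < config.arm_coupling:
        if rng.random() < float(np.mean(probs)):
            gains = list(arms)
    else:
        gains = [a for a, p in zip(arms, probs) if rng.random() < p]
    losses = [
        a
        for a in sorted(config.arm_loss_probabilities)
        if rng.random() < config.arm_loss_probabilities[a]
    ]
    return tuple(gains), tuple(losses)


def simulate_tumour(config: SimulationConfig, tumour_index: int):
    """Simulate one tumour: returns (snvs, indels, junctions, profile,
    ground_truth).  Deterministic given (config.seed, tumour_index)."""
    rng = np.random.default_rng([config.seed, tumour_index])
    karyotype = load_default_karyotype()
    signatures = load_default_signatures()
    snp_index = load_default_snp_index()
    rb1 = default_rb1_model()
    sample_id = f"RBSIM{tumour_index:03d}"
    snp_rows = list(snp_index)
    snp_sites = {(c, p) for c, p, _, _ in snp_rows}

    # --- per-tumour attributes (explicit config wins, else drawn)
    if config.ages_months is not None:
        age = float(config.ages_months[tumour_index])
    else:
        age = max(6.0, float(rng.normal(34.0, 16.0)))
    if config.treated is not None:
        treated = bool(config.treated[tumour_index])
    else:
        treated = config.n_tumours >= 10 and tumour_index == config.n_tumours - 1
    if config.rb1_mechanisms is not None:
        mechanism = config.rb1_mechanisms[tumour_index]
    else:
        mechs = list(_DEFAULT_MECHANISM_PROBS)
        mechanism = mechs[
            rng.choice(len(mechs), p=list(_DEFAULT_MECHANISM_PROBS.values()))
        ]
    if config.mycn_amplified is not None:
        mycn_amp = bool(config.mycn_amplified[tumour_index])
    else:
        mycn_amp = bool(rng.random() < 0.1)
    arm_gains, arm_losses = _draw_arm_events(rng, config)

    # --- substitutions from the signature mixture
    mixture = _effective_mixture(config, treated)
    expected = config.burden_intercept + config.burden_slope * age
    if treated and config.platinum_fraction > 0:
        expected = expected / (1.0 - config.platinum_fraction)
    n_sub = int(rng.poisson(expected))
    channel_probs = np.zeros(96)
    for name, frac in mixture.items():
        channel_probs += frac * signatures.column(name)
    channel_counts = rng.multinomial(n_sub, channel_probs)

    snvs: list[SnvRecord] = []
    used_positions = set()

    def place(chrom=None):
        # skip already-used positions and population-SNP sites so injected
        # contaminants are the only records the stringent filter removes
        while True:
            c, p = _random_position(rng, karyotype, chrom)
            if (c, p) not in used_positions and (c, p) not in snp_sites:
                used_positions.add((c, p))
                return c, p

    for ch_idx, count in enumerate(channel_counts):
        ref, alt, context = channel_mutation(CHANNELS_96[ch_idx])
        for _ in range(count):
            c, p = place()
            snvs.append(
                SnvRecord(
                    sample_id=sample_id,
                    chrom=c,
                    pos=p,
                    ref=ref,
                    alt=alt,
                    vaf=_truncated_beta_vaf(rng),
                    context=context,
                )
            )

    # optional UV-style CC>TT doublets (positive-control injection)
    for _ in range(config.n_uv_doublets):
        c, p = place()
        used_positions.add((c, p + 1))
        flank5 = _BASES[rng.integers(0, 4)]
        flank3 = _BASES[rng.integers(0, 4)]
        snvs.append(
            SnvRecord(sample_id, c, p, "C", "T", _truncated_beta_vaf(rng), f"{flank5}CC")
        )
        snvs.append(
            SnvRecord(sample_id, c, p + 1, "C", "T", _truncated_beta_vaf(rng), "CC" + flank3)
        )

    # --- RB1 mechanism
    junctions, patches, rb1_snv = realise_rb1_mechanism(
        mechanism, rb1, rng, sample_id=sample_id, karyotype=karyotype
    )
    if rb1_snv is not None:
        snvs.append(rb1_snv)

    n_true_sub = len(snvs)

    # --- contaminants
    leak_idx = rng.choice(len(snp_rows), size=config.n_snp_contaminants, replace=False)
    snp_keys = []
    for i in sorted(int(x) for x in leak_idx):
        c, p, ref, alt = snp_rows[i]
        snp_keys.append((c, p, ref, alt))
        snvs.append(
            SnvRecord(
                sample_id=sample_id,
                chrom=c,
                pos=p,
                ref=ref,
                alt=alt,
                vaf=_truncated_beta_vaf(rng),
                context=_random_flanks(rng, ref),
            )
        )
    low_vaf_keys = []
    for _ in range(config.n_low_vaf_artefacts):
        ch_idx = int(rng.integers(0, 96))
        ref, alt, context = channel_mutation(CHANNELS_96[ch_idx])
        c, p = place()
        r = SnvRecord(
            sample_id=sample_id,
            chrom=c,
            pos=p,
            ref=ref,
            alt=alt,
            vaf=_low_vaf(rng),
            context=context,
        )
        low_vaf_keys.append(r.key)
        snvs.append(r)

    snvs.sort(key=lambda r: (r.chrom, r.pos, r.alt))

    # --- indels
    n_indel = int(rng.poisson(config.indel_intercept + config.indel_slope * age))
    indels: list[IndelRecord] = []
    for _ in range(n_indel):
        c, p = place()
        anchor = _BASES[rng.integers(0, 4)]
        extra = "".join(_BASES[rng.integers(0, 4)] for _ in range(int(rng.integers(1, 6))))
        if rng.random() < 0.5:
            ref_allele, alt_allele = anchor + extra, anchor  # deletion
        else:
            ref_allele, alt_allele = anchor, anchor + extra  # insertion
        indels.append(
            IndelRecord(sample_id, c, p, ref_allele, alt_allele, consequence="other")
        )
    indels.sort(key=lambda r: (r.chrom, r.pos))

    # --- background rearrangements (kept off chromosome 13 so the locus
    # pattern label stays well defined)
    bg_chroms = [n for n in karyotype.names() if n != "13"]
    n_bg = int(rng.poisson(config.background_sv_mean))
    for _ in range(n_bg):
        if rng.random() < 0.2:
            c1, c2 = rng.choice(len(bg_chroms), size=2, replace=False)
            _, p1 = _random_position(rng, karyotype, bg_chroms[c1])
            _, p2 = _random_position(rng, karyotype, bg_chroms[c2])
            junctions.append(
                SvJunction(
                    sample_id,
                    Breakend(bg_chroms[c1], p1, "+-"[rng.integers(0, 2)]),
                    Breakend(bg_chroms[c2], p2, "+-"[rng.integers(0, 2)]),
                    "translocation",
                )
            )
        else:
            c = bg_chroms[rng.integers(0, len(bg_chroms))]
            _, p1 = _random_position(rng, karyotype, c)
            _, p2 = _random_position(rng, karyotype, c)
            if p1 == p2:
                continue
            a, b = sorted((p1, p2))
            orient = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")][rng.integers(0, 4)]
            cls = {
                ("+", "-"): "deletion",
                ("-", "+"): "tandem_duplication",
            }.get(orient, "inversion")
            junctions.append(
                SvJunction(
                    sample_id, Breakend(c, a, orient[0]), Breakend(c, b, orient[1]), cls
                )
            )

    # --- copy-number profile
    painter = _GenomePainter(karyotype)
    for arm in arm_gains:
        c, s, e = karyotype.arm_span(arm)
        painter.paint(c, s, e, 3, 1)
    for arm in arm_losses:
        c, s, e = karyotype.arm_span(arm)
        painter.paint(c, s, e, 1, 0)
    mycn_cn = 2
    if mycn_amp:
        mycn = next(g for g in load_default_gene_models() if g.symbol == "MYCN")
        mycn_cn = int(rng.integers(10, 200))
        painter.paint(
            mycn.chrom, mycn.gene_start - 50_000, mycn.gene_end + 50_000, mycn_cn, 1
        )
    for chrom, s, e, total, minor in patches:
        painter.paint(chrom, s, e, total, minor)
    profile = painter.profile(sample_id)

    truth = GroundTruth(
        sample_id=sample_id,
        tumour_index=tumour_index,
        age_months=round(age, 2),
        treated=treated,
        mechanism=mechanism,
        exposures={k: round(v, 6) for k, v in sorted(mixture.items())},
        n_substitutions=n_true_sub,
        n_indels=n_indel,
        n_rearrangements=len(junctions),
        arm_gains=arm_gains,
        arm_losses=arm_losses,
        mycn_amplified=mycn_amp,
        mycn_cn=mycn_cn,
        expected_biallelic=_EXPECTED_BIALLELIC[mechanism],
        snp_contaminant_keys=tuple(snp_keys),
        low_vaf_keys=tuple(low_vaf_keys),
    )
    return snvs, indels, junctions, profile, truth


# ---------------------------------------------------------------------------
# cohort on disk


def simulate_cohort(config: SimulationConfig, out_dir) -> list[GroundTruth]:
    """Write one file bundle per tumour plus cohort metadata and the
    ground-truth table.  Byte-identical across reruns with the same config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truths = []
    for i in range(config.n_tumours):
        snvs, indels, junctions, profile, truth = simulate_tumour(config, i)
        sid = truth.sample_id
        write_snv_vcf(snvs, out / f"{sid}.snv.vcf")
        write_indel_vcf(indels, out / f"{sid}.indel.vcf")
        write_bedpe(junctions, out / f"{sid}.sv.bedpe")
        write_segments(profile, out / f"{sid}.cn.tsv")
        truths.append(truth)

    with open(out / "cohort_metadata.tsv", "w") as fh:
        fh.write("sample\tage_months\ttreated\n")
        for t in truths:
            fh.write(f"{t.sample_id}\t{t.age_months:.2f}\t{int(t.treated)}\n")

    with open(out / "ground_truth.tsv", "w") as fh:
        fh.write(
            "tumour_id\tage_months\ttreated\tn_substitutions\tn_indels\t"
            "n_rearrangements\tmechanism\texposures\tarm_gains\tarm_losses\t"
            "mycn_amplified\tmycn_cn\texpected_biallelic\n"
        )
        for t in truths:
            exposures = ";".join(f"{k}:{v:.6f}" for k, v in t.exposures.items())
            fh.write(
                f"{t.sample_id}\t{t.age_months:.2f}\t{int(t.treated)}\t"
                f"{t.n_substitutions}\t{t.n_indels}\t{t.n_rearrangements}\t"
                f"{t.mechanism}\t{exposures}\t{';'.join(t.arm_gains)}\t"
                f"{';'.join(t.arm_losses)}\t{int(t.mycn_amplified)}\t{t.mycn_cn}\t"
                f"{t.expected_biallelic}\n"
            )
    return truths
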