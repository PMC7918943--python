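"""Structural-variant pattern classification at a target locus.

Rearrangements disrupting a tumour suppressor span a continuum of
complexity, from single balanced translocations that transect the gene
without any copy-number change, through clusters of intrachromosomal
junctions, to interchromosomal shatter patterns with oscillating copy
number (chromothripsis-like).  This module classifies that continuum,
quantifies breakend proximity to exon boundaries (which can explain
ambiguous probe-based clinical results), and resolves the per-allele
disruption status of the locus under the two-hit model.
"""

from __future__ import annotations

from dataclasses import dataclass

from .copy_number import is_wgd, loh_over_gene
from .io_formats import (
    Breakend,
    CopyNumberProfile,
    GeneModel,
    SnvRecord,
    TRUNCATING_CONSEQUENCES,
)
from .karyotype import KaryotypeTable

DEFAULT_MIN_BREAKPOINTS = 40
DEFAULT_MIN_SWITCHES = 10
DEFAULT_MAX_STATES = 3

PATTERNS = (
    "none",
    "simple",
    "complex_intrachromosomal",
    "complex_interchromosomal",
    "chromothripsis_like",
)

ALLELE_MECHANISMS = (
    "truncating_snv",
    "intragenic_deletion",
    "sv_transection",
    "loh",
    "not_detected",
)


def count_gene_breakends(junctions, gene: GeneModel) -> tuple[int, list[Breakend]]:
    """Breakends falling inside [gene_start, gene_end] on the gene's
    chromosome; a junction contributes up to two."""
    inside = [
        be
        for j in junctions
        for be in j.breakends
        if gene.contains(be.chrom, be.pos)
    ]
    return len(inside), inside


def breakend_exon_proximity(breakends, gene: GeneModel) -> list[tuple[int, int]]:
    """Per breakend: (nearest exon index, distance in bp).

    Distance is 0 inside an exon, otherwise base pairs to the nearest exon
    edge.  Exon indices are 0-based in genomic coordinate order.
    """
    out = []
    for be in breakends:
        best = None
        for i, (s, e) in enumerate(gene.exons):
            if s <= be.pos <= e:
                d = 0
            else:
                d = min(abs(be.pos - s), abs(be.pos - e))
            if best is None or d < best[1]:
                best = (i, d)
        if best is None:
            raise ValueError(f"{gene.symbol} has no exons")
        out.append(best)
    return out


@dataclass(frozen=True)
class ChromothripsisCall:
    chromosomes: frozenset
    n_breakpoints: int
    n_cn_state_switches: int
    n_distinct_cn_states: int
    verdict: bool


def _linked_chromosome_sets(junctions) -> list[set]:
    """Union-find of chromosomes linked by translocation junctions; every
    chromosome carrying a breakend appears in exactly one set."""
    parent: dict[str, str] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for j in junctions:
        find(j.breakend_a.chrom)
        find(j.breakend_b.chrom)
        if j.sv_class == "translocation":
            union(j.breakend_a.chrom, j.breakend_b.chrom)
    groups: dict[str, set] = {}
    for chrom in parent:
        groups.setdefault(find(chrom), set()).add(chrom)
    return sorted(groups.values(), key=lambda g: sorted(g))


def detect_chromothripsis_like(
    junctions,
    profile: CopyNumberProfile,
    karyotype: KaryotypeTable | None = None,
    min_breakpoints: int = DEFAULT_MIN_BREAKPOINTS,
    min_switches: int = DEFAULT_MIN_SWITCHES,
    max_states: int = DEFAULT_MAX_STATES,
) -> list[ChromothripsisCall]:
    """Chromothripsis-like calls per translocation-linked chromosome set.

    A set is positive when it carries >= ``min_breakpoints`` breakends, its
    ordered segments show >= ``min_switches`` adjacent total-copy-number
    switches, and those segments oscillate between <= ``max_states``
    distinct copy-number states.  Junction input order is irrelevant.
    """
    calls = []
    for chrom_set in _linked_chromosome_sets(junctions):
        n_breakends = sum(
            1
            for j in junctions
            for be in j.breakends
            if be.chrom in chrom_set
        )
        switches = 0
        states: set[int] = set()
        for chrom in sorted(chrom_set):
            segs = profile.segments_on(chrom)
            states.update(s.total_cn for s in segs)
            switches += sum(
                1 for a, b in zip(segs, segs[1:]) if a.total_cn != b.total_cn
            )
        verdict = (
            n_breakends >= min_breakpoints
            and switches >= min_switches
            and 0 < len(states) <= max_states
        )
        calls.append(
            ChromothripsisCall(
                chromosomes=frozenset(chrom_set),
                n_breakpoints=n_breakends,
                n_cn_state_switches=switches,
                n_distinct_cn_states=len(states),
                verdict=verdict,
            )
        )
    return calls


@dataclass(frozen=True)
class LocusRearrangementCall:
    sample_id: str
    gene: str
    n_breakends_in_gene: int
    n_junctions_on_chrom: int
    chromosomes_involved: frozenset
    pattern: str
    transected: bool

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if (self.pattern == "none") != (self.n_breakends_in_gene == 0):
            raise ValueError("pattern 'none' iff no in-gene breakends")


def classify_locus_rearrangement(
    junctions,
    profile: CopyNumberProfile,
    gene: GeneModel,
    chromothripsis_calls=None,
    sample_id: str | None = None,
) -> LocusRearrangementCall:
    """Classify the rearrangement pattern disrupting ``gene``.

    Precedence: chromothripsis-like (a positive call involving the gene's
    chromosome, with at least one in-gene breakend) > complex
    interchromosomal (>= 3 junctions touching the chromosome, >= 1 of them a
    translocation) > complex intrachromosomal (>= 3 junctions on the
    chromosome) > simple (1-2 junctions with an in-gene breakend) > none.
    """
    if chromothripsis_calls is None:
        chromothripsis_calls = detect_chromothripsis_like(junctions, profile)
    sid = sample_id
    if sid is None:
        sid = junctions[0].sample_id if junctions else profile.sample_id
    n_in_gene, _ = count_gene_breakends(junctions, gene)
    on_chrom = [
        j
        for j in junctions
        if gene.chrom in (j.breakend_a.chrom, j.breakend_b.chrom)
    ]
    chroms = frozenset(
        be.chrom for j in on_chrom for be in j.breakends
    )
    transected = n_in_gene >= 1

    pattern = "none"
    if n_in_gene >= 1:
        ct_positive = any(
            c.verdict and gene.chrom in c.chromosomes for c in chromothripsis_calls
        )
        has_translocation = any(j.sv_class == "translocation" for j in on_chrom)
        if ct_positive:
            pattern = "chromothripsis_like"
        elif len(on_chrom) >= 3 and has_translocation:
            pattern = "complex_interchromosomal"
        elif len(on_chrom) >= 3:
            pattern = "complex_intrachromosomal"
        else:
            pattern = "simple"
    return LocusRearrangementCall(
        sample_id=sid,
        gene=gene.symbol,
        n_breakends_in_gene=n_in_gene,
        n_junctions_on_chrom=len(on_chrom),
        chromosomes_involved=chroms,
        pattern=pattern,
        transected=transected,
    )


@dataclass(frozen=True)
class Rb1StatusCall:
    sample_id: str
    allele_1: str
    allele_2: str
    biallelic_status: str  # "confirmed" or "unresolved"

    def __post_init__(self):
        if self.allele_1 not in ALLELE_MECHANISMS or self.allele_2 not in ALLELE_MECHANISMS:
            raise ValueError("unknown allele mechanism")
        if self.biallelic_status not in ("confirmed", "unresolved"):
            raise ValueError(f"unknown biallelic status {self.biallelic_status!r}")
        if self.biallelic_status == "confirmed" and "not_detected" in (
            self.allele_1,
            self.allele_2,
        ):
            raise ValueError("confirmed status requires a mechanism on both alleles")


def _truncating_small_variants(snvs, indels, gene: GeneModel):
    hits = []
    for r in list(snvs) + list(indels):
        in_gene = gene.contains(r.chrom, r.pos) or (r.gene == gene.symbol)
        if in_gene and r.consequence in TRUNCATING_CONSEQUENCES:
            hits.append(r)
    return hits


def _intragenic_deletion(profile: CopyNumberProfile, gene: GeneModel) -> bool:
    """A copy-number drop whose footprint overlaps at least one exon.

    The drop baseline follows the large-scale gain rule's diploid/WGD split:
    total_cn < 2 in near-diploid genomes, < 4 with whole-genome duplication.
    Purely intronic copy-number noise does not count.
    """
    baseline = 4 if is_wgd(profile.ploidy) else 2
    for seg in profile.overlapping(gene.chrom, gene.gene_start, gene.gene_end):
        if seg.total_cn >= baseline:
            continue
        if any(seg.start <= e and seg.end >= s for s, e in gene.exons):
            return True
    return False


def resolve_rb1_status(
    snvs,
    indels,
    junctions,
    profile: CopyNumberProfile,
    gene: GeneModel,
    sample_id: str | None = None,
) -> Rb1StatusCall:
    """Resolve per-allele disruption of the locus under the two-hit model.

    Allele 1 takes the strongest positive finding (truncating small variant
    > intragenic deletion > SV transection).  Allele 2 is LOH when the whole
    footprint has minor copy number 0, else a second independent truncating
    small variant, else not detected.  Biallelic status is confirmed only
    when both alleles carry a positive mechanism; complex rearrangements
    without LOH honestly remain unresolved.
    """
    sid = sample_id or profile.sample_id
    truncating = _truncating_small_variants(snvs, indels, gene)
    n_breakends, _ = count_gene_breakends(junctions, gene)

    if truncating:
        allele_1 = "truncating_snv"
    elif _intragenic_deletion(profile, gene):
        allele_1 = "intragenic_deletion"
    elif n_breakends >= 1:
        allele_1 = "sv_transection"
    else:
        allele_1 = "not_detected"

    try:
        loh = loh_over_gene(profile, gene)
    except ValueError:
        loh = False
    if loh:
        allele_2 = "loh"
    elif len({r.key for r in truncating}) >= 2:
        allele_2 = "truncating_snv"
    else:
        allele_2 = "not_detected"

    confirmed = allele_1 != "not_detected" and allele_2 != "not_detected"
    return Rb1StatusCall(
        sample_id=sid,
        allele_1=allele_1,
        allele_2=allele_2,
        biallelic_status="confirmed" if confirmed else "unresolved",
    )
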