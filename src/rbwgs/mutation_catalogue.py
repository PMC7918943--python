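"""Stringent somatic SNV filtering and 96-channel catalogue construction.

Low-burden tumours are exquisitely sensitive to residual germline SNPs and
low-confidence calls, so before any signature analysis the SNV set is
filtered stringently: any variant whose (chrom, pos, ref, alt) key appears
in a population-SNP index is removed, as is any variant with VAF strictly
below 0.2.  The survivors are binned into the 96 pyrimidine-collapsed
trinucleotide channels.  Auxiliary UV statistics — dinucleotide (doublet)
substitutions and transcriptional strand bias — are computed here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.stats import binomtest

from ._channels import (
    CHANNEL_INDEX,
    CHANNELS_96,
    PYRIMIDINES,
    SUBSTITUTION_CLASSES,
    channel_of,
    reverse_complement,
)
from .io_formats import GeneModel, SnvRecord

DEFAULT_VAF_MIN = 0.2


class PopulationSnpIndex:
    """Allele-exact lookup of known population SNP sites."""

    def __init__(self, keys):
        self._keys = frozenset((str(c), int(p), str(r), str(a)) for c, p, r, a in keys)

    def __contains__(self, key) -> bool:
        return tuple(key) in self._keys

    def __len__(self) -> int:
        return len(self._keys)

    def __iter__(self):
        return iter(sorted(self._keys))

    @classmethod
    def from_tsv(cls, path) -> "PopulationSnpIndex":
        keys = []
        with open(path) as fh:
            header = fh.readline()
            assert header.split() == ["chrom", "pos", "ref", "alt"]
            for line in fh:
                c, p, r, a = line.split()
                keys.append((c, int(p), r, a))
        return cls(keys)


def load_default_snp_index() -> PopulationSnpIndex:
    """Bundled synthetic population-SNP fixture (stand-in for a 1000
    Genomes-derived site list)."""
    path = resources.files("rbwgs.data") / "population_snps_synthetic.tsv"
    with resources.as_file(path) as p:
        return PopulationSnpIndex.from_tsv(p)


@dataclass(frozen=True)
class RemovalRecord:
    record: SnvRecord
    reason: str  # "population_snp" or "low_vaf"


def stringent_filter(
    snvs, snp_index: PopulationSnpIndex, vaf_min: float = DEFAULT_VAF_MIN
) -> tuple[list[SnvRecord], list[RemovalRecord]]:
    """Remove population-SNP matches and sub-threshold-VAF calls.

    The VAF rule is strict: a record with VAF exactly ``vaf_min`` (default
    0.2) is retained.  Input order is preserved; the removal log records one
    reason per removed record (SNP-index membership takes precedence).
    """
    retained: list[SnvRecord] = []
    removed: list[RemovalRecord] = []
    for r in snvs:
        if r.key in snp_index:
            removed.append(RemovalRecord(r, "population_snp"))
        elif r.vaf < vaf_min:
            removed.append(RemovalRecord(r, "low_vaf"))
        else:
            retained.append(r)
    return retained, removed


@dataclass
class MutationalCatalogue:
    """96-channel substitution count vector for one sample."""

    sample_id: str
    counts: np.ndarray
    channel_order: tuple[str, ...] = CHANNELS_96

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (96,):
            raise ValueError(f"catalogue must have 96 channels, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative channel counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty catalogue has no frequencies")
        return self.counts / self.total

    def __getitem__(self, label: str) -> int:
        return int(self.counts[CHANNEL_INDEX[label]])


def build_catalogue(snvs, sample_id: str | None = None) -> MutationalCatalogue:
    """Bin SNVs into the 96 channels (purine refs reverse-complemented)."""
    counts = np.zeros(96, dtype=int)
    sid = sample_id
    for r in snvs:
        if sid is None:
            sid = r.sample_id
        try:
            label = channel_of(r.ref, r.alt, r.context)
        except ValueError as exc:
            raise ValueError(f"record {r.chrom}:{r.pos} ({r.ref}>{r.alt}): {exc}") from exc
        counts[CHANNEL_INDEX[label]] += 1
    return MutationalCatalogue(sample_id=sid or "unknown", counts=counts)


# ---------------------------------------------------------------------------
# doublet (dinucleotide) substitutions


@dataclass(frozen=True)
class DoubletEvent:
    chrom: str
    pos: int  # position of the 5' member
    ref_dinucleotide: str
    alt_dinucleotide: str
    dinucleotide_class: str  # canonical, e.g. "CC>TT"


def _canonical_dinucleotide(ref: str, alt: str) -> str:
    fwd = f"{ref}>{alt}"
    rev = f"{reverse_complement(ref)}>{reverse_complement(alt)}"
    return min(fwd, rev)


def detect_doublets(snvs) -> tuple[list[DoubletEvent], int]:
    """Find adjacent same-chromosome SNV pairs (|delta pos| = 1).

    Returns the doublet events plus the CC>TT count; CC>TT is counted on
    either strand, i.e. GG>AA pairs collapse onto it.
    """
    by_pos = sorted(snvs, key=lambda r: (r.chrom, r.pos))
    events = []
    for a, b in zip(by_pos, by_pos[1:]):
        if a.chrom == b.chrom and b.pos - a.pos == 1:
            cls = _canonical_dinucleotide(a.ref + b.ref, a.alt + b.alt)
            events.append(
                DoubletEvent(a.chrom, a.pos, a.ref + b.ref, a.alt + b.alt, cls)
            )
    cc_tt = sum(1 for e in events if e.dinucleotide_class == "CC>TT")
    return events, cc_tt


# ---------------------------------------------------------------------------
# transcriptional strand bias


@dataclass
class StrandBiasTable:
    """Per-substitution-class transcribed/untranscribed counts and binomial
    two-sided p-values (only mutations inside exactly one gene footprint
    contribute)."""

    counts: dict = field(default_factory=dict)  # class -> (transcribed, untranscribed)
    p_values: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)  # records spanning opposite-strand genes

    def total_on(self, which: str) -> int:
        idx = 0 if which == "transcribed" else 1
        return sum(v[idx] for v in self.counts.values())


def _pyrimidine_class(ref: str, alt: str) -> str:
    if ref in PYRIMIDINES:
        return f"{ref}>{alt}"
    return f"{reverse_complement(ref)}>{reverse_complement(alt)}"


def strand_bias(snvs, gene_models) -> StrandBiasTable:
    """Assign each genic SNV's pyrimidine to the transcribed or untranscribed
    strand and test each class against 0.5.

    The pyrimidine of the mutated pair sits on the reference (+) strand when
    ``ref`` is a pyrimidine.  If that strand matches the gene's coding
    strand the mutation is on the untranscribed strand; otherwise it is on
    the transcribed (template) strand.  SNVs overlapping two genes on
    opposite strands are excluded and logged.
    """
    table = StrandBiasTable(
        counts={cls: [0, 0] for cls in SUBSTITUTION_CLASSES}
    )
    for r in snvs:
        hits = [g for g in gene_models if g.contains(r.chrom, r.pos)]
        if not hits:
            continue
        strands = {g.strand for g in hits}
        if len(strands) > 1:
            table.excluded.append(r)
            continue
        gene_strand = strands.pop()
        pyr_strand = "+" if r.ref in PYRIMIDINES else "-"
        cls = _pyrimidine_class(r.ref, r.alt)
        if pyr_strand == gene_strand:
            table.counts[cls][1] += 1  # untranscribed (coding) strand
        else:
            table.counts[cls][0] += 1  # transcribed (template) strand
    for cls, (t, u) in table.counts.items():
        n = t + u
        table.counts[cls] = (t, u)
        table.p_values[cls] = (
            binomtest(t, n, 0.5, alternative="two-sided").pvalue if n else 1.0
        )
    return table
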