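"""On-disk formats and core domain types.

Internal coordinates are 1-based inclusive everywhere.  The only 0-based
half-open representation is BEDPE *on disk*: a breakend at internal
position ``pos`` is written as ``start = pos - 1, end = pos``.

Formats handled here:

* minimal somatic VCF (SNVs and indels) with INFO keys ``TNC`` (trinucleotide
  context), ``VAF``, ``GENE`` and ``CSQ``;
* 10-column BEDPE for rearrangement junctions;
* allele-specific copy-number segment TSV with a ``#ploidy=`` sidecar line;
* 96-row reference-signature TSV (COSMIC channel order);
* gene-model TSV carrying exon structure and gene role.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace

from cyvcf2 import VCF

from ._channels import CHANNELS_96, PYRIMIDINES

CONSEQUENCES = frozenset(
    {"synonymous", "missense", "nonsense", "essential_splice", "frameshift", "other"}
)
TRUNCATING_CONSEQUENCES = frozenset({"nonsense", "essential_splice", "frameshift"})

SV_CLASSES = ("deletion", "tandem_duplication", "inversion", "translocation")

GENE_ROLES = ("TSG", "oncogene", "other")

_VAF_DECIMALS = 6  # VAFs are carried to 6 decimals so VCF round trips exactly


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SnvRecord:
    """One somatic single-nucleotide variant."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    context: str
    gene: str | None = None
    consequence: str | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref equals alt ({self.ref})")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.chrom}:{self.pos}: not a single-base substitution")
        if len(self.context) != 3 or self.context[1] != self.ref:
            raise ValueError(
                f"{self.chrom}:{self.pos}: context {self.context!r} middle base "
                f"does not equal ref {self.ref!r}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"{self.chrom}:{self.pos}: VAF {self.vaf} outside [0, 1]")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class IndelRecord:
    """One somatic small insertion or deletion (no MNVs)."""

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str | None = None
    consequence: str | None = None

    def __post_init__(self):
        if len(self.ref_allele) == len(self.alt_allele):
            raise ValueError(
                f"{self.chrom}:{self.pos}: alleles of equal length are not an indel"
            )
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int
    orientation: str  # "+" or "-"

    def __post_init__(self):
        if self.orientation not in ("+", "-"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.pos < 1:
            raise ValueError(f"breakend position {self.pos} < 1")


@dataclass(frozen=True)
class SvJunction:
    """One rearrangement junction: two breakends plus a class label."""

    sample_id: str
    breakend_a: Breakend
    breakend_b: Breakend
    sv_class: str

    def __post_init__(self):
        if self.sv_class not in SV_CLASSES:
            raise ValueError(f"unknown sv_class {self.sv_class!r}")
        inter = self.breakend_a.chrom != self.breakend_b.chrom
        if inter != (self.sv_class == "translocation"):
            raise ValueError(
                "translocation class must coincide with differing chromosomes "
                f"({self.breakend_a.chrom} vs {self.breakend_b.chrom}, "
                f"{self.sv_class})"
            )
        if not inter and self.breakend_a.pos > self.breakend_b.pos:
            raise ValueError("intrachromosomal junction breakends not ordered")

    @property
    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.breakend_a, self.breakend_b)


@dataclass(frozen=True)
class CopyNumberSegment:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    total_cn: int
    minor_cn: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.chrom}: segment start {self.start} > end {self.end}")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError(f"{self.chrom}:{self.start}: negative copy number")
        # minor-allele definition: minor_cn cannot exceed half the total, rounded up
        if self.minor_cn > (self.total_cn + 1) // 2:
            raise ValueError(
                f"{self.chrom}:{self.start}: minor_cn {self.minor_cn} exceeds "
                f"ceil(total_cn/2) for total_cn {self.total_cn}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CopyNumberProfile:
    """Per-sample ASCAT-style ploidy plus allele-specific segments."""

    sample_id: str
    ploidy: float
    segments: list[CopyNumberSegment] = field(default_factory=list)

    def __post_init__(self):
        if self.ploidy <= 0:
            raise ValueError(f"ploidy {self.ploidy} must be positive")
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start))
        _check_no_overlap(self.segments)

    def segments_on(self, chrom: str) -> list[CopyNumberSegment]:
        return [s for s in self.segments if s.chrom == chrom]

    def overlapping(self, chrom: str, start: int, end: int) -> list[CopyNumberSegment]:
        return [
            s
            for s in self.segments
            if s.chrom == chrom and s.start <= end and s.end >= start
        ]


def _check_no_overlap(segments):
    offenders = []
    prev = None
    for seg in segments:
        if prev is not None and seg.chrom == prev.chrom and seg.start <= prev.end:
            offenders.append((prev, seg))
        prev = seg
    if offenders:
        desc = "; ".join(
            f"{a.chrom}:{a.start}-{a.end} overlaps {b.chrom}:{b.start}-{b.end}"
            for a, b in offenders
        )
        raise ValueError(f"overlapping copy-number segments: {desc}")


@dataclass(frozen=True)
class GeneModel:
    symbol: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...]
    role: str = "other"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.symbol}: unknown strand {self.strand!r}")
        if self.role not in GENE_ROLES:
            raise ValueError(f"{self.symbol}: unknown role {self.role!r}")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.symbol}: exon {s}-{e} reversed")
            if s < self.gene_start or e > self.gene_end:
                raise ValueError(f"{self.symbol}: exon {s}-{e} outside footprint")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.symbol}: exons overlap or are unsorted")
            prev_end = e

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.gene_start, self.gene_end)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.gene_start <= pos <= self.gene_end

    def intron(self, index: int) -> tuple[int, int]:
        """1-based intron index: intron i lies between exons i and i+1
        in genomic coordinate order."""
        a, b = self.exons[index - 1], self.exons[index]
        return (a[1] + 1, b[0] - 1)


@dataclass
class SignatureSet:
    """Reference mutational signatures: 96 x S column-stochastic matrix."""

    names: list[str]
    matrix: "object"  # numpy array, 96 x S
    channel_order: tuple[str, ...] = CHANNELS_96

    def __post_init__(self):
        import numpy as np

        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError(
                f"signature matrix shape {self.matrix.shape} != (96, {len(self.names)})"
            )
        if (self.matrix < 0).any():
            raise ValueError("signature matrix has negative entries")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"signature columns do not sum to 1: {sums}")

    def column(self, name: str):
        return self.matrix[:, self.names.index(name)]

    def subset(self, names) -> "SignatureSet":
        import numpy as np

        idx = [self.names.index(n) for n in names]
        return SignatureSet(list(names), np.asarray(self.matrix)[:, idx])


# ---------------------------------------------------------------------------
# minimal VCF dialect

def _vcf_header(records) -> str:
    contigs = "".join(
        f"##contig=<ID={c}>\n" for c in sorted({r.chrom for r in records})
    )
    return (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=TNC,Number=1,Type=String,Description="Trinucleotide reference context centred on POS">\n'
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">\n'
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n'
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n'
        + contigs
        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )


def _fetch_context(fasta, chrom: str, pos: int) -> str:
    seq = fasta[chrom][pos - 2 : pos + 1]  # pyfaidx is 0-based half-open
    return str(seq).upper()


def read_snv_vcf(path, sample_id: str, ref_fasta=None) -> list[SnvRecord]:
    """Read PASS SNVs from the minimal VCF dialect.

    Context comes from the ``TNC`` INFO key; when absent, it is derived from
    ``ref_fasta`` (a FASTA path opened with pyfaidx).  Multiallelic lines are
    split into one record per ALT.
    """
    fasta = None
    if ref_fasta is not None:
        from pyfaidx import Fasta

        fasta = Fasta(str(ref_fasta))
    records: list[SnvRecord] = []
    for v in VCF(str(path)):
        if v.FILTER is not None:  # None means PASS
            continue
        ref = v.REF
        if len(ref) != 1:
            continue
        alts = [a for a in v.ALT if len(a) == 1]
        if not alts:
            continue
        where = f"{v.CHROM}:{v.POS}"
        tnc = v.INFO.get("TNC")
        if tnc is None:
            if fasta is None:
                raise ValueError(
                    f"line {where}: no TNC INFO key and no reference FASTA supplied"
                )
            tnc = _fetch_context(fasta, v.CHROM, v.POS)
        vaf = v.INFO.get("VAF")
        if vaf is None:
            raise ValueError(f"line {where}: missing or malformed VAF")
        try:
            vaf = round(float(vaf), _VAF_DECIMALS)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"line {where}: malformed VAF {vaf!r}") from exc
        gene = v.INFO.get("GENE")
        csq = v.INFO.get("CSQ")
        for alt in alts:
            records.append(
                SnvRecord(
                    sample_id=sample_id,
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=ref,
                    alt=alt,
                    vaf=vaf,
                    context=str(tnc),
                    gene=gene,
                    consequence=csq,
                )
            )
    return records


def write_snv_vcf(records, path) -> None:
    with open(path, "w") as fh:
        fh.write(_vcf_header(records))
        for r in records:
            info = [f"TNC={r.context}", f"VAF={r.vaf:.6f}"]
            if r.gene is not None:
                info.append(f"GENE={r.gene}")
            if r.consequence is not None:
                info.append(f"CSQ={r.consequence}")
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{';'.join(info)}\n"
            )


def read_indel_vcf(path, sample_id: str) -> list[IndelRecord]:
    """Read PASS indels (alleles of unequal length) from the minimal dialect."""
    records: list[IndelRecord] = []
    for v in VCF(str(path)):
        if v.FILTER is not None:
            continue
        gene = v.INFO.get("GENE")
        csq = v.INFO.get("CSQ")
        for alt in v.ALT:
            if len(alt) == len(v.REF):
                continue
            records.append(
                IndelRecord(
                    sample_id=sample_id,
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref_allele=v.REF,
                    alt_allele=alt,
                    gene=gene,
                    consequence=csq,
                )
            )
    return records


def write_indel_vcf(records, path) -> None:
    with open(path, "w") as fh:
        fh.write(_vcf_header(records))
        for r in records:
            info = []
            if r.gene is not None:
                info.append(f"GENE={r.gene}")
            if r.consequence is not None:
                info.append(f"CSQ={r.consequence}")
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\tPASS\t"
                f"{';'.join(info) if info else '.'}\n"
            )


# ---------------------------------------------------------------------------
# BEDPE


def _infer_sv_class(chrom_a, orient_a, chrom_b, orient_b) -> str:
    if chrom_a != chrom_b:
        return "translocation"
    pair = (orient_a, orient_b)
    if pair == ("+", "-"):
        return "deletion"
    if pair == ("-", "+"):
        return "tandem_duplication"
    if pair in (("+", "+"), ("-", "-")):
        return "inversion"
    raise ValueError(f"unknown orientation pair {pair}")


def read_bedpe(path, sample_id: str) -> list[SvJunction]:
    """Read junctions from 10-column BEDPE (0-based half-open on disk).

    The name column carries the sv class when present; otherwise the class is
    inferred from chromosomes and orientations.  Interchromosomal junctions
    are translocations regardless of the name column.
    """
    junctions: list[SvJunction] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{path} line {ln}: expected 10 BEDPE columns")
            chrom1, start1, _, chrom2, start2, _, name, _, strand1, strand2 = f[:10]
            if strand1 not in ("+", "-") or strand2 not in ("+", "-"):
                raise ValueError(
                    f"{path} line {ln}: unknown orientation pair ({strand1}, {strand2})"
                )
            a = Breakend(chrom1, int(start1) + 1, strand1)
            b = Breakend(chrom2, int(start2) + 1, strand2)
            if a.chrom == b.chrom and a.pos > b.pos:
                a, b = b, a
            if a.chrom != b.chrom:
                sv_class = "translocation"
            elif name in SV_CLASSES and name != "translocation":
                sv_class = name
            else:
                sv_class = _infer_sv_class(a.chrom, a.orientation, b.chrom, b.orientation)
            junctions.append(SvJunction(sample_id, a, b, sv_class))
    return junctions


def write_bedpe(junctions, path) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            a, b = j.breakend_a, j.breakend_b
            fh.write(
                f"{a.chrom}\t{a.pos - 1}\t{a.pos}\t{b.chrom}\t{b.pos - 1}\t{b.pos}\t"
                f"{j.sv_class}\t.\t{a.orientation}\t{b.orientation}\n"
            )


# ---------------------------------------------------------------------------
# segments TSV

_SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "total_cn", "minor_cn"]


def read_segments(path) -> CopyNumberProfile:
    """Read one sample's allele-specific segments; ploidy from the
    ``#ploidy=<float>`` sidecar line."""
    ploidy = None
    rows = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for f in reader:
            if not f:
                continue
            if f[0].startswith("#ploidy="):
                ploidy = float(f[0].split("=", 1)[1])
                continue
            if header is None:
                header = f
                if header != _SEGMENT_COLUMNS:
                    raise ValueError(f"{path}: unexpected segment columns {header}")
                continue
            rows.append(f)
    if ploidy is None:
        raise ValueError(f"{path}: missing #ploidy= header line")
    sample_ids = {r[0] for r in rows}
    if len(sample_ids) > 1:
        raise ValueError(f"{path}: multiple sample ids {sorted(sample_ids)}")
    sample_id = rows[0][0] if rows else os.path.basename(str(path)).split(".")[0]
    segments = [
        CopyNumberSegment(r[1], int(r[2]), int(r[3]), int(r[4]), int(r[5])) for r in rows
    ]
    return CopyNumberProfile(sample_id=sample_id, ploidy=ploidy, segments=segments)


def write_segments(profile: CopyNumberProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#ploidy={profile.ploidy:.4f}\n")
        fh.write("\t".join(_SEGMENT_COLUMNS) + "\n")
        for s in profile.segments:
            fh.write(
                f"{profile.sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t"
                f"{s.total_cn}\t{s.minor_cn}\n"
            )


# ---------------------------------------------------------------------------
# signatures TSV


def read_signatures(path) -> SignatureSet:
    """Read a 96 x S signature table; columns are renormalised when their sums
    lie within 1e-3 of 1, otherwise an error is raised."""
    import numpy as np
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    if sorted(df.index) != sorted(CHANNELS_96):
        raise ValueError(f"{path}: row labels are not the 96 COSMIC channels")
    df = df.loc[list(CHANNELS_96)]
    matrix = df.to_numpy(dtype=float)
    sums = matrix.sum(axis=0)
    bad = [n for n, s in zip(df.columns, sums) if abs(s - 1.0) > 1e-3]
    if bad:
        raise ValueError(f"{path}: signature columns not summing to 1: {bad}")
    matrix = matrix / sums
    return SignatureSet(names=list(df.columns), matrix=matrix)


def write_signatures(sigset: SignatureSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("channel\t" + "\t".join(sigset.names) + "\n")
        for i, label in enumerate(CHANNELS_96):
            vals = "\t".join(f"{sigset.matrix[i, j]:.8f}" for j in range(len(sigset.names)))
            fh.write(f"{label}\t{vals}\n")


# ---------------------------------------------------------------------------
# gene models TSV

_GENE_COLUMNS = ["symbol", "chrom", "strand", "start", "end", "role", "exons"]


def read_gene_models(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            exons = tuple(
                tuple(int(x) for x in part.split("-"))
                for part in row["exons"].split(";")
                if part
            )
            genes.append(
                GeneModel(
                    symbol=row["symbol"],
                    chrom=row["chrom"],
                    strand=row["strand"],
                    gene_start=int(row["start"]),
                    gene_end=int(row["end"]),
                    exons=exons,
                    role=row["role"],
                )
            )
    return genes


def write_gene_models(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            exons = ";".join(f"{s}-{e}" for s, e in g.exons)
            fh.write(
                f"{g.symbol}\t{g.chrom}\t{g.strand}\t{g.gene_start}\t{g.gene_end}\t"
                f"{g.role}\t{exons}\n"
            )


def reverse_complement_record(record: SnvRecord) -> SnvRecord:
    """Strand-flip an SNV (ref, alt and context reverse-complemented)."""
    from ._channels import reverse_complement

    return replace(
        record,
        ref=reverse_complement(record.ref),
        alt=reverse_complement(record.alt),
        context=reverse_complement(record.context),
    )
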