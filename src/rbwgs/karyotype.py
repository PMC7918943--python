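"""Coordinate-only genome model: chromosome lengths, centromeres, arms.

All analyses in this package are coordinate- and context-based, so the genome
is represented purely as a GRCh37-style karyotype table (no sequence).  Arms
tile each chromosome minus the centromere; a fixed telomere mask is clipped
off both chromosome ends when arm coverage is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

DEFAULT_TELOMERE_MASK = 10_000  # bp masked at each chromosome end


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere_start: int
    centromere_end: int

    @property
    def p_arm(self) -> tuple[int, int]:
        return (1, self.centromere_start - 1)

    @property
    def q_arm(self) -> tuple[int, int]:
        return (self.centromere_end + 1, self.length)


@dataclass(frozen=True)
class KaryotypeTable:
    chromosomes: dict
    telomere_mask: int = DEFAULT_TELOMERE_MASK

    def chrom(self, name: str) -> Chromosome:
        return self.chromosomes[name]

    def names(self) -> list[str]:
        return list(self.chromosomes)

    def arm_span(self, arm: str) -> tuple[str, int, int]:
        """Arm label like "13q" -> (chrom, start, end)."""
        chrom_name, which = arm[:-1], arm[-1]
        c = self.chrom(chrom_name)
        span = c.p_arm if which == "p" else c.q_arm
        return (chrom_name, span[0], span[1])

    def unmasked_arm_span(self, arm: str) -> tuple[str, int, int]:
        """Arm span with the chromosome-end telomere mask clipped off."""
        chrom_name, start, end = self.arm_span(arm)
        c = self.chrom(chrom_name)
        if start == 1:
            start = 1 + self.telomere_mask
        if end == c.length:
            end = c.length - self.telomere_mask
        return (chrom_name, start, end)

    def arm_of(self, chrom: str, pos: int) -> str | None:
        c = self.chrom(chrom)
        if pos < c.centromere_start:
            return f"{chrom}p"
        if pos > c.centromere_end:
            return f"{chrom}q"
        return None  # centromeric

    def arms(self) -> list[str]:
        out = []
        for name, c in self.chromosomes.items():
            if c.p_arm[1] >= c.p_arm[0]:
                out.append(f"{name}p")
            out.append(f"{name}q")
        return out

    def masked_regions(self, chrom: str) -> list[tuple[int, int]]:
        """Telomere and centromere spans excluded from large-scale calls."""
        c = self.chrom(chrom)
        return [
            (1, self.telomere_mask),
            (c.centromere_start, c.centromere_end),
            (c.length - self.telomere_mask + 1, c.length),
        ]


def load_default_karyotype() -> KaryotypeTable:
    """Bundled GRCh37-style karyotype (synthetic stand-in table with
    approximate chromosome lengths and centromere spans)."""
    path = resources.files("rbwgs.data") / "karyotype_grch37_synthetic.tsv"
    chroms = {}
    with path.open() as fh:
        header = fh.readline()
        assert header.startswith("chrom")
        for line in fh:
            name, length, cen_start, cen_end = line.split()
            chroms[name] = Chromosome(name, int(length), int(cen_start), int(cen_end))
    return KaryotypeTable(chromosomes=chroms)
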