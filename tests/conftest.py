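import numpy as np
import pytest

from rbwgs.io_formats import Breakend, SnvRecord, SvJunction
from rbwgs.karyotype import load_default_karyotype
from rbwgs.mutation_catalogue import load_default_snp_index
from rbwgs.synthetic_cohort import (
    default_rb1_model,
    load_default_gene_models,
    load_default_signatures,
)


@pytest.fixture(scope="session")
def karyotype():
    return load_default_karyotype()


@pytest.fixture(scope="session")
def signatures():
    return load_default_signatures()


@pytest.fixture(scope="session")
def gene_models():
    return load_default_gene_models()


@pytest.fixture(scope="session")
def rb1(gene_models):
    return next(g for g in gene_models if g.symbol == "RB1")


@pytest.fixture(scope="session")
def snp_index():
    return load_default_snp_index()


def make_snv(
    chrom="13",
    pos=48_878_000,
    ref="C",
    alt="T",
    vaf=0.45,
    context=None,
    sample_id="S1",
    gene=None,
    consequence=None,
):
    if context is None:
        context = f"A{ref}A"
    return SnvRecord(
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        vaf=vaf,
        context=context,
        gene=gene,
        consequence=consequence,
    )


def make_junction(chrom_a, pos_a, orient_a, chrom_b, pos_b, orient_b, sv_class, sample_id="S1"):
    return SvJunction(
        sample_id,
        Breakend(chrom_a, pos_a, orient_a),
        Breakend(chrom_b, pos_b, orient_b),
        sv_class,
    )


def random_junctions(rng, n, karyotype, sample_id="S1"):
    """Random valid junctions across the genome (for round-trip and oracle tests)."""
    names = karyotype.names()
    out = []
    while len(out) < n:
        if rng.random() < 0.3:
            i, j = rng.choice(len(names), size=2, replace=False)
            out.append(
                make_junction(
                    names[i],
                    int(rng.integers(1_000_000, karyotype.chrom(names[i]).length - 1_000_000)),
                    "+-"[rng.integers(0, 2)],
                    names[j],
                    int(rng.integers(1_000_000, karyotype.chrom(names[j]).length - 1_000_000)),
                    "+-"[rng.integers(0, 2)],
                    "translocation",
                    sample_id,
                )
            )
        else:
            c = names[rng.integers(0, len(names))]
            p1, p2 = sorted(
                int(rng.integers(1_000_000, karyotype.chrom(c).length - 1_000_000))
                for _ in range(2)
            )
            if p1 == p2:
                continue
            orient = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")][rng.integers(0, 4)]
            cls = {("+", "-"): "deletion", ("-", "+"): "tandem_duplication"}.get(
                orient, "inversion"
            )
            out.append(make_junction(c, p1, orient[0], c, p2, orient[1], cls, sample_id))
    return out
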