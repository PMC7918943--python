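"""Cohort-level statistics, driver annotation and the pipeline runner.

Covers mutation burden and per-megabase densities, ordinary least-squares
regression of burden on age at enucleation (treatment-naive samples only),
the bilateral-tumour independence check (shared somatic mutations between
the two eyes of one patient), Cancer-Gene-Census-style driver rules, and
``run_pipeline`` which chains every stage over a cohort directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .copy_number import (
    call_arm_events,
    classify_amplification,
    cooccurrence_summary,
    focal_amplification_fold,
)
from .io_formats import (
    CopyNumberProfile,
    TRUNCATING_CONSEQUENCES,
    read_bedpe,
    read_indel_vcf,
    read_segments,
    read_snv_vcf,
)
from .karyotype import load_default_karyotype
from .mutation_catalogue import (
    build_catalogue,
    detect_doublets,
    load_default_snp_index,
    strand_bias,
    stringent_filter,
)
from .rearrangements import (
    classify_locus_rearrangement,
    detect_chromothripsis_like,
    resolve_rb1_status,
)
from .signature_fitting import fit_with_bootstrap
from .synthetic_cohort import load_default_gene_models, load_default_signatures

logger = logging.getLogger("rbwgs")

DEFAULT_GENOME_SIZE_MB = 3235.0  # callable genome implied by 275 subs ~ 0.085/Mb


@dataclass
class BurdenSummary:
    per_sample: pd.DataFrame  # sample, n_substitutions, n_indels, n_rearrangements
    genome_size_mb: float

    @property
    def cohort_means(self) -> dict:
        return {
            c: float(self.per_sample[c].mean())
            for c in ("n_substitutions", "n_indels", "n_rearrangements")
        }

    @property
    def cohort_ranges(self) -> dict:
        return {
            c: (int(self.per_sample[c].min()), int(self.per_sample[c].max()))
            for c in ("n_substitutions", "n_indels", "n_rearrangements")
        }

    def density(self, which: str) -> float:
        """Cohort mean density per Mb, rounded to 3 decimals for reports."""
        return round(self.cohort_means[which] / self.genome_size_mb, 3)


def burden_summary(
    call_sets: dict, genome_size_mb: float = DEFAULT_GENOME_SIZE_MB
) -> BurdenSummary:
    """``call_sets`` maps sample_id -> (snvs, indels, junctions)."""
    rows = []
    for sample_id, (snvs, indels, junctions) in call_sets.items():
        rows.append(
            {
                "sample": sample_id,
                "n_substitutions": len(snvs),
                "n_indels": len(indels),
                "n_rearrangements": len(junctions),
            }
        )
    df = pd.DataFrame(rows, columns=["sample", "n_substitutions", "n_indels", "n_rearrangements"])
    return BurdenSummary(per_sample=df, genome_size_mb=genome_size_mb)


@dataclass(frozen=True)
class AgeRegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    slope_ci: tuple


def age_regression(
    burdens: dict, ages_months: dict, exclude_ids=()
) -> AgeRegressionResult:
    """OLS of substitution burden on age at enucleation.

    Treated samples are passed through ``exclude_ids`` (mirroring the
    treatment-naive restriction); outliers are never removed automatically.
    """
    ids = [s for s in burdens if s not in set(exclude_ids)]
    if len(ids) < 3:
        raise ValueError(f"age regression needs >= 3 samples, got {len(ids)}")
    y = np.array([burdens[s] for s in ids], dtype=float)
    x = np.array([ages_months[s] for s in ids], dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return AgeRegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=len(ids),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
    )


@dataclass(frozen=True)
class BilateralOverlap:
    n_shared_snvs: int
    n_shared_indels: int
    n_shared_junctions: int
    verdict: str  # "independent" or "shared origin"


def _junction_signature(j):
    a, b = j.breakend_a, j.breakend_b
    return tuple(sorted([(a.chrom, a.pos), (b.chrom, b.pos)]))


def _shared_junctions(left, right, tolerance: int) -> int:
    right_sigs = [_junction_signature(j) for j in right]
    shared = 0
    for j in left:
        (ca, pa), (cb, pb) = _junction_signature(j)
        for (rca, rpa), (rcb, rpb) in right_sigs:
            if (
                ca == rca
                and cb == rcb
                and abs(pa - rpa) <= tolerance
                and abs(pb - rpb) <= tolerance
            ):
                shared += 1
                break
    return shared


def bilateral_overlap(calls_left, calls_right, junction_tolerance: int = 10):
    """Count somatic calls shared between two tumours of one patient.

    Small variants share by exact (chrom, pos, ref, alt) keys; junctions by
    both breakends lying within ``junction_tolerance`` bp.  Verdict is
    "independent" iff nothing is shared in any class.
    """
    snvs_l, indels_l, junc_l = calls_left
    snvs_r, indels_r, junc_r = calls_right
    shared_snvs = len({r.key for r in snvs_l} & {r.key for r in snvs_r})
    shared_indels = len({r.key for r in indels_l} & {r.key for r in indels_r})
    shared_junc = _shared_junctions(junc_l, junc_r, junction_tolerance)
    independent = shared_snvs == 0 and shared_indels == 0 and shared_junc == 0
    return BilateralOverlap(
        n_shared_snvs=shared_snvs,
        n_shared_indels=shared_indels,
        n_shared_junctions=shared_junc,
        verdict="independent" if independent else "shared origin",
    )


# ---------------------------------------------------------------------------
# driver annotation


@dataclass
class DriverKnowledge:
    """Census gene roles plus a (gene, variant key) -> occurrence lookup."""

    roles: dict  # gene -> role ("TSG" / "oncogene" / "other")
    recurrence: dict = field(default_factory=dict)

    @classmethod
    def from_fixtures(cls, gene_models, recurrence_path) -> "DriverKnowledge":
        roles = {g.symbol: g.role for g in gene_models}
        rec = {}
        with open(recurrence_path) as fh:
            header = fh.readline()
            assert header.split() == ["gene", "variant_key", "count"]
            for line in fh:
                gene, key, count = line.split()
                rec[(gene, key)] = int(count)
        return cls(roles=roles, recurrence=rec)


def load_default_knowledge() -> DriverKnowledge:
    """Census roles from the bundled gene models plus the synthetic
    COSMIC-style recurrence fixture."""
    path = resources.files("rbwgs.data") / "cosmic_recurrence_synthetic.tsv"
    with resources.as_file(path) as p:
        return DriverKnowledge.from_fixtures(load_default_gene_models(), p)


@dataclass(frozen=True)
class DriverCall:
    sample_id: str
    gene: str
    variant: str
    rule_fired: str  # cosmic_recurrent | truncating_in_tsg | focal_amplification | homozygous_deletion
    evidence: str


def annotate_drivers(
    small_variants,
    profile: CopyNumberProfile | None,
    knowledge: DriverKnowledge,
    gene_models=None,
    min_recurrence: int = 2,
) -> list[DriverCall]:
    """Apply the driver rules to one sample's calls.

    * ``cosmic_recurrent``: the exact variant recurs >= ``min_recurrence``
      times in the recurrence lookup;
    * ``truncating_in_tsg``: premature truncation (nonsense, essential
      splice, frameshift) in a census tumour suppressor;
    * ``focal_amplification`` / ``homozygous_deletion``: copy-number
      drivers over census genes (ploidy-aware amplification rule; total
      copy number 0 for homozygous deletion).

    A variant may fire several rules, yielding one call each.  Variants in
    genes absent from the census are skipped with a logged warning.
    """
    calls: list[DriverCall] = []
    for r in small_variants:
        if r.gene is None:
            continue
        if r.gene not in knowledge.roles:
            logger.warning("unknown gene symbol %s ignored", r.gene)
            continue
        key = ":".join(str(k) for k in r.key)
        desc = f"{r.chrom}:{r.pos} {r.key[2]}>{r.key[3]}"
        count = knowledge.recurrence.get((r.gene, key), 0)
        if count >= min_recurrence:
            calls.append(
                DriverCall(
                    r.sample_id,
                    r.gene,
                    desc,
                    "cosmic_recurrent",
                    f"variant seen {count} times",
                )
            )
        if (
            r.consequence in TRUNCATING_CONSEQUENCES
            and knowledge.roles.get(r.gene) == "TSG"
        ):
            calls.append(
                DriverCall(
                    r.sample_id,
                    r.gene,
                    desc,
                    "truncating_in_tsg",
                    f"{r.consequence} in tumour suppressor",
                )
            )
    if profile is not None and gene_models:
        for gene in gene_models:
            if gene.symbol not in knowledge.roles:
                continue
            segs = profile.overlapping(gene.chrom, gene.gene_start, gene.gene_end)
            if not segs:
                continue
            fold, amplified = focal_amplification_fold(profile, gene)
            if amplified:
                calls.append(
                    DriverCall(
                        profile.sample_id,
                        gene.symbol,
                        f"{gene.chrom}:{gene.gene_start}-{gene.gene_end}",
                        "focal_amplification",
                        f"total_cn {fold} at ploidy {profile.ploidy}",
                    )
                )
            if any(s.total_cn == 0 for s in segs):
                calls.append(
                    DriverCall(
                        profile.sample_id,
                        gene.symbol,
                        f"{gene.chrom}:{gene.gene_start}-{gene.gene_end}",
                        "homozygous_deletion",
                        "segment with total_cn 0",
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# pipeline runner


def _load_sample(cohort_dir: Path, sample_id: str):
    paths = {
        "snv": cohort_dir / f"{sample_id}.snv.vcf",
        "indel": cohort_dir / f"{sample_id}.indel.vcf",
        "sv": cohort_dir / f"{sample_id}.sv.bedpe",
        "cn": cohort_dir / f"{sample_id}.cn.tsv",
    }
    for kind, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"sample {sample_id}: missing {kind} file {p}")
    return (
        read_snv_vcf(paths["snv"], sample_id),
        read_indel_vcf(paths["indel"], sample_id),
        read_bedpe(paths["sv"], sample_id),
        read_segments(paths["cn"]),
    )


def run_pipeline(cohort_dir, out_dir, seed: int = 0, config: dict | None = None) -> dict:
    """Filter -> catalogue -> fit -> CNA -> locus classification -> RB1
    status -> drivers -> cohort statistics, over every sample in
    ``cohort_dir`` (discovered via cohort_metadata.tsv or ``*.snv.vcf``).

    Writes per-sample and cohort TSV/JSON reports into ``out_dir`` and
    returns the cohort summary dict.
    """
    config = dict(config or {})
    genome_size_mb = float(config.get("genome_size_mb", DEFAULT_GENOME_SIZE_MB))
    vaf_min = float(config.get("vaf_min", 0.2))
    n_boot = int(config.get("n_boot", 100))
    cohort_dir = Path(cohort_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    meta_path = cohort_dir / "cohort_metadata.tsv"
    ages, treated = {}, {}
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype={"sample": str})
        ages = dict(zip(meta["sample"], meta["age_months"]))
        treated = dict(zip(meta["sample"], meta["treated"].astype(bool)))
        sample_ids = list(meta["sample"])
    else:
        sample_ids = sorted(p.name[: -len(".snv.vcf")] for p in cohort_dir.glob("*.snv.vcf"))
    if not sample_ids:
        raise FileNotFoundError(f"no samples found in {cohort_dir}")

    karyotype = load_default_karyotype()
    signatures = load_default_signatures()
    snp_index = load_default_snp_index()
    gene_models = load_default_gene_models()
    knowledge = load_default_knowledge()
    rb1 = next(g for g in gene_models if g.symbol == "RB1")

    sample_rows = []
    call_sets = {}
    arm_calls = {}
    fit_rows = []
    driver_rows = []
    for i, sid in enumerate(sample_ids):
        snvs, indels, junctions, profile = _load_sample(cohort_dir, sid)
        retained, removed = stringent_filter(snvs, snp_index, vaf_min=vaf_min)
        call_sets[sid] = (retained, indels, junctions)
        catalogue = build_catalogue(retained, sample_id=sid)
        fit = fit_with_bootstrap(
            catalogue, signatures, n_boot=n_boot, seed=seed * 100_003 + i
        )
        doublets, cc_tt = detect_doublets(retained)
        bias = strand_bias(retained, gene_models)
        arm_calls[sid] = call_arm_events(profile, karyotype)
        ct_calls = detect_chromothripsis_like(junctions, profile, karyotype)
        locus = classify_locus_rearrangement(junctions, profile, rb1, ct_calls, sample_id=sid)
        status = resolve_rb1_status(retained, indels, junctions, profile, rb1, sample_id=sid)
        drivers = annotate_drivers(
            list(retained) + list(indels), profile, knowledge, gene_models
        )
        driver_rows += [
            {
                "sample": sid,
                "gene": d.gene,
                "variant": d.variant,
                "rule": d.rule_fired,
                "evidence": d.evidence,
            }
            for d in drivers
        ]
        for name in signatures.names:
            fit_rows.append(
                {
                    "sample": sid,
                    "signature": name,
                    "exposure_count": round(fit.exposures[name], 2),
                    "fraction": round(fit.fraction(name), 4),
                    "presence_probability": fit.bootstrap_presence[name],
                }
            )
        sample_rows.append(
            {
                "sample": sid,
                "n_snvs_raw": len(snvs),
                "n_snvs_retained": len(retained),
                "n_removed_population_snp": sum(
                    1 for r in removed if r.reason == "population_snp"
                ),
                "n_removed_low_vaf": sum(1 for r in removed if r.reason == "low_vaf"),
                "n_indels": len(indels),
                "n_rearrangements": len(junctions),
                "ploidy": profile.ploidy,
                "cc_tt_doublets": cc_tt,
                "rb1_pattern": locus.pattern,
                "rb1_breakends": locus.n_breakends_in_gene,
                "rb1_allele_1": status.allele_1,
                "rb1_allele_2": status.allele_2,
                "rb1_biallelic": status.biallelic_status,
            }
        )

    per_sample = pd.DataFrame(sample_rows)
    per_sample.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    pd.DataFrame(fit_rows).to_csv(out_dir / "signature_fits.tsv", sep="\t", index=False)
    pd.DataFrame(
        driver_rows, columns=["sample", "gene", "variant", "rule", "evidence"]
    ).to_csv(out_dir / "drivers.tsv", sep="\t", index=False)

    burden = burden_summary(call_sets, genome_size_mb=genome_size_mb)
    cooc = cooccurrence_summary(arm_calls)
    summary = {
        "n_samples": len(sample_ids),
        "burden_means": burden.cohort_means,
        "burden_ranges": {k: list(v) for k, v in burden.cohort_ranges.items()},
        "densities_per_mb": {
            k: burden.density(k)
            for k in ("n_substitutions", "n_indels", "n_rearrangements")
        },
        "arm_cooccurrence": cooc,
        "rb1_biallelic_confirmed": int(
            (per_sample["rb1_biallelic"] == "confirmed").sum()
        ),
    }
    if ages:
        naive = [s for s in sample_ids if not treated.get(s, False)]
        if len(naive) >= 3:
            burdens = dict(
                zip(per_sample["sample"], per_sample["n_snvs_retained"].astype(float))
            )
            reg = age_regression(
                burdens, ages, exclude_ids=[s for s in sample_ids if s not in naive]
            )
            summary["age_regression"] = {
                "slope": reg.slope,
                "intercept": reg.intercept,
                "r_squared": reg.r_squared,
                "p_value": reg.p_value,
                "n": reg.n,
            }
    with open(out_dir / "cohort_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %d samples -> %s", len(sample_ids), out_dir)
    return summary
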