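# Methods

This note documents the models, rules and numerical choices behind `rbwgs`,
what the synthetic cohort does and does not emulate, and the package's known
limitations.

## Scope and data model

The package operates strictly downstream of variant calling: it consumes
per-sample somatic SNV/indel calls (a minimal VCF dialect carrying the
trinucleotide context and VAF in INFO keys), rearrangement junctions (BEDPE),
and integer allele-specific copy-number segments with an ASCAT-style
genome-average ploidy. Read alignment, variant calling and copy-number
segmentation are out of scope. Internal coordinates are 1-based inclusive
everywhere; only BEDPE on disk is 0-based half-open. Trinucleotide context
travels in the VCF (`TNC=`), so no reference genome is required; an optional
FASTA enables context derivation for externally produced calls.

## Stringent somatic filtering

Low-burden tumours make even slight germline-SNP leak-through or artefactual
calls a large relative contamination. The filter removes an SNV when

1. its (chrom, pos, ref, alt) key appears in a population-SNP index
   (allele-exact matching — a deliberate choice; position-only matching would
   also discard genuine somatic hits at polymorphic sites), or
2. its VAF is strictly below 0.2 (a record at exactly 0.2 is retained).

Filtering is idempotent and order-preserving, and each removal is logged with
its reason. The bundled population-SNP index is a synthetic 300-site fixture
standing in for a 1000-Genomes-derived list; real analyses should substitute
their own table.

## Mutational catalogues and auxiliary UV statistics

Substitutions are binned into the 96 COSMIC channels: six pyrimidine classes
(C>A, C>G, C>T, T>A, T>C, T>G) by 16 flanking-base contexts, ordered 5' then
3' alphabetically; purine-reference records are reverse-complemented first.
Doublets are adjacent same-chromosome SNV pairs (|Δpos| = 1), reported by
canonical dinucleotide class with CC>TT counted on either strand (GG>AA
collapses onto it); doublet members remain in the 96-channel catalogue as two
single events. Transcriptional strand bias assigns the pyrimidine of each
genic mutation to the transcribed or untranscribed strand by comparing the
pyrimidine's strand to the gene's coding strand, and tests each class against
0.5 with a two-sided exact binomial test; SNVs overlapping genes on both
strands are excluded and logged.

## Signature fitting and bootstrap presence

Exposures solve `min ‖M·e − c‖₂` subject to `e ≥ 0` (scipy NNLS) on raw
counts, followed by iterative sparsity pruning: signatures below 5% of the
fitted mutations are dropped and the reduced system re-solved until stable.
Pruning is the guard against the well-known over-fitting of inappropriate
signatures in low-burden samples; the threshold is configurable.

Presence is a nonparametric bootstrap: each replicate resamples the catalogue
multinomially from its empirical channel frequencies (not from the
reconstruction), refits, and records whether the signature's exposure
fraction reaches the exposure threshold (default 5% of the sample's
mutations). The presence probability is the fraction of replicates passing;
the default decision cutoff is 0.9. Both thresholds are parameters; the
bootstrap is deterministic given its seed.

**Detection limits.** With n ≈ 300 mutations and a 5% exposure threshold, a
signature needs a realised fitted fraction of roughly 8% before its presence
probability can reach 0.9 — multinomial noise alone places a true 10%
component below that margin in about a quarter of samples. Presence calls for
exposures near the threshold are therefore genuinely uncertain at
retinoblastoma-like burdens; the test suite's recovery experiments keep their
smallest mixture component at 15% for this reason.

A UV verdict is "UV-consistent" only when the UV signature is confidently
present **and** CC>TT doublets are observed; strand bias is reported as
supporting evidence rather than a requirement, since the genic mutation count
of a low-burden genome gives the binomial test little power.

## Copy-number rules

All rules switch on ploidy at 2.7 (a profile at exactly 2.7 uses the
whole-genome-duplicated rule — the conservative choice for amplification
calling):

* focal amplification: total CN ≥ 5 (diploid) or ≥ 9 (WGD);
* large-scale events (segments > 3 Mb, telomere/centromere-masked segments
  excluded): gain when total CN > 2 (diploid) or > 4 (WGD); loss when minor
  CN = 0, flagged copy-neutral/amplified LOH when total CN ≥ 2 — a segment
  can be both gained and LOH;
* LOH over a gene: every base of the footprint covered by minor-CN-0
  segments (an uncovered footprint is an error, not a negative);
* arm-level events: qualifying large-scale segments covering ≥ 50% of the
  unmasked arm. The coverage fraction is not a published constant; 50%
  reproduces whole-arm event reporting while tolerating fragmentation, and
  is configurable;
* "fold" amplification of a named gene is reported as the raw maximum total
  CN over its footprint, matching the field's "N-fold amplified" usage.

The karyotype is a coordinate-only GRCh37-style table (approximate lengths
and centromere spans, 10 kb telomere mask); no analysis uses sequence.

## Rearrangement complexity and per-allele RB1 status

A breakpoint is a breakend: an intrachromosomal junction contributes two to
its chromosome. Chromothripsis-like detection links chromosomes into sets via
translocation junctions and calls a set positive when it carries ≥ 40
breakends, its ordered segments show ≥ 10 adjacent total-CN switches, and the
segments occupy ≤ 3 distinct CN states (the oscillation criterion). These
thresholds are calibrated to published case descriptions, not derived from a
formal definition — there is none — and all are parameters.

Locus patterns are assigned with precedence chromothripsis-like → complex
interchromosomal (≥ 3 junctions touching the chromosome, ≥ 1 translocation)
→ complex intrachromosomal (≥ 3 junctions) → simple (1–2 junctions with an
in-gene breakend) → none.

Per-allele status under the two-hit model: allele 1 takes the strongest
positive finding (truncating small variant > intragenic deletion — a CN drop
below the diploid/WGD baseline overlapping ≥ 1 exon; purely intronic noise
does not count > SV transection). Allele 2 is LOH over the full footprint,
else a second independent truncating variant, else not detected. Biallelic
status is "confirmed" only with positive mechanisms on both alleles; allele
phasing is not attempted, so complex rearrangements without LOH remain
"unresolved" — deliberately mirroring what short-read data can and cannot
establish.

## Driver rules

A small variant is a potential driver if the identical variant recurs at
least twice in the recurrence lookup (a user-supplied, version-pinned table;
never a live database query) or if it truncates a census tumour suppressor
(nonsense, essential splice, frameshift). Copy-number drivers are focal
amplifications (ploidy-aware rule) and homozygous deletions (total CN 0) over
census genes. The bundled census/recurrence tables are small synthetic
fixtures for testing.

## Cohort statistics

Burden densities divide counts by a configurable callable-genome size
(default 3235 Mb, the value consistent with a mean burden of 275 substitutions
at 0.085/Mb; published per-class densities imply slightly different
denominators, so the constant is explicitly a configuration, not a fact).
Burden-age regression is OLS of substitution count on age in months over
treatment-naive samples, reporting slope, r², and the two-sided slope
p-value; outliers are never removed automatically. Bilateral independence
compares post-filter call sets: exact keys for small variants, 10 bp breakend
tolerance for junctions (configurable; 0 gives exact matching), with verdict
"independent" only when nothing is shared in any class.

## The synthetic cohort: what it emulates, and what it does not

Defaults define the study conditions:

* burden `Poisson(10 + 8·age_months)` — mean ≈ 275 at the cohort's mean age
  (~34 ± 16 months, truncated at 6), spanning the tens-to-hundreds range;
  indels `Poisson(3 + 2·age)`; ~6 background rearrangements per tumour;
* background signature mixture 0.7 flat-clock / 0.3 CpG-clock; one treated
  tumour per 20-tumour cohort gains the platinum signature at fraction 0.7,
  which also scales its burden by 1/(1−0.7) ≈ 3.3× (≈ 930 substitutions) —
  making it the burden-age outlier a chemotherapy-exposed recurrence would be;
* *RB1* mechanisms drawn over point+LOH (0.40), intragenic deletion (0.10),
  simple translocation (0.10), complex intra (0.15), complex inter (0.15),
  chromothripsis-like (0.10), each constructed to satisfy its defining
  postconditions (e.g. 3–4 in-gene breakends among 14–64 on chromosome 13
  for complex intra; ≥ 40 breakends over chromosomes 13+8+14 with a
  14-segment CN oscillation between totals 2 and 3 for chromothripsis-like);
* arm gains 1q 0.60 / 2p 0.55 / 6p 0.70 with coupling κ = 0.57: with
  probability κ one shared Bernoulli (at the mean of the three marginals)
  drives all three arms, else they draw independently — κ = 1 makes gains
  all-or-none, κ = 0.57 yields ≈ 45% triple concurrence while shifting
  marginals by < 0.01; 16q loss 0.40; focal *MYCN* amplification in ~10% of
  tumours at 10–200 copies;
* contamination: 10 population-SNP leak-throughs plus 30 low-VAF
  (0.02–0.195) artefacts per tumour.

Generator-specific simplifications to keep ground truth exact: true somatic
VAFs follow Beta(8, 12) truncated at 0.2, so the injected artefacts are
exactly the sub-threshold records; background rearrangements avoid chromosome
13, so the locus-pattern label is unambiguous; positions are uniform over
chromosome arms and never collide with population-SNP sites. All randomness
flows from `default_rng([seed, tumour_index])`, making each tumour
reproducible in isolation and cohort output byte-identical.

Real data differ in ways the generator does not model: subclonality and
purity (VAFs below 0.2 can be genuine), kataegis and clustered mutations,
indel context spectra, sequence-dependent mappability artefacts, breakend
imprecision, and germline structural variation. Passing tests therefore
demonstrate the correctness of the rules and estimators under the stated
statistical structure, not robustness to every failure mode of real somatic
calling.

The bundled reference signatures are synthetic analogues (a CpG-deamination
clock, a flat T>C-dominated clock, a platinum-adduct signature, a UV
signature) constructed with disjoint-support structure so that they are
statistically identifiable at n ≈ 300; they are column-stochastic 96-vectors
in the standard channel order and are interchangeable with any published
reference table of the same shape.

## Numerical choices and degenerate inputs

Problem sizes in the test suite are chosen to finish in seconds while leaving
clear statistical margins (20-seed replicates for cosine experiments, 200
catalogues for recovery, 200 replicates for calibration checks). VAFs are
carried to six decimals so VCF round trips are exact under float32 INFO
storage. Zero catalogues are errors for fitting and bootstrap; zero vectors
are errors for cosine similarity; an empty junction list classifies as
pattern "none"; segment tables must cover a gene's footprint before LOH can
be asserted. Signature tables are renormalised only when column sums are
within 1e-3 of 1, otherwise rejected.

## Known limitations

* Rearrangement order and derivative-chromosome structure are not
  reconstructed; allele phasing of complex events is not attempted.
* The chromothripsis-like call is a heuristic screen, not a formal test;
  its thresholds should be revisited for genomes with heavy background
  rearrangement.
* Arm-level calls depend on the 50% coverage convention; fragmented
  profiles near the threshold flip calls.
* Presence calls for signatures contributing < ~10% of a low-burden sample
  are intrinsically unstable (see detection limits above).
* The indel model is burden-only (no ID-channel spectra), and doublets are
  modelled only as injected positive controls.
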