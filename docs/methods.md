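# Methods

## Data model

A `GenotypeMatrix` holds N diploid varieties × L biallelic SNP loci as an
`int8` code matrix (0 = hom-ref, 1 = het, 2 = hom-alt, −1 = missing).
Genotypes are unordered and unphased; phase is discarded when reading VCF.
Coordinates are 1-based inclusive (VCF convention) everywhere. Chromosome
labels are opaque strings compared against a declared ordered list
(default `chr1`…`chr12`, matching a 12-chromosome genome); no numeric
parsing is attempted. Multiallelic VCF records are dropped with a warning
by default (`on_multiallelic="error"` to refuse instead); indel records
are skipped and counted.

## Marker statistics

All per-locus statistics are complete-case: missing calls leave the
denominator. With genotype-class counts (n_rr, n_het, n_aa), n = their
sum, and p = (2·n_aa + n_het)/(2n):

- MAF = min(p, 1−p);
- PIC = 1 − (p² + q²) − 2p²q² with q = 1−p (Botstein's measure restricted
  to two alleles). It is symmetric in p↔q, strictly increasing in MAF, and
  attains 0.375 at p = 0.5. This form is adopted because the documented
  MAF endpoints of the screened set (0.346 and 0.500) map exactly onto its
  documented PIC endpoints (0.350 and 0.375);
- H_o = n_het / n; H_e = 2p(1−p) (≤ 0.5 for a biallelic locus);
- HWE: by default a chi-square goodness of fit of (n_rr, n_het, n_aa)
  against (nq², 2npq, np²) on 1 df without continuity correction;
  monomorphic loci return p = 1. An exact test (full enumeration of the
  conditional distribution of heterozygote counts given allele counts,
  summing outcomes no more probable than the observed one) is available
  via `hwe_test(..., method="exact")`. The chi-square default is
  well calibrated at the sample sizes this package targets (hundreds of
  varieties); the test suite checks its type-I rate at α = 0.01 over
  2,500 simulated HWE loci of n = 418.

Reports round MAF/PIC to 3 decimals, matching conventional precision.

## Screening cascade

Six conjunctive criteria screen core-candidate loci. Criterion 1 ("even
distribution across chromosomes") constrains the panel, not a locus, and
is therefore enforced at selection time. The per-locus criteria, applied
in order with attrition recorded at each step, are:

| step | rule | default | boundary |
|---|---|---|---|
| missing | n_missing ≤ max_missing | 0 | inclusive |
| unmeasured | n_missing < max_unmeasured | 20 | exclusive |
| MAF | maf ≥ min_maf | 0.34 | inclusive |
| PIC | pic > min_pic | 0.35 | exclusive |
| HWE | hwe_p ≥ min_hwe_p | 0.01 | inclusive |
| flank | no other catalogued variant within flank_bp | 100 bp | Δ ≤ 100 fails |

The zero-missing rule and the <20-unmeasured rule overlap; they are kept
as independent thresholds because both conventions occur in practice
(zero-missing describes a final validated assay panel, the <20 bound a
raw call set). With both at their defaults the stricter one governs.
A min_pic of 0.30 is the documented alternative used when selecting core
loci from an already-validated candidate set.

The survivor *set* equals the intersection of the per-criterion pass sets
(order only affects where attrition is booked); the test suite asserts
this against an independent per-locus predicate. Flank uniqueness is a
sorted nearest-neighbour sweep per chromosome, contract-equivalent to the
all-pairs comparison (also asserted by oracle), and is always judged
against the full pre-filter catalogue — a screened-out neighbour still
spoils a flank.

## Core panel and minimal discriminating set

`select_core` distributes a target of k markers over the declared
chromosomes: each gets ⌊k / n_chrom⌋, the remainder goes to the
chromosomes with the most candidates, and quotas a chromosome cannot fill
are redistributed the same way. Within a chromosome, candidates are taken
by descending PIC (ties: smaller position) subject to mutual spacing
greater than flank_bp. The procedure is deterministic given its input.
"Even distribution" has no canonical operationalisation; the floor-quota
rule is this package's choice.

`minimal_discriminating_set` treats discrimination as set cover: the
universe is the C(N,2) variety pairs, and a marker covers a pair when
both calls are non-missing and their unordered allele pairs differ. A
comparison involving a missing call never distinguishes a pair — the
conservative choice, preventing missingness from inflating apparent
resolution. Greedy selection adds the marker with the largest coverage
gain (ties: higher PIC, then chromosome order and position, so output is
deterministic) and stops when no candidate adds coverage; pairs no
candidate separates are returned, never raised. Exact set cover is
NP-hard, so the optimal-subset search (`exhaustive_minimum_set`) is
provided only as a small-instance oracle (≤ 16 candidates); tests assert
greedy coverage equals optimal coverage on such instances. The size of
the resulting panel is a property of the data, not a target of the
algorithm.

Fingerprints render each variety over the panel in (chromosome, position)
order, alleles alphabetical within a genotype, `NN` for missing, joined
by `|`. Two varieties whose fingerprints differ at ≤ 1 locus are called
"identical-or-highly-similar" (threshold configurable; 0 flags exact
fingerprint duplicates). The concordance rate between two typings of the
same panel is the fraction of variety×locus cells with identical
non-missing genotypes; cells missing on either side are excluded from the
denominator and counted separately, and a zero-cell comparison yields NaN
with a warning rather than an error.

## KASP flank extraction

For each panel SNP the reference forward-strand sequence is emitted as
`LEFT[REF/ALT]RIGHT` with up to 100 bp per side — the de-facto KASP
submission format. Flanks truncated by a contig end are flagged rather
than dropped, as are loci whose flank contains another catalogued
variant. A reference base disagreeing with the catalogued reference
allele produces a per-locus error record without aborting the batch.
Primer thermodynamics and strand selection are out of scope (assays are
designed by vendors from these sheets).

## Synthetic data generator

The generator emulates the statistical structure of a germplasm
collection; its defaults are the study conditions the package was built
around: 418 varieties, 1,000 catalogued loci on 12 chromosomes, K = 6
subpopulations. Per-locus ancestral frequencies are Uniform(0.05, 0.5)
(a broad raw-catalogue MAF spectrum; the screens are what concentrate it).
Subpopulation frequencies follow the Balding–Nichols model,
Beta(p(1−F)/F, (1−p)(1−F)/F), with F_ST = 0.1 by default — moderate
differentiation typical of structured crop collections. Each variety
draws a Dirichlet admixture vector concentrated (α = 0.1) on a home
subpopulation assigned round-robin, and genotypes are sampled under HWE
at the admixture-weighted frequency. Missingness is uniform at random
(default 1%, a realistic post-filter genotyping rate). Exact and
near-duplicate variety pairs are planted by row copy before missingness;
position clusters place a configurable fraction of loci (default 10%)
within 100 bp of a neighbour to exercise the flank rule, with anchor
sites spaced > 2×flank so clusters never interact. The reference FASTA is
i.i.d. uniform ACGT with catalogued reference alleles substituted.

Each concern (frequencies, positions, genotypes, duplicates, missingness,
reference) draws from its own child stream of the master seed, so
outputs are byte-identical across runs and changing one dimension does
not perturb the others.

What the generator does **not** model: linkage disequilibrium along a
chromosome, genotyping error correlated with depth or allele balance,
inbreeding excess beyond what population structure induces, multiallelic
sites, and indels. Passing tests therefore demonstrate the algorithms'
correctness and calibration under idealised population-genetic sampling,
not robustness to every artefact of real reduced-representation
sequencing data.

## Problem sizes and numerical choices

The end-to-end recovery checks run at the full design scale (418
varieties × 1,000 loci; pairwise structures over all 87,153 pairs are
held as boolean matrices, ~50 MB at worst) and complete in seconds;
oracle-equivalence checks run at reduced scale (≤ 500-locus catalogues,
≤ 15 varieties × 12 candidates for exhaustive search) where the quadratic
and exponential oracles are exact and cheap. HWE calibration uses 2,500
multinomial loci at n = 418. Ties everywhere are broken
deterministically (PIC, then chromosome order, then position); degenerate
inputs (all-missing columns, empty survivor sets, zero comparable cells)
return defined values or typed errors as documented above.

## Known limitations

- Greedy set cover can exceed the optimal panel size (never its
  coverage); an ILP would be needed for certified minimality at scale.
- The chi-square HWE test is anticonservative for very small samples or
  extreme frequencies; use `method="exact"` there.
- Flank extraction has no reverse-complement option; assays are always
  specified on the reference forward strand.
- VCF writing emits GT-only records and synthesises contig lengths from
  the largest catalogued position, so foreign INFO/FORMAT fields do not
  survive a round trip.
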