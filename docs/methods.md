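# Methods

## The identity model

A sample's identifier is its ordered genotype (dosage) vector over a
fixed panel of biallelic SNPs. Dosage counts the second-listed allele
of the panel file (`allele_b`), so a diploid genotype is 0, 1 or 2;
missing calls are an explicit sentinel and excluded per comparison
pair, never imputed. The packaged panel (`snptrace/data/panel24.tsv`)
holds 24 exonic SNPs with HapMap 3 allele frequencies for CEU, CHB,
JPT and YRI. The frequencies are carried verbatim from their source at
two-decimal precision, including one CHB value (0.81 at the LAMA3 SNP)
just outside the nominal 0.2–0.8 design band; whether the AF columns
refer to `allele_a` or `allele_b` is a labelling convention only,
because every statistic used here is invariant under p ↔ 1−p.

The distance between two profiles is the allelic mismatch count
`d(a, b) = Σ_s |g_a,s − g_b,s|` over sites called in both. On complete
profiles this is the L1 metric on dosage vectors, bounded by 2×24 = 48
(the panel's "points of allelic comparison"). The package treats
genotype identity questions (duplicates, collisions) and assignment
questions (is this VCF column the sample its label claims?) both
through this distance.

### Decision rule

A pair is declared same-source when `d ≤ 2` over at least 20
informative markers. Under Hardy–Weinberg equilibrium (HWE) unrelated
pairs have expected distance ≈ 18 with SD ≈ 3.2 for a well-balanced
24-SNP panel, and the smallest distance observed between distinct
individuals in large reference cohorts is 3, so the threshold
separates the two distributions with margin while tolerating up to two
genotyping errors. Both knobs are arguments of
`identity.verify_assignments` / the `verify` CLI. Pairs with fewer
than 20 co-called markers are reported "inconclusive" rather than
guessed; close relatives can approach the threshold and are
deliberately not modelled (no kinship estimation) — they surface as
inconclusive or near-threshold matches for a human to review.

In `verify_assignments`, a sample failing against its own orthogonal
profile is scanned against all others; a mutual best-match exchange is
reported as a reciprocal transposition (the signature of a physical
plate swap), a one-directional match as a reassignment fragment, and
no match as unresolved. Duplicate detection (`find_duplicates`)
requires `d = 0` and treats hits as candidates only; confirmation uses
concordance over an extended SNP set (default threshold 0.98) when
such genotypes are supplied, since unrelated pairs concordance
percentages sit far below that.

## Power model

With allele frequency p (q = 1−p) and HWE, two independent individuals
share a genotype at one SNP with probability

    m(p) = (p²)² + (2pq)² + (q²)²,

minimised at m(1/2) = 3/8. With SNPs independent (enforced at design
time by the LD criterion), a whole profile matches with
`P_match = Π_s m(p_s)`, and a cohort of n contains

    E[C] = n(n−1)/2 · P_match

expected collisions, where a profile shared by k samples counts
k(k−1)/2 — the convention that makes the analytic expectation exact
for the simulated statistic. The per-SNP mismatch distribution
(P(d=0) = m(p), P(d=2) = 2p²q², P(d=1) the remainder) gives the mean
and variance of pairwise distances by summation; all closed forms are
unit-tested against exhaustive genotype-pair enumeration.

Single-SNP dropout multiplies expected collisions by 1/m(p_s) ≤ 8/3,
so no single technical failure can cost a three-fold power loss; this
fold change is the dropout metric reported by `dropout_analysis`.

### Monte-Carlo engine

`simulate_collisions` draws each replicate cohort as an n × S dosage
matrix with genotype probabilities (q², 2pq, p²) via a single-uniform
inverse-CDF draw per genotype — distributionally identical to
Binomial(2, p) (property-tested against numpy's binomial sampler) and
fast enough that the full validation (5 AF sources × 20,000 replicates
× 10,000 profiles) runs in about four minutes on one CPU. Collisions
are counted by encoding each profile as a base-3 integer (exact for
panels ≤ 39 SNPs; larger panels fall back to row hashing) and summing
k(k−1)/2 over multiplicity runs. Replicate r uses the RNG stream
seeded by (master_seed, r), so growing the replicate count never
perturbs earlier replicates, and results are exactly reproducible per
seed.

Validation scale: tests exercise the published conditions directly —
n = 10,000 cohorts, 20,000 replicates per AF source — with the
simulated means checked both against the published table (±35 %,
covering the two-decimal AF rounding of the panel file plus
Monte-Carlo error) and against the package's own closed form within 4
standard errors. The mismatch-distribution check uses a 2,000-profile
cohort (≈2 × 10⁶ pairs; the U-statistic standard error of the cohort
mean is ≈ 0.055, and the test allows 0.25).

## Panel design cascade

`apply_primary_filters` and `apply_secondary_filters` evaluate every
criterion on the complete input independently, so the audit report's
per-criterion counts are order-free and a variant failing several
criteria appears under each; survivors are the all-pass set. Design
choices on the points the criteria leave open:

- **Flanking GC**: computed upstream over a 250 bp total window
  centred on the SNP; the window size is a `FilterConfig` knob since
  reasonable tools differ on this convention.
- **Homopolymers**: a candidate fails if the longest identical-base
  run overlapping or adjacent to the site is ≥ 5 bp
  (`homopolymer_len` annotation).
- **LD rule**: no published threshold exists for "outside linkage
  disequilibrium", so the default is conservative: greedy exclusion
  of any candidate with r² ≥ 0.1 to an already-selected SNP, falling
  back, where no LD annotation is available, to requiring a different
  chromosome or > 1 Mb separation. The power model's independence
  assumption motivates erring on the side of exclusion.
- **Off-target similarity** is consumed as a precomputed per-candidate
  alignment score (fail above 100) rather than running an aligner,
  keeping the cascade self-contained and deterministic.
- **Prioritisation** ranks by `Σ_pop |AF − 0.5|` ascending with ties
  broken lexicographically by rsid, then picks greedily under the
  per-chromosome cap and the LD rule — deterministic builds by
  construction, verified against an independent best-score-first
  reference on random candidate sets.

Interval intersection (capture-kit overlap) merges each input set and
sweeps pairwise; it is tested against a per-base membership oracle and
against BEDTools. Reproducing the published candidate counts would
require specific historical releases of dbSNP, HapMap and the vendors'
capture BED files, which the package deliberately does not fetch; the
cascade is validated on synthetic candidate sets with planted,
plan-derived outcomes instead.

## Synthetic data

`generate_cohort` models the validation workflow: truth profiles are
HWE draws from a chosen AF source; the sequencing set applies planted
swaps (and appends planted duplicates) to the truth; the orthogonal
set applies independent per-call missingness and genotyping error to
the truth. Noise is applied to the orthogonal set and swaps to the
sequencing set because the replicate plate for orthogonal genotyping
is made directly from the primary plate — a downstream swap lives in
one pipeline only. The error model is a symmetric ±1 dosage
perturbation clipped to [0, 2]; adequate for threshold testing, though
real genotyping errors are not symmetric in this way. Every generator
is deterministic per seed and returns a ledger of planted events
sufficient to verify any downstream detection.

What the synthetic data does **not** emulate: capture bias and
coverage-dependent missingness (missingness is uniform), linkage
between panel SNPs, population substructure or relatedness within a
cohort, and contamination (mixtures). Passing tests therefore
demonstrate the correctness of the algorithms under the stated model,
not robustness to cohorts of close relatives or contaminated libraries
— on real data those appear as inconclusive or near-threshold results
by design.

## Degenerate inputs and numerical notes

Monomorphic SNPs (p ∈ {0, 1}) are valid: m(p) = 1, contributing
nothing to discrimination and nothing to mismatch variance. VCF sites
whose alleles cannot be reconciled with the panel (including
multi-allelic records and indels) become missing calls with a logged
warning rather than errors, since one bad site should not void a
batch; genotype *tables* are stricter (hard error naming the row),
because a wrong allele there indicates the wrong assay. Profiles with
fewer than the required informative overlap yield "inconclusive", and
`extended_concordance` with zero co-called sites returns None rather
than NaN. All collision counting is integer-exact; the only floating
point is in probabilities and summary statistics.
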