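# Methods

This note documents the models and procedures implemented in `rohpipe`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not establish.

## 1. Quality control

Animal filter first (call rate ≥ 0.90 over all markers), then SNP
filters recomputed on the retained animals: call rate ≥ 0.90, folded
minor allele frequency ≥ 0.02 (monomorphic SNPs fail this rule), and
Hardy–Weinberg exact-test p ≥ 1e-4. One pass, no iteration. When a SNP
fails several rules, the reported reason is the first failing rule in
the order call_rate → maf → hwe.

**HWE test.** The conditional exact test with probability ordering:
given the observed allele counts, the two-sided p-value is the summed
conditional probability of every heterozygote count whose probability
does not exceed the observed one, with conditional weights
`w(h) ∝ n! 2^h / (n_AA! h! n_aa!)`. An exact test (rather than
chi-square) is used because the 1e-4 threshold acts exactly where
asymptotics are worst — rare alleles and excess-homozygosity tails. The
weights are built by an exact integer recurrence and compared as
integers, so ties in the conditional distribution (which do occur) are
resolved without floating-point ambiguity; results are cached per
(n, minor-allele-count).

Two consequences worth knowing. First, exact-test p-values are bounded
away from 0 in small samples (with 5 genotyped animals the minimum
attainable p is ≈ 0.127), so the 1e-4 rule only bites at realistic
cohort sizes. Second, the filters are monotone per record type, but
raising the *animal* threshold changes the animal subset behind the SNP
metrics and can legitimately flip a SNP's fate in either direction —
sequential QC is order-dependent by construction.

## 2. ROH window semantics

A window `[i, j]` of one animal's calls on one chromosome is **valid**
iff the endpoint calls are homozygous and non-missing, it contains at
most `max_het` heterozygous and `max_miss` missing calls, spans
`pos[j] − pos[i] ≥ min_length_bp`, and has `j − i + 1 ≥ min_snps`
markers. Defaults: 1 Mb, 10 SNPs, 1 het, 5 missing. Reported runs are
the inclusion-maximal valid windows after longest-in-bp-first overlap
resolution (ties to the leftmost). Run length is `end_bp − start_bp`,
the span between the first and last marker.

Design notes:

* The het/miss allowances are interior-only: the endpoint rule prevents
  trailing heterozygous or missing calls from inflating run length.
* Maximality, not greedy extension, defines candidates; this makes the
  output order-free and checkable against the O(n²) enumeration oracle
  (`brute_force_scan`), which the test suite does exhaustively on random
  chromosomes (exact set equality).
* No density or maximum-gap constraint is applied (none is part of the
  run definition); adding one is a config-level extension point.
* Total bp of *reported* runs is not monotone in the thresholds: under
  longest-first overlap resolution, removing a long candidate can free
  two shorter non-overlapping candidates that jointly cover more. The
  monotone quantity is the bp union of all valid windows; the tests
  assert that corrected property.

**Known limitation — boundary overshoot at low marker density.** Because
up to one heterozygote is allowed inside a run, a maximal window extends
past a truly autozygous segment into Hardy–Weinberg background until the
*second* background heterozygote. With per-marker heterozygosity around
0.36 that is ≈ 5 markers of overshoot per side, and at sparse densities
(≈10 markers/Mb) chance background windows of ≥10 SNPs/≥1 Mb with ≤1
heterozygote also appear (≈7% per window position). At the array density
this package defaults to (≈40 markers/Mb) both effects are negligible —
false runs require ~40 consecutive near-homozygous calls (probability
≈ 4e-7) and overshoot is ≈ 0.1 Mb against a ≥1 Mb run — but segment
boundaries should never be interpreted as marker-exact, and ROH calling
on arrays sparser than ~20 markers/Mb needs a larger `min_snps`.

## 3. Genomic inbreeding

`Froh = Σ run lengths / L_aut`, with `L_aut` the SNP-covered autosomal
span (per chromosome, last minus first marker bp, summed). The covered
span rather than a fixed 2.5 Gb constant keeps the coefficient invariant
to array redesign and equal in denominator for every animal on one map.

## 4. Descriptive summaries

Length classes are left-closed right-open Mb bins with an unbounded last
bin (a 2.0 Mb run belongs to 2–4). Two presets: nine descriptive classes
(1–2, 2–4, …, 14–16, >16) and the six model classes (1–2, 2–4, 4–6,
6–8, 8–16, >16). Per-chromosome coverage is the mean over animals of the
per-animal union of run bp divided by the chromosome's covered span — a
population-level proportion, not pooled bp. "Identical ROH" across
animals means identical first and last marker index; an overlap-based
notion of sharing is a documented extension, not implemented, because
shared runs in this context are reported with a single start/end.

## 5. Association

**PTA layer.** Per distinct ROH with at least `min_carriers` carriers
(default 50) and per PTA trait, OLS on {intercept, carrier indicator}.
The slope is exactly the carrier minus non-carrier mean; t on n − 2 df.
Runs carried by all or no animals are skipped (non-informative
indicator). Covariates are deliberately absent in this layer.

**Animal-model layer.** Per trait and length class,

```
y = mu + HY + month + alpha*age + beta1*Froh + Σ beta2*Lroh + cow + e
```

Fixed effects use reference-level dummy coding (first observed level);
a greedy orthogonalisation sweep reduces rank-deficient designs to an
estimable basis, logging dropped columns. With a single first-lactation
record per cow, an i.i.d. cow effect is not identifiable, so the random
cow effect has covariance `G σa²` with `G` the VanRaden method-1 GRM
(codes centred by 2p, missing imputed to 2p, `G = WW'/2Σp(1−p)` over
polymorphic markers). Solutions come from Henderson's mixed-model
equations; `G` is inverted by Cholesky with a logged 1e-6 ridge fallback.
The residual variance is `(y'y − b'X'y − u'Z'y)/(n − rank X)`; fixed
standard errors use the corresponding diagonal of the inverse coefficient
matrix, and β2 t-tests use n − rank(X) df (a standard approximation —
no exact small-sample df is available for this design). Significance is
flagged at raw p < 0.05; a Benjamini–Hochberg column per trait is
provided but does not drive the flag.

**Variance components.** Default `lambda = σe²/σa² = 1` (equal genetic
and residual variance, i.e. h² = 0.5 for the record). Optional EM-REML:
`σa² ← (u'G⁻¹u + tr(G⁻¹C22)σe²)/q`, `σe² ← (y'y − b'X'y − u'Z'y)/(n −
rank X)`, iterated to relative tolerance 1e-6; the restricted
log-likelihood is non-decreasing across iterations (asserted in tests)
and λ is recovered within a factor 2 in ≥90% of seeded replicates at
n = 300 with a marker-based G. Identifiability of λ with one record per
cow rests entirely on the eigenvalue spread of G; in small or weakly
related cohorts the default λ = 1 is more robust than REML.

## 6. Synthetic cohorts and what green tests mean

The generator produces: per-marker minor allele frequencies uniform on
(0.05, 0.5); Hardy–Weinberg background genotypes; per animal a
Poisson(2.4) number of non-overlapping autozygous segments with
exponential(4.8 Mb) lengths truncated to 1–100 Mb (truncated mean
5.8 Mb), inside which calls are homozygous — the allele drawn once per
segment-marker from the marker's frequency, approximating one inherited
haplotype — with a 0.002 heterozygous-error rate; 0.01 missingness
genome-wide. The default genome is 5 × 100 Mb at 4,000 markers per
chromosome (≈40 markers/Mb, the density of a ~100k array on a ~2.5 Gb
autosome), giving an expected autozygous fraction of 2.4 × 5.8/500 ≈
0.028, typical of a moderately inbred Holstein cohort. Phenotypes follow
the association model above with `u ~ N(0, G σa²)`; herd-year and month
effects are drawn once per level; age ~ U(22, 40) months; default trait
means follow first-lactation Holstein records (e.g. 12,743 kg milk) with
deliberately scaled-down dispersions; the Froh depression default for
milk is β1 = −2500 kg per unit Froh (−25 kg per 1% inbreeding, the
order reported across dairy studies). PTAs are half the genetic value
plus independent noise. One seed fixes everything bit-for-bit through
three independently spawned generators (map / genotypes / phenotypes).

What the simulation does **not** emulate: linkage disequilibrium between
markers (background calls are independent given allele frequencies),
haplotype sharing between relatives (the planted segments of different
animals are placed independently, except for explicit effect templates),
selection, and pedigree structure. Consequently a green planted-segment
recovery test establishes that the scanner finds dense homozygous
stretches of known location — not that it would resolve the LD-driven
short-ROH background of real arrays; and exact-coordinate ROH sharing
across many animals, common in real cohorts where flanking breakpoints
are inherited, only arises here when an effect template spans a whole
(small) chromosome. Effect-recovery tests therefore take carrier status
from the simulation truth; the pipeline-level test plants a
whole-chromosome template.

A related caveat: a planted segment carried by ≳30% of a cohort produces
a genuine Hardy–Weinberg violation at its markers, and the HWE filter
removes them. That is correct behaviour, and the reason effect templates
in the examples use carrier frequency ≈ 0.2.

## 7. Numerical choices

* Genotype codes int8; polarity (which homozygote is 0) never affects
  any downstream quantity except the sign convention inside the GRM,
  which is invariant under per-marker flips after centring.
* HWE p-values: exact integers until the final division; ties included
  by integer comparison.
* MME solved by `numpy.linalg.solve` on the full coefficient matrix;
  solution residual `max|Ms − rhs|` is reported and asserted < 1e-8 ×
  scale in tests. λ → ∞ reduces to OLS (verified to 1e-6), `G = I`
  reduces to per-cow ridge (verified exactly).
* Estimable-basis sweep tolerance: column kept if its residual norm
  after projection exceeds 1e-8 × its norm.
* Degenerate inputs: all-missing markers get call_rate 0/maf 0/hwe 1;
  zero-residual OLS reports the t → ±∞, p → 0 limit; constant traits are
  flagged `degenerate` with β2 = 0 rather than fitted.
* Segment placement uses bounded rejection (100 retries) and fails with
  an instruction to use smaller segments rather than silently degrading.

## 8. Known limitations

* Boundary overshoot and sparse-density false positives as in §2.
* The PTA layer is plain OLS by design (no herd or Froh covariates); it
  measures marginal carrier contrasts, not adjusted effects.
* EM-REML is slow near the boundary σa² → 0 (EM's usual behaviour) and
  is off by default.
* Binary PLINK (BED), VCF input, imputation, phasing, ROH islands and
  annotation joins are out of scope.
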