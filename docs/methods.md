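# Methods

## Model

Phenotypes follow the standard single-component animal model

```
y = Xb + g + ε,   g ~ N(0, G σg²),   ε ~ N(0, I σe²).
```

Fixed effects are an intercept, a two-level sex indicator and slaughter
age as a linear covariate.  `G` is built from a dosage design `M` by
`G = M M′ / c` with `c = 2 Σⱼ pⱼ(1 − pⱼ)`.  Two constructions are
offered:

- `vanraden1` (default): `M` is centered only (`xᵢⱼ − 2pⱼ`).  This is
  the standard allele-frequency-weighted GRM; its diagonal averages ~1
  for unrelated individuals, which the tests assert.
- `paper_literal`: `M` is centered *and* scaled by `√(2pⱼ(1−pⱼ))`
  before the same division by `c`.  This reproduces a formula pair
  sometimes printed in the applied literature; it double-scales
  relative to either standard construction (its diagonal is ≈ H/c, not
  ≈ 1) and is kept only for faithfulness.  REML and BLUP are invariant
  to the overall scale of G up to a rescaling of σg², so prediction
  accuracies are essentially unchanged; the reported σg² is not.

`pⱼ` is the allele's own frequency, not the folded minor-allele
frequency: folding would break the exact zero mean of centered columns
for alleles above frequency ½ and with it the back-solve identity
below.

A centered GRM is *exactly* singular: every row of the centered design
sums to zero across a block's alleles, so `G·1 = 0`.  The diagnostic
ridge (add 1e-6 to the diagonal when the smallest eigenvalue is below
1e-8, always logged) therefore fires on every GRM; it stabilizes
V-solves inside REML/BLUP.  Back-solving and prediction instead use the
Moore–Penrose inverse of the un-ridged G.  This is exact, not an
approximation: with an intercept in `X`, the GLS residual satisfies
`1′V⁻¹r = 0`, hence `ĝ = σg² G V⁻¹ r` is orthogonal to the null space
of G, and `M û = M M′ G⁺ ĝ / c = ĝ` holds to machine precision (the
tests assert 1e-8).  The held-out prediction routes
`G_new G⁺ ĝ` and `M_new û` coincide exactly for the same reason.

## REML

With a single genomic variance component, the restricted likelihood
reduces to one dimension.  The fixed effects are projected out with an
orthonormal basis `A` of the complement of col(X); one symmetric
eigendecomposition of `A′GA` turns the restricted log-likelihood into

```
lR(λ) = −½ [ (n−p)(log 2πσ̂e²(λ) + 1) + Σ log(λξs + 1) ],
σ̂e²(λ) = Σ ηs²/(λξs + 1) / (n−p),
```

with `λ = σg²/σe²`, `ξ` the eigenvalues and `η` the rotated residual
data.  A 49-point grid over log₁₀λ ∈ [−6, 6] locates the basin; bounded
Brent refinement drives the change in lR below 1e-8.  A maximizer at
the lower grid edge is clamped to σg² = 0 (the boundary case).  Negative
eigenvalues from rounding are clipped at 0.  Standard errors come from
the analytic observed information in (σg², σe²), with the h² SE by the
delta method.  The running best log-likelihood is recorded and is
non-decreasing by construction.  An independent check in the test suite
maximizes the untransformed restricted likelihood
`−½[log|V| + log|X′V⁻¹X| + r′V⁻¹r]` by Nelder–Mead and agrees with the
profile search to ~1e-4 in h².  (The G = I limit cannot serve as such a
check: with identity relatedness only σg² + σe² is identified.)

## LD distance and constrained clustering

For loci A, B with alt-allele frequencies `pA, pB` and joint frequency
`pAB`, `D = pAB − pA·pB` and

```
Dmax = min(pA(1−pB), (1−pA)pB)          if D > 0
       max(−pA·pB, −(1−pA)(1−pB))       if D < 0,
```

`D′ = D/Dmax`.  Under this sign-dependent bound `D′` is non-negative
for any 2×2 table and invariant to swapping either locus's ref/alt
labels, so the magnitude-based distance `1 − |D′|` (default) and the
literal `1 − D′` coincide; both modes are exposed.  Conventions: `D = 0`
or a monomorphic locus gives `D′ = 0` (distance 1), haplotypes missing
at either locus are deleted pairwise with a two-haplotype minimum, and
distances are clipped to [0, 1] against one-ulp overshoot.

Clustering is agglomerative complete linkage restricted to physically
adjacent merges.  Each chromosome keeps a linear list of
adjacent-cluster distances; each iteration merges the pair at the
minimum entry (leftmost on ties, so runs are reproducible), deletes the
three affected entries and recomputes the two distances between the
merged cluster and its neighbours by a direct vectorized max over cross
pairs.  The Lance–Williams max-update is deliberately not used: it
needs the distance between non-adjacent clusters, which the linear list
does not carry.  Merging stops when the chromosome reaches its share of
the genome-wide target `K = round(n_snps/k)`, apportioned to
chromosomes by largest remainder (each ≥ 1) — adjacency makes
cross-chromosome merges impossible, so a per-chromosome allocation is
required even though only a genome-wide K is specified.  Merge
distances under this constrained scheme need not be monotone and are
not asserted to be; instead every logged merge distance is reproducible
by recomputation, and the whole procedure is tested for exact agreement
with a quadratic-time reference that rebuilds the full distance list at
every step.

Block construction conventions: count-based blocks handle the per-
chromosome remainder by policy (`short_block` default; `drop`
reproduces the accounting where every block has exactly k SNPs;
`merge_last` appends the tail to the last full block).  Length windows
are anchored at each chromosome's first SNP (no leading empty windows),
half-open in bp; empty windows are omitted.  All three methods yield
contiguous, non-overlapping, chromosome-respecting partitions with
explicit drop lists, which the tests assert as laws.

## Encoding

A block's alleles are its distinct phased SNP strings over the 2N
haplotypes, ordered by descending frequency (ties lexicographic).
Dosages are exact copy counts, so per-block row sums are 2 for every
individual — asserted everywhere.  Haplotypes with missing entries are
assigned to the most frequent compatible complete haplotype (per-SNP
major allele as fallback); a strict mode errors instead.  Fixed columns
are dropped only at standardization time, with a count.  Rare-allele
filtering is available but off by default.

## QC

Filter order: duplicate (chrom, pos) records (first kept) → individual
call rate ≥ 0.95 → SNP call rate ≥ 0.95 → MAF ≥ 0.01 → Hardy–Weinberg
χ² p ≥ 0.001.  The order matters for the per-filter counts and is
logged; each removed SNP is attributed to the first filter it fails.
MAF is computed from phased haplotype counts with missing entries out
of the denominator.  Phenotype and age outliers are removed by iterated
two-sided Grubbs tests (α = 0.05): the flagged value is removed and the
variable retested until no test is significant.  A flagged trait value
is set missing; a flagged age drops the record, since age is a
mandatory covariate.  The Grubbs p-value uses the exact
t-distribution relation `p = min(1, 2n·P(T_{n−2} > t))` with
`t² = n(n−2)G² / ((n−1)² − nG²)`.

## Validation

Accuracy is the Pearson correlation between held-out GEBVs and
pre-corrected phenotypes (OLS residuals on intercept + sex + age).
Blocks and allele catalogues are built once on the full genotype panel —
genotypes are observed for everyone and are not the predicted quantity —
but *every phenotype-dependent quantity* is computed from training
individuals only: allele frequencies entering the training GRM, REML,
BLUP, and the pre-correction coefficients applied to test individuals.
The tests assert that perturbing test phenotypes leaves the training
fit bit-identical.  A `whole_data` pre-correction mode mirrors the
common simpler protocol; `within_fold` is the default.  A degenerate
predictor (REML at the σg² = 0 boundary gives constant GEBVs) scores 0
rather than NaN.  Paired t-tests compare methods on matched
(repeat, fold) accuracies.  Forward validation trains on animals born
before a cutoff date (boundary date goes to test).

## Synthetic data

The generator is a founder mosaic, not a coalescent simulator: it gives
direct control over block-level allelic structure, which is the
quantity the method exploits, with no extra dependency.  Per LD
segment (4–12 SNPs, uniform) the founder pool holds 3 *common* core
haplotypes (random polymorphic patterns, Dirichlet(2) weights carrying
85% of the mass) and 16 *rare* founders, each a single-crossover
recombinant of two cores with per-SNP mutation probability 0.08,
sharing the remaining 15%.  Each sampled haplotype keeps its founder
lineage across a segment boundary except for a switch with probability
0.1.  The commons generate high pairwise r² among a segment's SNPs;
the rare recombinants multiply the distinct alleles per block beyond
the linear span of the block's SNP dosages — without them, any
allele-level QTL would be exactly representable by a SNP model and
block designs could never help.

These defaults were calibrated jointly against three population
diagnostics typical of dense bovine chip panels and then frozen:
mean within-segment r² 0.41 (target ≈ 0.43), 12.2 alleles per 5-SNP
block (≈ 11.7), 323 alleles per 50-SNP block (≈ 334).  Mean SNP spacing
is 4 kb (positions uniform on 10 Mb chromosomes, 2500 SNPs each);
default n = 1000 individuals, large enough for stable REML at
minutes-scale tests.

Traits: `snp_additive` draws i.i.d. effects on common SNP dosages;
`haplotype_allelic` attaches i.i.d. effects to the distinct haplotype
alleles of QTL segments of 3–6 SNPs.  The size restriction is
deliberate: the method's accuracy optimum at ~5-SNP haplotypes implies
the QTL-relevant allelic structure lives at that scale, and a k = 5
block can only represent a whole-haplotype contrast it does not split.
Effect draws for a segment are rejected (up to 10 redraws, else the
segment is skipped) whenever any single segment SNP reaches r² ≥ 0.9
with the segment's genetic value, making "no single SNP tags a QTL"
true by construction.  Genetic values are scaled so
Var(g)/(Var(g)+σe²) equals the target h² (default 0.4, mid-range for
carcass traits); sex (Bernoulli ½, +25 units for males) and age
(uniform 24–36 months, +2.5/month) effects are added on top.  Birth
dates increase with individual index over six years, so the optional
founder-weight drift (`founder_drift`, default 0 = stationary) produces
allele-frequency change along the time axis for forward-validation
scenarios.

What the simulator does *not* emulate: pedigree/family structure,
selection, genotyping error, imputation error, MAF ascertainment bias
of real chips, and LD decay within segments (LD is piecewise-constant
by construction).  Passing tests therefore show the algorithms are
correct and that the haplotype advantage appears under allele-level
genetics with realistic LD and allele-richness summaries — not that any
particular accuracy value transfers to a real population.

## Problem sizes used by the automated checks

The exact-oracle checks run at the sizes their contracts state (1000
two-locus datasets of 200 haplotypes; 200 clustering instances of ≤ 12
SNPs; REML recovery at n = 1000, m = 2000, 10 replicates per h² level).
The end-to-end comparison runs 10 replicates at n = 1000 with 2 × 1000
SNPs, 70 allelic QTL, 3-fold single-repeat cross-validation — enough
folds for a stable mean while keeping the whole suite in a few minutes.
The GRM double-loop oracle runs at 60 × 200, where a pure-Python loop
is feasible.  `scripts/acceptance.py` uses n = 800, 2 × 1200 SNPs and
3 replicates; its default 5 × 5 cross-validation analogue is 3-fold ×
1 repeat for the same reason.

## Known limitations

- REML handles exactly one genomic component; no dominance, epistasis,
  GxE, or multi-kernel models.
- The haplotype-similarity relatedness alternative (grouping alleles by
  similarity rather than identity) is out of scope.
- Unphased heterozygotes are rejected or set missing — phasing quality
  is upstream of this package and directly limits block quality.
- The `paper_literal` GRM and `/N` back-solve variants are provided for
  comparability, not recommended for analysis.
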