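# Methods

`rootherit` quantifies how much of the variation in traits measured on a
clonal grafted scion ("Hass" avocado in the motivating use case) is
transmitted by the genetically diverse seedling rootstocks it is grafted
onto.  Because the scion is a single clone, any additive genetic signal
in scion traits that tracks rootstock relatedness is rootstock-mediated.
The pipeline has four stages: marker relatedness, Bayesian genetic
prediction, genomic heritability, and a triple-permutation significance
test; a synthetic-population generator with known ground truth closes the
loop for validation.

## Pairwise relatedness from SSR genotypes

For codominant multi-allelic markers (SSRs scored as fragment lengths),
the package implements the Ritland method-of-moments estimator.  At locus
l with observed alleles i of reference frequency p_i, genotypes (a,b) and
(c,d) give

    S_i = 1/4 (d_ai + d_bi)(d_ci + d_di),
    r_l = 2/(n_l − 1) ( Σ_i S_i / p_i − 1 ),

and loci combine with weights w_l = n_l − 1 (n_l = number of observed
alleles; monomorphic loci carry zero weight and are excluded, as are loci
missing in either sample).  The diagonal of the pairwise matrix is set to
1 by convention.  Properties that matter downstream:

- the estimator is unbiased given **reference** allele frequencies but
  unbounded: single-locus values of ±2 are normal, and the matrix is in
  general not positive semidefinite.  Negative estimates are kept; no PSD
  repair is applied.
- with **plug-in frequencies estimated from the panel itself**, estimates
  are relative to the panel's mean gene-pool correlation: in a panel of
  few large half-sib families, within-family means fall noticeably below
  the pedigree value 0.25, and the shortfall shrinks as the number of
  founder families grows; with the true pool frequencies supplied the
  estimator is unbiased.  Calibration tests therefore pass known
  frequencies; analysis runs use plug-in frequencies, as the field's
  software does.
- frequencies are computed from all panel samples including the focal
  pair (an `exclude_focal_pairs` flag provides the leave-pair-out
  variant); pairs with no usable locus are imputed at the off-diagonal
  mean so the downstream design stays complete.

## The genetic-prediction model

For each trait the model is the additive regression

    y_i = μ + Σ_j x_ij β_j + e_i,

fit by a conjugate Gibbs sampler with β_j ~ iid N(0, σβ²), a flat prior
on μ, and scaled-inverse-χ² priors on σβ² and the residual variance σδ²
(df 5; scales set so each component's prior mean is an R² = 0.5 share of
var(y)).  In RELATEDNESS mode x_ij is the relatedness of analyzed sample
i to genotyped sample j — a kernel-style design with one column per
genotyped rootstock — which tolerates the non-PSD relatedness matrix; in
MARKER mode x_ij are 0/1/2 locus-allele dosages (missing calls imputed at
the locus mean).  The sampler works in the SVD basis of the design, where
the β-conditional is diagonal; this is algebraically the same draw as the
block multivariate-normal update at O(nm) per sweep, and null-space
components of β are drawn from their prior so the σβ² update stays exact.
Chains are bit-reproducible under a fixed seed.

Per retained draw, g = Xβ, σa² is the empirical variance of g across
samples, and

    h² = σa² / (σa² + σδ²).

The GEBV vector is the posterior mean of g, and the model fit r is the
Pearson correlation of phenotype with GEBV.  Reported summaries are the
posterior mean of the per-draw h² ratio and its central 95% credible
interval (the ratio-of-posterior-means variant is reported alongside).
Default chains are 10,000 iterations with 5,000 burn-in; permutation
refits default to 2,000/1,000 since the posterior mean of h² stabilizes
far earlier.

**What this h² measures.**  σa² = var(Xβ) is the *marker-captured*
additive variance.  When the trait's additive variance includes
components the markers cannot see — in a half-sib design the
Mendelian-sampling term, ¾ of σa², is independent of unlinked markers —
the estimate is attenuated toward the captured share, while a saturated
kernel design contributes a modest overfitting floor on pure noise.  The
recovery checks in the validation suite quantify this: at n ≈ 300 with
200 loci the estimated-vs-true relation has a slope well below one.
This is not a sampler artifact (longer chains agree; the fixed-variance
chain matches the ridge closed form), and the alternative
variance-component parametrization (u ~ N(0, σu²K)) trades it for an
inflated null, since σu² is weakly identified under a kernel dominated
by its diagonal.  Absolute h² values should therefore be read
comparatively; calibrated significance comes from the permutation test
below, which is unaffected by the shared attenuation.

## Triple-permutation significance

Three randomizations destroy different links while preserving marginal
structure:

1. **phenotype**: shuffle y across samples (design fixed);
2. **marker matrix**: shuffle each locus independently across samples —
   allele frequencies are invariant, multilocus identity (and hence real
   relatedness) is destroyed — then recompute relatedness and refit;
3. **relatedness matrix**: one joint row/column permutation P·M·Pᵀ, which
   preserves symmetry, the unit diagonal, and the spectrum.

Each strategy uses 50 permutations by default; the one-sided p-value is
the proportion of null h² values *strictly greater* than the observed
estimate (so p = 0.00 is attainable and p has resolution 1/50, rendered
as "<0.02" in the text report).  A trait is significant only if p < 0.05
for all three strategies simultaneously.  Strategies 1 and 3 are both
sample relabelings of the same exchangeable null and give
indistinguishable null distributions; strategy 2 is genuinely different.
At the default 13 loci all three are well calibrated.  With many more
loci the locus-wise shuffle produces a matrix whose null h² tends to run
higher than the observed structure-bearing matrix, making strategy 2
conservative there — a property of the estimator's noise spectrum, and
the reason power analyses use the 13-locus study scale.  One master seed spawns all
child seeds, so a full report is reproducible from one integer.

Strategy 2 uses cached per-locus contribution matrices when
n²·n_loci ≤ 5·10⁷: shuffling a locus permutes its contribution matrix
symmetrically, so the permuted-panel matrix is assembled exactly without
recomputation.

## Synthetic populations

The generator mirrors the study design it emulates: 3 agroecological
regions holding 2+4+2 orchards of 30 trees (240 trees), 12 "plus-tree"
donor mothers whose open-pollinated seed is distributed across all
orchards (nursery mixing), and 13 SSR loci with per-locus allele counts
drawn from {5..12} and Dirichlet(1) frequencies.  Offspring genotypes are
one maternal gamete plus one pollen gamete from the panmictic pool, so
same-mother trees are half sibs (expected additive relatedness 0.25;
fathers untracked).  Breeding values follow the infinitesimal model: donor
A ~ N(0, σa²), offspring A = ½A_mother + N(0, ¾σa²); phenotypes add a
fixed per-region shift (SD 0.5 phenotypic SD by default) and residual
noise with σa²/(σa² + σe²) equal to the configured true h².  Region
shifts are excluded from the true-h² denominator (within-environment
definition); the realized alternative including them is recorded on the
truth object, and per-region refits show the expected h² inflation when
environmental variance shrinks.  Missing genotype calls and phenotypes
are masked last, at configurable rates.

What the generator does *not* emulate: linkage between loci, selfing or
inbreeding, admixture from diverged gene pools, genotype-by-environment
interaction, and repeated measures across years (the motivating study
averaged three seasons upstream).  Passing recovery tests on this
generator therefore demonstrates correctness of the estimator chain under
idealized family structure, not robustness to those features.

The pedigree oracle (numerator-relationship matrix: 1 on the diagonal,
0.25 for half sibs, 0.5 mother–offspring, 0 otherwise) provides the
independent truth for relatedness tests; marker estimates correlate with
it at r ≥ 0.6 over pairs at 200 loci, with estimator MSE decreasing
monotonically from 13 to 50 to 200 loci.

## Numerical and design choices

- Allele identity is exact integer equality of fragment length; a record
  with one of two alleles scored is treated as missing (capillary dropout
  is ambiguous).  Missing is written as 0, read as 0 or empty.
- Phenotypes are centered before fitting; μ is reported on the original
  scale.  No transformation is applied by default (an analysis of skewed
  count traits may pass log1p-transformed columns).
- The per-draw h² ratio (not the ratio of posterior means) is the primary
  summary; both are reported.
- Problem sizes in the validation suite: calibration uses 500 independent
  pairs per relationship class at 200 loci; recovery uses n = 304 trees
  (8 orchards of 38), 200 loci, no region shifts, 10 seeds per truth with
  2,000/1,000 chains; null calibration uses 40 pure-noise traits on the
  default 240-tree, 13-locus population with 50 permutations per strategy
  (1,000/500 refit chains); power uses 20 replicate populations with true
  h² = 0.6 at n = 304, 13 loci.  These sizes are the package's validation
  conditions; the full study protocol (10,000/5,000 chains) is available
  via `--paper-protocol` and `GibbsConfig()` defaults.

## Known limitations

- Absolute h² is attenuated whenever markers tag only part of the
  additive variance (see above); between-design comparisons and
  permutation significance are the supported inferences.
- The relatedness-design regression leaves region/orchard effects in the
  residual; per-region refits are the provided control, not a fixed-effect
  adjustment.
- The marker-direct (dosage-design) mode with a handful of SSRs is
  statistically weak; it is provided for completeness and comparison.
- With very small analyzable subsets (< 10 samples) the model refuses to
  fit rather than return unstable estimates.
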