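# Methods

## The model

`regionscan` estimates the share of a quantitative trait's variance that is
attributable to short genomic regions. The analysis phenotype *y* (covariate-
adjusted, rank-transformed; see below) is modelled with two nested
variance-component models,

    null:  y = 1μ + a + e
    full:  y = 1μ + a + r + e

where *a* ~ N(0, σ²_w G_w) is a whole-genome polygenic effect with G_w the
marker-based relationship matrix over all post-QC autosomal SNPs, *r* ~
N(0, σ²_r G_r) is a regional effect with G_r built from the SNPs of one
window, and *e* ~ N(0, σ²_e I). Both models are fitted by restricted maximum
likelihood (REML); the evidence for a regional effect is the likelihood-ratio
statistic LRT = max(0, 2(ℓ_full − ℓ_null)). Regional and whole-genome
heritabilities are h²_r = σ²_r/σ²_p and h²_w = σ²_w/σ²_p with σ²_p = σ²_w +
σ²_r + σ²_e. The scan tiles the genome with 100-SNP windows advancing by 50
SNPs, and re-scans the top-ranked windows with 10-SNP windows advancing by 5.

The null model does not depend on the window and is fitted once per scan.
The whole-genome matrix retains each window's SNPs (no leave-region-out).

## Relationship matrices

Off-diagonals are the frequency-weighted cross-products of centred dosages
(dosages coded 0/0.5/1 for AA/AB/BB of the counted B allele, frequencies p_k
estimated from the analysis sample):

    f_ij = (2/m_ij) Σ_k (g_ik − p_k)(g_jk − p_k) / (p_k(1 − p_k)),

summed over the m_ij SNPs non-missing in both individuals (pairwise-complete,
unbiased under missingness at random). Diagonals use the homozygosity
estimator f_ii = 1 + (Obs(hom)_i − E(hom)_i)/(m_i − E(hom)_i) with
E(hom)_i = Σ_k (1 − 2p_k(1 − p_k)) over the SNPs observed in individual *i*.
The factor 2 puts self-relationship at 1 + F̂, so the attached variance
components read directly as additive genetic variances; a 0.5-diagonal
kinship convention is available (`--kinship-scale`) and only rescales the
σ²'s — LRT and h² ratios are invariant. Obs/E(hom) are aggregated per
individual; a per-SNP aggregation differs only in weighting and was not
adopted. Matrices are "bent" before REML: eigenvalues below 10⁻⁸ are raised
to that floor (regional matrices from m < n SNPs are always rank-deficient).

## REML fitting

The restricted log-likelihood ℓ_R(σ²) = −½[log|V| + log|X'V⁻¹X| + y'Py],
V = Σ_c σ²_c G_c + σ²_e I, X the intercept column, is maximised:

- **one genetic component** — the model is rotated into the eigenbasis of G,
  the total variance is profiled out in closed form, and the heritability
  ratio γ = σ²_g/(σ²_g + σ²_e) is found by bounded scalar minimisation
  (tolerance 10⁻¹² in γ). Likelihood evaluations are O(n) after one O(n³)
  eigendecomposition.
- **two components** — L-BFGS-B on the log-variance scale with the analytic
  REML gradient ∂ℓ/∂σ²_c = −½[tr(P G_c) − y'P G_c P y] (the trace computed
  as an elementwise sum, O(n²) given P). Log-variances keep the iterates
  positive and well scaled.

A boundary pass re-solves with each component whose estimate falls below
10⁻¹⁰·var(y) pinned at exactly 0, so boundary solutions are exact. Starting
values split var(y) equally unless the caller passes the null solution (the
scan does). If a window's full-model likelihood lands below the null's
(optimiser failure), the window is refitted from the null solution; windows
that still fail are logged and excluded from summaries, never aborting the
scan.

## The boundary LRT and significance

σ²_r is tested on its boundary, so the LRT's null law is not χ²(1). The
default reference distribution is **χ² with 0.5 degrees of freedom**, which
reproduces the published (LRT, −log₁₀p) pairs to ±0.03 for statistics up to
~26 (e.g. 26.42 → 7.16 against a printed 7.15); the two largest published
pairs (47.76 → 11.91, 54.26 → 13.35) deviate by ~0.07–0.08, a known residual
of this mapping. The 50:50 mixture ½χ²(0) + ½χ²(1) is available as a config
option; it is the asymptotic boundary law but misses the published pairs by
up to ~0.3. Under the simulated null the realised LRT distribution is
stochastically below χ²(1), and the χ²(0.5) mapping is mildly
anti-conservative relative to the mixture — both calibrations are exercised
in the test suite.

Genome-wide thresholds are Bonferroni at α = 0.05 over the number of tests;
for overlapping-window scans the effective test count is **half** the window
count (adjacent windows share half their SNPs), used verbatim even when
fractional (5373/2 = 2686.5 reproduces the published 4.73 exactly). The
suggestive threshold is −log₁₀(1/m): one expected false positive per scan.
Summaries round to 2 decimals; machine-readable outputs keep full precision.

## Single-SNP scan

The comparison method fits the polygenic null once and score-tests each SNP:
T = [g̃'V̂⁻¹(y − μ̂)]²/(g̃'V̂⁻¹g̃) with g̃ the centred (mean-imputed) dosage,
referred to χ²(1) — the family-based "mmscore" construction. With σ̂²_w = 0
it reduces exactly to the classical regression score test. V̂⁻¹-products use
the cached eigendecomposition of G_w, so a scan is one matrix rotation.

## Phenotype preparation

Within each cohort the trait is regressed on sex, age and age² (OLS;
collinear columns dropped with a warning; age uncentred — this affects
coefficients, not residuals), and the residual ranks are mapped to
standard-normal quantiles by Φ⁻¹((rank − 0.5)/n) with average ranks for
ties; Blom's offset 3/8 is available. Cohorts are adjusted and transformed
separately, then concatenated — adjustment order is fixed.

## Quality control

Per-SNP filters run first, in order: call rate ≥ 0.98, MAF ≥ 0.001 (strictly
below is discarded, exactly 0.001 retained), exact Hardy-Weinberg p ≥ 10⁻⁸;
then individuals with call rate < 0.98 are removed. The HWE test is the
exact conditional test (summing tables no more probable than the observed),
because at a 10⁻⁸ floor the χ² approximation is unreliable in small genotype
classes. The single pass is deterministic but not idempotent at threshold
boundaries (removing samples can nudge a borderline SNP call rate);
`iterate=True` recomputes to a fixpoint, which is idempotent.

## Synthetic cohorts

The generator produces the structure the model assumes, so every stage is
testable without restricted data:

- **Allele frequencies**: a bounded random walk along each chromosome
  (reflection into [0.01, 0.5], reset to a fresh uniform draw with
  probability 1 − `ld_decay` per step), with an optional rare tail. The walk
  matters: two SNPs can only be in strong LD if their frequencies are
  similar, so i.i.d. frequencies would make high copying probabilities
  physically incoherent and leave untyped variants untaggable.
- **Haplotypes**: latent-uniform copying — each haplotype carries a uniform
  u that is copied from the previous SNP with probability `ld_decay` and
  redrawn otherwise; the allele is 1{u < p_k}. Marginal frequencies are
  exact (per-SNP Hardy-Weinberg holds), adjacent-marker correlation decays
  geometrically.
- **Families**: nuclear families (2 founders + sibship) by gene dropping
  with per-interval crossover probability `recomb_rate` (default 0.01);
  remaining samples are unrelated singletons; families stay within one of
  the `n_cohorts` cohorts (round-robin).
- **Phenotype**: per-cohort sex/age/age² covariate effects plus a regional
  QTL part (equal-weight sum of standardised causal dosages scaled to
  exactly h²_region of the unit-variance genetic-plus-residual part), a
  polygenic part (independent normal weights on all non-causal SNPs, scaled
  to h²_poly) and a normal residual. The truth record stores *realized*
  fractions (empirical component variance over the realised total), which
  differ from the nominal targets only through sampling covariance between
  components.
- **Distortions**: uniform genotype missingness; `n_hwe_violators` SNPs
  overwritten with fully homozygous genotypes at the same allele frequency
  (inbreeding coefficient 1 — decisively detected by the exact test);
  `drop_causal_snps` removes causal SNPs from the emitted panel while
  keeping their phenotypic effect, reproducing the ungenotyped-causal-variant
  scenario.

All randomness flows from `numpy.random.default_rng` (PCG64) seeded from the
config; cohorts are bit-reproducible across platforms.

What the generator does **not** emulate: realistic human LD block structure
and recombination maps, demographic history, selection, genotyping batch
effects, X chromosome, imputation uncertainty. Passing tests therefore show
that the estimator and its calibration behave correctly under the model's own
assumptions plus first-order LD and family relatedness — not that any
particular real-cohort result is reproduced.

## Test and study sizes

Monte-Carlo checks run at desk scale, sized up front from flop counts so the
suite completes on one CPU:

- *Parameter recovery*: 50 replicates at n = 800, 3,000 SNPs, true h²_poly =
  0.45 and one 100-SNP window at h²_r = 0.05; means within ±0.02 (regional)
  and ±0.05 (whole-genome).
- *Null calibration*: 20 regional scans at n = 400 over 2,000 independent
  SNPs with no QTL (family-wise hit control at the scan's own Bonferroni
  threshold), and a permutation null single-SNP scan over 5,000 LD-free
  SNPs at n = 500 (binomial check of the 5% size). The null panels carry
  little or no LD deliberately: with a small, strongly LD-clustered panel,
  single windows genuinely hold an outsized share of the polygenic variance,
  so flagging them is correct behaviour, not miscalibration — the regional
  null requires the background spread thinly relative to the window, as it
  is on a dense array.
- *Ungenotyped-variant scenario*: replicas preserve the reference study's
  regional noncentrality n·h²_r ≈ 2246 × 0.048 ≈ 108, giving h²_r = 0.18 at
  n = 600 over a 4 × 500-SNP map; causal variants are common (the scenario
  this mirrors concerns a common meta-analysis variant absent from the
  array) and LD is dense (`ld_decay` = 0.95) so the panel can tag the
  removed variants.

## Known limitations

- The two-component REML is dense (O(n³) per iteration); cohorts beyond a
  few thousand need a low-rank regional update, not implemented.
- The χ²(0.5) reference is an empirical calibration of the boundary law, not
  an asymptotic result; its mild anti-conservatism is documented above.
- Score-test p-values assume χ²(1); no saddlepoint correction for very rare
  variants.
- Fine-map windows inherit the coarse scan's null fit; their thresholds use
  the actual fine-window count unless pinned via `pinned_counts`.
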