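# Methods

## The question and the estimand

Self-identified ethnicity correlates with DNA methylation for two distinct
reasons: ethnic groups differ in genetic ancestry (so any
ancestry-associated variant or meQTL creates group differences), and they
differ in environment and exposures. `methadmix` separates these by
fitting, per CpG, nested linear models on the M-value scale and asking (a)
whether the ethnicity association survives adjustment for global genetic
ancestry, (b) how the explained variance splits between ethnicity and
ancestry blocks, (c) how much of an ethnicity effect is *mediated* by an
ancestry proportion, and (d) whether ancestry associations are local (cis,
a nearby variant) or global.

## Generative model of the simulator

One synthetic autosome of genetic length L Morgans (default 2), physical
coordinates via a linear 1 cM/Mb map.

- **Ethnic groups.** Each group g has global ancestry q ~ Dirichlet(α_g)
  over K = 3 ancestries (AFR, EUR, NAM). Default means are anchored to the
  published admixed-cohort medians (Mexican ≈ .043/.405/.554,
  Puerto Rican ≈ .228/.657/.112 AFR/EUR/NAM; the two smaller groups
  intermediate) with concentration 30, which reproduces the within-group
  spread such cohorts show. Default group sizes are the source cohort's
  (276/220/16/61).
- **Local ancestry.** Per haplotype, a continuous-time Markov chain:
  switch points are Poisson with rate G per Morgan (G = 8 generations
  since admixture, a typical Latino-admixture timescale) and the state
  after each switch is redrawn from q. Same-state switches are allowed, so
  the stationary distribution is exactly q and mean inter-switch distance
  is exactly 1/G. The two haplotypes of an individual are independent.
- **Genotypes.** Ancestral allele frequencies are Balding–Nichols draws
  around a shared ancestral frequency with divergence F ≈ 0.2; each
  haplotype's allele is Bernoulli with the frequency of its local ancestry
  at the SNP. Optionally one fixed-difference SNP (frequency 1 in AFR, 0
  elsewhere) emulates a Duffy-null-like variant, with a dedicated CpG 212
  bp away carrying a pure cis-meQTL effect (default 1.35 M per allele).
- **Methylation.** M = intercept + cellsᵀδ + g·β_meqtl + qᵀθ +
  env(group) + plate + ε, then beta = 2^M/(2^M+1). Intercepts are bimodal
  (±2.5 ± 1) like array data. Default residual sd is 0.45 M-units —
  variance ≈ 0.2, the 90th percentile of per-CpG M-variance reported for
  the motivating cohort's pilot data, i.e. a deliberately noisy CpG.
  Effect CpGs are disjoint classes: cis meQTLs (β = 1 M/allele), global-
  ancestry CpGs (θ = 1 M per unit proportion, loaded on AFR or NAM; EUR is
  always the reference), and environment CpGs (±0.5 M shift for one
  group, default Puerto Rican). A configurable fraction of CpGs loads on
  cell composition; plates add small shifts (sd 0.05); detection-p
  failures hit a 0.2% random probe subset.
- **Cells.** True proportions ~ Dirichlet around (.51, .42, .07)
  (granulocytes/lymphocytes/monocytes, whole-blood means), concentration
  200. A separate panel of 100 discriminating probes with cell-specific
  profiles supports reference-based deconvolution; cohort methylation at
  those probes is the true mixture plus N(0, 0.1) noise.

What the generator does **not** emulate: LD within ancestral populations
(only ancestry-induced LD exists), read-level noise, probe cross-
reactivity, sex chromosomes, and beta-scale heteroscedasticity beyond what
the logistic transform induces. Passing tests therefore show that the
*statistical machinery* recovers known architectures under realistic
effect/noise scales — not that it is robust to every artifact of real
array data.

## Statistical procedures

- **Omnibus tests.** All inference is OLS on M-values. A block of
  predictors (k−1 ethnicity indicators; K−1 = 2 ancestry proportions) is
  tested by nested ANOVA: F = ((RSS_r − RSS_f)/df1)/(RSS_f/df2). For
  Gaussian linear models this is the exact-F equivalent of the likelihood
  ratio test. Scans share one design across CpGs and compute RSS via a QR
  projection, so a 2000-CpG scan is a single matrix product.
- **Covariates.** Default adjustment: case status, age, sex, estimated
  cell proportions (two of three — compositional), plate and position.
  Constant covariate columns are dropped (unidentifiable next to the
  intercept).
- **Thresholds.** Bonferroni α/n_probes for discovery. Classification of
  a discovery hit after ancestry adjustment uses nominal p < 0.05 for
  *remains*: ethnicity–ancestry collinearity inflates the adjusted SEs, so
  requiring genome-wide significance after adjustment misfiles real but
  attenuated residual effects as "explained" (on the calibration cohort
  this biased the explained fraction from the true 2/3 to 0.81). The
  genome-wide alternative is one argument away.
- **Stability.** A hit is *unstable* when the adjusted/unadjusted SE ratio
  of any ethnicity coefficient exceeds 10 or any ethnicity/ancestry design
  VIF exceeds 100 — liberal cutoffs that only catch near-collinearity.
- **Non-linearity.** Nested-ANOVA of a non-linear ancestry block over the
  linear term: polynomial (a², a³; 2 df) or cubic-spline. The spline block
  is the three truncated cubics (a − k)³₊ with knots at the 25/50/75%
  ancestry quantiles — next to an existing linear term this is the unique
  cubic-spline departure block with exactly 3 df (a full B-spline basis
  would add 5). Power depends strongly on the ancestry spread: by the
  noncentral-F oracle, a 1 M-unit quadratic effect at sd 0.45, n = 500 has
  ~93% power when ancestry is spread uniformly on (0,1) but far less in a
  concentrated single group.
- **Deconvolution.** Per sample, minimise ‖x − Wᵀp‖² s.t. p ≥ 0, Σp ≤ 1.
  The QP is solved exactly by enumerating active sets (≤ 2^C·2
  equality-constrained solves, trivial for C ≤ 6 cell types); this makes
  noiseless mixtures exact and the solver deterministic. The Σp ≤ 1 (not
  = 1) constraint tolerates unmodelled cell types.
- **HWE.** Exact test by full enumeration of heterozygote counts given the
  allele counts (two-sided: summed probability of outcomes no more likely
  than observed; no mid-p), applied per ethnic group, after a
  missingness > 5% filter.
- **PCoA / PCA.** Classical scaling: Gower double-centering of −D²/2,
  eigendecomposition, coordinates scaled by √eigenvalue; numerically
  negative eigenvalues are clipped with a warning. Genotype PCA centers at
  2p̂ and scales by √(2p̂(1−p̂)) after mean-imputing missing calls and
  dropping monomorphic SNPs. Both orient each axis so its
  largest-magnitude loading is positive (deterministic signs). Genotype
  PCs 3–10 serve as fine-structure covariates (PCs 1–2 are collinear with
  continental ancestry by construction in admixed cohorts).
- **Local ancestry at CpGs.** Diploid dosage is interpolated between the
  flanking SNPs linearly in *genetic* distance (ancestry LD decays with
  genetic, not physical, distance); agreeing flanks reduce to the shared
  state, queries outside the SNP range take the nearest SNP, ties go to
  the left flank. Interpolated dosages stay on the diploid simplex.
  Misses relative to the true tract state are confined to inter-SNP gaps
  containing a switch (~G·gap/4 of haplotype×CpG pairs).
- **Variance partition.** PVE(block) = Var(X_b β̂_b)/Var(y) from the joint
  fit; cross-block covariance is assigned only to the joint term, shares
  are block/joint truncated to [0,1]. A marginal-fit variant exists for
  comparison. Reported medians/IQRs condition on discovery-significant
  CpGs.
- **Mediation.** Two regressions (mediator ~ treatment + covariates;
  outcome ~ treatment + mediator + covariates); ACME = a·b, ADE = c′,
  total = a·b + c′. Uncertainty is quasi-Bayesian: draw a from its
  asymptotic normal and (c′, b) from their joint asymptotic normal (same
  fit), percentile intervals from n_sims = 1000 draws; the mediation p is
  the two-sided tail share of ACME draws. The proportion mediated is
  reported truncated to [0,1]; the raw value is retained. Multi-group
  ethnicity is reduced to a contrast between the two largest groups by
  default. Bootstrap is not implemented; the quasi-Bayesian intervals
  over-cover slightly (≈98% at nominal 95% in the recovery study), which
  is conservative.
- **Conditional cis scan.** SNPs within ±10 kb (boundaries inclusive; 1 Mb
  by flag) are ranked by additive-dosage p; the local-ancestry block is
  then re-tested conditional on the best SNP. At a perfect fixed-difference
  SNP the genotype *equals* a local-dosage column; such absorbed columns
  are dropped from the conditional block (their signal is fully explained),
  and if none remain the conditional p is 1 — the numerically well-defined
  form of "the SNP explains the admixture association".

## Reproducibility and problem sizes

Every stochastic stage draws from an independent, tagged substream of one
master seed (`numpy` SeedSequence with fixed stage tags), so any run is
bit-identical under the same seed, and stages can be re-run in isolation.
The validation studies use the sizes their claims are stated at — null
calibration at n = 200 × 2000 CpGs, mediation recovery at 200 replicates
of n = 500, classification recovery at n = 500 with 300 effect CpGs, the
fixed-difference study at n = 500 — while the demo pipeline and unit tests
use smaller cohorts (60–200 samples, 80–400 CpGs), sizes at which every
property under test is already well-resolved.

## Known limitations

- Global ancestry is derived from the (known) simulated tracts, not
  re-inferred from genotypes; structure inference is exercised only
  through PCA. Real-data workflows would substitute ADMIXTURE/LAMP-LD-style
  estimates with their own error.
- The classifier's explained/remains boundary is threshold-based, not a
  formal test of full mediation; CpGs with both genetic and environmental
  effects are assigned to whichever component dominates at the threshold.
- Single chromosome; trans-meQTL architecture is represented only through
  global-ancestry effects.
- The per-CpG noise sd is constant by default; real arrays show strong
  mean–variance coupling on the beta scale.
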