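# Methods

`mrscreen` implements a metabolome-wide two-sample Mendelian-randomization
(MR) screen for a binary disease outcome, together with the orthogonal
analyses that such a screen needs to be credible: robust MR estimators and
sensitivity diagnostics, multivariable MR (MVMR) for mediation questions,
cross-trait LD-score regression (LDSC), and Firth penalized
logistic-regression burden tests for rare variants. Everything runs offline
on synthetic data with known generating truth; this note records the models,
the numerical conventions, the choices made where the design was open, and
what the synthetic experiments do and do not establish.

## The two-sample MR model

For instrument SNP j, let β̂_Xj (se_Xj) be its estimated per-allele effect
on the exposure and β̂_Yj (se_Yj) its effect on the outcome (log-odds scale
for a case-control outcome), both signed with respect to the same effect
allele. Under the instrumental-variable assumptions each Wald ratio
θ̂_j = β̂_Yj/β̂_Xj estimates the causal effect θ, and the screen's primary
estimator is the inverse-variance-weighted (IVW) mean of ratios with
weights w_j = β̂_Xj²/se_Yj² — equivalently weighted least squares of β̂_Y
on β̂_X through the origin. We use the *multiplicative random-effects*
variant: the residual scale φ = Q/(L−1), with Q the Cochran heterogeneity
statistic, multiplies the variance of θ̂, so balanced pleiotropy widens the
confidence interval rather than biasing the estimate.

### Small-sample inference convention

IVW p-values come from the t distribution with L−1 degrees of freedom, and
MR-Egger slope/intercept p-values from t with L−2 — the exact small-sample
inference for a weighted regression with an estimated residual scale. We do
not floor the residual scale at 1. This combination was chosen after
measuring the alternatives under the screen's own operating conditions
(6–14 instruments per metabolite): flooring the scale and/or using the
normal reference either deflates (type-I ≈ 0.03, null-screen λ ≈ 0.82) or
inflates (type-I ≈ 0.08) the null distribution, while t inference gives
empirical type-I 0.049–0.057 and null-screen λ ≈ 1.00–1.05. A calibrated
null is the load-bearing property of a 566-metabolite screen with Bonferroni
correction, so it decides the convention.

### Estimator battery

- **MR-Egger**: weighted regression of β̂_Y on β̂_X *with* an intercept,
  after orienting every instrument to a non-negative exposure effect. The
  intercept estimates average directional pleiotropy; the slope is a
  bias-adjusted causal effect valid under the InSIDE assumption. The
  I²_GX statistic (dispersion of β̂_X relative to se_X) is reported as the
  weak-instrument-dilution diagnostic; values near 1 mean the Egger slope is
  essentially undiluted.
- **Weighted median**: the 0.5 point of the cumulative standardized weights
  over sorted ratios, linearly interpolated; consistent while >50% of the
  weight comes from valid instruments. Standard error by parametric
  bootstrap (β̂* ~ N(β̂, se), default 1000 draws, seeded).
- **Weighted mode**: the argmax of the w-weighted Gaussian kernel density of
  the ratios on a fixed 512-point grid spanning the ratio range ±3
  bandwidths, with the modified Silverman bandwidth
  h = φ_bw·0.9·min(sd, IQR/1.349)·L^(−1/5) (φ_bw = 1 by default); zero
  modal pleiotropy assumption; bootstrap standard error as for the median.
- **MR-Lasso**: per-SNP pleiotropy intercepts α_j penalized by λΣ|α_j|,
  solved by coordinate descent (soft-thresholding) on a 50-point descending
  log grid from λ_max (the smallest λ with all α = 0) down to λ_max/1000.
  The penalty is relaxed until the zero-α ("valid") subset is first
  homogeneous by Cochran's Q at the 0.95 χ² quantile; the reported estimate
  is IVW on that subset. With no pleiotropy the rule stops at the top of
  the grid and the estimate reduces exactly to IVW; if no λ yields a
  homogeneous valid subset of ≥2 SNPs, the full-set IVW is returned with a
  warning flag.

The weighted median's bootstrap standard error is *conservative* at small
instrument counts: at L = 10 it exceeds the empirical sampling sd by about
10%, and the studentized statistic is platykurtic, giving an empirical
type-I rate near 0.025 at nominal 0.05 (1000 seeded null replicates). This
is a documented property of the estimator, not an implementation artifact;
the acceptance suite records it as a two-sided calibration failure rather
than hiding it.

## Harmonization, clumping, proxies

Harmonization aligns outcome effects to the exposure effect allele: direct
match keeps β̂_Y, swapped labels negate it (and reflect the frequency),
strand complementation is attempted only when both direct and swapped
matching fail. Palindromic (A/T, C/G) SNPs cannot be resolved by labels;
they are dropped when the exposure-side minor allele frequency exceeds 0.42
(or when either frequency is missing — a conservative extension for the
undiscussed missing-frequency case) and otherwise oriented by frequency
agreement across the two traits. Every drop, flip and substitution is
appended to a provenance list, and harmonization is idempotent.

Clumping is the standard greedy procedure against a reference dosage panel:
candidates sorted by (p, rsid) — the rsid tie-break makes the result
invariant to input order — and retained iff r² ≤ 0.001 with every
already-retained SNP on the same chromosome within the window. The window
defaults to 10,000 kb (the conventional genome-scale default; a literal
10 kb window is available as configuration but leaves long-range LD
unpruned). r² of a monomorphic variant is defined as 0 with a warning so
clumping stays total. Instruments absent from the outcome are replaced by
the highest-r² available proxy with r² ≥ 0.9; the sign of the dosage
correlation supplies the allele orientation, which is chained with the
raw-allele orientations of both summary-statistics records.

Note that r² between truly independent variants has a sampling floor of
≈1/n_samples, well above the 0.001 ceiling; the ceiling therefore acts
within LD neighbourhoods (where the window confines comparisons), exactly
as in real genome-wide practice where independent instruments sit at
distant loci.

## Sensitivity battery and the inflation factor

Cochran's Q = Σ w_j(θ̂_j − θ̂_IVW)² with df = L−1 (identically (L−1)·φ).
The MR-PRESSO global test simulates the null distribution of the
leave-one-out residual sum of squares RSS = Σ(β̂_Yj − θ̂_(−j)β̂_Xj)²/se_Yj²
by parametric draws around the leave-one-out fits, with the add-one p-value
estimator (1+#{RSS* ≥ RSS})/(sims+1); instruments are put in canonical
(rsid) order before simulation so the p-value is order-invariant at a fixed
seed. Leave-one-out IVW estimates use closed-form delete-one updates of the
weighted mean and Q (algebraically identical to refitting) and flag runs
where a single SNP carries significance or flips the sign.

The screen inflation factor λ is computed on the genomic-control scale:
p-values are converted to χ²₁ quantiles and λ is the observed median over
0.4549 (the χ²₁ median), so λ ≈ 1 under a global null. The literal ratio of
median p-values is exposed as `scale="pvalue"`; the two agree at the null
and rank inflation the same way.

## The screen

Per metabolite: filter to p < 5e−6 (a deliberately liberal instrument
threshold — power over purity, with the diagnostics battery as the
backstop), clump, proxy, harmonize, fit IVW-MRE, run the full battery. The
instrument-count filter keeps analyses with 6–14 SNPs: very small counts
give single SNPs undue weight, very large counts accumulate heterogeneous
outliers. λ is reported before and after the filter, Bonferroni correction
uses the post-filter test count (the pre-filter denominator is also
reported), and `tune_count_filter` selects count bounds minimizing |λ−1|
over an explicit candidate grid (ties to the widest interval). An
alternative heterogeneity filter (drop Q_p ≤ 0.05, keep L ≥ 6) is provided.
A per-metabolite seed derived from CRC32 of the exposure id keeps every row
reproducible and order-independent. The within-screen PheWAS cross-check
flags instrumental SNPs of a hit that associate (p < 5e−6) with any other
screened metabolite and refits without them; `replicate` reruns hits
against a second outcome GWAS.

## Multivariable MR

With d exposures, θ is the weighted least-squares solution of
β̂_Y ≈ Σ_k θ_k β̂_Xk (no intercept, weights 1/se_Y²); residual
heterogeneity Q_A has L−d df and the same multiplicative-scale convention
as IVW. Instrument sets are the union of per-exposure selections, clumped
jointly by the minimum p across exposures (preserving the strongest
instrument of either exposure) and harmonized across all d+1 traits onto
the first exposure's effect alleles. Conditional instrument strength for
exposure k regresses β̂_Xk on the other exposures' columns (weights
1/se_Xk², no intercept) and divides the weighted residual sum of squares by
L−d; >10 is the conventional adequacy bound. Cross-exposure sampling
covariance is taken as zero, appropriate when exposures come from
independent cohorts. Exactly singular designs raise an error naming the
collinear exposure pair; a d = 1 fit reproduces univariable IVW to machine
precision.

## LD-score regression

E[z1_j z2_j] = ρ_g√(n1 n2)·ℓ_j/M + intercept; the slope of the weighted
regression of z-score products on LD scores rescales to the genetic
covariance ρ_g. Weights are the single-pass heteroskedasticity form
1/(1+ℓ)² rather than the reference tool's iterative two-step weighting —
a deliberate simplification that is adequate for screening near-zero
covariances (the use-case here) and is exact in expectation; the intercept
is estimated, not constrained, so sample overlap would be absorbed rather
than assumed away. Standard errors come from a delete-one block jackknife
over contiguous SNP blocks (200 by default), implemented with sufficient-
statistic downdates. Input filtering intersects the traits with a keep-list
(HapMap3-style), drops strand-ambiguous SNPs and MAF < 1%, and sign-aligns
trait 2 onto trait 1's effect alleles before forming z = β/se.

## Firth burden testing

Qualifying variants (external reference MAF < 1%; either all missense or
the disruptive loss-of-function classes: frameshift, splice site, exon
loss, stop gained/lost, start lost, transcript ablation) are collapsed per
sample to a carrier indicator (allele-count collapsing is a switch; the
indicator is the standard choice for ultra-rare variation). Case status is
regressed on [burden, sex, platform, 10 PCs, intercept] by Firth logistic
regression: Newton iteration on the modified score
U*_r = Σ_i (y_i − π_i + h_i(½ − π_i))x_ir with penalized-fit leverages h_i
and step-halving on the penalized likelihood ℓ(β) + ½log det I(β). The
Jeffreys penalty keeps estimates finite under complete separation — the
regime rare variants routinely produce. The burden p-value is a penalized
likelihood-ratio test: the restricted optimum re-maximizes the same
penalized likelihood (full-design penalty) with the burden coefficient
fixed at zero; the Wald p is also reported. Missing genotypes are imputed
homozygous-reference with logging; missing external frequencies fall back
to cohort frequency with a warning.

## Synthetic data: what it emulates and what it does not

Summary statistics are simulated directly at the summary level:
β̂_Xj = γ_j + N(0, se_Xj), β̂_Yj = θγ_j + sign(γ_j)·α_j + N(0, se_Yj), with
se = 1/√(2·maf(1−maf)·N) for a standardized trait. Pleiotropic effects α_j
are defined relative to the exposure-increasing allele (the orientation
under which "directional" is meaningful and which MR-Egger adopts);
balanced mode is mean-zero by construction. The reference panel generates
Hardy–Weinberg dosages by thresholding two blockwise-AR(1) latent Gaussian
haplotypes; LD blocks are placed 20 Mb apart so that, as in real data,
cross-locus pairs are never inside a clump window.

Default study conditions: exposure GWAS n = 20,000 and outcome n = 30,000
(metabolite-GWAS and ALS-GWAS scale); per-SNP instrument strength
F ~ U(30, 100) for generic liberal-threshold instruments in `make_truth`;
F ~ U(200, 2000) for screen metabolites and U(300, 3000) for the mediation
exposures, reflecting the strong cis-acting loci that drive serum
metabolite and vitamin levels — this is what makes a 0.05 log-odds/SD
effect detectable at metabolome-wide significance with ~10 SNPs, matching
the scale of real reported estimates (se ≈ 0.01). Screen fixtures draw
instrument counts from U{4..20} so the count filter has work to do; planted
causal metabolites draw counts from U{10..14} and strength from
U(1000, 3000), a power-run design: with θ = 0.05 fixed, detectability at
the Bonferroni threshold requires E[t] ≈ 9, and planting an undetectable
hit would test nothing. The directional-pleiotropy power fixture uses
α ~ N(0.08, 0.01), again from a power analysis: the Egger intercept's
standard error under these fixtures is ≈0.02, so ~3.5σ pleiotropy is the
smallest magnitude a >80% detection claim can honestly be made about.

The generators do **not** emulate: genome-wide LD maps (LD exists only
within synthetic blocks), population stratification, sample overlap between
exposure and outcome GWAS, winner's-curse in instrument selection from a
discovery scan, or allele-frequency differences between panels. Passing
tests therefore demonstrate internal statistical correctness and
calibration of the machinery under the stated generating model — not
robustness to those real-data pathologies.

The mediation fixture wires exposure A to deplete mediator B
(q = −0.5) and B to affect the outcome, with disjoint instrument sets; with
zero direct effect, univariable MR of A shows its total effect
(θ_direct + θ_via) while MVMR attenuates A to its direct effect — the
conditioning logic the MVMR module exists for. The LDSC fixture draws
per-SNP genetic components with per-SNP covariance ρ_g√(n1n2)ℓ/M plus unit
sampling noise, the exact regression model. The cohort generator draws rare
genotypes binomially, covariates (sex, platform, 10 small PCs), and case
status from a logistic model whose intercept targets the requested case
fraction; extreme carrier log-odds produce separation scenarios on purpose.

## Numerical details and degenerate inputs

Exact-fit degeneracies (zero residual scale) return p = 0/1 explicitly
rather than dividing by zero. Instruments with β̂_X = 0 are excluded from
ratio tables with provenance. The weighted-mode grid is configuration
(512 points default); doubling it moves the mode by less than h/10.
Bootstrap replicates default to 1000 with a mandatory seed; calibration
experiments in the test-suite use 100–200 replicates, a problem-size choice
that leaves the se estimate's own noise well below the quantities asserted.
MR-PRESSO requires L ≥ 4 and marks itself not-applicable below that rather
than failing a screen row. All random streams derive from explicit seeds;
screens derive per-metabolite seeds from the global seed and the exposure
id, so results are independent of metabolite order.

## Problem sizes used by the acceptance experiments

Type-I calibration uses 2000 null replicates for IVW and 1000 for Egger and
the weighted median; recovery and power runs use 200–500 replicates; screen
calibration uses 200-metabolite screens replicated 100 times in the test
suite and 30 times in `scripts/acceptance.py`; burden calibration uses
500–1000 cohorts of 600–800 samples. These sizes put Monte-Carlo error
comfortably below every asserted margin while keeping a full run on one CPU
in minutes.

## Known limitations

- The weighted median/mode bootstrap is conservative at small L (see
  above); interval coverage is above nominal rather than below.
- MR-Lasso's λ rule stops at the first homogeneous valid subset; with
  clustered pleiotropy several subsets may be defensible and the rule picks
  the largest-λ one.
- LDSC's single-pass weights are less efficient than iterative weighting
  for strongly heritable trait pairs; the point estimate is unaffected in
  expectation.
- The proxy search considers LD only through the panel's dosage
  correlation; phased-haplotype measures (D′) are out of scope.
- Burden testing assumes unrelated samples; kinship correction is out of
  scope.
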