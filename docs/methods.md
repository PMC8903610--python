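# Methods

`holoquail` reimplements, against simulated data with known ground truth, a
hologenomic analysis of a quail F2 intercross: how strongly host genetics
shapes the relative abundances of ileal bacterial genera, how those genera
feed back on phosphorus utilization (PU) and related performance traits,
where in the genome the host control sits, and how well host genome and
microbiota predict the traits.  This note records the models, the choices
made where the design was genuinely open, and what the synthetic data do
and do not emulate.

## The synthetic study

`simdata` generates a three-generation design: two divergent founder lines
(12 males + 12 females each), an F1 generation from line-A sire x line-B
dam matings, 17 F1 sires each mated to 2 F1 dams, and up to 920 F2 birds
of which 758 carry complete records (microbiota composition, SNP
genotypes, trait records).  ~3,986 SNPs are placed on 24 linkage groups
whose map lengths fall from 200 to 20 cM; markers recombine without
interference (Haldane map function), so the sequential-Bernoulli gamete
sampler and the linkage-scan HMM share one model.

**Founder lines.** By default the lines are fully inbred and fixed for
alternate alleles.  That makes every F1 heterozygous at every marker and
the F2 genotype-class probabilities exact — the property the QTL machinery
is validated against.  It has a sharp corollary: because every parent of
an F2 is identically heterozygous, single-locus genotypes of two F2
individuals are uncorrelated, so the expected off-diagonal of the VanRaden
genomic relationship matrix is zero for *every* pair, however related.
Genomic resemblance between relatives, and hence any correlation between
G and the pedigree matrix A, requires polymorphic founders.
`SimConfig.founder_line_freq` (default 1.0) relaxes the fixation: at e.g.
0.8 each founder haplotype carries its line's characteristic allele with
probability 0.8, giving divergent outbred lines like the real study's.

**Genetic architectures.** Each genus and each trait declares how its
additive values arise: `"pedigree"` (infinitesimal model dropped along the
pedigree; resemblance follows A — what the pedigree-based heritability
machinery assumes) or `"markers"` (a sum of genome-wide SNP effects,
rescaled so the sample variance equals the requested `s2_a`; resemblance
follows the realized G — what genomic prediction requires).  Under fixed
founder lines these two are *not* interchangeable (see above), so tests of
pedigree-REML use the former and tests of GBLUP the latter.

**Microbiota.** Per genus the latent value is
`mu + QTL effects + additive value + test-day effect + residual`, with the
latent variance normalized to 1 so `s2_a` is directly the latent
heritability (defaults: 24 of 59 genera heritable, h2 from 0.04 to 0.17,
test-day variance 0.10).  Latent vectors are exponentiated and
renormalized per bird to relative abundances; a Box-Cox transform of the
result is therefore approximately linearizing.  Abundances below a
detection floor (default 1e-6) are zeroed.  Each genus is split into its
OTUs by per-sample Dirichlet draws around fixed within-genus weights
(concentration 300), so genus totals are preserved exactly.  A planted
additive QTL with effect `a` contributes `a (g - 1)` on the latent scale;
an effect explaining 5% of latent variance has `a = sqrt(0.1)` (F2
additive variance `a^2/2`).

**Traits.** The latent trait is
`z = test-day + additive value + sum_g lambda_g g_std + residual`, where
`g_std` is the standardized log relative abundance of genus `g`; the
recorded phenotype is `mu + scale * z`.  Because variances are chosen so
var(z) is about 1, each `lambda_g` is directly in phenotypic-SD units —
the scale on which recursive effects are reported (|lambda| <= 0.1 by
default).  Field-realistic scales: PU 65 +- 6 % of P intake, FI 60 +- 8 g,
BWG 30 +- 5 g over the 5-day test, body weight at day 10 50 +- 4 g.
F:G is derived as FI/BWG (never simulated directly), P intake as
FI x 4.5 mg/g (a low-P corn-soy diet), and P excretion as
`intake x (1 - PU/100)` plus 0.2 mg of measurement noise, so the derived
PU reproduces the simulated one almost exactly.

**What the generator does not emulate:** sequencing reads and depth-driven
zero inflation (only the detection floor), sex chromosomes, genotyping
errors and missingness (the QC filters are exercised on constructed
fixtures instead), diet/housing variation beyond the test-day effect, and
reverse causality from feed intake to the microbiota.  Tests passing on
these simulations show the estimators recover the parameters of *this*
generative model; they cannot certify the biological assumptions (e.g.
the genus -> trait direction of the recursive model) on real data.

## Preprocessing

Counts are closed to relative abundances per sample.  OTUs aggregate to
genera by summation; OTUs without a genus label pool into per-family
`unclassified_<family>` buckets.  The mean-abundance filters follow the
field's phrasing exactly: genera are kept at mean >= 0.01% (inclusive),
OTUs at mean > 0.0001% (strict).  The Box-Cox parameter is a grid argmax
(grid [-2, 2], step 0.005) of the normal profile log-likelihood including
the Jacobian term `(lambda - 1) sum log y`; zeros are replaced by half the
genus's smallest positive value first (rank-preserving; the alternative of
dropping zero-containing genera would discard most of the table).  PU is
fixed as percentage retention, `100 (P_in - P_out) / P_in`.

## Variance components: AI-REML

All mixed models run through one engine for variance structures linear in
their parameters, `V = sum_k theta_k K_k`: average-information updates
with step halving against the restricted likelihood, an EM-style
multiplicative fallback when an AI step cannot improve, variances clamped
at a floor of `1e-6 x var(y)`, and components pinned at the floor with
negative score dropped from the Newton system (otherwise the flat
direction stalls convergence short of the optimum).  Convergence is
`|delta logL| < 1e-8`.  The engine is validated against dense grid search
of the restricted likelihood at small n.

Heritability per genus is `h2 = s2_a / (s2_a + s2_td + s2_e)` — the
test-day variance stays in the denominator.  The likelihood-ratio
statistic for the animal term is referred to a plain chi-square with 1 df
(the boundary-respecting 50:50 mixture is available as an option but the
plain reference matches the reported p-value semantics).  FDR q values are
step-up against a fixed family size (59 genera) even when only the
significant p values are supplied; a Storey-style pi0 rescaling is
available but indistinguishable on partial families.

## Recursive structural equation model

The genus -> trait pair is fit in reduced form: a bivariate REML (genus
first, trait second) with unstructured 2x2 test-day and genetic
covariances, diagonal residual covariance (the identifiability
constraint), and the observed genus value entering the trait equation as
a fixed regression whose coefficient is the structural coefficient
lambda.  This is exactly the structural model's likelihood — the
(I - Lambda) transform has unit Jacobian — and lambda-hat equals the GLS
coefficient at the estimated dispersions, which the tests verify.

Two reporting choices were open:

- **Standardization.**  "lambda in sigma_p units" is implemented as
  `lambda x sd(genus) / sd(trait)` with both phenotypic SDs taken from
  P* = T* + G* + R*.  Dividing by the trait SD alone would leave the
  value tied to the arbitrary Box-Cox scale of the genus; with the genus
  standardized the two conventions coincide.
- **The SE of lambda.**  The naive fixed-effect (GLS) SE is
  anticonservative here, because lambda competes with the genetic and
  test-day covariances to explain the genus-trait association —
  identification rests only on the diagonal-R constraint — and because
  the genus covariate is endogenous whenever the true genetic covariance
  is nonzero.  The default SE is therefore taken from the curvature of
  the restricted likelihood profiled over lambda (three warm-started
  fixed-lambda fits); simulation shows it calibrated (about 100% coverage
  of +-2 SE under the null) where the GLS SE covers only ~75-80%.
  `se_method="gls"` restores the naive value.

System dispersions map to no-recursion parameters through the
`(I - Lambda)^{-1}` sandwich; genetic and phenotypic correlations are read
off G* and P*, clipped into [-1, 1] (REML covariances are not constrained
PSD), with delta-method SEs propagated numerically from the AI asymptotic
covariance (lambda held at its estimate).  Only the starred matrices are
reported.  The recursion direction is fixed genus -> trait for all four
traits.

## QTL linkage mapping

Genotype-class probabilities come from a three-state forward-backward HMM
on a 1-cM grid (markers always included), Haldane transitions over two
independent meioses, and a genotyping-error emission (default 1e-4).
The inbred-line F2 model replaces the outbred-line machinery of the
original analysis; externally computed probability grids can be supplied
as a `GenoProb` directly.  The scan regresses the phenotype on intercept,
test-day dummies, the additive score `P(BB) - P(AA)` and the dominance
score `P(AB)`; `LOD = (n/2) log10(RSS0/RSS1)` against the covariates-only
null.  Collinear covariates are projected out (with a warning), so
adding redundant columns leaves the profile unchanged.

Permutations shuffle phenotype and covariate rows jointly against the
genotype probabilities — implemented by inversely permuting the
probability scores, which gives identical LOD profiles — keeping the
test-day/phenotype association intact (default 10,000 permutations;
reduced counts are used where runtime matters, see below).  Support
intervals take the contiguous run above `peak - 1.5` LOD, extended one
grid point past each crossing and clipped at chromosome ends; ties at
the maximum resolve to the leftmost position.  Within-interval SNP
association fits the polygenic model once per interval (REML with a
leave-one-chromosome-out G) and then tests each SNP's allele count by
GLS at those components (Wald); with the polygenic variance at zero this
reduces exactly to OLS.  No multiple-testing correction inside the
interval.

## Hologenomic prediction

MBLUP: `y = mu + td + k + e`, `k ~ N(0, M s2_k)` with M from
log-transformed (offset 1e-6), column-standardized OTU abundances,
`M = XX'/n_otus` — the common form of the construction, since the exact
formula lives in prior literature; its mean diagonal is 1 by algebra.
Microbiability is `s2_k / (s2_k + s2_td + s2_e)`.  GBLUP replaces A by
VanRaden method-1 G.  The two-step mediated predictor re-fits the
microbiota effects and feeds `k-hat` into `k-hat = mu + m + e` with
`m ~ N(0, G s2_m)`; `h2_k = s2_m / (s2_m + s2_e)`.

Cross-validation uses repeated random 80/20 splits with variance
components fixed at full-data estimates.  Validation effects are
predicted through the covariance linking validation to training animals
(partitioned BLUP); for the mediated predictor the microbiota effects are
re-estimated inside each training fold (BLUP at fixed components) to
avoid leakage — using full-data `k-hat` is available as an option.
Accuracy is the raw Pearson correlation between predicted effects and
observed validation phenotypes, not divided by h; splits are simple
random draws without test-day stratification.

## Problem sizes and numerical choices

The validation suite runs the stated conditions where they matter
statistically — heritability recovery on 30 replicate n = 400
populations, SEM lambda recovery on 20 replicate n = 800 populations, QTL
detection on 20 replicate n = 600 genomes — and smaller fixtures for
exact algebraic checks.  `scripts/acceptance.py` analyses one
study-condition population (920 F2, 758 phenotyped, 59 genera, divergent
outbred founder lines at line-allele frequency 0.8, matching the real
cross) with 1,000 permutations per scanned genus and 100
cross-validation repetitions; these counts, chosen as a sensible demonstration scale,
only widen the Monte-Carlo noise of thresholds and CIs relative to the
10,000/500 defaults and can be raised via `--n-perm`/`--cv-reps`.

Stabilization adds 1e-6 to the diagonal of G and M before any
inversion-dependent use (M is rank-deficient whenever samples outnumber
OTUs).  Missing genotypes are mean-imputed per SNP in G; the Mendelian
conflict check treats missing calls as compatible.  Relationship-matrix
alignment is by individual identifier throughout, so table order never
matters.

## Known limitations

- The pedigree-based and marker-based genetic architectures cannot both
  be satisfied by one simulation under fixed founder lines (see "Founder
  lines"); real outbred founders do not have this dichotomy.
- The GLS SE of lambda (and the reported SEs of r_g, which ignore the
  lambda-dispersion cross terms) understate uncertainty near weak
  identification; the profile SE repairs lambda but r_g SEs remain
  first-order.
- The QTL HMM assumes fully informative markers; with
  `founder_line_freq < 1` the probabilities are approximations.
- Model-1 heritabilities of transformed compositions are mildly
  attenuated by the shared closure term of the log-ratio geometry; at 20+
  genera the effect is within the tested tolerance.
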