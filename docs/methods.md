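# Methods

`phenosel` implements a complete genomic-versus-phenomic prediction
workflow for plant-breeding trials — from plot-level phenotypes and
grain near-infrared (NIR) spectra to adjusted genotype means, marker-
and spectra-derived relationship matrices, cross-validated kernel-BLUP
predictions, and the predictor-bias diagnostics that compare the two
prediction routes. Because the breeding data such analyses run on are
proprietary, the package ships a synthetic-study generator that encodes
the statistical structure the analysis assumes; every stage is validated
against that generative truth.

## Two-stage phenotypic adjustment

Stage 1 fits, per trial (one location-year), the spatial mixed model

    y_ijk = mu + g_i + r_j + c_k + sp_jk + e_ijk

with random row (`r_j`) and column (`c_k`) effects and a smooth spatial
surface `sp_jk` modelled as a tensor product of cubic B-spline marginal
bases with a single isotropic variance. The default basis size is
`min(10, ceil(dim/2))` functions per margin — enough to recover smooth
fertility trends on the trial sizes we target while keeping the REML
problem small; it is configurable via `spline_basis`. This is a
deliberate simplification of the PS-ANOVA decomposition used by
dedicated spatial packages (three smoothing parameters, explicit
polynomial parts); the simpler form recovers injected surfaces with
correlation > 0.8 in our validation battery, which is what the
downstream adjustment needs.

With genotypes *fixed* the model yields per-trial BLUEs; with genotypes
*random* it yields the variance components of single-trial
repeatability

    rep^2 = sigma2_G / (sigma2_G + sigma2_e / r_bar).

Stage 2 fits, per location, `y_ij = mu + g_i + y_j + e_ij` on the
per-year BLUEs, giving across-year BLUEs (genotypes fixed) or
broad-sense heritability H^2 (genotypes random, same algebra with
`r_bar` now the effective number of years).

`r_bar` is the harmonic mean of per-genotype observation counts
(an arithmetic-mean option exists). The harmonic mean is the
entry-mean-basis convention for unbalanced designs; for a p-rep trial
with a quarter of entries duplicated it equals 1/(0.8/1 + 0.2/...) ≈ 1.25.

The same two-stage machinery is applied independently to every spectral
wavenumber. A wavenumber whose fit fails to converge (or is numerically
constant) falls back to the plain mean over all entries, and each
substitution is logged with its location, stage and wavenumber.

### REML engine

All variance components are estimated by REML. The generic
multi-component engine profiles the residual variance and the fixed
effects out of the restricted likelihood and searches the log variance
ratios by Nelder–Mead (ratios bounded in [1e-8, 1e8]; iteration cap 200
per dimension; a fit that ends at a bound or at the iteration cap is
flagged `converged=False`). Two structural optimisations keep the
per-wavenumber fits cheap without changing the estimator: all linear
algebra runs through the Woodbury identity on the stacked random-effect
design (cost `O(q^3)` in the number of random-effect levels, independent
of the number of plots), and when the fixed design is a genotype
incidence matrix (diagonal X'X) the matrix-determinant lemma removes the
cost of the fixed dimension as well. Designs are built once per trial
and refitted across wavenumbers with warm starts; the per-wavenumber
tolerance is relaxed to `xatol=2e-3` on the log-ratio scale, which moves
BLUEs by far less than their standard errors.

The single-kernel model `y = 1 mu + g + e`, `g ~ N(0, K sigma2_g)`, is
fitted by eigendecomposition of K: the restricted likelihood becomes a
one-dimensional function of `lambda = sigma2_e / sigma2_g`, maximised by
a coarse grid over `log lambda in [-8, 8]` followed by bounded Brent
refinement (tolerance 1e-8). Validation-set predictions use the
train-conditional expectation `mu + K_vt (K_tt + lambda I)^{-1}
(y_t - mu)`, which for this model is equivalent to solving the full
mixed-model equations with the validation responses missing, and is
directly testable against ridge regression: GBLUP predictions equal
rrBLUP predictions with `lambda_m = m * lambda` to 1e-6, which the test
suite asserts at n=200, m=1000.

## Spectra

Pretreatments follow standard chemometric practice: SNV (per-sample
standardisation, sample-variance convention), quadratic detrending
(OLS residual on the wavenumber grid), and Savitzky–Golay first/second
derivatives (default window 37 points, polynomial order m+1). SG output
is trimmed to the interior positions where the full window fits —
padding would invent data, and the kernel only needs relative
covariance. Non-uniform grids are rejected rather than silently
resampled. A descending instrument grid is reversed on input and the
reversal recorded in the pretreatment provenance, which is append-only
and replayable.

The spectral relationship matrix is built from genotype-level spectra
(across-year BLUEs per location): columns are centred/scaled with the
sample-sd convention, then rows with the population-sd convention, and

    H = S S' / l

with `l` the number of wavenumbers. The row convention makes
`diag(H) = 1` exact and off-diagonals equal to Pearson correlations of
genotype spectra. The double standardisation is a single column-then-row
pass; it is *not* idempotent (re-applying perturbs values at
`O(1/sqrt(n))`), which is why the kernel contract is stated in terms of
the exact properties that matter: unit diagonal, symmetry, positive
semi-definiteness.

## Markers and G

Markers are coded {-1, 0, 1}; allele frequency is estimated from the
data (heterozygotes count half). Missing calls are imputed by column
mode by default, or by a chromosome-wise k-nearest-neighbour majority
vote; imputation quality is not a focus here, and at the default 2%
missingness the resulting G matrices are nearly indistinguishable.
Markers with minor-allele frequency below 5% are dropped *after*
imputation (boundary retained). The genomic relationship matrix is
VanRaden's: `Z = M - (2p - 1)`, `G = ZZ'/(2 sum p(1-p))`.

Matrix comparison uses the Mantel correlation (Pearson over
strictly-lower-triangle entries; permutation p-value by simultaneous
row/column permutation) and cumulative-variance profiles of the leading
principal components.

## The synthetic study

The generator emulates a winter-wheat advanced-yield-trial series:
461 lines, three locations, four years, p-rep trials with a quarter of
entries duplicated, six traits (GY grain yield dt/ha, PC protein
content %, HD heading date, PH plant height cm, TW test weight kg/hl,
TKW thousand-kernel weight g), and grain NIR spectra on a 700-point
grid over 4000–12500 cm^-1. All sizes are configurable; the validation
battery and the acceptance script run a scaled-down analogue (250
genotypes, 250 markers, 80 wavenumbers) chosen so the whole battery
completes in minutes on a single laptop core while keeping per-fold
REML estimates stable.

Generative structure, term by term:

* **Markers.** Independent biallelic loci on 21 chromosomes for fully
  inbred lines; allele frequencies uniform on the MAF range. Linkage
  disequilibrium is deliberately absent — VanRaden G and the
  GBLUP/rrBLUP equivalence do not require it, and independent loci keep
  every oracle exact. A consequence worth noting: with independent
  loci the number of simulated markers *is* the effective marker
  dimensionality, so the scaled-down runs use a few hundred markers to
  emulate the effective dimensionality that a dense, LD-structured
  6.7k-marker panel has on a few hundred related breeding lines.
* **Breeding values.** A shared set of QTL (default 300) with per-trait
  effects drawn jointly from `N(0, rho_G)`, then rescaled to each
  trait's genetic SD — genetic correlations therefore emerge through
  shared loci, and the realised correlation matrix is reported in the
  truth object. The default `rho_G` puts the GY–PC correlation at
  -0.8: the starch/protein trade-off is genetically entrenched, and
  with GY heritability ~0.3 a strong genetic correlation is what
  produces the weak-to-moderate phenotypic correlations seen in
  breeding data.
* **GxE.** Each trial adds per-genotype deviations with SD calibrated
  from the trait's heritability target (`H2 = g^2/(g^2 + s2_e2/n_years)`
  solved for the GxE variance). Deviations are correlated across traits
  by `rho_E`, default nearly diagonal except a *positive* 0.10 for
  GY–PC: environmentally, a favourable season or nitrogen status lifts
  yield and protein together, which attenuates the phenotypic GY–PC
  correlation into the observed band. TraitSpec carries an explicit
  `gxe_sd` override.
* **Trials.** Serpentine row-major p-rep layout with randomised entry
  order; random row/column effects (default 0.4 x residual SD); a
  smooth fertility surface (Gaussian-filtered noise, standardized,
  scaled by `spatial_amplitude x residual SD`, shared shape across
  traits) stored in the truth object for recovery tests.
* **Spectra.** Per plot: a fixed smooth background plus Gaussian
  absorption bands, each driven by the z-scored plot values of a
  composition trait (PC dominates; TW and TKW contribute), a per-year
  scalar, or per-plot noise; wrapped in per-plot affine scatter
  `a + b * spectrum` plus white noise. **Grain yield is never a direct
  driver** — any GY information in the spectra flows only through the
  GY–PC (and weaker GY–TW/TKW) correlations, which is precisely the
  mechanism the predictor-bias analysis interrogates. SNV removes the
  affine scatter exactly in the noise-free limit (asserted as an
  algebraic test).

What the generator does *not* emulate: real NIR physics (water bands,
Beer–Lambert chemistry, wavelength-dependent scatter), marker LD and
pedigree structure, selection-induced correlations between phenology
and quality, and year-to-year heterogeneity of trial design. Passing
tests therefore demonstrate that the pipeline's estimators recover the
structure this model encodes — not that any particular real dataset
will show the same effect sizes.

## Cross-validation and bias diagnostics

For each population size (default 100/200/300/400 at full scale;
60/130/210 in the scaled battery) and each of 20 repetitions, a random
sample of genotypes is split into five folds of near-equal size; each
fold is predicted once from the other four. Prediction ability is the
per-fold Pearson correlation of predictions with observed BLUEs,
averaged across folds — the per-fold convention; a pooled alternative
is a one-liner on the tidy records. Predictor bias is the per-fold
correlation of the predictions with a secondary trait (PC), compared
with the phenotypic correlation of target and secondary trait on the
complete set. Degenerate folds (constant predictions) are dropped from
aggregates with a logged count.

Selection indices per location: GYD (residuals of GY regressed on PC),
PY = GY x PC / 100 (dt/ha with PC in percent — the bare product would
not carry yield units), and EWPY = z(GY) + z(PC) with per-location
standardisation constants. Index predictions are evaluated by their
correlations with GY and PC against the complete-set references.

On the default scenario the battery asserts the headline contrast: the
spectra-derived kernel's GY predictions over-correlate with PC by more
than 0.1 beyond the phenotypic reference, while the marker-derived
kernel's predictions stay within 0.1 of it; GBLUP's ability grows
faster with training-set size than HBLUP's; H reaches 90% of its
variance within 5 principal components while G needs more than 10; and
HBLUP's EWPY predictions over-correlate with PC. The fixed-seed
scaled-down conditions for these checks were chosen once (scenario seed
1; bias evaluated at the largest size stratum, mirroring the full
study's use of its largest sample for the bias analysis) and the
per-location phenotypic GY–PC correlation is calibrated into the
[-0.45, -0.20] band; per-location estimates at 250 genotypes scatter
around their mean with an SE of about 0.06, so band membership is
asserted on the location mean.

## Numerical conventions and edge cases

* Variance ratios live in [1e-8, 1e8]; hitting a bound flags
  non-convergence. Perfect-fit responses clamp the profiled residual
  quadratic form at a tiny positive value.
* SNV refuses constant samples (named in the error); the kernel
  standardisation refuses constant rows/columns (indices listed).
* MAF boundary: markers at exactly the threshold are retained.
* Mantel refuses constant off-diagonal vectors; relationship matrices
  validate symmetry to 1e-10 and eigenvalues >= -1e-8 at construction.
* CV with `size % k != 0` puts the remainder one-per-fold (sizes differ
  by at most one).
* All generators and designs are pure functions of their inputs and an
  explicit integer seed; configs without a seed fail validation.

## Known limitations

* The spatial model is a single-variance tensor-spline approximation;
  it is not an AR1xAR1 or full PS-ANOVA fit, and its variance
  *partitioning* between spline, row/column and residual terms is only
  weakly identified on small p-rep trials (the BLUEs are insensitive to
  this).
* PLSR component selection uses inner 5-fold CV with the
  one-standard-error rule; it is a baseline, not a tuned chemometric
  calibration.
* Heritability calibration targets the across-year entry-mean H^2;
  realised values scatter by roughly +/-0.05 around targets at the
  default scale.
* The Mantel correlation between G and H on synthetic data (~0.03-0.1)
  is lower than typically reported on real breeding panels, because the
  synthetic H carries no LD-structured genetic signal beyond the
  composition traits.
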