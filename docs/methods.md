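# Methods

This note documents the models, numerical choices, and limitations of
the `metabrescue` pipeline, and what its synthetic-data generator does
and does not emulate.

## Study model

The pipeline assumes a factorial four-group design — genotype (wild
type vs APP/PS1 transgenic) x treatment (vehicle vs drug) — with both
sexes, up to six tissues (cerebellum, frontal/parietal/temporal cortex,
liver, plasma), and targeted-metabolomics plates that carry study
wells, repeated kit QC wells, and blank wells. Tissues are analyzed
independently throughout; no repeated-measures or mixed models are
fitted across tissues.

## Synthetic data generator

Analyte abundances are log-normal: each analyte has a baseline log-mean
(N(3, 1)) and a log-scale SD drawn from U(0.2, 0.6). Effects are
planted on the log scale in units of that SD, so a planted genotype
effect of -1.78 means the transgenic-vehicle mean sits 1.78 reference
SDs below wild type — the scale of the largest effects this kind of
study detects. The drug arm retains (1 - correction_fraction) of the
genotype shift; a sex-interaction parameter s plants +s in transgenic
males and -s in females, so the regression interaction coefficient
recovers 2s.

Plate structure: each plate receives a multiplicative log-normal bias
(sd 0.15 by default, or explicit biases). QC wells scatter tightly
(5% log-normal) around expected_qc x bias; blanks are low-level
background near one third of the censoring threshold with 5% scatter,
also bias-scaled, so LODs derived from normalized blanks are
cross-plate consistent. Below-LOD study values are replaced by
truncated uniform sub-LOD draws (never zero, unless the zero policy is
requested), since weak signals remain the best relative estimate of the
true value. The censoring threshold per analyte is the planted quantile
of the clean study values, which makes the realized below-LOD fraction
track the requested fraction within about +/-0.05 at n >= 200.

Phenotypes are per-subject: measure = sum of loadings x standardized
log-abundance of the coupled analytes (in one coupling tissue) +
N(0, 0.5) noise, so a loading w implies a planted Pearson correlation
of w / sqrt(w^2 + 0.25). The default noise SD of 0.5 puts the strongest
planted couplings (w = 0.9) at r ~ 0.87, comparable to the strongest
correspondences such studies report.

Not emulated: chromatographic drift, isotope correction, calibration
curves, real panel composition, missing tissue harvests (missingness
can be introduced by the caller), or any real biological covariance
between analytes — analytes are conditionally independent given the
planted effects. Passing recovery tests therefore demonstrates that the
statistical machinery is correct and well calibrated under the design's
noise model, not that it is robust to correlated biological pathways
or batch pathologies beyond multiplicative plate bias.

## Preprocessing

Stage order is fixed: plate normalization -> LOD filter -> indicators
-> Box-Cox -> Tukey fencing -> reference standardization. The order of
fencing vs standardization follows the listing order of the emulated
analysis workflow; fencing is computed across all study samples of an
analyte and tissue (not per group), because per-group fencing would
shrink the very group differences under study.

* Plate normalization divides every well on a plate by (QC median /
  expected QC). An analyte without usable QC on a plate becomes missing
  on that plate, with a warning. Raw QC/blank values are kept in the
  provenance record.
* LOD = 3 x median blank signal. The filter removes a metabolite only
  when the below-LOD fraction is strictly greater than 0.5 in *every*
  genotype-x-treatment subgroup within a tissue; exactly 50% retains.
  Surviving below-LOD values are not adjusted.
* Indicators: sums propagate missing components; ratios are missing
  when the denominator sum is zero. An indicator's method label is the
  majority method of its components; its FDR stratum is
  (method, indicator).
* Box-Cox lambda is chosen by profile maximum likelihood on a fixed
  grid (-3 to 3, step 0.01), computed with a vectorized log-likelihood
  that matches `scipy.stats.boxcox_llf` pointwise. Nonpositive values
  are shifted by half the smallest positive observed value by default
  (policy "error" raises instead). Fits use study samples only, per
  analyte per tissue, and need >= 5 observations.
* Tukey fencing clamps values outside Q1 - k*IQR / Q3 + k*IQR (k = 3)
  to the fence (winsorization). Quartiles use linear interpolation
  between order statistics; the convention is configurable because
  fence positions depend on it. Fencing is idempotent; IQR = 0 leaves
  data untouched.
* Standardization: z = (y - mean_ref) / sd_ref with the WT-vehicle
  group of the same tissue as reference (ddof = 1). A degenerate
  reference (< 2 values or zero SD) marks the analyte non-analyzable
  for that tissue.

Missing values are never imputed; every model uses complete cases per
analyte.

## Differential analysis

Per analyte and tissue: OLS of the standardized value on an intercept,
a case-group indicator and sex. Values are re-standardized to the
contrast's own reference group within the complete cases, so the
coefficient is the case displacement in reference-SD units regardless
of which standardization the table carries. Two-tailed p-values use the
t distribution with residual degrees of freedom (group sizes of 6-12
make the normal approximation inappropriate). Models are solved as
batched least squares over analytes sharing a missingness pattern; a
unit test verifies coefficients, standard errors, p-values and CIs
against statsmodels OLS. Designs that are rank deficient (e.g.
single-sex subsets), have < 3 complete cases in a cell, or a zero
reference SD are skipped with the reason recorded.

The sex-interaction model adds a case x (sex - mean sex) column — the
centered column spans the same space as the raw product, leaving the
interaction coefficient unchanged while keeping the main effects
interpretable.

### FDR

Storey q-values per stratum: pi0 is estimated from pi0(lambda) =
#{p > lambda} / (m (1 - lambda)) on lambda = 0.05 ... 0.95, smoothed by
a cubic spline and evaluated at lambda = 0.95, clipped to (0, 1]. With
fewer than 10 p-values, or an unstable estimate, pi0 falls back to 1,
which makes the q-values equal Benjamini-Hochberg adjusted p-values
(verified against statsmodels). Strata are (contrast, analytical
method, analyte kind); tissues pool within a stratum, so a stratum's
q-values never depend on another stratum's p-values.

### Significance rule

An effect is significant when q <= 0.05 ("fdr" route), or when
p <= 0.05 and some other tissue reaches q <= 0.05 for the same analyte
and contrast with the same coefficient sign ("cross-tissue" route).
Sign agreement is required deliberately: consistency between tissues is
read as the same direction of change, the minimal interpretation under
which the rule borrows strength.

## Rescue classification

One sex-adjusted model on all four groups with three group dummies
against WT-vehicle provides both displacements on a common scale:
beta_genotype (transgenic-vehicle dummy) and beta_correction =
coef(transgenic-drug) - coef(transgenic-vehicle). A single model was
chosen over two separate fits so the two displacements share one
reference standardization and residual variance.

Delta = 100 x beta_correction / (-beta_genotype): the drug displacement
projected onto the direction from the transgenic-vehicle mean toward
the wild-type mean, as a percent of the genotype displacement. Delta
> 100 (overcorrection) still counts as improved — normalization past
the wild-type mean; Delta < 0 is worsening. Delta is undefined (call
suppressed with a warning) when beta_genotype is numerically zero,
which eligibility makes rare.

Eligibility is arm-specific. Improvement arm: direct contrast
(transgenic-vehicle vs WT-vehicle among vehicle mice) at FDR <= 0.05,
or transgenic-vehicle vs all other subjects at FDR <= 0.05 with direct
p <= 0.05. Non-improvement arm: the direct FDR route, or all transgenic
vs all wild-type at FDR <= 0.05 with direct p <= 0.05. An analyte
eligible under both arms (always true on the direct route) receives
exactly one category, decided by Delta >= 50 (inclusive). An analyte
eligible only under the arm whose Delta criterion it fails receives no
call; this mirrors reporting only the improved and non-improved panels
and avoids asserting a category whose eligibility evidence came from
the other arm's pooled contrast. No multiplicity control is applied to
Delta itself.

## Integration

Per (analyte, tissue, measure), among transgenic mice only: Pearson r
on complete pairs (>= 4 overall, >= 3 per treatment subgroup), with
subgroup correlations inside the vehicle and drug arms. The consistency
filter requires |r_subgroup| >= 0.5 |r_all| in both arms (inclusive),
the signature of a relationship holding along the recovery trajectory
rather than an artifact of the group split. beta_extra is the
treatment-group coefficient from phenotype ~ analyte + group + sex —
the phenotype difference between arms *not* explained by the analyte
(the regression is phenotype-on-analyte because the quantity of
interest is residual group signal in the phenotype). The final score

    score = |r| / (max|r| - min|r|)  -  |beta_extra| / (max|b| - min|b|)

uses ranges over all post-filter scored analytes (pre-filter ranges are
selectable); the sign of r is retained in the report but the score uses
magnitudes. A degenerate range sets its term to zero with a warning.
Ties break by larger |r|, then analyte name. All tissues pool into one
ranking per measure, so brain, liver and plasma analytes compete
directly; the top 10 are reported. Scores are comparable only within
one (measure, run) because of the range normalization. The module also
reports phenotype-phenotype correlations so users can check that
separately analyzed measures are not proxies of each other.

## Phenotype statistics

Welch's t-test (scipy, Satterthwaite df) compares measures between
group pairs. AUC is the Mann-Whitney probability estimate with ties
counted one half; its variance comes from DeLong's
structural-components estimator via midrank placement values, and the
normal-theory CI is truncated to [0, 1] — at AUC = 1 with small samples
the interval degenerates and the truncation (e.g. an interval like
90%-100%) should be read as such. Case/control orientation is always
explicit; the package never flips direction automatically, so AUC < 0.5
is reportable and means the case group tends lower. This is a
deliberate divergence from tools that auto-orient, to keep reported
AUCs interpretable.

## Validation studies and problem sizes

`metabrescue.validation` runs the recovery studies used by the test
suite and the reproduction script, with replicate seeds spawned from a
base seed via `numpy.random.SeedSequence`:

* Effect recovery: planted betas (-1.78, -1.37, 0) at n = 6 per group
  per sex, 200 replicates. The estimator standardizes by a reference SD
  estimated from ~12 animals, which inflates |beta| by a few percent in
  finite samples (E[1/s] > 1/sigma); the measured bias stays well
  inside +/-0.15 SD. Running the full preprocessing chain per replicate
  adds a further small inflation from transform estimation; the default
  measurement fits on the generator's log-scale, plate-normalized
  values to isolate the estimator.
* Null FDR: 500 null analytes x 200 replicates; the mean fraction of
  q <= 0.05 rejections (all false by construction) is reported.
* Rescue recovery: correction fractions 0.1 / 0.5 / 0.9 planted on a
  -1.5 SD genotype effect at n = 50/group, 200 replicates.
* Driver ranking: one planted driver (loading 0.9) among 200 noise
  analytes, 100 replicates, top-10 hit rate. Plate normalization is
  applied before scoring, as in any real run; without it, plate bias
  acts as analyte measurement error and occasionally inflates the
  driver's beta_extra penalty.

The group-contrast studies fit on the generator's log-scale values
without re-estimating plate factors: log-scale plate offsets are
symmetric across groups, and a factor estimated from a handful of QC
wells only adds shared noise to the estimate, which would measure QC
design quality rather than the estimator. The integrative study keeps
the normalization because its auxiliary regression is sensitive to
analyte measurement error. Problem sizes were chosen so the full suite
runs in minutes on one CPU.

## Known limitations

* The pi0 smoother uses scipy's default spline smoothing rather than an
  exact reimplementation of R's `smooth.spline` df = 3; the pi0 = 1
  fallback bounds the consequences (BH behavior).
* Linear QC-median scaling is the only calibration path; seven-point
  calibration curves are out of scope.
* The cross-tissue significance rule and the arm-specific rescue
  eligibility involve interpretation choices (sign agreement; no-call
  analytes) documented above; both are configurable at the threshold
  level only, not in structure.
* Indicators computed from components measured by different analytical
  methods get the majority method label for stratification; mixed-method
  indicators are rare in practice but possible in user registries.
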