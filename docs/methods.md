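# Methods

`pdxms` models which primary breast tumours will successfully engraft as
patient-derived xenografts (PDXs) from two kinds of input: per-patch
tissue-class label maps of the resected tumour (the output of an upstream
patch classifier) and a clinicopathological cohort table with a binary
engraftment outcome. This note describes the models, the synthetic data
that stand in for unreleased patient data, and the numerical conventions.

## Tissue label maps and morphometrics

A label map is a 2-D grid in which each cell is one 112 × 112-pixel patch
(at 400× magnification) labelled as one of six classes: adipose,
background, necrosis, carcinoma, stroma, or terminal ductal lobular unit
(TDLU). An aligned raster stores the fraction of each patch's area
occupied by lymphocytes.

**Tumour delineation.** The carcinoma mask is morphologically closed with
a square structuring element of radius `close_radius` (default 2 patches),
holes are filled, and the largest 8-connected component is kept (ties
break to the component with the smallest top-left cell; 4-connectivity is
available by flag). No published algorithm exists for this boundary — only
an illustration of the intended result — so closing + hole-fill + largest
component was chosen as the simplest reconstruction that encircles a
carcinoma mass with its internal necrosis and stroma; the radius is a
config knob so alternative reconstructions can be compared. The operation
is idempotent on its own output, and enlarging the radius can only grow
the region.

**Proportions.** For each class *c*, the intratumoral proportion is
10000 · (patches of class *c* inside the boundary) / (patches inside the
boundary). The ×10,000 scale mirrors how such proportions are reported
(large denominators make raw fractions unreadable). The six class
proportions sum to exactly 10,000. The background class is counted in the
denominator by default because background is tracked as a patch class of
its own; `include_background=False` switches to a tissue-only denominator.
The invasive carcinoma proportion is ICP = carcinomaP × invasive_fraction,
where the invasive fraction in [0, 1] is a pathologist-assessed scalar
correcting for in-situ carcinoma, which the patch taxonomy does not
separate from invasive disease. TILP is 10,000 × the mean in-region
lymphocyte area fraction (patch areas are uniform, so area-weighting is a
constant factor).

A note on scaling: odds ratios for these features are conventionally
quoted per 1,000-unit change. On the ×10,000 scale, 1,000 units is 10
percentage points of intratumoral area, although source material sometimes
glosses it as "0.1%". `scaled_odds_ratio` therefore takes an explicit
`delta` rather than hard-wiring either reading.

## Synthetic data

**Label maps.** No generative model of tumour morphology is prescribed
anywhere, so the generator is the package's own design: a single simply
connected carcinoma mass is stamped as a star-shaped blob (radius
perturbed by a few smooth Fourier harmonics; star-shapedness guarantees
simple connectivity after rasterisation) covering `tumor_mass` of the
grid, default 0.30. Cells inside the mass are assigned by per-class
smoothed Gaussian random fields whose additive offsets are calibrated
iteratively to hit the requested intratumoral composition; `smoothness`
(the Gaussian kernel width, in patches, default 2) sets the size of
coherent tissue pockets. Outside the mass, the non-carcinoma part of the
composition is renormalised and used the same way; a pure-carcinoma
composition degenerates to a grid-filling tumour. The lymphocyte fraction
is Beta-distributed with mean `mean_lymph_fraction` (default 0.02,
concentration 10), multiplied by 1.5 inside stroma to mimic stromal TILs,
clipped to [0, 1], and zeroed on background. The generated ground-truth
mass mask is kept on the object so recovery tests can count labels
directly. The default intratumoral composition follows the
engraftment-failure group means of a published primary breast cancer
cohort (adipose 0.064, background 0.030, necrosis 0.074, carcinoma 0.444,
stroma 0.338, TDLU 0.050).

What this emulates — and does not: the maps have realistic class mixtures
and spatial coherence, but no pixel-level texture, no correlation between
tissue classes and lymphocyte hotspots beyond the stroma multiplier, and a
single tumour mass by construction. Passing tests therefore demonstrate
that the measurement and modelling chain is correct, not that the patch
classifier upstream of it would be.

**Cohorts.** Covariate marginals default to a 353-patient primary breast
cancer PDX cohort: age N(50.9, 12.2²) truncated to [18, 95]; Ki-67
labelling index N(39.0, 29.1²) truncated to [0, 100) and floor-discretised
to the 10-step grid used in routine reporting; tumour size N(3.3, 2.2²) on
[0.1, 20] cm; positive lymph nodes a rounded truncated normal ≥ 0; stromal
TIL% discretised like Ki-67; subtype, NAC, grade, LVI and diagnosis
categorical with the published frequencies; Miller-Payne grade, RCB score
and class generated only for NAC-treated cases. Morphometric proportions
are Dirichlet on the ×10,000 scale (concentration 30) so the six classes
sum exactly to 10,000; the invasive fraction is Beta(8, 2). The joint
distribution is independent across covariates by default — only marginals
are published — and correlations are deliberately left to the caller. The
outcome is Bernoulli(logistic(β·x)); the default β loosely matches
published multivariate odds ratios (a configuration default, not a truth
claim), and the spec used to generate a cohort is returned with the table
so parameter-recovery tests can check against the exact β that generated
the data.

`expand_counts` turns printed outcome-by-category contingency counts into
record-level data (one row per counted unit), which is how every
printed-count quantity is regenerated.

## Group comparisons

Continuous variables are compared with the Welch two-sample t-test
(pooled-variance available by flag; Welch is the safer default when group
variances differ and nothing in the source dictates a choice). Categorical
variables use the Pearson chi-square without continuity correction when
every expected count is ≥ 5, and Fisher's exact test otherwise (scipy's
2×2 exact test; larger sparse tables by full enumeration of tables with
the observed margins, feasible below total count 200 and cross-checked
against R's `fisher.test`; sparse r × c tables too large to enumerate fall
back to Pearson with an explanatory note). One printed sparse-table p-value of 1.000
turns out to correspond to the Yates continuity-corrected chi-square
(whose statistic vanishes for that table), not to Fisher's exact test
(p = 0.52); `method="yates"` exposes that convention, while the automatic
rule above stays the default. Identical constant groups are reported as
t = 0, p = 1; untestable variables are flagged rather than raised when
summarising a whole table. No multiple-testing correction is applied,
matching the exploratory use of these tables.

## Logistic regression and model selection

Fitting is plain maximum likelihood by IRLS: convergence when every
coefficient moves by < 1e-8, cap of 50 iterations, standard errors from
the observed information. Categorical terms are dummy-coded against the
first level in sorted order (HER2+ for subtype, grade 2, NAC no — the
references implied by the reported contrasts) unless overridden. Wald 95%
CIs use the exact normal quantile Φ⁻¹(0.975) = 1.959964; printed CI bounds
reproduce at 2 dp with this choice and not with 1.96. Separation is
flagged and reported, never penalised — no Firth correction — because the
enormous CIs in the source tables are consistent with plain ML on sparse
cells. Aliased columns are dropped with a warning before fitting.

The univariate screen fits one predictor at a time and passes variables
with Wald p < 0.2 to the multivariate step. Backward elimination starts
from the full candidate model, removes at each step the term whose removal
lowers the AIC (−2ℓ + 2k) the most, breaks exact AIC ties toward the term
with the larger Wald p (the source is silent; removing the least
significant term is the natural convention), and stops at the first model
no removal improves. Re-entry (bidirectional search) is intentionally not
implemented: the procedure is described as backward. The trace is
returned, and AIC is strictly decreasing along it by construction.

## Classification trees

CART with Gini impurity: splits maximise the n-weighted impurity decrease;
continuous candidates are midpoints of adjacent distinct values;
categorical splits order levels by outcome rate and scan that ordering
(optimal for a binary outcome). Growth stops at `minsplit=20`,
`minbucket=7`, `maxdepth=30` (rpart's conventions). Pruning follows
cost-complexity weakest-link ordering computed on the misclassification-
risk scale relative to the root, as in rpart's CP table; the Gini
criterion is used for choosing splits and for importance, risk for the
pruning sequence. `fit_cart` builds the full CP sequence and, by default,
a 10-fold cross-validated error per pruning level (fold assignment from
the seed; each level evaluated at the geometric mean of neighbouring CPs;
`xstd` is the standard error of the per-observation loss on the relative
scale). Variable importance is the percent share of summed realised Gini
decreases at primary splits; surrogate splits are not implemented, so
importances can differ from rpart's surrogate-inclusive numbers — a
documented divergence. Pruning at cp collapses every branch whose
weakest-link improvement is below cp: cp = 0 is a no-op and any cp above
the root improvement leaves a stump.

## Discrimination and the bootstrap

AUC is the Mann–Whitney statistic with midrank ties, identical to the
trapezoidal area under the empirical ROC. The bootstrap resamples subjects
with replacement (unstratified — stratification is not part of the
described procedure), refits the FIXED term set on each replicate (no
re-selection inside the loop, consistent with a reported small bias), and
records the replicate's apparent AUC; bias = mean(replicates) − original
and se = SD(replicates). An optimism-corrected variant is deliberately not
the default. Replicates drawing a single outcome class are redrawn and
counted. BCa intervals adjust percentile endpoints by z₀ = Φ⁻¹(fraction of
replicates below the original) and the acceleration a from the jackknife
skewness of leave-one-out estimates; endpoints are taken as order
statistics (the ⌈αB⌉-th), so BCa reduces exactly to the percentile
interval when z₀ = a = 0 and interval ends are always elements of the
replicate vector. z₀ is clipped to (1/2B, 1 − 1/2B) before the probit so
degenerate replicate vectors stay finite.

The operating cutoff maximises Youden's J = sensitivity + specificity − 1
over midpoints of adjacent sorted unique scores plus ±∞, calling
score ≥ cutoff positive and breaking ties toward the smallest cutoff (the
≥ convention and the tie-break are package conventions; none is dictated).
PPV and NPV at the cutoff are reported with explicit undefined flags when
a predicted group is empty.

## Calibration simulations and problem sizes

Because the patient-level data behind the headline models were never
deposited, the package validates itself on quantities that are either
exactly derivable from printed counts or are properties of the machinery:

* every univariate odds ratio derivable from printed contingency counts is
  refitted from expanded records and reproduces at printed precision, as
  do the printed group rates;
* Wald 95% CI coverage of the generator's true Ki-67 slope: 500 cohorts of
  n = 1000 (observed ≈ 0.95–0.96);
* backward-AIC vs exhaustive subset search over six covariates (three real
  effects, three noise), 100 cohorts of n = 1000;
* BCa coverage for the AUC of a fixed score: 200 cohorts of n = 300 at
  prevalence 0.17, scores N(0,1)/N(1,1) (true AUC Φ(1/√2) ≈ 0.760), 1000
  replicates each.

These sizes keep the whole suite comfortably fast while leaving Monte
Carlo error well inside the asserted tolerances.

## Known limitations

* No patch classification from pixels: the package starts at label maps.
* Single dominant tumour mass only; multiple disjoint masses are resolved
  by taking the largest, and nothing else is reported about the rest.
* No penalised regression, interaction search, DeLong variance,
  calibration or decision-curve analysis.
* Synthetic cohorts draw covariates independently; real cohorts correlate
  Ki-67 with grade and subtype, so synthetic multivariate fits understate
  collinearity effects.
* The exact r × c Fisher enumeration is exponential and refuses tables
  with total count above 200.
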