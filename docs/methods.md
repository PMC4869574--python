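# Methods

## Hazard model and survival simulation

Mortality follows a discrete-day Gompertz law: the log of the daily hazard
is linear in age, ln h(t) = a + bt, and the daily death probability is
1 − exp(−h(t)). The amyloid stressor enters in two age-dependent ways,
chosen as the minimal structure that yields parallel displaced trajectories
for early-life exposure and steeper trajectories for mature-life exposure:

- before a maturity age (default day 15), each active day adds a permanent
  ln-hazard displacement of `stressor_accrual_rate` (default 0.08/day, i.e.
  1.2 ln-units over a full 0–15 window);
- from the maturity age on, while active, the gradient is increased by
  `stressor_slope_delta` (default 0.10/day).

Baseline parameters (intercept −7.0 ln-units, slope 0.12/day) give a
control median lifespan near 36 days at daily scoring, matching a
moderately stressful culture temperature. The default cohort layout is 100
flies in 10 subgroups of 10 (10,000 flies for parameter-recovery runs),
censored at day 90. Time is whole days, the resolution of daily scoring.

## Life tables and trimmed trajectories

The daily death probability ("chance of dying over the coming 24 h") is
deaths/at-risk at the start of each day, unsmoothed. For trajectories, the
earliest and latest ⌈5% · D⌉ of the D death events are discarded; the
retained events define the day window of the trajectory and, within that
window, at-risk counts every fly still alive (censored flies until their
horizon). Counting at-risk only among retained flies would force the last
retained day to probability 1 (ln = 0), a deterministic end artifact that
biases the fitted gradient upward by ~12%; with the day-window convention
the Gompertz slope is recovered to within ~4% at n = 10,000.

Subgroup medians use the lower-median convention (smallest day by which at
least half the subgroup has died), consistent with right-continuous
survival curves. Group summaries are the mean and SD over subgroup medians,
and group comparisons use a two-sided Wilcoxon rank-sum on the subgroup
medians — exact by enumeration (dynamic programming over midranks, so ties
are handled) for combined n ≤ 20, normal approximation with tie correction
above. Displacement between trajectories defaults to the mean difference
over shared days ("paired"); a fitted-line mode is available. Reported
rates are rounded half-up to two decimals (0.095 → 0.10).

## Spectrum generator

Spectra live on a descending 10.0 to −0.5 ppm grid of 2101 points
(0.005 ppm/point). Each metabolite is a Lorentzian multiplet (fixed FWHM
0.02 ppm; multiplet structure collapsed to the listed chemical shifts)
normalised so its discrete integral equals `base_intensity` × fold change.
Fold changes factor into:

- a universal **age trend** shared by all genotypes (glucose and glutamine
  falling, trehalose rising, fastest before day 8) — this carries the PCA
  age trajectory and the age-regression signal; in Arctic bodies it is
  evaluated 5 days ahead of calendar age, encoding the "metabolically
  older" phenotype;
- a genotype-specific **effect profile**, identically 1 for controls:
  maltose up in all Aβ genotypes (plateau fold 4 from day 14, with roughly
  two-thirds of the effect already present at day 1, since genotype
  displacement is evident from the first sampling day), tyrosine down,
  xanthurenic acid up in Aβ heads; Arctic-specific age-increasing gluconic
  acid and histidine (rising from day 8 in bodies, day 14 in heads),
  raised head lactate, lowered body AXP and phosphocholine from day 1, and
  unassigned aromatic signals present from day 1.

Nuisance structure exercises the preprocessing: per-metabolite
multiplicative log-normal noise (CV 0.10, a typical triplicate
reproducibility for extract NMR), a nonnegative quadratic baseline (~1% of
total signal), a global per-sample ppm jitter (SD 0.002 ppm) recorded as
ground truth for alignment tests, and a per-sample amount multiplier
(CV 0.20, removed by total-intensity normalisation). Per-sample random
streams derive from `SeedSequence([seed, sample_index])`, so sets are
reproducible and individual samples do not depend on the rest of the
design. Absolute intensities are arbitrary units; the study conditions fix
only fold changes and directions, so noise levels and base intensities are
free parameters documented here.

The design is 4 genotypes × ages {1, 8, 14, 18, 21, 24, 30, 40} (Arctic
truncated at 26) × {head, body} × 3 replicates = 186 samples.

What the generator deliberately omits: J-coupling/multiplet physics,
peak-shape distortions, chemical-shift dependence on pH/ionic strength,
correlated metabolite networks beyond the programmed factors, and
per-point spectrometer noise. Passing tests therefore demonstrate that the
pipeline recovers the programmed structure under realistic nuisance
variation, not performance on real spectra.

## Preprocessing

Order is enforced via the processing log: TSP referencing → region
excision → alignment → total-intensity normalisation → pareto scaling.
Referencing shifts each spectrum by a whole number of grid points so its
tallest peak in ±0.2 ppm lands at −0.017 ppm. Excision drops the residual
water band (4.88–4.67 ppm inclusive) and everything outside 9.5–0.5 ppm;
grid points are point samples, endpoints inclusive. Alignment is a
simplified icoshift: fixed-width segments (default 0.05 ppm), per segment
and sample the integer shift (|k| ≤ 4) maximising Pearson correlation with
the pointwise-median reference, candidates visited by increasing |k| so
zero wins ties, edge-value padding. Normalisation divides each spectrum by
its summed intensity. Pareto scaling centers each variable and divides by
the square root of its SD (n−1 denominator; zero-SD columns map to zero);
training means/SDs can be reused to scale held-out samples. Heads and
bodies are processed as separate sets throughout. Normalisation precedes
scaling and follows excision (the stated text order); the alternative
order is switchable by composing the ops directly.

## PCA, OPLS and OPLS-DA

PCA is SVD on the scaled matrix with a deterministic sign convention
(largest-|loading| element positive). The two-way MANOVA on PC scores
(Wilks' Λ, F approximation; genotype and age as crossed categorical main
effects, no interaction) is delegated to statsmodels.

OPLS uses NIPALS throughout (deterministic initialisation from the first
response column; tolerance 1e-10, ≤500 iterations). The response-weight
subspace is the SVD basis of XᵀY; each orthogonal component takes the PLS
loading p, projects off that subspace, and deflates X, which makes
orthogonal scores exactly uncorrelated with Y. The final predictive fit on
the filtered X is a standard NIPALS PLS (n_classes − 1 components for
class dummy responses, one for age). With zero orthogonal components the
predictive component reduces exactly to the first PLS component — a
cross-check kept as a test against an independently coded PLS1.

Per-variable correlation loadings R are Pearson correlations between the
*original* (preprocessed, centered) variables and the predictive scores.
Class assignment is nearest centroid in the space of 7-fold
cross-validated training scores (deterministic stratified round-robin
folds; fold component signs aligned to the full model). The orthogonal
count default is 1 for class/contrast models; a Q²-based selector
(7-fold, stop when the gain < 0.01) is provided. The "metabolomic age" of
a sample is the prediction of the single-component OPLS age regression
trained on 14–40-day control and Aβ42 spectra.

## Permutation calibration

For a contrast model, the class labels are shuffled across samples (whole
rows, preserving spectral covariance), the model — including its
orthogonal components — is refitted, and all per-variable R² values are
pooled over permutations. The cutoff is the (1 − α/n_metab) quantile
(linear interpolation of order statistics), default α = 0.01 Bonferroni
corrected for an assumed 100 metabolites, 10,000 permutations (analysis
drivers default to 1,000; the effective tail probability of 1e-4 sits at
the extreme of the pooled distribution, so cutoff estimates at reduced
permutation counts are conservative approximations). Refitting the
orthogonal components in the null matters: without them the null
predictive score aligns with the dominant metabolite factors and the
pooled cutoff saturates near R² ≈ 1. A max-statistic mode (per-permutation
maximum R², (1 − α) quantile, no Bonferroni divisor) is available for
direct familywise control. Significant variables are merged into
contiguous same-sign ppm runs, reported with direction (relative to the
second group) and maximum |R|.

## Numerical and reporting choices

- All stochastic stages consume explicit seeds; sub-seeds derive from
  `SeedSequence([master, stream])` and stay below 2³¹. Reports are JSON
  with sorted keys and 10-decimal rounding, so reruns are byte-identical.
- Degenerate inputs raise: empty cohorts, all-censored subgroups, <20
  deaths for trimming, flat reference windows, nonpositive totals,
  zero-variance responses, mismatched variable counts.
- Problem sizes: parameter-recovery runs use 10,000 flies/cohort;
  permutation checks in tests use 300–500 permutations with the full
  protocol exposed via configuration; the metabolomic-age direction check
  aggregates 10–20 independent simulated data sets.
- Plots are not produced by the pipelines; the reports and TSV tables
  contain the plot-ready data (PC trajectories, score tables, region
  tables).

## Known limitations

- The hazard estimator ln(deaths/at-risk) understates ln h(t) at high
  hazards (h ≳ 0.3), attenuating fitted gradients by a few percent; the 5%
  tail trimming bounds the effect, and recovery tests budget for it.
- The pooled permutation cutoff at effective α = 1e-4 is an extreme
  quantile; with strongly collinear synthetic spectra it is dominated by
  the few most structured variables, making the test conservative for
  weaker effects (head-tissue gluconic acid at 14–24 days, for example,
  falls below the cutoff at desk scale).
- OPLS-DA here is the single-block variant; the original analysis used a
  proprietary implementation whose cross-validation internals are not
  published, so cross-validated scores match in construction, not
  numerically.
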