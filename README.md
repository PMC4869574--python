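# flyaging

Analysis pipeline for two linked questions about amyloid-beta (Aβ) toxicity
in ageing *Drosophila*: **when** in life Aβ expression kills flies, and
**what** it does to their metabolome.

The package implements, as tested library code driven by a synthetic-data
generator, the two bespoke analyses of a fly model in which Aβ isoforms
(Aβ40, Aβ42, Arctic E22G Aβ42) are expressed pan-neuronally, with an
inducible variant that restricts expression to chosen age windows:

1. **Mortality-trajectory decomposition.** The mortality trajectory is
   ln μ(t), the natural log of the daily probability of death, plotted
   against age t; under the Gompertz law ln μ(t) = a + bt it is linear.
   Aβ expression confined to early life (days 0–15) leaves the gradient b
   untouched but displaces the trajectory vertically by a constant Δ;
   expression in mature life steepens the gradient by δ. Dividing the
   early-life displacement by the window length (Δ/15 days) converts it to
   an equivalent daily rate, so the age-dependence of Aβ toxicity reduces
   to comparing Δ/15 with δ.
2. **¹H-NMR metabolomics.** Spectra (9.5–0.5 ppm, TSP-referenced, water
   region excised, icoshift-style aligned, total-intensity normalised,
   pareto-scaled and centered) are analysed by PCA with a two-way MANOVA on
   the PC scores, OPLS-DA class models trained on mature (18/21-day) flies
   and applied to all other ages, an OPLS regression of spectra on age
   whose prediction is a sample's "metabolomic age", and per-variable
   correlation loadings R whose significance cutoff comes from refitting
   the predictive component on 10,000 permuted data sets (p < 0.01,
   Bonferroni-corrected for an assumed 100 metabolites).

No public data accompany the original study, so a first-class synthetic
module (`flyaging.simulate`) generates survival tables from the
displacement-then-gradient hazard model and spectrum sets with the study's
genotype × age × tissue fold-change structure; every downstream stage is
tested against this known ground truth.

## Layout

- `src/flyaging/` — the library: `simulate` (generators),
  `survival` (life tables, trimmed trajectories, decomposition),
  `spectra` (preprocessing), `multivariate` (PCA, OPLS/OPLS-DA, MANOVA),
  `permutation` (null-calibrated significance), `pipeline`, `cli`.
- `analysis/01…06_*.py` — numbered drivers that run the study end to end
  and write tables under `results/`.
- `docs/methods.md` — model assumptions, parameter choices, limitations.

## Worked example

```bash
python analysis/01_simulate_survival.py --seed 1
python analysis/02_mortality_decomposition.py --seed 1
```

prints, among other lines:

```
 induction  mean_median  sd_median  n_subgroups
continuous         24.3   1.946507           10
     never         35.6   3.204164           10
never vs continuous: Wilcoxon p = 1.083e-05

measured from simulated cohorts:
  displacement (continuous vs late):  1.133
  accrual rate over 15 days:          0.0755 /day
  gradient delta (cont. vs early):    0.0912 /day
canonical arithmetic (in-study inputs):
  1.2/15 = 0.08;  0.7/15 -> 0.05
  young mean 0.06;  mature mean 0.10;  excess 50 %
```

Continuous Aβ induction costs ~11 days of median life; the fitted
decomposition recovers the injected early-life accrual (0.08 ln-units/day)
and mature-life gradient increase (0.10/day) to within ~10%, and the
canonical arithmetic shows the mature-life rate exceeding the early-life
rate by 50%. The metabolome arm
(`analysis/03…06`) then reports MANOVA genotype effects at p < 1e-60,
≥90% correct genotype assignment for held-out ages, Arctic body samples
reading 6–8 days metabolically older than their calendar age, and
significant contrast regions that recover the injected metabolite changes
(maltose up in all Aβ genotypes; gluconic acid and histidine up in Arctic).

A thin CLI wraps the same calls: `flyaging simulate survival|spectra`,
`flyaging survival`, `flyaging spectra`, `flyaging run-survival`,
`flyaging run-metabolome`.

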