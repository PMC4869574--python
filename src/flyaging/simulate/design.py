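"""Default study design: four genotypes, eight sampling ages, two tissues.

Cohorts and effect templates encode the qualitative biology of pan-neuronal
amyloid-beta (Abeta) expression in Drosophila:

* survival — a Gompertz baseline plus a stressor that, before day 15, accrues
  a permanent ln-hazard displacement (0.08 per active day, i.e. 1.2 over a
  full 0-15 window) and, after day 15, steepens the trajectory gradient by
  0.10 day^-1 while active;
* metabolome — maltose up in every Abeta genotype in heads and bodies,
  xanthurenic acid up in Abeta heads, tyrosine down; the toxic Arctic variant
  additionally shows age-increasing gluconic acid and histidine, raised head
  lactate, lowered body adenosine nucleotides (AXP) and phosphocholine, and
  unassigned aromatic signals present from day 1. A universal age trend
  (falling glucose/glutamine, rising trehalose) carries the age trajectory
  shared by all genotypes; in Arctic bodies it is evaluated 5 days ahead of
  calendar age (metabolically "older" flies).

Arctic flies are short-lived, so their sampling schedule stops at day 26.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np

from .hazards import CohortSpec, HazardSpec
from .nmr import DesignCell, MetaboliteTemplate, SpectraSpec

__all__ = [
    "GENOTYPES",
    "ABETA_GENOTYPES",
    "SAMPLING_AGES",
    "ARCTIC_AGES",
    "default_cohort_specs",
    "default_metabolites",
    "default_spectra_spec",
    "default_design",
]

GENOTYPES = ("control", "ab40", "ab42", "arctic")
ABETA_GENOTYPES = ("ab40", "ab42", "arctic")
SAMPLING_AGES = (1, 8, 14, 18, 21, 24, 30, 40)
ARCTIC_AGES = (1, 8, 14, 18, 21, 24, 26)
TISSUES = ("head", "body")

# stressor parameters (per-day displacement accrual before maturity;
# gradient increase after maturity)
ACCRUAL_RATE = 0.08
GRADIENT_DELTA = 0.10
MATURITY_DAY = 15.0
BASELINE_INTERCEPT = -7.0
BASELINE_SLOPE = 0.12


def default_cohort_specs(n_flies: int = 100, n_subgroups: int = 10) -> List[CohortSpec]:
    """Four induction cohorts: never, early-only (0-15), late (15+), continuous."""

    def hz(window):
        return HazardSpec(
            baseline_intercept=BASELINE_INTERCEPT,
            baseline_slope=BASELINE_SLOPE,
            stressor_slope_delta=GRADIENT_DELTA,
            stressor_accrual_rate=ACCRUAL_RATE,
            maturity_day=MATURITY_DAY,
            induction_window=window,
        )

    windows = {
        "never": None,
        "early": (0.0, 15.0),
        "late": (15.0, math.inf),
        "continuous": (0.0, math.inf),
    }
    return [
        CohortSpec(
            genotype=f"ab42_{label}",
            n_flies=n_flies,
            n_subgroups=n_subgroups,
            hazard=hz(window),
            max_day=90,
            induction_label=label,
        )
        for label, window in windows.items()
    ]


def _ramp(ages, folds):
    """Piecewise-linear fold profile of age, clamped at the end points."""
    xs = np.asarray(ages, dtype=float)
    ys = np.asarray(folds, dtype=float)

    def f(age: float) -> float:
        return float(np.interp(age, xs, ys))

    return f


def _abeta_effect(ramp, tissues=("head", "body"), genotypes=ABETA_GENOTYPES):
    """Genotype effect applied to the listed genotypes/tissues, 1 elsewhere.

    ``ramp`` is either one fold-profile of age or a dict tissue -> profile
    (for metabolites whose response starts earlier in one tissue).
    """

    def profile(genotype: str, age: float, tissue: str) -> float:
        if genotype in genotypes and tissue in tissues:
            f = ramp[tissue] if isinstance(ramp, dict) else ramp
            return f(age)
        return 1.0

    return profile


def default_metabolites() -> Tuple[MetaboliteTemplate, ...]:
    both, head, body = ("head", "body"), ("head",), ("body",)
    arctic = ("arctic",)
    mets = [
        # internal chemical-shift reference
        MetaboliteTemplate("tsp", (-0.017,), base_intensity=150.0),
        # responses to Abeta expression irrespective of toxicity; genotype
        # separation is present from day 1 and full by mid-adult life
        MetaboliteTemplate(
            "maltose", (5.40, 4.64), 60.0,
            effect_profile=_abeta_effect(_ramp([1, 14], [2.8, 4.0]), both),
        ),
        MetaboliteTemplate(
            "tyrosine", (7.18, 6.88), 40.0,
            effect_profile=_abeta_effect(_ramp([1, 14], [0.68, 0.6]), both),
        ),
        MetaboliteTemplate(
            "xanthurenic_acid", (7.53, 7.37, 7.16, 6.92), 10.0,
            effect_profile=_abeta_effect(_ramp([1, 14], [2.2, 3.0]), head),
        ),
        # toxicity-specific responses (Arctic only); the rise starts around
        # day 8 in bodies and day 14 in heads
        MetaboliteTemplate(
            "gluconic_acid", (4.10, 4.01, 3.75), 15.0,
            effect_profile=_abeta_effect(
                {
                    "body": _ramp([1, 8, 14, 26], [1.0, 1.8, 3.2, 5.0]),
                    "head": _ramp([1, 14, 18, 26], [1.0, 1.2, 2.5, 4.5]),
                },
                both, arctic,
            ),
        ),
        MetaboliteTemplate(
            "histidine", (7.77, 7.05), 25.0,
            effect_profile=_abeta_effect(
                {
                    "body": _ramp([1, 8, 14, 26], [1.3, 1.7, 2.4, 3.5]),
                    "head": _ramp([1, 14, 26], [1.3, 1.9, 3.5]),
                },
                both, arctic,
            ),
        ),
        MetaboliteTemplate(
            "lactate", (1.31,), 50.0,
            effect_profile=_abeta_effect(_ramp([1, 14], [1.0, 2.5]), head, arctic),
        ),
        MetaboliteTemplate(
            "alanine", (3.77, 1.47), 45.0,
            effect_profile=_abeta_effect(_ramp([1, 14], [1.0, 0.7]), head, arctic),
        ),
        MetaboliteTemplate(
            "axp", (8.52, 8.26, 6.13), 20.0,
            effect_profile=_abeta_effect(_ramp([1, 1], [0.5, 0.5]), body, arctic),
        ),
        MetaboliteTemplate(
            "phosphocholine", (4.17, 3.58, 3.21), 35.0,
            effect_profile=_abeta_effect(_ramp([1, 1], [0.6, 0.6]), body, arctic),
        ),
        MetaboliteTemplate(
            "acetate", (1.90,), 30.0,
            effect_profile=_abeta_effect(_ramp([1, 14], [1.0, 1.5]), body, arctic),
        ),
        MetaboliteTemplate(
            "fatty_acid_ch2", (1.26,), 55.0,
            effect_profile=_abeta_effect(_ramp([1, 14], [1.0, 1.5]), body, arctic),
        ),
        MetaboliteTemplate(
            "aromatic_unknown_head", (7.93, 6.93), 4.0,
            effect_profile=_abeta_effect(_ramp([1, 1], [6.0, 6.0]), head, arctic),
        ),
        MetaboliteTemplate(
            "aromatic_unknown_body", (8.03, 7.80, 7.20, 6.90), 4.0,
            effect_profile=_abeta_effect(_ramp([1, 1], [6.0, 6.0]), body, arctic),
        ),
        # universal age trend shared by all genotypes (fast change to day 8)
        MetaboliteTemplate(
            "glucose", (5.23, 3.47, 3.24), 80.0,
            age_trend=_ramp([1, 8, 40], [1.6, 1.2, 0.8]),
        ),
        MetaboliteTemplate(
            "trehalose", (5.19, 3.64), 70.0,
            age_trend=_ramp([1, 8, 40], [0.6, 0.9, 1.4]),
        ),
        MetaboliteTemplate(
            "glutamine", (2.44, 2.12), 50.0,
            age_trend=_ramp([1, 8, 40], [1.4, 1.1, 0.85]),
        ),
    ]
    return tuple(mets)


def default_spectra_spec(n_replicates: int = 3) -> SpectraSpec:
    design = []
    for genotype in GENOTYPES:
        ages = ARCTIC_AGES if genotype == "arctic" else SAMPLING_AGES
        for tissue in TISSUES:
            for age in ages:
                design.append(DesignCell(genotype, float(age), tissue, n_replicates))
    return SpectraSpec(
        metabolites=default_metabolites(),
        design=tuple(design),
        age_advance={("arctic", "body"): 5.0},
    )


def default_design(
    n_flies: int = 100, n_replicates: int = 3
) -> Tuple[List[CohortSpec], SpectraSpec]:
    """The cohort list and spectra spec emulating the full study conditions."""
    return default_cohort_specs(n_flies=n_flies), default_spectra_spec(n_replicates)
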