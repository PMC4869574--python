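"""Synthetic 1H-NMR spectrum sets with genotype x age x tissue structure.

Each sample is a sum of metabolite signals on a common descending ppm grid.
A metabolite contributes a Lorentzian multiplet (its listed peak positions,
collapsed multiplet structure) normalised so the metabolite's discrete
integral equals ``base_intensity`` times its fold change. Fold changes
factor into a universal ``age_trend`` (shared by every genotype, optionally
evaluated at an advanced age for chosen genotype/tissue cells) and a
genotype-specific ``effect_profile`` which is identically 1 for controls.

Nuisance structure exercised by the preprocessing pipeline: multiplicative
log-normal noise per metabolite, a smooth nonnegative polynomial baseline, a
per-sample global ppm jitter (recorded in the metadata as ground truth for
alignment tests), and a per-sample amount multiplier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..spectra import SpectrumSet

__all__ = ["MetaboliteTemplate", "SpectraSpec", "DesignCell", "simulate_spectra"]

EffectProfile = Callable[[str, float, str], float]  # (genotype, age_days, tissue) -> fold
AgeTrend = Callable[[float], float]                 # age_days -> fold


@dataclass(frozen=True)
class MetaboliteTemplate:
    """One metabolite: peak positions (ppm), linewidth, intensity, effects."""

    name: str
    peak_positions: Tuple[float, ...]
    base_intensity: float
    peak_width: float = 0.02       # Lorentzian FWHM, ppm
    effect_profile: Optional[EffectProfile] = None  # genotype effect, 1 for controls
    age_trend: Optional[AgeTrend] = None            # shared age-dependent fold

    def fold(self, genotype: str, age_days: float, tissue: str,
             age_advance: float = 0.0) -> float:
        f = 1.0
        if self.age_trend is not None:
            f *= float(self.age_trend(age_days + age_advance))
        if self.effect_profile is not None:
            f *= float(self.effect_profile(genotype, age_days, tissue))
        if f <= 0:
            raise ValueError(f"{self.name}: fold change must be positive, got {f}")
        return f


@dataclass(frozen=True)
class DesignCell:
    genotype: str
    age_days: float
    tissue: str          # "head" | "body"
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class SpectraSpec:
    """Grid, metabolite templates, noise levels and sampling design."""

    metabolites: Tuple[MetaboliteTemplate, ...]
    design: Tuple[DesignCell, ...]
    ppm_max: float = 10.0
    ppm_min: float = -0.5
    n_points: int = 2101
    noise_cv: float = 0.10            # per-metabolite multiplicative CV
    baseline_amplitude: float = 0.01  # per-point units
    ppm_jitter_sd: float = 0.002      # ppm, global per-sample axis shift
    amount_scale_cv: float = 0.20     # per-sample global multiplier CV
    age_advance: dict = field(default_factory=dict)  # (genotype, tissue) -> days

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("need at least 2 grid points")
        if self.ppm_max <= self.ppm_min:
            raise ValueError("ppm_max must exceed ppm_min")
        lo, hi = self.ppm_min, self.ppm_max
        for m in self.metabolites:
            for p in m.peak_positions:
                if not (lo <= p <= hi):
                    raise ValueError(f"{m.name}: peak at {p} ppm outside grid")

    @property
    def ppm_grid(self) -> np.ndarray:
        return np.linspace(self.ppm_max, self.ppm_min, self.n_points)

    @property
    def grid_step(self) -> float:
        return (self.ppm_max - self.ppm_min) / (self.n_points - 1)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and the given CV."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _metabolite_shape(grid: np.ndarray, met: MetaboliteTemplate,
                      shift: float) -> np.ndarray:
    """Unit-integral Lorentzian multiplet evaluated on the (shifted) grid."""
    hw = met.peak_width / 2.0
    y = np.zeros_like(grid)
    for pos in met.peak_positions:
        y += hw * hw / ((grid - (pos + shift)) ** 2 + hw * hw)
    total = y.sum()
    if total <= 0:
        raise ValueError(f"{met.name}: no signal on grid")
    return y / total


def simulate_spectra(spec: SpectraSpec, seed: int) -> SpectrumSet:
    """Generate one SpectrumSet; pure function of (spec, seed).

    Per-sample randomness uses independent streams derived from
    ``SeedSequence([seed, sample_index])`` so the set is reproducible and
    insensitive to design reordering of *other* samples.
    """
    grid = spec.ppm_grid
    rows, meta = [], []
    idx = 0
    for cell in spec.design:
        adv = float(spec.age_advance.get((cell.genotype, cell.tissue), 0.0))
        for rep in range(1, cell.n_replicates + 1):
            rng = np.random.default_rng(np.random.SeedSequence([seed, idx]))
            shift = rng.normal(0.0, spec.ppm_jitter_sd) if spec.ppm_jitter_sd > 0 else 0.0
            amount = float(_lognormal_factor(rng, spec.amount_scale_cv))
            y = np.zeros_like(grid)
            for met in spec.metabolites:
                fold = met.fold(cell.genotype, cell.age_days, cell.tissue, adv)
                noise = float(_lognormal_factor(rng, spec.noise_cv))
                y += (met.base_intensity * fold * noise) * _metabolite_shape(
                    grid, met, shift
                )
            if spec.baseline_amplitude > 0:
                u = (grid - spec.ppm_min) / (spec.ppm_max - spec.ppm_min)
                c = rng.random(3)
                y = y + spec.baseline_amplitude * (c[0] + c[1] * u + c[2] * u * u)
            rows.append(amount * y)
            meta.append(
                {
                    "id": f"{cell.genotype}_{cell.tissue}_d{cell.age_days:g}_r{rep}",
                    "genotype": cell.genotype,
                    "age_days": cell.age_days,
                    "tissue": cell.tissue,
                    "replicate": rep,
                    "shift_ppm_true": shift,
                }
            )
            idx += 1
    return SpectrumSet(
        ppm=grid,
        intensities=np.vstack(rows),
        sample_meta=pd.DataFrame(meta),
        processing_log=[{"step": "simulate", "params": {"seed": seed}}],
    )
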