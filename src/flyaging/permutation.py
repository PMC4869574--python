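"""Permutation-null calibration of per-variable correlation significance.

For an OPLS(-DA) contrast model, each spectral variable carries a Pearson
correlation R with the predictive score. To decide which |R| are larger than
chance, the response is permuted across samples many times, the predictive
component refitted for each permutation, and the null distribution of R^2
collected. The significance cutoff is the (1 - alpha / n_metab) quantile of
the pooled null R^2 values — a Bonferroni correction at alpha for an assumed
number of independent metabolites (the spectral variables are far from
independent, so the variable count itself would be too harsh a divisor).

Permutations shuffle whole samples (response rows), preserving the spectral
covariance structure of X.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .multivariate import fit_opls

__all__ = ["PermutationResult", "permutation_r2_cutoff", "contrast_report"]


@dataclass(frozen=True)
class PermutationResult:
    n_permutations: int
    null_r2: np.ndarray          # pooled values, or per-dataset maxima in max mode
    alpha: float
    n_assumed_metabolites: int
    r2_cutoff: float
    observed_r: np.ndarray   # signed correlation with the predictive score
    significant_variable_indices: np.ndarray
    mode: str = "pooled"

    @property
    def observed_r2(self) -> np.ndarray:
        return self.observed_r**2

    @property
    def effective_alpha(self) -> float:
        return self.alpha / self.n_assumed_metabolites


def _predictive_r(Xc: np.ndarray, x_norms: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Signed correlation of each centered variable with the single
    predictive OPLS score for centered response y (no orthogonal filtering:
    the predictive component then equals the first PLS component). The score
    is oriented to correlate positively with y."""
    w = Xc.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        return np.zeros(Xc.shape[1])
    t = Xc @ (w / nw)
    tc = t - t.mean()
    tn = np.linalg.norm(tc)
    if tn == 0:
        return np.zeros(Xc.shape[1])
    if float(tc @ y) < 0:
        tc = -tc
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ tc) / (x_norms * tn)
    r[~np.isfinite(r)] = 0.0
    return r


def permutation_r2_cutoff(
    X: np.ndarray,
    response: Sequence[float],
    seed: int,
    n_perm: int = 10_000,
    alpha: float = 0.01,
    n_metab: int = 100,
    n_orthogonal: int = 0,
    mode: str = "pooled",
) -> PermutationResult:
    """Null-calibrated R^2 cutoff for one contrast.

    ``mode="pooled"`` (default) pools all per-variable null R^2 values and
    takes the (1 - alpha/n_metab) quantile; ``mode="max"`` keeps each
    permuted data set's maximum R^2 and takes the (1 - alpha) quantile
    (direct familywise control, no Bonferroni divisor).
    """
    if n_perm < 100:
        raise ValueError("need >= 100 permutations for a stable tail")
    if mode not in ("pooled", "max"):
        raise ValueError(f"unknown mode: {mode!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    if len(y) != X.shape[0]:
        raise ValueError("response length must match sample count")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    Xc = X - X.mean(axis=0)
    x_norms = np.sqrt((Xc**2).sum(axis=0))

    def r_for(y_vec: np.ndarray) -> np.ndarray:
        yc = y_vec - y_vec.mean()
        if n_orthogonal == 0:
            return _predictive_r(Xc, x_norms, yc)
        m = fit_opls(X, y_vec[:, None], n_predictive=1, n_orthogonal=n_orthogonal)
        return m.correlation[:, 0]

    observed = r_for(y)
    null_vals = []
    for _ in range(n_perm):
        r2 = r_for(rng.permutation(y)) ** 2
        null_vals.append(r2.max() if mode == "max" else r2)
    null = np.asarray(null_vals).ravel() if mode == "max" else np.concatenate(null_vals)
    q = 1.0 - (alpha if mode == "max" else alpha / n_metab)
    cutoff = float(np.quantile(null, q, method="linear"))
    return PermutationResult(
        n_permutations=n_perm,
        null_r2=null,
        alpha=alpha,
        n_assumed_metabolites=n_metab,
        r2_cutoff=cutoff,
        observed_r=observed,
        significant_variable_indices=np.flatnonzero(observed**2 > cutoff),
        mode=mode,
    )


def contrast_report(
    ppm: np.ndarray,
    correlation: np.ndarray,
    r2_cutoff: float,
) -> pd.DataFrame:
    """Merge significant variables into contiguous ppm regions.

    ``correlation`` is the per-variable R against the contrast's predictive
    score, oriented so positive R means higher intensity in the second group.
    Runs are split where the sign flips. Columns: ppm_high, ppm_low,
    direction ("increase"/"decrease" in the second group), max_abs_r,
    n_points.
    """
    ppm = np.asarray(ppm, dtype=float)
    r = np.asarray(correlation, dtype=float)
    if len(ppm) != len(r):
        raise ValueError("ppm and correlation lengths differ")
    sig = r * r > r2_cutoff
    rows = []
    i = 0
    while i < len(r):
        if not sig[i]:
            i += 1
            continue
        j = i
        sign = np.sign(r[i])
        while j + 1 < len(r) and sig[j + 1] and np.sign(r[j + 1]) == sign:
            j += 1
        seg = slice(i, j + 1)
        k = i + int(np.argmax(np.abs(r[seg])))
        rows.append(
            {
                "ppm_high": float(ppm[seg].max()),
                "ppm_low": float(ppm[seg].min()),
                "direction": "increase" if sign > 0 else "decrease",
                "max_abs_r": float(abs(r[k])),
                "n_points": j - i + 1,
            }
        )
        i = j + 1
    return pd.DataFrame(rows, columns=["ppm_high", "ppm_low", "direction",
                                       "max_abs_r", "n_points"])
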