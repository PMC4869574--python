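"""1H-NMR spectrum sets and their preprocessing pipeline.

The pipeline mirrors standard small-molecule NMR chemometrics practice:
chemical-shift referencing to the internal TSP standard, excision of the
residual-water region and the signal-free spectrum ends, interval-based
(icoshift-style) alignment to a median reference, normalisation of each
spectrum to its total intensity (removing sample-amount variation), and
pareto scaling with centering (per-variable mean subtraction and division by
the square root of the standard deviation — a compromise between unit
variance and no scaling that keeps large peaks from drowning out small ones
without blowing up baseline noise).

Each applied step is appended to a ``processing_log``; steps enforce the
canonical order and refuse to run after a later step has been applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = ["id", "genotype", "age_days", "tissue", "replicate"]

# canonical pipeline order; each op records its stage index in the log
_STAGES = {
    "reference_to_tsp": 0,
    "exclude_regions": 1,
    "align_segments": 2,
    "normalize_total_intensity": 3,
    "pareto_scale": 4,
}

__all__ = [
    "SpectrumSet",
    "META_COLUMNS",
    "reference_to_tsp",
    "exclude_regions",
    "align_segments",
    "normalize_total_intensity",
    "pareto_scale",
    "preprocess",
    "read_spectrum_set",
    "write_spectrum_set",
]


@dataclass
class SpectrumSet:
    """A common ppm axis, one intensity row per sample, and sample metadata.

    ``ppm`` is strictly decreasing (conventional NMR display order).
    ``processing_log`` is append-only; ops validate ordering against it.
    """

    ppm: np.ndarray
    intensities: np.ndarray
    sample_meta: pd.DataFrame
    processing_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if not np.all(np.diff(self.ppm) < 0):
            raise ValueError("ppm axis must be strictly decreasing")
        if self.intensities.shape[1] != len(self.ppm):
            raise ValueError("intensity columns must match ppm axis length")
        if len(self.sample_meta) != self.intensities.shape[0]:
            raise ValueError("sample_meta rows must match intensity rows")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(
            ppm=self.ppm.copy(),
            intensities=self.intensities.copy(),
            sample_meta=self.sample_meta.copy(),
            processing_log=list(self.processing_log),
        )

    def select(self, mask) -> "SpectrumSet":
        """Row-subset by boolean mask or integer index array."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectrumSet(
            ppm=self.ppm.copy(),
            intensities=self.intensities[idx],
            sample_meta=self.sample_meta.iloc[idx].reset_index(drop=True),
            processing_log=list(self.processing_log),
        )

    def _check_order(self, step: str) -> None:
        stage = _STAGES[step]
        applied = [_STAGES[e["step"]] for e in self.processing_log if e["step"] in _STAGES]
        if applied and stage < max(applied):
            raise ValueError(
                f"{step} cannot be applied after "
                f"{[s for s, i in _STAGES.items() if i == max(applied)][0]}"
            )

    def _logged(self, step: str, **params) -> "SpectrumSet":
        out = self.copy()
        out.processing_log.append({"step": step, "params": params})
        return out


def _shift_points(row: np.ndarray, k: int) -> np.ndarray:
    """Shift a vector by k points toward higher indices, edge-value padding."""
    if k == 0:
        return row.copy()
    out = np.roll(row, k)
    if k > 0:
        out[:k] = row[0]
    else:
        out[k:] = row[-1]
    return out


def reference_to_tsp(
    s: SpectrumSet,
    search_window: tuple = (0.2, -0.2),
    target: float = -0.017,
) -> SpectrumSet:
    """Shift each spectrum so its tallest peak in the reference window sits at
    the TSP position (default -0.017 ppm).

    Shifts are applied in whole grid steps (nearest-point rounding) so a
    spectrum whose reference peak already sits at the grid point closest to
    the target is returned unchanged.
    """
    s._check_order("reference_to_tsp")
    hi, lo = max(search_window), min(search_window)
    in_win = (s.ppm >= lo) & (s.ppm <= hi)
    if not in_win.any():
        raise ValueError("reference search window outside ppm axis")
    step = float(abs(np.median(np.diff(s.ppm))))
    out = s._logged("reference_to_tsp", search_window=list(search_window), target=target)
    win_idx = np.flatnonzero(in_win)
    for i in range(s.n_samples):
        seg = s.intensities[i, win_idx]
        if seg.max() <= seg.min() + 1e-12 * max(abs(seg.max()), 1.0):
            raise ValueError(f"sample {i}: no reference peak in search window")
        peak_ppm = s.ppm[win_idx[np.argmax(seg)]]
        # ppm descends with index, so a positive ppm shift moves points down
        k = int(round((peak_ppm - target) / step))
        if k != 0:
            out.intensities[i] = _shift_points(s.intensities[i], k)
    return out


def exclude_regions(
    s: SpectrumSet,
    water: tuple = (4.88, 4.67),
    keep: tuple = (9.5, 0.5),
) -> SpectrumSet:
    """Drop the residual-water region and everything outside the informative
    window (endpoints inclusive; grid points are treated as point samples)."""
    s._check_order("exclude_regions")
    eps = 1e-9
    w_hi, w_lo = max(water), min(water)
    k_hi, k_lo = max(keep), min(keep)
    mask = (
        (s.ppm >= k_lo - eps)
        & (s.ppm <= k_hi + eps)
        & ~((s.ppm >= w_lo - eps) & (s.ppm <= w_hi + eps))
    )
    if not mask.any():
        raise ValueError("region exclusion removed every point")
    out = s._logged("exclude_regions", water=list(water), keep=list(keep))
    out.ppm = out.ppm[mask]
    out.intensities = out.intensities[:, mask]
    return out


def _segment_slices(n_points: int, seg_len: int) -> list:
    bounds = list(range(0, n_points, seg_len))
    slices = [slice(b, min(b + seg_len, n_points)) for b in bounds]
    # merge a tiny trailing remainder into the previous segment
    if len(slices) > 1 and (slices[-1].stop - slices[-1].start) < 3:
        slices[-2] = slice(slices[-2].start, n_points)
        slices.pop()
    return slices


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    ac, bc = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0 or nb == 0:
        return 0.0
    return float(ac @ bc / (na * nb))


def _best_segment_shift(seg: np.ndarray, ref: np.ndarray, max_shift: int) -> int:
    """Integer shift of `seg` (|shift| <= max_shift) maximising Pearson
    correlation with `ref`; candidates are visited by increasing |shift| so
    the smallest shift wins ties (zero preferred)."""
    best_shift, best_score = 0, _corr(seg, ref)
    for mag in range(1, max_shift + 1):
        for sh in (mag, -mag):
            score = _corr(_shift_points(seg, sh), ref)
            if score > best_score + 1e-9:
                best_score, best_shift = score, sh
    return best_shift


def align_segments(
    s: SpectrumSet,
    segment_ppm: float = 0.05,
    max_shift_points: int = 4,
    reference: Optional[np.ndarray] = None,
) -> SpectrumSet:
    """Icoshift-style alignment: fixed ppm segments, per-segment integer shift
    of each sample maximising cross-correlation with the pointwise-median
    reference spectrum, edge-value padding."""
    s._check_order("align_segments")
    step = float(abs(np.median(np.diff(s.ppm))))
    seg_len = max(int(round(segment_ppm / step)), 1)
    if seg_len < 3:
        raise ValueError("segment smaller than 3 points")
    ref = np.median(s.intensities, axis=0) if reference is None else np.asarray(reference)
    out = s._logged(
        "align_segments", segment_ppm=segment_ppm, max_shift_points=max_shift_points
    )
    all_shifts = []
    for sl in _segment_slices(len(s.ppm), seg_len):
        ref_seg = ref[sl]
        col = np.zeros(s.n_samples, dtype=int)
        for i in range(s.n_samples):
            seg = s.intensities[i, sl]
            sh = _best_segment_shift(seg, ref_seg, max_shift_points)
            col[i] = sh
            if sh:
                out.intensities[i, sl] = _shift_points(seg, sh)
        all_shifts.append(col)
    out.processing_log[-1]["params"]["applied_shifts"] = np.column_stack(all_shifts).tolist()
    return out


def normalize_total_intensity(s: SpectrumSet) -> SpectrumSet:
    """Divide each spectrum by its summed intensity so row sums equal 1."""
    s._check_order("normalize_total_intensity")
    totals = s.intensities.sum(axis=1)
    if np.any(totals <= 0):
        bad = int(np.flatnonzero(totals <= 0)[0])
        raise ValueError(f"sample {bad} has nonpositive total intensity")
    out = s._logged("normalize_total_intensity")
    out.intensities = out.intensities / totals[:, None]
    return out


def pareto_scale(
    s: SpectrumSet,
    means: Optional[np.ndarray] = None,
    sds: Optional[np.ndarray] = None,
) -> SpectrumSet:
    """Center each variable and divide by the square root of its standard
    deviation (n-1 denominator); zero-sd variables map to all-zero columns.

    Passing ``means``/``sds`` from a training set scales new samples with the
    training constants, as required when projecting held-out spectra onto a
    fitted model.
    """
    reused = means is not None or sds is not None
    if not reused and s.n_samples < 2:
        raise ValueError("pareto scaling needs >= 2 samples")
    s._check_order("pareto_scale")
    if means is None:
        means = s.intensities.mean(axis=0)
    if sds is None:
        sds = s.intensities.std(axis=0, ddof=1)
    out = s._logged("pareto_scale", reused_constants=reused)
    centered = out.intensities - means
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = centered / np.sqrt(sds)
    scaled[:, np.asarray(sds) <= 0] = 0.0
    out.intensities = scaled
    return out


def preprocess(
    s: SpectrumSet,
    align: bool = True,
    segment_ppm: float = 0.05,
    max_shift_points: int = 4,
    scale: bool = True,
) -> SpectrumSet:
    """Full pipeline: reference -> exclude -> (align) -> normalize -> (pareto)."""
    s = reference_to_tsp(s)
    s = exclude_regions(s)
    if align:
        s = align_segments(s, segment_ppm=segment_ppm, max_shift_points=max_shift_points)
    s = normalize_total_intensity(s)
    if scale:
        s = pareto_scale(s)
    return s


def write_spectrum_set(s: SpectrumSet, matrix_path, meta_path) -> None:
    """TSV matrix (first column ppm, one column per sample) + JSON metadata."""
    df = pd.DataFrame(s.intensities.T, columns=s.sample_meta["id"].tolist())
    df.insert(0, "ppm", s.ppm)
    df.to_csv(matrix_path, sep="\t", index=False)
    payload = {
        "samples": s.sample_meta.to_dict(orient="records"),
        "processing_log": s.processing_log,
    }
    with open(meta_path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_spectrum_set(matrix_path, meta_path) -> SpectrumSet:
    df = pd.read_csv(matrix_path, sep="\t")
    with open(meta_path) as fh:
        payload = json.load(fh)
    meta = pd.DataFrame(payload["samples"])
    ids = meta["id"].astype(str).tolist()
    return SpectrumSet(
        ppm=df["ppm"].to_numpy(),
        intensities=df[ids].to_numpy().T,
        sample_meta=meta,
        processing_log=payload.get("processing_log", []),
    )
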