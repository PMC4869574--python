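"""Preprocessing pipeline: referencing, excision, alignment, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from flyaging import spectra as sp
from flyaging.simulate import default_spectra_spec, simulate_spectra


def _set(ppm, rows, log=None):
    meta = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(len(rows))],
            "genotype": "g",
            "age_days": 1.0,
            "tissue": "head",
            "replicate": 1,
        }
    )
    return sp.SpectrumSet(np.asarray(ppm, float), np.asarray(rows, float), meta,
                          processing_log=list(log or []))


def _grid(step=0.01):
    n = int(round(10.5 / step)) + 1
    return np.linspace(10.0, -0.5, n)


def _lorentz(ppm, pos, width=0.02):
    hw = width / 2
    return hw * hw / ((ppm - pos) ** 2 + hw * hw)


class TestReferencing:
    def test_peak_at_nearest_grid_point_unchanged(self):
        ppm = _grid()
        idx = np.argmin(abs(ppm + 0.017))
        row = _lorentz(ppm, ppm[idx])
        out = sp.reference_to_tsp(_set(ppm, [row]))
        assert np.array_equal(out.intensities[0], row)

    def test_displaced_peak_is_shifted_back(self):
        ppm = _grid()
        out = sp.reference_to_tsp(_set(ppm, [_lorentz(ppm, 0.01)]))
        peak_after = ppm[np.argmax(out.intensities[0])]
        assert abs(peak_after - (-0.017)) <= 0.01 + 1e-9  # within one grid step

    def test_flat_spectrum_raises(self):
        ppm = _grid()
        with pytest.raises(ValueError):
            sp.reference_to_tsp(_set(ppm, [np.ones_like(ppm)]))


class TestExcision:
    def test_retained_point_count_on_centipoint_grid(self):
        ppm = _grid(0.01)
        out = sp.exclude_regions(_set(ppm, [np.ones_like(ppm)]))
        # [0.5, 9.5] inclusive holds 901 centipoints; [4.67, 4.88] holds 22
        assert len(out.ppm) == 901 - 22
        assert out.ppm.max() == pytest.approx(9.5)
        assert out.ppm.min() == pytest.approx(0.5)

    def test_signal_only_in_water_region_zeroed(self):
        ppm = _grid()
        row = np.where((ppm >= 4.70) & (ppm <= 4.85), 1.0, 0.0)
        out = sp.exclude_regions(_set(ppm, [row]))
        assert out.intensities.sum() == 0.0


class TestAlignment:
    def test_identical_samples_not_changed(self):
        ppm = _grid()
        row = _lorentz(ppm, 5.0) + _lorentz(ppm, 2.0)
        out = sp.align_segments(_set(ppm, [row, row, row]))
        assert np.allclose(out.intensities, [row, row, row])

    def test_integer_displacement_recovered(self):
        ppm = _grid()
        base = _lorentz(ppm, 5.0)
        shifted = np.roll(base, 2)  # displaced by +2 grid points
        out = sp.align_segments(
            _set(ppm, [base, base, shifted]), segment_ppm=0.3, max_shift_points=4
        )
        assert np.allclose(out.intensities[2], base, atol=2e-2)

    def test_segment_too_small_raises(self):
        ppm = _grid()
        with pytest.raises(ValueError):
            sp.align_segments(_set(ppm, [np.ones_like(ppm)]), segment_ppm=0.01)

    def test_jittered_default_design_realigned(self):
        """Injected axis shifts of ~2 grid steps are corrected to <=1 point
        for at least 95% of samples (residual shift vs the median spectrum)."""
        spec = default_spectra_spec(n_replicates=1)
        step = spec.grid_step
        jittered = simulate_spectra(
            type(spec)(
                metabolites=spec.metabolites,
                design=spec.design,
                noise_cv=spec.noise_cv,
                baseline_amplitude=spec.baseline_amplitude,
                ppm_jitter_sd=2 * step,
                amount_scale_cv=spec.amount_scale_cv,
                age_advance=spec.age_advance,
            ),
            seed=13,
        )
        aligned = sp.align_segments(jittered, segment_ppm=0.25, max_shift_points=8)
        ref = np.median(aligned.intensities, axis=0)

        def residual_shift(row):
            scores = [
                float(np.dot(np.roll(row, k), ref)) for k in range(-4, 5)
            ]
            return int(np.argmax(scores)) - 4

        residuals = np.array([residual_shift(r) for r in aligned.intensities])
        assert np.mean(np.abs(residuals) <= 1) >= 0.95


class TestNormalization:
    def test_scale_invariance(self):
        ppm = _grid()
        row = _lorentz(ppm, 3.0) + 0.1
        out = sp.normalize_total_intensity(_set(ppm, [row, 7 * row]))
        assert np.allclose(out.intensities[0], out.intensities[1], atol=1e-14)
        assert np.allclose(out.intensities.sum(axis=1), 1.0, atol=1e-12)

    def test_idempotent(self):
        ppm = _grid()
        rows = [_lorentz(ppm, 3.0) + 0.1, _lorentz(ppm, 6.0) + 0.2]
        once = sp.normalize_total_intensity(_set(ppm, rows))
        twice = sp.normalize_total_intensity(once)
        assert np.allclose(once.intensities, twice.intensities, atol=1e-15)

    def test_nonpositive_total_raises(self):
        ppm = _grid()
        with pytest.raises(ValueError):
            sp.normalize_total_intensity(_set(ppm, [np.zeros_like(ppm)]))

    @settings(deadline=None, max_examples=20)
    @given(
        hnp.arrays(
            float, (3, 20),
            elements=st.floats(min_value=0.01, max_value=1e3),
        )
    )
    def test_row_sums_one_for_any_positive_matrix(self, rows):
        ppm = np.linspace(5.0, 0.0, 20)
        out = sp.normalize_total_intensity(_set(ppm, rows))
        assert np.allclose(out.intensities.sum(axis=1), 1.0, atol=1e-9)


class TestParetoScaling:
    def test_constant_column_maps_to_zero_and_columns_centered(self):
        ppm = np.linspace(3.0, 1.0, 3)
        rows = np.array([[1.0, 0.0, 5.0], [1.0, 2.0, 6.0]])
        out = sp.pareto_scale(_set(ppm, rows))
        assert np.allclose(out.intensities[:, 0], 0.0)
        assert np.allclose(out.intensities.mean(axis=0), 0.0, atol=1e-12)

    def test_hand_computed_column(self):
        # column {0, 2}: mean 1, sd sqrt(2) (n-1 denominator),
        # scaled values +-1/2**(1/4) = +-0.840896...
        ppm = np.linspace(3.0, 1.0, 3)
        rows = np.array([[0.0, 1.0, 5.0], [2.0, 2.0, 6.0]])
        out = sp.pareto_scale(_set(ppm, rows))
        assert out.intensities[0, 0] == pytest.approx(-(2 ** -0.25), abs=1e-12)
        assert out.intensities[1, 0] == pytest.approx(2 ** -0.25, abs=1e-12)

    def test_single_sample_requires_reference_constants(self):
        ppm = np.linspace(3.0, 1.0, 3)
        with pytest.raises(ValueError):
            sp.pareto_scale(_set(ppm, [[1.0, 2.0, 3.0]]))
        out = sp.pareto_scale(
            _set(ppm, [[1.0, 2.0, 3.0]]),
            means=np.array([0.0, 0.0, 0.0]),
            sds=np.array([1.0, 4.0, 1.0]),
        )
        assert out.intensities[0, 1] == pytest.approx(1.0)  # 2 / sqrt(4)


class TestPipelineOrder:
    def test_out_of_order_application_rejected(self):
        ppm = _grid()
        rows = [_lorentz(ppm, 3.0) + 0.1, _lorentz(ppm, 3.0) + 0.2]
        s = sp.normalize_total_intensity(_set(ppm, rows))
        with pytest.raises(ValueError):
            sp.align_segments(s)
        with pytest.raises(ValueError):
            sp.exclude_regions(s)

    def test_skipping_a_stage_is_allowed(self):
        ppm = _grid()
        rows = [_lorentz(ppm, 3.0) + 0.1, _lorentz(ppm, 3.0) + 0.2]
        s = sp.exclude_regions(_set(ppm, rows))  # no referencing first
        s = sp.normalize_total_intensity(s)      # no alignment
        assert [e["step"] for e in s.processing_log] == [
            "exclude_regions",
            "normalize_total_intensity",
        ]

    def test_log_is_append_only_and_copied(self):
        ppm = _grid()
        rows = [_lorentz(ppm, 3.0) + 0.1]
        base = _set(ppm, rows)
        out = sp.reference_to_tsp(base)
        assert base.processing_log == []
        assert [e["step"] for e in out.processing_log] == ["reference_to_tsp"]


def test_roundtrip_tsv_json(tmp_path):
    spec = default_spectra_spec(n_replicates=1)
    ss = simulate_spectra(spec, seed=3).select(np.arange(4))
    sp.write_spectrum_set(ss, tmp_path / "m.tsv", tmp_path / "m.json")
    back = sp.read_spectrum_set(tmp_path / "m.tsv", tmp_path / "m.json")
    assert np.allclose(back.intensities, ss.intensities, atol=1e-9)
    assert back.sample_meta["genotype"].tolist() == ss.sample_meta["genotype"].tolist()
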