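"""The finite-window Fourier wavenumber estimator and its analytic spectrum."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axobeat import (
    SyntheticBeatParams,
    WavelengthConfig,
    analytic_G,
    bias_curve,
    estimate_wavelength,
    generate_tangent_field,
    power_spectrum,
    wavenumber_grid,
)
from axobeat.preprocess import segment_beats
from axobeat.wavelength import spectrum_matrix


def test_zero_profile_has_zero_spectrum():
    s = np.arange(46) * 0.218
    k = wavenumber_grid(10.0)
    G = power_spectrum(np.zeros_like(s), s, k)
    assert np.abs(G.G).max() == 0.0


def test_single_frame_spectrum_matches_dense_quadrature():
    """The trapezoid-integrated single-frame spectrum peaks where a 20×-denser
    quadrature of the same integrals does (the single-frame peak itself
    carries a phase-dependent finite-window shift of order 1/(k0·L), which
    is why the estimator averages over the beat)."""
    lam0 = 5.0
    s = np.arange(0, 4 * lam0 + 1e-9, 0.05)
    k = wavenumber_grid(4 * lam0, 4096)
    G = power_spectrum(np.sin(2 * np.pi * s / lam0), s, k)
    s_dense = np.linspace(0, s[-1], 20 * s.size)
    G_dense = power_spectrum(np.sin(2 * np.pi * s_dense / lam0), s_dense, k)
    assert abs(int(np.argmax(G.G)) - int(np.argmax(G_dense.G))) <= 1
    # and the shift from k0 stays below the ~1/(k0 L) finite-window scale
    k0 = 2 * np.pi / lam0
    assert abs(k[np.argmax(G.G)] - k0) < 1.5 / (k0 * s[-1]**2) * 2 * np.pi


def test_beat_averaged_peak_is_unbiased_at_unit_ratio(unit_ratio_field):
    """With λ0 = L the argmax of the beat-averaged spectrum is k0."""
    k = wavenumber_grid(unit_ratio_field.length_um, 2048)
    G = spectrum_matrix(unit_ratio_field.psi, unit_ratio_field.s_um, k).mean(axis=1)
    k0 = 2 * np.pi / 10.0
    assert abs(k[np.argmax(G)] - k0) <= k[1] - k[0]


class TestEstimateWavelength:
    def test_unit_ratio_beat_within_one_percent(self, unit_ratio_field,
                                                unit_ratio_segmentation):
        est = estimate_wavelength(unit_ratio_field, unit_ratio_segmentation)
        assert est.lambda_um == pytest.approx(10.0, rel=0.01)
        assert est.n_beats == 66
        assert est.k0_per_um == pytest.approx(2 * np.pi / est.lambda_um)

    def test_multi_wavelength_regime_within_one_percent(self):
        p = SyntheticBeatParams(length_um=22.0, wavelength_um=15.0)
        f = generate_tangent_field(p)
        est = estimate_wavelength(f, segment_beats(f, p.frequency_hz))
        assert est.lambda_um == pytest.approx(15.0, rel=0.01)

    def test_fifty_percent_noise_moves_estimate_less_than_two_percent(
        self, unit_ratio_params, unit_ratio_segmentation
    ):
        noisy = generate_tangent_field(unit_ratio_params.replace(noise_level=0.5, seed=0))
        est = estimate_wavelength(noisy, unit_ratio_segmentation)
        assert est.lambda_um == pytest.approx(10.0, rel=0.02)

    def test_out_of_range_peak_is_flagged(self):
        # λ0 far above the searched [L/4, 2L] upper bound pushes the peak
        # onto the low-k boundary
        p = SyntheticBeatParams(length_um=8.0, wavelength_um=40.0)
        f = generate_tangent_field(p)
        est = estimate_wavelength(f, segment_beats(f, p.frequency_hz))
        assert "k_peak_on_boundary" in est.flags

    def test_per_beat_and_all_frames_modes_agree_on_clean_data(
        self, unit_ratio_field, unit_ratio_segmentation
    ):
        per_beat = estimate_wavelength(unit_ratio_field, unit_ratio_segmentation)
        record = estimate_wavelength(
            unit_ratio_field, unit_ratio_segmentation, WavelengthConfig(mode="all_frames")
        )
        assert record.lambda_um == pytest.approx(per_beat.lambda_um, rel=0.005)


class TestAnalyticG:
    def test_zero_amplitude_is_zero(self):
        k = wavenumber_grid(10.0, 256)
        assert np.abs(analytic_G(k, 2 * np.pi / 10, 10.0, amplitude_rad=0.0)).max() == 0.0

    def test_peak_sits_at_k0_when_window_equals_wavelength(self):
        lam0 = 10.0
        k = np.linspace(0.05, 4.0, 20000)
        G = analytic_G(k, 2 * np.pi / lam0, lam0)
        assert abs(k[np.argmax(G)] - 2 * np.pi / lam0) <= k[1] - k[0]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        lw=st.floats(5.0, 25.0),
        lam_frac=st.floats(0.5, 1.0),
        k_frac=st.floats(0.0, 1.0),
    )
    def test_matches_brute_force_quadrature(self, lw, lam_frac, k_frac):
        """Uniform-phase-averaged dense quadrature reproduces the closed form."""
        k0 = 2 * np.pi / (lam_frac * lw)
        k = 2 * np.pi / (2 * lw) + k_frac * (2 * np.pi / (lw / 4) - 2 * np.pi / (2 * lw))
        s = np.linspace(0.0, lw, 20001)
        phases = 2 * np.pi * np.arange(16) / 16
        psi = np.sin(k0 * s[None, :] + phases[:, None])
        c = np.trapezoid(psi * np.cos(k * s), s, axis=1)
        sn = np.trapezoid(psi * np.sin(k * s), s, axis=1)
        brute = float((c**2 + sn**2).mean())
        peak = float(analytic_G(np.array([k0]), k0, lw)[0])
        assert abs(float(analytic_G(np.array([k]), k0, lw)[0]) - brute) < 1e-6 * peak

    def test_argmax_agrees_with_numerical_estimator(self, unit_ratio_field):
        k = wavenumber_grid(unit_ratio_field.length_um, 2048)
        G_num = spectrum_matrix(unit_ratio_field.psi, unit_ratio_field.s_um, k).mean(axis=1)
        G_ana = analytic_G(k, 2 * np.pi / 10.0, unit_ratio_field.length_um, 0.5)
        assert abs(int(np.argmax(G_num)) - int(np.argmax(G_ana))) <= 1


class TestBiasCurve:
    def test_bias_below_one_percent_for_ratio_at_least_one(self):
        df = bias_curve([1.0, 2.0])
        assert (df["relative_error"].abs() < 0.01).all()

    def test_half_ratio_boundary_is_reported_not_asserted(self):
        df = bias_curve([0.5])
        assert np.isfinite(df["relative_error"]).all()


class TestEstimatorProperties:
    def test_scale_equivariance_of_the_length_wavelength_ratio(self):
        lam_hats = []
        for c in (1.0, 2.0):
            p = SyntheticBeatParams(length_um=12.0 * c, wavelength_um=10.0 * c,
                                    ds_um=0.218 * c, n_frames=300)
            f = generate_tangent_field(p)
            est = estimate_wavelength(f, segment_beats(f, p.frequency_hz))
            lam_hats.append(est.lambda_um / (10.0 * c))
        assert lam_hats[0] == pytest.approx(lam_hats[1], rel=1e-6)

    def test_amplitude_invariance(self, unit_ratio_field, unit_ratio_segmentation):
        scaled = unit_ratio_field
        est1 = estimate_wavelength(scaled, unit_ratio_segmentation)
        import dataclasses

        doubled = dataclasses.replace(scaled, psi=3.7 * scaled.psi)
        est2 = estimate_wavelength(doubled, unit_ratio_segmentation)
        assert est2.lambda_um == pytest.approx(est1.lambda_um, rel=1e-9)

    def test_grid_refinement_does_not_worsen_the_estimate(
        self, unit_ratio_field, unit_ratio_segmentation
    ):
        coarse = estimate_wavelength(unit_ratio_field, unit_ratio_segmentation,
                                     WavelengthConfig(n_k=1024))
        fine = estimate_wavelength(unit_ratio_field, unit_ratio_segmentation,
                                   WavelengthConfig(n_k=2048))
        k = wavenumber_grid(unit_ratio_field.length_um, 1024)
        dlam_old_step = (k[1] - k[0]) * 10.0**2 / (2 * np.pi)
        assert abs(fine.lambda_um - 10.0) <= abs(coarse.lambda_um - 10.0) + dlam_old_step

    def test_middle_80_percent_trim_restricts_the_window(self, unit_ratio_field,
                                                         unit_ratio_segmentation):
        est = estimate_wavelength(unit_ratio_field, unit_ratio_segmentation,
                                  WavelengthConfig(trim_fraction=0.1))
        # still a sane estimate, but carrying the finite-window penalty
        assert est.lambda_um == pytest.approx(10.0, rel=0.05)
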