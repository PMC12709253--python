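"""Rotation removal, beat segmentation, and static/dynamic decomposition."""

import numpy as np
import pytest

from axobeat import (
    InputDataError,
    SyntheticBeatParams,
    TangentField,
    decompose,
    generate_centerlines,
    generate_tangent_field,
    remove_rotation,
    segment_beats,
)
from axobeat.geometry import centerline_to_tangent_field


def _field(psi, ds=0.218, dt=1e-3):
    n_s, n_t = psi.shape
    return TangentField(psi=psi, s_um=np.arange(n_s) * ds, t_s=np.arange(n_t) * dt)


class TestRemoveRotation:
    def test_zero_rotation_leaves_the_field_nearly_unchanged(self):
        p = SyntheticBeatParams(length_um=10.0, wavelength_um=10.0)
        f = generate_tangent_field(p)
        out = remove_rotation(f).field
        # the trend of a zero-mean oscillation is ≈ 0 away from the record
        # boundaries, where LOESS sees one-sided windows
        interior = slice(100, 900)
        assert np.abs(out.psi[:, interior] - f.psi[:, interior]).max() < 0.01

    def test_pure_linear_trend_is_cancelled(self):
        t = np.arange(1000) * 1e-3
        psi = np.tile(1.0 * t, (40, 1))  # Ω = 1 rad/s, no oscillation
        # LOESS needs an oscillation-free explicit span here (no beat to size it)
        out = remove_rotation(_field(psi), loess_frac=0.3)
        interior = slice(100, 900)
        assert np.abs(out.field.psi[0, interior]).max() < 0.01

    def test_rotation_rate_recovered_within_five_percent(self):
        p = SyntheticBeatParams(
            length_um=10.0, wavelength_um=10.0, frequency_hz=65.0,
            rotation_rate_rad_s=2.0,
        )
        field = centerline_to_tangent_field(generate_centerlines(p), ds_um=0.218)
        rot = remove_rotation(field)
        assert rot.rotation_rate_rad_s == pytest.approx(2.0, rel=0.05)

    def test_degenerate_time_grid_is_rejected(self):
        # all-equal timestamps violate the field's grid contract up front
        with pytest.raises(InputDataError):
            TangentField(psi=np.zeros((10, 12)), s_um=np.arange(10) * 0.2,
                         t_s=np.zeros(12))


class TestSegmentBeats:
    def test_exact_division_50hz(self, unit_ratio_field):
        seg = segment_beats(unit_ratio_field, 50.0)
        assert seg.period_frames == 20
        assert seg.n_beats == 50
        assert seg.beat_windows[0] == (0, 20)

    def test_rounding_65hz_discards_trailing_frames(self, unit_ratio_field):
        seg = segment_beats(unit_ratio_field, 65.0)
        assert seg.period_frames == 15
        assert seg.n_beats == 66
        assert seg.n_complete_frames == 990  # 10 frames discarded

    def test_undersampled_period_raises(self, unit_ratio_field):
        with pytest.raises(InputDataError, match="undersampled"):
            segment_beats(unit_ratio_field, 400.0)


class TestDecompose:
    def test_time_constant_field_is_all_static(self):
        s = np.arange(46) * 0.218
        psi = np.tile(0.2 * s[:, None], (1, 100))
        f = _field(psi)
        seg = segment_beats(f, 50.0)
        d = decompose(f, seg)
        assert np.abs(d.psi_dynamic.psi).max() < 1e-12
        assert d.static_curvature_per_um == pytest.approx(0.2, abs=1e-12)

    def test_integer_beats_of_a_pure_sinusoid_average_to_zero(self):
        p = SyntheticBeatParams(length_um=10.0, wavelength_um=10.0, frequency_hz=50.0,
                                n_frames=1000)
        f = generate_tangent_field(p)
        d = decompose(f, segment_beats(f, 50.0))
        assert np.abs(d.psi_static).max() < 1e-12

    def test_static_curvature_recovered_within_two_percent(self):
        p = SyntheticBeatParams(length_um=10.0, wavelength_um=10.0,
                                static_curvature_per_um=0.2)
        f = generate_tangent_field(p)
        d = decompose(f, segment_beats(f, p.frequency_hz))
        assert d.static_curvature_per_um == pytest.approx(0.2, rel=0.02)

    def test_reconstruction_is_exact_and_decompose_is_idempotent(self, unit_ratio_field,
                                                                 unit_ratio_segmentation):
        d = decompose(unit_ratio_field, unit_ratio_segmentation)
        np.testing.assert_allclose(
            d.psi_static[:, None] + d.psi_dynamic.psi, unit_ratio_field.psi,
            rtol=0, atol=1e-14,
        )
        d2 = decompose(d.psi_dynamic, unit_ratio_segmentation)
        assert np.abs(d2.psi_static).max() < 1e-12

    def test_segmentation_beyond_record_raises(self, unit_ratio_field):
        seg = segment_beats(unit_ratio_field, 65.0)
        short = TangentField(psi=unit_ratio_field.psi[:, :100],
                             s_um=unit_ratio_field.s_um,
                             t_s=unit_ratio_field.t_s[:100])
        with pytest.raises(InputDataError):
            decompose(short, seg)


def test_joint_rate_and_curvature_recovery_across_lengths():
    """Pipeline-order recovery of (Ω, C0) within 5% for lengths 8–25 μm."""
    for L in (8.0, 12.0, 15.0, 20.0, 25.0):
        p = SyntheticBeatParams(
            length_um=L, wavelength_um=min(L, 15.0), static_curvature_per_um=0.2,
            rotation_rate_rad_s=1.0, n_frames=500,
        )
        field = centerline_to_tangent_field(generate_centerlines(p), ds_um=0.218)
        rot = remove_rotation(field)
        d = decompose(rot.field, segment_beats(rot.field, p.frequency_hz))
        assert rot.rotation_rate_rad_s == pytest.approx(1.0, rel=0.05), L
        assert d.static_curvature_per_um == pytest.approx(0.2, rel=0.05), L
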