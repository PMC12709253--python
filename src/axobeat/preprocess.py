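"""Rotation removal, static/dynamic decomposition, and beat segmentation.

A curved axoneme swims in circles, so the lab-frame tangent angle carries a
slowly growing rigid-body rotation on top of the beat oscillation.  The
rotation is estimated as a LOESS trend of the (time-unwrapped) leading
tangent angle ψ(s=0, t) and subtracted from every arc-length position of
each frame.  The rotation-free field is then split into a static component
ψ̄(s) — the time average over complete beat cycles, a circular arc whose
slope is the static curvature C0 — and the dynamic residual
ψ_d(s, t) = ψ(s, t) − ψ̄(s), the propagating beat that the wavelength and
velocity estimators analyze.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.stats import linregress
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import InputDataError, ParameterError
from .geometry import TangentField

__all__ = [
    "RotationRemoval",
    "BeatSegmentation",
    "BeatDecomposition",
    "remove_rotation",
    "segment_beats",
    "decompose",
]


@dataclass
class RotationRemoval:
    """Rotation-subtracted field plus the trend that was removed."""

    field: TangentField
    trend_rad: np.ndarray  # LOESS trend of the leading angle, per frame
    rotation_rate_rad_s: float  # slope of the trend (interior fit)
    loess_frac: float


@dataclass
class BeatSegmentation:
    """Disjoint, ordered [start, end) frame windows, one per beat cycle."""

    beat_windows: list[tuple[int, int]]
    period_frames: int

    def __post_init__(self):
        if not self.beat_windows:
            raise InputDataError("no complete beat window in record")
        starts = [w[0] for w in self.beat_windows]
        ends = [w[1] for w in self.beat_windows]
        if any(e <= s for s, e in self.beat_windows) or sorted(starts) != starts:
            raise InputDataError("beat windows must be ordered and non-empty")
        if any(s2 < e1 for (_, e1), (s2, _) in zip(self.beat_windows, self.beat_windows[1:])):
            raise InputDataError("beat windows must be disjoint")

    @property
    def n_beats(self) -> int:
        return len(self.beat_windows)

    @property
    def n_complete_frames(self) -> int:
        return self.beat_windows[-1][1]


@dataclass
class BeatDecomposition:
    """Static profile ψ̄(s), dynamic residual ψ_d(s,t), and static curvature."""

    psi_static: np.ndarray  # (n_s,)
    psi_dynamic: TangentField  # same grids as the input field
    static_curvature_per_um: float
    rotation_trend: np.ndarray | None = None
    segmentation: BeatSegmentation | None = None
    meta: dict = dc_field(default_factory=dict)


def estimate_frequency_provisional(field: TangentField) -> float:
    """Coarse beat frequency from the leading tangent angle's periodogram.

    Used only to size the LOESS span and the beat windows; the final
    frequency is recomputed on the dynamic field with peak interpolation.
    """
    leading = np.unwrap(field.psi[0, :])
    leading = leading - np.polyval(np.polyfit(field.t_s, leading, 1), field.t_s)
    power = np.abs(np.fft.rfft(leading)) ** 2
    power[0] = 0.0
    k = int(np.argmax(power))
    if k == 0:
        raise InputDataError("no oscillation detected in leading tangent angle")
    return float(np.fft.rfftfreq(field.n_frames, field.dt_s)[k])


def remove_rotation(
    field: TangentField,
    loess_frac: float | None = None,
    periods_in_span: float = 5.0,
) -> RotationRemoval:
    """Subtract the rigid-body rotation trend from the tangent field.

    The leading angle ψ(0, t) is unwrapped in time (it grows without bound
    for a rotating swimmer), LOESS-smoothed, and the trend value at each
    frame is subtracted from ψ(s, t) at *all* s — a per-frame scalar shift,
    so curvature and the beat shape are untouched.

    Parameters
    ----------
    loess_frac : LOESS span as a fraction of the record; by default the
        fraction spanning ``periods_in_span`` beat periods, with the period
        taken from a provisional FFT of the leading angle.  The span must
        be wide relative to one beat so the oscillation averages out of the
        trend, but narrow relative to the record so slow rate drift passes.
    """
    if field.n_frames < 10:
        raise InputDataError("need at least 10 frames to estimate a rotation trend")
    t = field.t_s
    if np.ptp(t) <= 0:
        raise InputDataError("degenerate time grid (all frames simultaneous)")
    if loess_frac is None:
        f_prov = estimate_frequency_provisional(field)
        loess_frac = float(np.clip(periods_in_span / (f_prov * np.ptp(t)), 0.01, 1.0))
    elif not 0 < loess_frac <= 1:
        raise ParameterError("loess_frac", "must lie in (0, 1]")

    leading = np.unwrap(field.psi[0, :])
    trend = lowess(leading, t, frac=loess_frac, return_sorted=False)

    # rate from the interior of the trend; LOESS is biased at the boundaries
    lo, hi = int(0.1 * t.size), int(0.9 * t.size)
    rate = float(linregress(t[lo:hi], trend[lo:hi]).slope)

    out = TangentField(
        psi=field.psi - trend[None, :], s_um=field.s_um, t_s=field.t_s, meta=dict(field.meta)
    )
    return RotationRemoval(
        field=out, trend_rad=trend, rotation_rate_rad_s=rate, loess_frac=loess_frac
    )


def segment_beats(field: TangentField, frequency_hz: float) -> BeatSegmentation:
    """Partition frames into consecutive one-beat windows of round(1/(f·dt)) frames.

    The trailing partial window is discarded.
    """
    duration = field.dt_s * field.n_frames
    nyquist = 0.5 / field.dt_s
    if not (1.0 / duration < frequency_hz < nyquist):
        raise ParameterError(
            "frequency_hz", f"must lie in (1/duration, Nyquist) = ({1/duration:.3g}, {nyquist:.3g}) Hz"
        )
    period = int(round(1.0 / (frequency_hz * field.dt_s)))
    if period < 3:
        raise InputDataError(
            f"beat period of {period} frames is undersampled (need >= 3 frames per beat)"
        )
    n_beats = field.n_frames // period
    if n_beats < 1:
        raise InputDataError("record shorter than one beat period")
    return BeatSegmentation(
        beat_windows=[(i * period, (i + 1) * period) for i in range(n_beats)],
        period_frames=period,
    )


def decompose(
    field: TangentField,
    seg: BeatSegmentation,
    rotation_trend: np.ndarray | None = None,
) -> BeatDecomposition:
    """Split a rotation-free field into static and dynamic components.

    ψ̄(s) is the time average over complete beat windows only (a partial
    final cycle would bias it); ψ_d = ψ − ψ̄ so the reconstruction
    ψ̄ + ψ_d is exact by construction.  The static curvature is the
    ordinary-least-squares slope of ψ̄(s) against s.
    """
    if seg.n_complete_frames > field.n_frames:
        raise InputDataError("segmentation extends beyond the record")
    psi_static = field.psi[:, : seg.n_complete_frames].mean(axis=1)
    psi_dynamic = TangentField(
        psi=field.psi - psi_static[:, None],
        s_um=field.s_um,
        t_s=field.t_s,
        meta=dict(field.meta),
    )
    curv = float(linregress(field.s_um, psi_static).slope)
    return BeatDecomposition(
        psi_static=psi_static,
        psi_dynamic=psi_dynamic,
        static_curvature_per_um=curv,
        rotation_trend=rotation_trend,
        segmentation=seg,
    )
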