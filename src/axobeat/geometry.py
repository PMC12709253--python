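"""Cartesian centerlines and the arc-length / tangent-angle representation.

The central in-memory objects of the pipeline live here:

* :class:`CenterlineSeries` -- per-frame ordered midline coordinates (μm),
  leading (basal) point first, with frame timestamps.
* :class:`TangentField` -- the tangent angle ψ(s, t) on a regular
  arc-length × time grid, the representation every downstream estimator
  works on.  Curvature is ∂ψ/∂s; a circular arc has constant slope.

Conversion from coordinates to ψ(s, t) resamples each frame with a cubic
spline at a fixed arc-length spacing (0.218 μm by default, the effective
pixel size of the recordings this pipeline targets) and differentiates
centrally, so the tangent is second-order accurate including at the ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import InputDataError, ParameterError

__all__ = [
    "CenterlineSeries",
    "TangentField",
    "axoneme_length",
    "centerline_to_tangent_field",
]

#: frames whose arc length deviates from the median by more than this
#: fraction are flagged as probable tracking failures
LENGTH_DEVIATION_FLAG = 0.05


@dataclass
class CenterlineSeries:
    """Ordered (x, y) midline coordinates per frame, base first, in μm."""

    frames: list[np.ndarray]  # each (n_i, 2), ordered base -> tip
    times_s: np.ndarray  # (n_frames,)

    def __post_init__(self):
        if len(self.frames) == 0:
            raise InputDataError("CenterlineSeries needs at least one frame")
        self.times_s = np.asarray(self.times_s, dtype=float)
        if len(self.times_s) != len(self.frames):
            raise InputDataError("times_s length must match number of frames")
        self.frames = [np.atleast_2d(np.asarray(f, dtype=float)) for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.ndim != 2 or f.shape[1] != 2 or f.shape[0] < 2:
                raise InputDataError(f"frame {i}: need an (n>=2, 2) coordinate array")
            seg = np.linalg.norm(np.diff(f, axis=0), axis=1)
            if not np.all(seg > 0):
                raise InputDataError(f"frame {i}: consecutive points must be distinct")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def length_um(self) -> float:
        """Mean polyline arc length over frames."""
        return axoneme_length(self)


@dataclass
class TangentField:
    """Tangent angle ψ(s_i, t_j) in rad on regular arc-length and time grids."""

    psi: np.ndarray  # (n_s, n_t)
    s_um: np.ndarray  # (n_s,), regular spacing ds
    t_s: np.ndarray  # (n_t,), regular spacing dt
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=float)
        self.s_um = np.asarray(self.s_um, dtype=float)
        self.t_s = np.asarray(self.t_s, dtype=float)
        if self.psi.shape != (self.s_um.size, self.t_s.size):
            raise InputDataError(
                f"psi shape {self.psi.shape} does not match grids "
                f"({self.s_um.size}, {self.t_s.size})"
            )
        if not np.all(np.isfinite(self.psi)):
            raise InputDataError("psi contains non-finite values")
        for name, g in (("s_um", self.s_um), ("t_s", self.t_s)):
            if g.size >= 2:
                step = np.diff(g)
                if not np.all(step > 0) or not np.allclose(step, step[0], rtol=1e-6, atol=1e-12):
                    raise InputDataError(f"{name} grid must be regular and increasing")

    @property
    def ds_um(self) -> float:
        return float(self.s_um[1] - self.s_um[0])

    @property
    def dt_s(self) -> float:
        return float(self.t_s[1] - self.t_s[0])

    @property
    def n_frames(self) -> int:
        return self.t_s.size

    @property
    def length_um(self) -> float:
        """Arc-length extent of the gridded field."""
        return float(self.s_um[-1] - self.s_um[0])


def _polyline_length(xy: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))


def axoneme_length(series: CenterlineSeries) -> float:
    """Mean axoneme length L (μm): per-frame polyline arc length, averaged.

    Bending does not change arc length, so on a well-tracked record the
    per-frame lengths scatter tightly around L.
    """
    return float(np.mean([_polyline_length(f) for f in series.frames]))


def centerline_to_tangent_field(
    series: CenterlineSeries,
    ds_um: float = 0.218,
    min_points: int = 4,
    length_flag_frac: float = LENGTH_DEVIATION_FLAG,
) -> TangentField:
    """Convert a centerline series to the tangent-angle field ψ(s, t).

    Per frame: cumulative chordal arc length; cubic-spline resampling of
    x(s), y(s) onto a common regular grid spanning [0, L_min]; tangent
    angle from central differences (second-order one-sided at the ends),
    unwrapped along s.

    Parameters
    ----------
    ds_um : arc-length spacing of the output grid (μm); must be < L/4.
    min_points : frames with fewer tracked points are rejected with a warning.
    length_flag_frac : frames whose length deviates from the median by more
        than this fraction are flagged in ``meta['flagged_frames']`` as
        probable tracking failures (they are kept).

    Raises
    ------
    InputDataError : if every frame is rejected or ds_um is too coarse.
    """
    if ds_um <= 0:
        raise ParameterError("ds_um", "must be positive")

    kept, kept_times, lengths = [], [], []
    for i, xy in enumerate(series.frames):
        if xy.shape[0] < min_points:
            warnings.warn(f"frame {i} rejected: fewer than {min_points} points")
            continue
        kept.append(xy)
        kept_times.append(series.times_s[i])
        lengths.append(_polyline_length(xy))
    if not kept:
        raise InputDataError("all frames rejected (too few points per frame)")

    lengths = np.asarray(lengths)
    med = np.median(lengths)
    flagged = np.nonzero(np.abs(lengths - med) > length_flag_frac * med)[0]

    l_min = float(lengths.min())
    if ds_um >= l_min / 4:
        raise ParameterError("ds_um", f"must be smaller than L/4 = {l_min / 4:.3g} μm")
    n_s = int(np.floor(l_min / ds_um)) + 1
    s_grid = np.arange(n_s) * ds_um

    psi = np.empty((n_s, len(kept)))
    for j, xy in enumerate(kept):
        seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(seg)])
        sx = CubicSpline(arclen, xy[:, 0])
        sy = CubicSpline(arclen, xy[:, 1])
        x = sx(s_grid)
        y = sy(s_grid)
        dx = np.gradient(x, ds_um, edge_order=2)
        dy = np.gradient(y, ds_um, edge_order=2)
        psi[:, j] = np.unwrap(np.arctan2(dy, dx))

    return TangentField(
        psi=psi,
        s_um=s_grid,
        t_s=np.asarray(kept_times),
        meta={
            "flagged_frames": flagged.tolist(),
            "mean_length_um": float(lengths.mean()),
            "n_rejected": series.n_frames - len(kept),
        },
    )
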