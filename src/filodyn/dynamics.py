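"""Extent time series and piecewise-linear dynamic models.

A filopodium's extent at one frame is the Euclidean distance between its
tracked base and tip points.  Two kinetic descriptions are fitted to each
extent series:

* **triangle** — two phases (elongation, retraction).  The apex is the
  maximum observed extent; the feet sit one frame before the first and one
  frame after the last observation, at zero extent.  The side slopes are the
  elongation velocity ``Ve`` and retraction velocity ``Vr``.
* **trapezoid** — three phases (elongation, stationary, retraction).  The
  stationary phase is anchored at ``Es``, the extent at half lifetime, with
  slope ``Vs`` equal to the mean frame-to-frame velocity among stationary
  points (observed extents >= Es); the sides connect the feet to the
  stationary line at the first/last stationary point.

The label assigned to a filopodium is the model with the smaller RMSE over
the observed frames; the trapezoid, having more free vertices, must win by
a margin (see :data:`TRAPEZOID_RMSE_MARGIN`), and ties (including a
trapezoid that degenerates to the triangle) go to the simpler triangle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import FitError, NoExtensionError, TrackValidationError
from .track_io import AcquisitionMeta, FilopodiumTrack, PairedFrame, pair_frames

#: Absolute slack used when comparing model RMSEs; keeps degenerate
#: trapezoids (identical curve, different arithmetic path) on the triangle
#: side of the tie rule.
_RMSE_TIE_TOL = 1e-12

#: Fractional slack (relative to the observed maximum) below Es when
#: collecting stationary-phase points.  A strict ``extent >= Es`` cutoff sits
#: at an order statistic of the plateau: localization noise then reduces the
#: stationary set to the single noisiest plateau point and the trapezoid
#: degenerates to a triangle.  The slack is well below one elongation-phase
#: frame increment, so noiseless grid-aligned series are unaffected.
STATIONARY_TOLERANCE_FRACTION = 0.05

#: The trapezoid (3 phases, more free vertices) must beat the triangle's RMSE
#: by this factor to win; anything closer counts as a tie and the simpler
#: triangle is kept.  A plain argmin lets the extra trapezoid flexibility
#: soak up noise on genuinely triangular series.
TRAPEZOID_RMSE_MARGIN = 0.7


@dataclass
class ExtentSeries:
    """Time-ordered (t, E) samples for one filopodium."""

    times: np.ndarray
    extents: np.ndarray
    frame_interval: float
    touches_window_start: bool = False
    touches_window_end: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.extents = np.asarray(self.extents, dtype=float)
        if self.times.shape != self.extents.shape or self.times.ndim != 1:
            raise TrackValidationError("times and extents must be 1-D and equal length")
        if self.times.size == 0:
            raise TrackValidationError("empty extent series")
        if np.any(np.diff(self.times) <= 0):
            raise TrackValidationError("times must be strictly increasing")
        if np.any(self.extents < 0):
            raise TrackValidationError("extents must be non-negative")
        if self.frame_interval <= 0:
            raise TrackValidationError("frame_interval must be > 0")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class TriangleModel:
    """Two-phase model.  ``t_peak_first``/``t_peak_last`` coincide unless the
    observed maximum is a plateau, in which case the first peak defines the
    elongation slope and the last peak the retraction slope."""

    t_origin: float
    t_peak_first: float
    t_peak_last: float
    t_end: float
    Emax: float
    Ve: float
    Vr: float
    lifetime: float

    @property
    def t_peak(self) -> float:
        return self.t_peak_first

    def __post_init__(self) -> None:
        if not (self.t_origin < self.t_peak_first <= self.t_peak_last < self.t_end):
            raise FitError("triangle vertices out of order")
        if self.Ve <= 0 or self.Vr <= 0 or self.Emax <= 0:
            raise FitError("triangle model requires positive Emax, Ve, Vr")


@dataclass(frozen=True)
class TrapezoidModel:
    """Three-phase model with a stationary segment of slope ``Vs`` passing
    through (half-lifetime, ``Es``)."""

    t_origin: float
    t_s_start: float
    t_s_end: float
    t_end: float
    Es: float
    Vs: float
    Ve: float
    Vr: float
    lifetime: float

    @property
    def t_half(self) -> float:
        return 0.5 * (self.t_origin + self.t_end)

    def stationary_value(self, t: float) -> float:
        return self.Es + self.Vs * (t - self.t_half)

    def __post_init__(self) -> None:
        if not (self.t_origin < self.t_s_start <= self.t_s_end < self.t_end):
            raise FitError("trapezoid vertices out of order")
        if self.Es < 0:
            raise FitError("trapezoid requires Es >= 0")
        if self.Ve <= 0 or self.Vr <= 0:
            raise FitError("trapezoid model requires positive Ve and Vr")


@dataclass
class DynamicsFit:
    model_label: str  # "triangle" | "trapezoid"
    triangle: TriangleModel
    trapezoid: TrapezoidModel | None
    rmse_triangle: float
    rmse_trapezoid: float

    @property
    def winner(self) -> TriangleModel | TrapezoidModel:
        if self.model_label == "trapezoid" and self.trapezoid is not None:
            return self.trapezoid
        return self.triangle


@dataclass
class FilopodiumSummary:
    """Per-filopodium measurements: Emax, lifetime, model label, Ve, Vr.

    ``Ve``/``Vr`` are ``None`` when the corresponding phase was not observed
    (filopodium already extended at window start, or still present at window
    end)."""

    filopodium_id: int
    Emax: float
    lifetime: float
    model_label: str
    Ve: float | None
    Vr: float | None
    has_elongation: bool
    has_retraction: bool
    rmse_triangle: float
    rmse_trapezoid: float
    group_label: str = ""


def compute_extent_series(
    pairs: Sequence[PairedFrame], window: AcquisitionMeta
) -> ExtentSeries:
    """Extent E = sqrt((x_tip - x_base)^2 + (y_tip - y_base)^2) per frame."""
    if len(pairs) < 2:
        raise TrackValidationError("need at least 2 paired frames")
    times = np.array([p.t for p in pairs])
    extents = np.hypot(
        np.array([p.tip.x - p.base.x for p in pairs]),
        np.array([p.tip.y - p.base.y for p in pairs]),
    )
    return ExtentSeries(
        times=times,
        extents=extents,
        frame_interval=window.frame_interval_min,
        touches_window_start=pairs[0].base.frame == window.window_start_frame,
        touches_window_end=pairs[-1].base.frame == window.window_end_frame,
    )


def _feet(series: ExtentSeries) -> tuple[float, float]:
    """Origin and end: one frame before/after the observed data, extent 0."""
    return (
        float(series.times[0]) - series.frame_interval,
        float(series.times[-1]) + series.frame_interval,
    )


def fit_triangle(series: ExtentSeries) -> TriangleModel:
    extents = series.extents
    emax = float(extents.max())
    if emax <= 0:
        raise NoExtensionError("no extension: all extents are zero")
    t_origin, t_end = _feet(series)
    peaks = np.flatnonzero(extents == emax)
    t_first = float(series.times[peaks[0]])
    t_last = float(series.times[peaks[-1]])
    return TriangleModel(
        t_origin=t_origin,
        t_peak_first=t_first,
        t_peak_last=t_last,
        t_end=t_end,
        Emax=emax,
        Ve=emax / (t_first - t_origin),
        Vr=emax / (t_end - t_last),
        lifetime=t_end - t_origin,
    )


def fit_trapezoid(
    series: ExtentSeries,
    stationary_tolerance_fraction: float = STATIONARY_TOLERANCE_FRACTION,
) -> TrapezoidModel:
    times, extents = series.times, series.extents
    emax = float(extents.max())
    if emax <= 0:
        raise NoExtensionError("no extension: all extents are zero")
    t_origin, t_end = _feet(series)
    t_half = 0.5 * (t_origin + t_end)
    es = float(np.interp(t_half, times, extents))
    stationary = np.flatnonzero(extents >= es - stationary_tolerance_fraction * emax)
    i0, i1 = int(stationary[0]), int(stationary[-1])
    t_s_start = float(times[i0])
    t_s_end = float(times[i1])
    if i1 > i0:
        vs = float(np.mean(np.diff(extents[i0 : i1 + 1]) / np.diff(times[i0 : i1 + 1])))
    else:
        vs = 0.0
    y_start = es + vs * (t_s_start - t_half)
    y_end = es + vs * (t_s_end - t_half)
    if y_start <= 0 or y_end <= 0:
        raise FitError("degenerate trapezoid: stationary line reaches zero extent")
    return TrapezoidModel(
        t_origin=t_origin,
        t_s_start=t_s_start,
        t_s_end=t_s_end,
        t_end=t_end,
        Es=es,
        Vs=vs,
        Ve=y_start / (t_s_start - t_origin),
        Vr=y_end / (t_end - t_s_end),
        lifetime=t_end - t_origin,
    )


def model_curve(
    model: TriangleModel | TrapezoidModel, times: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Piecewise-linear model evaluation; 0 outside [t_origin, t_end]."""
    t = np.asarray(times, dtype=float)
    if isinstance(model, TriangleModel):
        if model.t_peak_first == model.t_peak_last:
            apex_t, apex_e = model.t_peak_first, model.Emax
        else:
            # plateau at Emax: the triangle's sides (slope Ve through the
            # first peak, slope -Vr through the last) meet above it
            apex_t = (model.Ve * model.t_origin + model.Vr * model.t_end) / (
                model.Ve + model.Vr
            )
            apex_e = model.Ve * (apex_t - model.t_origin)
        xs = [model.t_origin, apex_t, apex_t, model.t_end]
        ys = [0.0, apex_e, apex_e, 0.0]
    else:
        xs = [model.t_origin, model.t_s_start, model.t_s_end, model.t_end]
        ys = [
            0.0,
            model.stationary_value(model.t_s_start),
            model.stationary_value(model.t_s_end),
            0.0,
        ]
    # np.interp needs strictly increasing xp: collapse a zero-length apex.
    if xs[1] == xs[2]:
        xs = [xs[0], xs[1], xs[3]]
        ys = [ys[0], ys[1], ys[3]]
    return np.interp(t, xs, ys, left=0.0, right=0.0)


def _rmse(model: TriangleModel | TrapezoidModel, series: ExtentSeries) -> float:
    residuals = model_curve(model, series.times) - series.extents
    return float(np.sqrt(np.mean(residuals**2)))


def classify_dynamics(series: ExtentSeries) -> DynamicsFit:
    """Fit both models and label the series by the smaller RMSE.

    Ties go to the triangle.  A trapezoid fit that degenerates to an invalid
    model (stationary line reaching zero) also yields a triangle label, with
    ``rmse_trapezoid = nan``.
    """
    triangle = fit_triangle(series)
    rmse_tri = _rmse(triangle, series)
    try:
        trapezoid = fit_trapezoid(series)
    except FitError:
        return DynamicsFit("triangle", triangle, None, rmse_tri, math.nan)
    rmse_trap = _rmse(trapezoid, series)
    tol = _RMSE_TIE_TOL * max(1.0, triangle.Emax)
    label = "trapezoid" if rmse_trap < TRAPEZOID_RMSE_MARGIN * rmse_tri - tol else "triangle"
    return DynamicsFit(label, triangle, trapezoid, rmse_tri, rmse_trap)


def summarize_filopodium(
    track: FilopodiumTrack, window: AcquisitionMeta
) -> FilopodiumSummary:
    """Full per-filopodium summary with phase-presence bookkeeping.

    Elongation is only credited when the filopodium does not touch the start
    of the recording window AND its first observed extent lies below Emax
    (a filopodium born fully extended has no observable elongation phase);
    retraction requires not touching the window end.
    """
    pairs = pair_frames(track)
    series = compute_extent_series(pairs, window)
    fit = classify_dynamics(series)
    emax = float(series.extents.max())
    has_elongation = (not series.touches_window_start) and float(series.extents[0]) < emax
    has_retraction = not series.touches_window_end
    winner = fit.winner
    return FilopodiumSummary(
        filopodium_id=track.filopodium_id,
        Emax=emax,
        lifetime=winner.lifetime,
        model_label=fit.model_label,
        Ve=winner.Ve if has_elongation else None,
        Vr=winner.Vr if has_retraction else None,
        has_elongation=has_elongation,
        has_retraction=has_retraction,
        rmse_triangle=fit.rmse_triangle,
        rmse_trapezoid=fit.rmse_trapezoid,
        group_label=track.group_label,
    )
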