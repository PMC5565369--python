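"""Synthetic base/tip track cohorts with known ground-truth dynamics.

Tracks are built by sampling a triangle or trapezoid model on the frame grid:
the base follows a straight drift path, the tip sits at
``base + unit_direction * model(t) (+ Gaussian localization noise)``.  Model
vertices are snapped to the frame grid so that the fitting conventions
(origin/end one frame outside the data) recover generating parameters
exactly at zero noise.

Also provides a 1-D plateau-plus-exponential-decay intensity-profile
generator with a closed-form expression for the half-maximum domain width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import numpy as np

from .dynamics import TrapezoidModel, TriangleModel, model_curve
from .errors import ConfigError, UnobservableTrackError
from .gradient import IntensityProfile
from .track_io import AcquisitionMeta, FilopodiumTrack, TrackPoint

TRIANGLE = "triangle"
TRAPEZOID = "trapezoid"


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort generator parameters.

    Defaults mirror the acquisition setup the pipeline targets: 2-min frame
    interval, 30-min window, 49 x 76 µm region.  ``noise_fraction_of_emax``,
    when set, overrides ``noise_sigma_um`` with a per-track sigma scaled to
    that track's Emax.  ``allow_truncation=False`` restricts birth times so
    every track fits entirely inside the window.
    """

    n_tracks: int = 100
    p_trapezoid: float = 0.5
    emax_range: tuple[float, float] = (2.0, 8.0)
    lifetime_range: tuple[float, float] = (8.0, 26.0)
    plateau_fraction_range: tuple[float, float] = (0.2, 0.6)
    vs_range: tuple[float, float] = (0.0, 0.0)
    noise_sigma_um: float = 0.0
    noise_fraction_of_emax: float | None = None
    frame_interval_min: float = 2.0
    window_min: float = 30.0
    region_width_um: float = 49.0
    region_height_um: float = 76.0
    base_drift_um_per_min: float = 0.0
    allow_truncation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 0:
            raise ConfigError("n_tracks must be >= 0")
        if not 0.0 <= self.p_trapezoid <= 1.0:
            raise ConfigError("p_trapezoid must be in [0, 1]")
        for name in ("emax_range", "lifetime_range", "plateau_fraction_range", "vs_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} must be ordered (lo <= hi), got ({lo}, {hi})")
        if self.emax_range[0] <= 0:
            raise ConfigError("emax_range must be strictly positive")
        if self.noise_sigma_um < 0:
            raise ConfigError("noise_sigma_um must be >= 0")
        if self.frame_interval_min <= 0 or self.window_min <= 0:
            raise ConfigError("frame_interval_min and window_min must be > 0")
        n = self.window_min / self.frame_interval_min
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("window_min must be an integer multiple of frame_interval_min")

    @property
    def n_window_frames(self) -> int:
        """Grid positions 0..n inclusive span the window."""
        return int(round(self.window_min / self.frame_interval_min))

    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(
            frame_interval_min=self.frame_interval_min,
            window_min=self.window_min,
            region_width_um=self.region_width_um,
            region_height_um=self.region_height_um,
        )


@dataclass
class GroundTruthRecord:
    filopodium_id: int
    true_label: str
    true_Ve: float
    true_Vr: float
    true_Emax: float
    true_lifetime: float
    truncated_start: bool
    truncated_end: bool


def _sample_triangle(
    rng: np.random.Generator, config: GeneratorConfig, t_origin: float
) -> TriangleModel:
    dt = config.frame_interval_min
    lo = max(4, int(math.ceil(config.lifetime_range[0] / dt)))
    hi = max(lo, int(math.floor(config.lifetime_range[1] / dt)))
    n_life = int(rng.integers(lo, hi + 1))
    n_e = int(rng.integers(2, n_life - 1))  # >= 2 up phases, >= 2 down
    emax = float(rng.uniform(*config.emax_range))
    t_peak = t_origin + n_e * dt
    t_end = t_origin + n_life * dt
    return TriangleModel(
        t_origin=t_origin,
        t_peak_first=t_peak,
        t_peak_last=t_peak,
        t_end=t_end,
        Emax=emax,
        Ve=emax / (n_e * dt),
        Vr=emax / ((n_life - n_e) * dt),
        lifetime=n_life * dt,
    )


def _sample_trapezoid(
    rng: np.random.Generator, config: GeneratorConfig, t_origin: float
) -> TrapezoidModel:
    dt = config.frame_interval_min
    lo = max(6, int(math.ceil(config.lifetime_range[0] / dt)))
    hi = max(lo, int(math.floor(config.lifetime_range[1] / dt)))
    n_life = int(rng.integers(lo, hi + 1))
    frac = float(rng.uniform(*config.plateau_fraction_range))
    # n_p >= 2 gives >= 3 observed plateau points; with fewer, a trapezoid is
    # indistinguishable from a triangle whose apex falls between frames
    n_p = min(max(2, int(round(frac * n_life))), n_life - 4)
    m = n_life - n_p  # frames split between the two sloped phases
    # plateau must straddle the half lifetime: |n_e - n_r| <= n_p
    lo_e = max(2, int(math.ceil((m - n_p) / 2)))
    hi_e = min(m - 2, int(math.floor((m + n_p) / 2)))
    n_e = int(rng.integers(lo_e, hi_e + 1))
    n_r = m - n_e
    es = float(rng.uniform(*config.emax_range))
    vs = float(rng.uniform(*config.vs_range))
    t_s_start = t_origin + n_e * dt
    t_end = t_origin + n_life * dt
    t_s_end = t_end - n_r * dt
    t_half = 0.5 * (t_origin + t_end)
    y_start = es + vs * (t_s_start - t_half)
    y_end = es + vs * (t_s_end - t_half)
    if y_start <= 0 or y_end <= 0:
        raise ConfigError("vs_range too steep for the sampled plateau geometry")
    return TrapezoidModel(
        t_origin=t_origin,
        t_s_start=t_s_start,
        t_s_end=t_s_end,
        t_end=t_end,
        Es=es,
        Vs=vs,
        Ve=y_start / (n_e * dt),
        Vr=y_end / (n_r * dt),
        lifetime=n_life * dt,
    )


def _emitted_grid(model: TriangleModel | TrapezoidModel, config: GeneratorConfig) -> np.ndarray:
    """Frame-grid times inside both the window and the model's support."""
    dt = config.frame_interval_min
    grid = np.arange(config.n_window_frames + 1) * dt
    mask = (grid > model.t_origin + 1e-9) & (grid < model.t_end - 1e-9)
    return grid[mask]


def gen_track(
    model: TriangleModel | TrapezoidModel,
    config: GeneratorConfig,
    rng: np.random.Generator,
    filopodium_id: int = 1,
    group_label: str = "",
) -> tuple[FilopodiumTrack, GroundTruthRecord]:
    """Emit one synthetic track plus its ground truth.

    Raises :class:`UnobservableTrackError` when fewer than two positive-extent
    frames of the model fall inside the recording window.
    """
    dt = config.frame_interval_min
    times = _emitted_grid(model, config)
    if times.size < 2:
        raise UnobservableTrackError(
            f"model on [{model.t_origin}, {model.t_end}] min leaves "
            f"{times.size} observable frame(s) in the {config.window_min}-min window"
        )
    extents = model_curve(model, times)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    direction = np.array([math.cos(theta), math.sin(theta)])
    phi = rng.uniform(0.0, 2.0 * math.pi)
    drift = config.base_drift_um_per_min * np.array([math.cos(phi), math.sin(phi)])
    p0 = np.array(
        [
            rng.uniform(0.0, config.region_width_um),
            rng.uniform(0.0, config.region_height_um),
        ]
    )
    true_emax = float(extents.max())
    sigma = config.noise_sigma_um
    if config.noise_fraction_of_emax is not None:
        sigma = config.noise_fraction_of_emax * true_emax
    base_pts: list[TrackPoint] = []
    tip_pts: list[TrackPoint] = []
    for t, extent in zip(times, extents):
        frame = int(round(t / dt)) + 1
        base_xy = p0 + drift * t
        tip_xy = base_xy + direction * extent
        if sigma > 0:
            tip_xy = tip_xy + rng.normal(0.0, sigma, size=2)
        base_pts.append(TrackPoint(frame=frame, t=float(t), x=float(base_xy[0]), y=float(base_xy[1])))
        tip_pts.append(TrackPoint(frame=frame, t=float(t), x=float(tip_xy[0]), y=float(tip_xy[1])))
    track = FilopodiumTrack(
        filopodium_id=filopodium_id,
        base=base_pts,
        tip=tip_pts,
        frame_interval=dt,
        window_start_frame=1,
        window_end_frame=config.n_window_frames + 1,
        group_label=group_label,
    )
    record = GroundTruthRecord(
        filopodium_id=filopodium_id,
        true_label=TRIANGLE if isinstance(model, TriangleModel) else TRAPEZOID,
        true_Ve=model.Ve,
        true_Vr=model.Vr,
        true_Emax=true_emax,
        true_lifetime=model.lifetime,
        truncated_start=model.t_origin < 0,
        truncated_end=model.t_end > config.window_min,
    )
    return track, record


def _sample_birth(
    rng: np.random.Generator, config: GeneratorConfig, n_life: int
) -> float:
    dt = config.frame_interval_min
    n_w = config.n_window_frames
    if config.allow_truncation:
        offset = int(rng.integers(-n_life + 1, n_w))
    else:
        hi = max(0, n_w - n_life)
        offset = int(rng.integers(0, hi + 1))
    return offset * dt


def gen_cohort(
    config: GeneratorConfig, group_label: str = ""
) -> tuple[list[FilopodiumTrack], list[GroundTruthRecord]]:
    """Generate ``n_tracks`` tracks, labels ~ Bernoulli(p_trapezoid).

    Fully reproducible from ``config.seed``; birth times are redrawn (up to a
    bound) until a model leaves at least two observable frames.
    """
    rng = np.random.default_rng(config.seed)
    tracks: list[FilopodiumTrack] = []
    records: list[GroundTruthRecord] = []
    for fid in range(1, config.n_tracks + 1):
        label = TRAPEZOID if rng.random() < config.p_trapezoid else TRIANGLE
        for _attempt in range(1000):
            if label == TRAPEZOID:
                model = _sample_trapezoid(rng, config, 0.0)
            else:
                model = _sample_triangle(rng, config, 0.0)
            n_life = int(round(model.lifetime / config.frame_interval_min))
            t_origin = _sample_birth(rng, config, n_life)
            model = _shift_model(model, t_origin)
            try:
                track, record = gen_track(model, config, rng, fid, group_label)
            except UnobservableTrackError:
                continue
            break
        else:  # pragma: no cover - bound is generous
            raise ConfigError("could not place an observable track in 1000 attempts")
        tracks.append(track)
        records.append(record)
    return tracks, records


def _shift_model(
    model: TriangleModel | TrapezoidModel, t_origin: float
) -> TriangleModel | TrapezoidModel:
    delta = t_origin - model.t_origin
    if isinstance(model, TriangleModel):
        return TriangleModel(
            t_origin=model.t_origin + delta,
            t_peak_first=model.t_peak_first + delta,
            t_peak_last=model.t_peak_last + delta,
            t_end=model.t_end + delta,
            Emax=model.Emax,
            Ve=model.Ve,
            Vr=model.Vr,
            lifetime=model.lifetime,
        )
    return TrapezoidModel(
        t_origin=model.t_origin + delta,
        t_s_start=model.t_s_start + delta,
        t_s_end=model.t_s_end + delta,
        t_end=model.t_end + delta,
        Es=model.Es,
        Vs=model.Vs,
        Ve=model.Ve,
        Vr=model.Vr,
        lifetime=model.lifetime,
    )


def true_domain_width(
    plateau_len: float,
    decay_len: float,
    threshold_fraction: float = 0.5,
    amplitude: float = 1.0,
) -> float:
    """Closed-form width of the synthetic profile at a fractional threshold.

    The profile is ``amplitude`` over ``[0, plateau_len]`` followed by
    ``amplitude * exp(-(x - plateau_len)/decay_len)``, so the crossing of
    ``threshold_fraction * amplitude`` sits at
    ``plateau_len + decay_len * ln(1/threshold_fraction)``.
    """
    if amplitude <= 0:
        return 0.0
    if not 0 < threshold_fraction <= 1:
        raise ConfigError("threshold_fraction must be in (0, 1]")
    return plateau_len + decay_len * math.log(1.0 / threshold_fraction)


def gen_intensity_profile(
    plateau_len: float,
    decay_len: float,
    amplitude: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
    background: float = 0.0,
    spacing: float = 0.5,
    total_len: float | None = None,
    channel_label: str = "synthetic",
) -> IntensityProfile:
    """1-D profile: background + plateau + exponential decay (+ noise).

    ``total_len`` defaults to ``plateau_len + 30 * decay_len`` so the distal
    10% used for background estimation is effectively flat.
    """
    if plateau_len <= 0 or decay_len <= 0:
        raise ConfigError("plateau_len and decay_len must be > 0")
    if total_len is None:
        total_len = plateau_len + 30.0 * decay_len
    positions = np.arange(0.0, total_len + spacing / 2, spacing)
    signal = np.where(
        positions <= plateau_len,
        amplitude,
        amplitude * np.exp(-(positions - plateau_len) / decay_len),
    )
    intensities = background + signal
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensities = intensities + rng.normal(0.0, noise_sigma, size=positions.size)
    intensities = np.clip(intensities, 0.0, None)
    return IntensityProfile(
        positions=positions, intensities=intensities, channel_label=channel_label
    )
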