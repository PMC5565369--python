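import numpy as np
import pytest

from filodyn.dynamics import ExtentSeries, FilopodiumSummary
from filodyn.track_io import AcquisitionMeta, FilopodiumTrack, TrackPoint


@pytest.fixture
def meta():
    """Default acquisition: 2-min frames, 30-min window (frames 1..16)."""
    return AcquisitionMeta()


def make_track(
    base_xy, tip_xy, frames=None, frame_interval=2.0, window_end_frame=16,
    filopodium_id=1, group_label="",
):
    """Build a FilopodiumTrack from coordinate lists (one (x, y) per frame)."""
    if frames is None:
        frames = list(range(1, len(base_xy) + 1))
    base = [
        TrackPoint(frame=f, t=(f - 1) * frame_interval, x=float(x), y=float(y))
        for f, (x, y) in zip(frames, base_xy)
    ]
    tip = [
        TrackPoint(frame=f, t=(f - 1) * frame_interval, x=float(x), y=float(y))
        for f, (x, y) in zip(frames, tip_xy)
    ]
    return FilopodiumTrack(
        filopodium_id=filopodium_id,
        base=base,
        tip=tip,
        frame_interval=frame_interval,
        window_start_frame=1,
        window_end_frame=window_end_frame,
        group_label=group_label,
    )


def make_series(extents, frame_interval=2.0, t0=0.0, **flags):
    times = t0 + frame_interval * np.arange(len(extents))
    return ExtentSeries(
        times=times, extents=np.asarray(extents, dtype=float),
        frame_interval=frame_interval, **flags,
    )


def make_summary(
    filopodium_id=1, Emax=5.0, lifetime=12.0, model_label="triangle",
    Ve=1.0, Vr=1.0, has_elongation=True, has_retraction=True, group_label="",
):
    if not has_elongation:
        Ve = None
    if not has_retraction:
        Vr = None
    return FilopodiumSummary(
        filopodium_id=filopodium_id, Emax=Emax, lifetime=lifetime,
        model_label=model_label, Ve=Ve, Vr=Vr,
        has_elongation=has_elongation, has_retraction=has_retraction,
        rmse_triangle=0.0, rmse_trapezoid=0.0, group_label=group_label,
    )


MDF_EXAMPLE = """\
MTrackJ 1.5.1 Data File
Assembly 1 FF0000
Cluster 1 FF0000
Track 1 FF0000 true
Point 1 0.0 0.0 1.0 1.0 1.0
Point 2 0.0 0.0 1.0 2.0 1.0
Point 3 0.0 0.0 1.0 3.0 1.0
Track 2 FF0000 true
Point 1 3.0 4.0 1.0 1.0 1.0
Point 2 6.0 8.0 1.0 2.0 1.0
Point 3 3.0 4.0 1.0 3.0 1.0
End of MTrackJ Data File
"""


def write_mdf(tmp_path, text, name="tracks.mdf"):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path
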