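"""Wing-disc quantifications: longest-protrusion averages and expression
domain widths from 1-D intensity profiles along the A/P axis.

Positions are in µm with 0 at the compartment border, increasing into the
receiving territory.  The domain width is measured with a fractional
threshold between a distal background estimate and the profile maximum,
with sub-sample linear interpolation at the crossing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, NoDomainError, TrackValidationError


@dataclass
class ProtrusionLengthSet:
    """Protrusion lengths (µm, border to tip) measured in one disc."""

    disc_id: str
    lengths: np.ndarray
    group_label: str = ""

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.ndim != 1:
            raise TrackValidationError("lengths must be 1-D")
        if np.any(self.lengths < 0):
            raise TrackValidationError("lengths must be >= 0")


@dataclass
class IntensityProfile:
    positions: np.ndarray
    intensities: np.ndarray
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape or self.positions.ndim != 1:
            raise TrackValidationError("positions and intensities must be 1-D, equal length")
        if self.positions.size < 2:
            raise TrackValidationError("profile needs at least 2 samples")
        if np.any(np.diff(self.positions) <= 0):
            raise TrackValidationError("positions must be strictly increasing")
        if np.any(self.intensities < 0):
            raise TrackValidationError("intensities must be >= 0")


def top_k_mean_extent(lengths: ProtrusionLengthSet, k: int = 10) -> float:
    """Mean of the k largest protrusion lengths in one disc."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    n = lengths.lengths.size
    if n < k:
        raise ConfigError(
            f"disc {lengths.disc_id}: need {k} protrusion lengths, got {n} (short by {k - n})"
        )
    top = np.sort(lengths.lengths)[-k:]
    return float(top.mean())


def domain_width(profile: IntensityProfile, threshold_fraction: float = 0.5) -> float:
    """Distance from position 0 to the farthest threshold crossing.

    Background is the median intensity over the 10% most-distal samples;
    the threshold is ``background + threshold_fraction * (max - background)``.
    The width is invariant to affine intensity rescaling (uniform gain and
    offset).
    """
    if not 0 < threshold_fraction <= 1:
        raise ConfigError("threshold_fraction must be in (0, 1]")
    intensities = profile.intensities
    positions = profile.positions
    n_bg = max(1, int(round(0.1 * intensities.size)))
    background = float(np.median(intensities[-n_bg:]))
    peak = float(intensities.max())
    if peak <= background:
        raise NoDomainError("no domain: profile maximum does not exceed background")
    threshold = background + threshold_fraction * (peak - background)
    above = np.flatnonzero(intensities >= threshold)
    i = int(above[-1])
    if i == intensities.size - 1:
        return float(positions[i])
    # interpolate the crossing between the last above-threshold sample and
    # its (below-threshold) distal neighbour
    x0, x1 = positions[i], positions[i + 1]
    y0, y1 = intensities[i], intensities[i + 1]
    return float(x0 + (x1 - x0) * (y0 - threshold) / (y0 - y1))


def compare_domain_widths(groups: dict[str, list[float]]) -> pd.DataFrame:
    """Per-condition mean, sample SD (n-1 denominator) and n."""
    rows = []
    for label in groups:
        widths = np.asarray(groups[label], dtype=float)
        if widths.size < 1:
            raise ConfigError(f"condition {label!r}: need at least one width")
        sd = float(widths.std(ddof=1)) if widths.size > 1 else float("nan")
        rows.append(
            {
                "group_label": label,
                "n": int(widths.size),
                "mean_um": float(widths.mean()),
                "sd_um": sd,
            }
        )
    return pd.DataFrame(rows, columns=["group_label", "n", "mean_um", "sd_um"])


def read_length_sets(path: str | Path) -> list[ProtrusionLengthSet]:
    """CSV columns: disc_id, group_label, length_um."""
    df = pd.read_csv(path, dtype={"disc_id": str, "group_label": str})
    required = {"disc_id", "group_label", "length_um"}
    if not required.issubset(df.columns):
        raise ConfigError(f"{path}: expected columns {sorted(required)}")
    out = []
    for (disc_id, group), sub in df.groupby(["disc_id", "group_label"], sort=True):
        out.append(
            ProtrusionLengthSet(
                disc_id=str(disc_id),
                lengths=sub["length_um"].to_numpy(dtype=float),
                group_label=str(group),
            )
        )
    return out


def read_profiles(path: str | Path) -> list[IntensityProfile]:
    """CSV columns: channel_label, position_um, intensity."""
    df = pd.read_csv(path, dtype={"channel_label": str})
    required = {"channel_label", "position_um", "intensity"}
    if not required.issubset(df.columns):
        raise ConfigError(f"{path}: expected columns {sorted(required)}")
    if df.empty:
        raise ConfigError(f"{path}: no profile rows")
    out = []
    for label, sub in df.groupby("channel_label", sort=True):
        sub = sub.sort_values("position_um")
        out.append(
            IntensityProfile(
                positions=sub["position_um"].to_numpy(dtype=float),
                intensities=sub["intensity"].to_numpy(dtype=float),
                channel_label=str(label),
            )
        )
    return out
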