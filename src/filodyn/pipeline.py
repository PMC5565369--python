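"""End-to-end runs: analyze tracked cohorts, simulate synthetic cohorts,
quantify gradients.  All outputs are deterministic CSV files."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dynamics import FilopodiumSummary, summarize_filopodium
from .errors import (
    ConfigError,
    FilodynError,
    NoExtensionError,
    TrackTooShortError,
)
from .gradient import (
    compare_domain_widths,
    domain_width,
    read_length_sets,
    read_profiles,
    top_k_mean_extent,
)
from .stats import (
    VARIABLES,
    compare_cohorts,
    type_proportions,
)
from .synthetic import GeneratorConfig, GroundTruthRecord, gen_cohort
from .track_io import (
    AcquisitionMeta,
    FilopodiumTrack,
    read_csv_tracks,
    read_mdf,
    write_csv_tracks,
)

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "filopodium_id",
    "group_label",
    "Emax_um",
    "lifetime_min",
    "model_label",
    "Ve_um_per_min",
    "Vr_um_per_min",
    "has_elongation",
    "has_retraction",
    "rmse_triangle",
    "rmse_trapezoid",
]

COMPARISON_COLUMNS = [
    "variable",
    "group_a",
    "group_b",
    "n_a",
    "n_b",
    "mean_a",
    "mean_b",
    "median_a",
    "median_b",
    "shapiro_p_a",
    "shapiro_p_b",
    "mw_U",
    "mw_p",
    "stars",
]

GROUND_TRUTH_COLUMNS = [
    "filopodium_id",
    "true_label",
    "true_Ve",
    "true_Vr",
    "true_Emax",
    "true_lifetime",
    "truncated_start",
    "truncated_end",
]


@dataclass
class TrackInput:
    path: Path
    format: str = "csv"  # "csv" | "mdf"
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        if self.format not in ("csv", "mdf"):
            raise ConfigError(f"unknown track format {self.format!r}")


@dataclass
class RunConfig:
    inputs: list[TrackInput] = field(default_factory=list)
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    exclude_ids: tuple[int, ...] = ()
    group_a: str | None = None
    group_b: str | None = None
    out_dir: Path | None = None
    threshold_fraction: float = 0.5
    k: int = 10
    seed: int = 0


@dataclass
class AnalyzeResult:
    summaries: list[FilopodiumSummary]
    comparisons: pd.DataFrame
    proportions: pd.DataFrame
    n_accepted: int = 0
    n_rejected: int = 0
    n_excluded: int = 0  # too short / no extension

    @property
    def n_ve_eligible(self) -> int:
        return sum(1 for s in self.summaries if s.Ve is not None)

    @property
    def n_vr_eligible(self) -> int:
        return sum(1 for s in self.summaries if s.Vr is not None)


def summaries_frame(summaries: list[FilopodiumSummary]) -> pd.DataFrame:
    rows = [
        {
            "filopodium_id": s.filopodium_id,
            "group_label": s.group_label,
            "Emax_um": s.Emax,
            "lifetime_min": s.lifetime,
            "model_label": s.model_label,
            "Ve_um_per_min": s.Ve,
            "Vr_um_per_min": s.Vr,
            "has_elongation": s.has_elongation,
            "has_retraction": s.has_retraction,
            "rmse_triangle": s.rmse_triangle,
            "rmse_trapezoid": s.rmse_trapezoid,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n", na_rep="")


def load_tracks(config: RunConfig) -> tuple[list[FilopodiumTrack], int]:
    """Read every input file; returns (tracks, n_rejected_clusters)."""
    tracks: list[FilopodiumTrack] = []
    n_rejected = 0
    for inp in config.inputs:
        if inp.format == "mdf":
            result = read_mdf(
                inp.path, config.meta, group_label=inp.group_label or "", exclude_ids=config.exclude_ids
            )
            loaded = result.tracks
        else:
            result = read_csv_tracks(inp.path, config.meta, exclude_ids=config.exclude_ids)
            loaded = result.tracks
            if inp.group_label is not None:
                for t in loaded:
                    if not t.group_label:  # stored labels take precedence
                        t.group_label = inp.group_label
        n_rejected += len(result.rejected)
        for rej in result.rejected:
            logger.warning("%s: cluster %d rejected: %s", inp.path, rej.cluster_id, rej.reason)
        tracks.extend(loaded)
    return tracks, n_rejected


def run_analyze(config: RunConfig) -> AnalyzeResult:
    """Tracks -> per-filopodium summaries -> comparisons and proportions.

    Accounting: every input filopodium is counted exactly once as accepted,
    rejected (at read time) or excluded (too short / never extended)."""
    tracks, n_rejected = load_tracks(config)
    summaries: list[FilopodiumSummary] = []
    n_excluded = 0
    for track in tracks:
        try:
            summaries.append(summarize_filopodium(track, config.meta))
        except (TrackTooShortError, NoExtensionError) as exc:
            n_excluded += 1
            logger.warning("filopodium %d excluded: %s", track.filopodium_id, exc)
    groups = sorted({s.group_label for s in summaries})
    prop_rows = []
    for g in groups:
        tp = type_proportions([s for s in summaries if s.group_label == g], g)
        prop_rows.append(
            {
                "group_label": g,
                "n_triangle": tp.n_triangle,
                "n_trapezoid": tp.n_trapezoid,
                "pct_triangle": tp.pct_triangle,
                "pct_trapezoid": tp.pct_trapezoid,
            }
        )
    proportions = pd.DataFrame(
        prop_rows,
        columns=["group_label", "n_triangle", "n_trapezoid", "pct_triangle", "pct_trapezoid"],
    )
    comp_rows = []
    if config.group_a is not None and config.group_b is not None:
        group_a = [s for s in summaries if s.group_label == config.group_a]
        group_b = [s for s in summaries if s.group_label == config.group_b]
        if not group_a or not group_b:
            raise FilodynError(
                f"empty cohort for comparison: {config.group_a!r} (n={len(group_a)}) vs "
                f"{config.group_b!r} (n={len(group_b)})"
            )
        for variable in VARIABLES:
            try:
                c = compare_cohorts(group_a, group_b, variable, config.group_a, config.group_b)
            except FilodynError as exc:
                logger.warning("comparison skipped: %s", exc)
                continue
            comp_rows.append({col: getattr(c, col) for col in COMPARISON_COLUMNS})
    comparisons = pd.DataFrame(comp_rows, columns=COMPARISON_COLUMNS)
    result = AnalyzeResult(
        summaries=summaries,
        comparisons=comparisons,
        proportions=proportions,
        n_accepted=len(summaries),
        n_rejected=n_rejected,
        n_excluded=n_excluded,
    )
    logger.info(
        "analyze: %d accepted, %d rejected, %d excluded; Ve-eligible %d, Vr-eligible %d",
        result.n_accepted,
        n_rejected,
        n_excluded,
        result.n_ve_eligible,
        result.n_vr_eligible,
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_csv(summaries_frame(summaries), out / "summaries.csv")
        _write_csv(comparisons, out / "comparisons.csv")
        _write_csv(proportions, out / "type_proportions.csv")
    return result


def ground_truth_frame(records: list[GroundTruthRecord]) -> pd.DataFrame:
    rows = [
        {
            "filopodium_id": r.filopodium_id,
            "true_label": r.true_label,
            "true_Ve": r.true_Ve,
            "true_Vr": r.true_Vr,
            "true_Emax": r.true_Emax,
            "true_lifetime": r.true_lifetime,
            "truncated_start": r.truncated_start,
            "truncated_end": r.truncated_end,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)


def run_simulate(
    gen_config: GeneratorConfig,
    out_dir: str | Path,
    group_label: str = "synthetic",
    self_check: bool = False,
) -> dict:
    """Emit tracks.csv + ground_truth.csv; optionally re-analyze and report
    label-recovery accuracy."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracks, records = gen_cohort(gen_config, group_label=group_label)
    write_csv_tracks(tracks, out / "tracks.csv")
    _write_csv(ground_truth_frame(records), out / "ground_truth.csv")
    info: dict = {"n_tracks": len(tracks)}
    if self_check and tracks:
        config = RunConfig(
            inputs=[TrackInput(out / "tracks.csv", "csv")],
            meta=gen_config.meta(),
        )
        result = run_analyze(config)
        by_id = {r.filopodium_id: r for r in records}
        n_match = sum(
            1 for s in result.summaries if by_id[s.filopodium_id].true_label == s.model_label
        )
        info["classification_accuracy"] = n_match / len(result.summaries)
        info["n_ve_eligible"] = result.n_ve_eligible
        info["n_vr_eligible"] = result.n_vr_eligible
    return info


def run_gradient(
    lengths_path: str | Path | None,
    profiles_path: str | Path | None,
    out_dir: str | Path,
    k: int = 10,
    threshold_fraction: float = 0.5,
) -> dict:
    """Top-k protrusion means per disc + per-condition mean +/- SD, and
    domain widths per profile."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    info: dict = {}
    if lengths_path is not None:
        sets = read_length_sets(lengths_path)
        rows = []
        for s in sets:
            try:
                mean = top_k_mean_extent(s, k)
            except ConfigError as exc:
                logger.warning("disc skipped: %s", exc)
                continue
            rows.append(
                {
                    "disc_id": s.disc_id,
                    "group_label": s.group_label,
                    "n_lengths": int(s.lengths.size),
                    "top_k_mean_um": mean,
                }
            )
        per_disc = pd.DataFrame(
            rows, columns=["disc_id", "group_label", "n_lengths", "top_k_mean_um"]
        )
        _write_csv(per_disc, out / "topk_per_disc.csv")
        by_group: dict[str, list[float]] = {}
        for row in rows:
            by_group.setdefault(row["group_label"], []).append(row["top_k_mean_um"])
        condition = compare_domain_widths(by_group) if by_group else pd.DataFrame(
            columns=["group_label", "n", "mean_um", "sd_um"]
        )
        _write_csv(condition, out / "topk_by_condition.csv")
        info["n_discs"] = len(rows)
    if profiles_path is not None:
        profiles = read_profiles(profiles_path)
        rows = []
        for p in profiles:
            rows.append(
                {
                    "channel_label": p.channel_label,
                    "width_um": domain_width(p, threshold_fraction),
                }
            )
        widths = pd.DataFrame(rows, columns=["channel_label", "width_um"])
        _write_csv(widths, out / "domain_widths.csv")
        info["n_profiles"] = len(rows)
    return info
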