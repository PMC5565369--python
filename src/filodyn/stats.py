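"""Cohort statistics: normality testing, two-group nonparametric comparison
and dynamic-type proportions.

The two-group comparison is the standard two-sided Mann-Whitney-Wilcoxon
rank-sum location test: exact by enumeration for small tie-free samples
(n_a + n_b <= 14), otherwise the normal approximation with midrank tie
correction and continuity correction.  Shapiro-Wilk normality is reported
descriptively per group and does not gate the comparison.  Significance
stars follow p < 0.05 (*), < 0.01 (**), < 1e-3 (***), < 1e-4 (****).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .dynamics import FilopodiumSummary
from .errors import ConfigError, FilodynError

VARIABLES = ("Emax", "lifetime", "Ve", "Vr")

EXACT_MAX_TOTAL_N = 14

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass
class VariableSample:
    variable: str
    group_label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ConfigError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("values must be finite")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class CohortComparison:
    variable: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    shapiro_p_a: float
    shapiro_p_b: float
    mw_U: float
    mw_p: float
    stars: str


@dataclass
class TypeProportions:
    group_label: str
    n_triangle: int
    n_trapezoid: int

    @property
    def pct_triangle(self) -> float:
        total = self.n_triangle + self.n_trapezoid
        return 100.0 * self.n_triangle / total if total else 0.0

    @property
    def pct_trapezoid(self) -> float:
        total = self.n_triangle + self.n_trapezoid
        return 100.0 * self.n_trapezoid / total if total else 0.0


def stars_for_p(p: float) -> str:
    """Map a p-value onto the significance-star code. Pure function."""
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"p-value out of [0, 1]: {p}")
    for threshold, code in STAR_THRESHOLDS:
        if p < threshold:
            return code
    return "ns"


def shapiro_wilk(sample: VariableSample) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and approximate p (3 <= n <= 5000)."""
    if not 3 <= sample.n <= 5000:
        raise ConfigError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={sample.n}")
    res = sps.shapiro(sample.values)
    return float(res.statistic), float(res.pvalue)


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(a: VariableSample, b: VariableSample) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (statistic of sample *a*) and p-value.

    Exact null distribution when n_a + n_b <= 14 with no ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x, y = a.values, b.values
    if x.size < 1 or y.size < 1:
        raise ConfigError("both samples must be non-empty")
    exact = (x.size + y.size) <= EXACT_MAX_TOTAL_N and not _has_ties(x, y)
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def extract_variable(
    summaries: Iterable[FilopodiumSummary], variable: str, group_label: str = ""
) -> VariableSample:
    """Pool one variable across summaries; Ve/Vr only from filopodia whose
    corresponding phase was observed."""
    if variable not in VARIABLES:
        raise ConfigError(f"unknown variable {variable!r}; expected one of {VARIABLES}")
    values: list[float] = []
    for s in summaries:
        if variable == "Emax":
            values.append(s.Emax)
        elif variable == "lifetime":
            values.append(s.lifetime)
        elif variable == "Ve":
            if s.has_elongation and s.Ve is not None:
                values.append(s.Ve)
        elif s.has_retraction and s.Vr is not None:
            values.append(s.Vr)
    if not values:
        raise FilodynError(
            f"variable {variable!r}: no eligible filopodia in group {group_label!r}"
        )
    return VariableSample(variable=variable, group_label=group_label, values=np.array(values))


def compare_cohorts(
    summaries_a: Sequence[FilopodiumSummary],
    summaries_b: Sequence[FilopodiumSummary],
    variable: str,
    group_a: str = "A",
    group_b: str = "B",
) -> CohortComparison:
    """Descriptive statistics + Shapiro-Wilk per group + Mann-Whitney test."""
    sa = extract_variable(summaries_a, variable, group_a)
    sb = extract_variable(summaries_b, variable, group_b)
    sh_a = shapiro_wilk(sa)[1] if 3 <= sa.n <= 5000 else math.nan
    sh_b = shapiro_wilk(sb)[1] if 3 <= sb.n <= 5000 else math.nan
    u, p = mann_whitney_u(sa, sb)
    return CohortComparison(
        variable=variable,
        group_a=group_a,
        group_b=group_b,
        n_a=sa.n,
        n_b=sb.n,
        mean_a=float(sa.values.mean()),
        mean_b=float(sb.values.mean()),
        median_a=float(np.median(sa.values)),
        median_b=float(np.median(sb.values)),
        shapiro_p_a=sh_a,
        shapiro_p_b=sh_b,
        mw_U=u,
        mw_p=p,
        stars=stars_for_p(p),
    )


def type_proportions(
    summaries: Sequence[FilopodiumSummary], group_label: str | None = None
) -> TypeProportions:
    """Counts and percentages of triangle vs trapezoid labels."""
    summaries = list(summaries)
    if not summaries:
        raise ConfigError("need at least one summary")
    if group_label is None:
        group_label = summaries[0].group_label
    n_tri = sum(1 for s in summaries if s.model_label == "triangle")
    n_trap = sum(1 for s in summaries if s.model_label == "trapezoid")
    return TypeProportions(group_label=group_label, n_triangle=n_tri, n_trapezoid=n_trap)


def plot_violins(
    samples: Sequence[VariableSample],
    path: str,
    title: str = "",
) -> None:
    """Violin plot per group with a mean diamond and a median line.

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.6 * max(2, len(samples)), 4))
    data = [s.values for s in samples]
    positions = list(range(1, len(samples) + 1))
    ax.violinplot(data, positions=positions, showextrema=False)
    for pos, s in zip(positions, samples):
        ax.hlines(np.median(s.values), pos - 0.2, pos + 0.2, colors="black", lw=2)
        ax.scatter([pos], [s.values.mean()], marker="D", zorder=3)
    ax.set_xticks(positions)
    ax.set_xticklabels([s.group_label or s.variable for s in samples])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
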