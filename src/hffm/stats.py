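"""Group-level comparison of gait-cycle summary outcomes.

The statistical unit is the foot.  For every angle, the three outcomes
(cycle mean, maximum and range of motion) form one test family: a one-way
(equal-variance) ANOVA is run per (angle, outcome) and the raw p-value is
Bonferroni-adjusted by the family size 3 -- never across angles.  Pairwise
group contrasts are reported as Bonferroni-adjusted two-sample t-tests within
the same family.  Shapiro-Wilk normality checks are advisory only: the
analysis proceeds regardless of their outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateGeometryError

__all__ = [
    "OUTCOMES",
    "GroupedOutcomes",
    "anova_bonferroni",
    "shapiro_wilk_check",
    "pearson_correlation",
    "group_summary_table",
]

OUTCOMES = ("mean", "max", "rom")
_FAMILY = len(OUTCOMES)  # Bonferroni factor: the three outcomes per angle


@dataclass
class GroupedOutcomes:
    """Tidy per-foot summary outcomes.

    ``data`` columns: ``group``, ``foot``, ``angle``, ``mean``, ``max``,
    ``rom`` -- one row per foot per angle.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = {"group", "foot", "angle", *OUTCOMES}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if self.data["group"].nunique() < 2:
            raise ValueError("need at least two groups")
        counts = self.data.groupby(["group", "angle"])["foot"].nunique()
        if (counts < 3).any():
            raise ValueError("need at least three feet per group and angle")

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    @property
    def angles(self) -> list[str]:
        return sorted(self.data["angle"].unique())


@dataclass
class ComparisonTables:
    """ANOVA omnibus table plus Bonferroni-adjusted pairwise contrasts."""

    omnibus: pd.DataFrame
    pairwise: pd.DataFrame


def anova_bonferroni(g: GroupedOutcomes, alpha: float = 0.05) -> ComparisonTables:
    """One-way ANOVA per (angle, outcome) with within-family Bonferroni.

    Raises :class:`DegenerateGeometryError` if an (angle, outcome) cell has no
    variance in any group (the F statistic is undefined there).
    """
    rows, pair_rows = [], []
    groups = g.groups
    for angle in g.angles:
        sub = g.data[g.data["angle"] == angle]
        for outcome in OUTCOMES:
            samples = [
                sub.loc[sub["group"] == grp, outcome].to_numpy() for grp in groups
            ]
            if all(np.ptp(s) == 0 for s in samples):
                raise DegenerateGeometryError(
                    f"zero variance in every group for {angle}/{outcome}"
                )
            F, p = sps.f_oneway(*samples)
            p_adj = min(1.0, _FAMILY * float(p))
            rows.append({
                "angle": angle,
                "outcome": outcome,
                "F": float(F),
                "p_raw": float(p),
                "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
            })
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    t, pp = sps.ttest_ind(samples[i], samples[j])
                    pair_rows.append({
                        "angle": angle,
                        "outcome": outcome,
                        "group_a": groups[i],
                        "group_b": groups[j],
                        "t": float(t),
                        "p_raw": float(pp),
                        "p_bonferroni": min(1.0, _FAMILY * float(pp)),
                        "significant": min(1.0, _FAMILY * float(pp)) < alpha,
                    })
    return ComparisonTables(pd.DataFrame(rows), pd.DataFrame(pair_rows))


def shapiro_wilk_check(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value (advisory normality check)."""
    x = np.asarray(values, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateGeometryError("constant sample: normality test undefined")
    stat, p = sps.shapiro(x)
    return float(stat), float(p)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with two-sided p, e.g. kinematic vs radiographic angles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateGeometryError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def group_summary_table(g: GroupedOutcomes) -> pd.DataFrame:
    """Group mean +/- SD of each outcome per angle (the publication layout)."""
    rows = []
    for angle in g.angles:
        sub = g.data[g.data["angle"] == angle]
        for grp in g.groups:
            cell = sub[sub["group"] == grp]
            row = {"angle": angle, "group": grp, "n_feet": len(cell)}
            for outcome in OUTCOMES:
                row[outcome] = float(cell[outcome].mean())
                row[f"{outcome}_sd"] = float(cell[outcome].std(ddof=1))
            rows.append(row)
    return pd.DataFrame(rows)
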