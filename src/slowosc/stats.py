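"""Group-level statistics: independent-samples t-test, Pearson correlation,
and mean +/- SE summaries of metric tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import MetricTable

__all__ = ["ttest_independent", "pearson", "GroupSummary", "summarize"]


def ttest_independent(a, b) -> tuple[float, float]:
    """Classic pooled-variance two-sample Student t-test, two-sided.

    Degenerate case: zero pooled variance with equal means gives
    (t=0, p=1); zero pooled variance with unequal means is an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class GroupSummary:
    """Per-(group, age, area, metric) summaries and group contrasts."""

    cells: pd.DataFrame  # group, age, area, metric_name, n, mean, se
    contrasts: pd.DataFrame  # age, area, metric_name, group_a, group_b, t, p

    def __str__(self) -> str:
        return (
            "Group summaries (mean +/- SE):\n"
            + self.cells.to_string(index=False)
            + "\n\nGroup contrasts (Student t, independent samples; raw p, uncorrected):\n"
            + self.contrasts.to_string(index=False)
        )


def summarize(table: MetricTable, pool_areas: bool = True) -> GroupSummary:
    """Mean +/- SE per cell and pooled-area group contrasts.

    With ``pool_areas`` the contrast between two groups at each age
    enters every per-recording area value as an observation (an "all"
    area row), alongside per-area contrasts.
    """
    df = table.to_frame()
    if df.empty:
        raise ValueError("empty metric table")

    def _agg(frame: pd.DataFrame, area_label: str) -> pd.DataFrame:
        g = (
            frame.groupby(["group", "age", "metric_name"])["value"]
            .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
            .reset_index()
        )
        g["se"] = g["sd"] / np.sqrt(g["n"])
        g["area"] = area_label
        return g.drop(columns="sd")

    pieces = [
        _agg(sub, area) for area, sub in df.groupby("area")
    ]
    if pool_areas:
        pieces.append(_agg(df, "all"))
    cells = pd.concat(pieces, ignore_index=True)[
        ["group", "age", "area", "metric_name", "n", "mean", "se"]
    ]

    rows = []
    scopes = list(df.groupby(["age", "area", "metric_name"]))
    if pool_areas:
        pooled = df.assign(area="all")
        scopes += list(pooled.groupby(["age", "area", "metric_name"]))
    for (age, area, metric), sub in scopes:
        groups = sorted(sub["group"].unique())
        if len(groups) != 2:
            continue
        va = sub.loc[sub["group"] == groups[0], "value"].to_numpy()
        vb = sub.loc[sub["group"] == groups[1], "value"].to_numpy()
        if va.size < 2 or vb.size < 2:
            continue
        try:
            t, p = ttest_independent(va, vb)
        except ValueError:
            continue
        rows.append(
            {
                "age": age,
                "area": area,
                "metric_name": metric,
                "group_a": groups[0],
                "group_b": groups[1],
                "t": t,
                "p": p,
            }
        )
    contrasts = pd.DataFrame(
        rows, columns=["age", "area", "metric_name", "group_a", "group_b", "t", "p"]
    )
    return GroupSummary(cells=cells, contrasts=contrasts)
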