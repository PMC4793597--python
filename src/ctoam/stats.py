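"""Bilateral and between-subject comparisons of maxima locations and MAR.

Left-vs-right differences are tested per measure and view with the
equal-variance two-sample Student's t-test; between-subject differences with
one-way ANOVA followed, when the omnibus test is significant at alpha =
0.05, by Bonferroni-adjusted all-pairs t-tests.  Grid coordinates are
analysed per axis (x and y separately).  Summaries are reported as
"mean (SD)" with the sample (n-1) standard deviation.

Input records are plain mappings or a DataFrame with columns ``subject``,
``side``, ``view`` and the measures (``grid_x``, ``grid_y``, ``mar``,
``total_pixels``, ``max_pixels`` — whichever are present are analysed).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
MEASURES = ("grid_x", "grid_y", "mar", "total_pixels", "max_pixels")

UNDEFINED_NOTE = "no difference, test undefined (zero variance, equal means)"


@dataclass
class ComparisonReport:
    """Tidy table of test results plus the significance level used."""

    grouping: str            # "side" or "subject"
    table: pd.DataFrame      # one row per view x measure (+ pairwise rows)
    alpha: float = ALPHA

    def __str__(self) -> str:
        return f"Comparison by {self.grouping} (alpha={self.alpha}):\n{self.table.to_string(index=False)}"


def _as_frame(results) -> pd.DataFrame:
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(list(results))
    if df.empty:
        raise ValueError("no records to analyse")
    return df


def _present_measures(df: pd.DataFrame) -> list[str]:
    cols = [m for m in MEASURES if m in df.columns]
    if not cols:
        raise ValueError(f"records contain none of the measures {MEASURES}")
    return cols


def students_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    """Equal-variance two-sample t-test; returns (t, p, note).

    When both groups have zero variance and equal means the statistic is
    undefined (0/0); that degenerate case is reported as a note with NaN
    statistics rather than a numeric p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return (np.nan, np.nan, UNDEFINED_NOTE)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return (float(t), float(p), "")


def oneway_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA omnibus F and p over two or more groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    f, p = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return (float(f), float(p))


def bonferroni(p_values: np.ndarray) -> np.ndarray:
    """Bonferroni family-wise adjustment: p * m, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * p.size, 1.0)


def compare_sides(results) -> ComparisonReport:
    """Left vs right, per view and measure, with Student's t-test."""
    df = _as_frame(results)
    rows = []
    for view, sub in df.groupby("view", sort=True):
        left = sub[sub["side"] == "left"]
        right = sub[sub["side"] == "right"]
        if len(left) < 2 or len(right) < 2:
            raise ValueError(f"need >= 2 records per side in view {view!r}")
        for measure in _present_measures(df):
            t, p, note = students_t(left[measure].to_numpy(), right[measure].to_numpy())
            rows.append(
                {
                    "view": view,
                    "measure": measure,
                    "test": "t",
                    "statistic": t,
                    "p_value": p,
                    "significant": bool(p < ALPHA) if np.isfinite(p) else False,
                    "note": note,
                }
            )
    return ComparisonReport("side", pd.DataFrame(rows))


def compare_subjects(results) -> ComparisonReport:
    """Between-subject one-way ANOVA with Bonferroni post-hoc pairs.

    Subjects contributing a single observation are excluded with a warning.
    Pairwise Bonferroni-adjusted t-tests are added only when the omnibus
    test is significant at alpha.
    """
    df = _as_frame(results)
    counts = df.groupby("subject").size()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        warnings.warn(
            f"excluding subjects with a single observation: {singletons}", stacklevel=2
        )
        df = df[~df["subject"].isin(singletons)]
    if df["subject"].nunique() < 2:
        raise ValueError("need at least two subjects with >= 2 observations")
    rows = []
    for view, sub in df.groupby("view", sort=True):
        subjects = sorted(sub["subject"].unique())
        for measure in _present_measures(df):
            groups = [sub.loc[sub["subject"] == s, measure].to_numpy() for s in subjects]
            f, p = oneway_anova(groups)
            rows.append(
                {
                    "view": view,
                    "measure": measure,
                    "test": "anova",
                    "comparison": "omnibus",
                    "statistic": f,
                    "p_value": p,
                    "p_adjusted": np.nan,
                    "significant": bool(p < ALPHA),
                    "note": "",
                }
            )
            if p < ALPHA:
                pairs = list(itertools.combinations(range(len(subjects)), 2))
                raw, raw_t = [], {}
                for i, j in pairs:
                    t, pp, note = students_t(groups[i], groups[j])
                    raw.append(pp)
                    raw_t[(i, j)] = t
                adj = bonferroni(np.array(raw))
                for (i, j), pr, pa in zip(pairs, raw, adj):
                    rows.append(
                        {
                            "view": view,
                            "measure": measure,
                            "test": "t",
                            "comparison": f"{subjects[i]} vs {subjects[j]}",
                            "statistic": raw_t[(i, j)],
                            "p_value": pr,
                            "p_adjusted": pa,
                            "significant": bool(pa < ALPHA),
                            "note": "bonferroni",
                        }
                    )
    return ComparisonReport("subject", pd.DataFrame(rows))


def summarise(results, decimals: int = 1) -> pd.DataFrame:
    """Per side x view summary of each measure, formatted "mean (SD)".

    SD is the sample (n-1) standard deviation; a single record yields SD 0.
    Empty side/view cells are omitted with a warning.
    """
    df = _as_frame(results)
    measures = _present_measures(df)
    sides = sorted(df["side"].unique())
    views = sorted(df["view"].unique())
    rows = []
    for view in views:
        for side in sides:
            cell = df[(df["view"] == view) & (df["side"] == side)]
            if cell.empty:
                warnings.warn(f"no records for side={side!r}, view={view!r}; row omitted",
                              stacklevel=2)
                continue
            row = {"view": view, "side": side, "n": len(cell)}
            for m in measures:
                vals = cell[m].to_numpy(dtype=float)
                sd = vals.std(ddof=1) if vals.size > 1 else 0.0
                row[m] = f"{vals.mean():.{decimals}f} ({sd:.{decimals}f})"
            rows.append(row)
    return pd.DataFrame(rows)
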