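"""Cohort assembly and group comparison.

Per-capsule summary rows (spontaneous fraction, single-cell kinetics,
activation/deactivation speeds, grouping slopes, network metrics) are
compared between labeled groups with one-way ANOVA, Bonferroni-corrected
within a comparison family, at significance level P <= 0.05.  A
cell-level comparison of spontaneously active vs inactive cells uses
per-capsule-normalized activation/deactivation times so capsules with
different absolute kinetics remain comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "one_way_anova",
    "bonferroni",
    "per_cell_normalized_comparison",
    "run_full_comparison",
    "cohort_table",
]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    variable: str
    groups: tuple[str, ...]
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    p_adjusted: float = math.nan
    significant: bool | None = None

    def adjust(self, m: int, alpha: float = ALPHA) -> "ComparisonResult":
        self.p_adjusted = min(1.0, m * self.p_value)
        self.significant = self.p_adjusted <= alpha
        return self


def one_way_anova(groups: Sequence[Sequence[float]],
                  group_names: Sequence[str] | None = None,
                  variable: str = "") -> ComparisonResult:
    """Classic one-way fixed-effects ANOVA.

    Degenerate inputs where both the between- and within-group variance
    vanish (all values identical) give F = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs >= 2 values")
    names = tuple(group_names) if group_names else \
        tuple(f"g{k}" for k in range(len(arrays)))
    k = len(arrays)
    n = sum(a.size for a in arrays)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return ComparisonResult(variable, names, 0.0, k - 1, n - k, 1.0)
    f, p = stats.f_oneway(*arrays)
    return ComparisonResult(variable, names, float(f), k - 1, n - k, float(p))


def bonferroni(p_values: Sequence[float],
               alpha: float = ALPHA) -> tuple[list[float], list[bool]]:
    """p_adj = min(1, m * p) for a family of m comparisons."""
    m = len(p_values)
    adj = [min(1.0, m * float(p)) for p in p_values]
    return adj, [a <= alpha for a in adj]


def adjust_family(results: list[ComparisonResult],
                  alpha: float = ALPHA) -> list[ComparisonResult]:
    """Bonferroni-adjust a family of comparisons in place."""
    m = len(results)
    for r in results:
        r.adjust(m, alpha)
    return results


def per_cell_normalized_comparison(events_by_capsule: dict[str, pd.DataFrame],
                                   column: str = "dt_act") -> ComparisonResult:
    """Spontaneous vs non-spontaneous cells on capsule-normalized times.

    Each responder's value is divided by its capsule's mean before
    pooling; capsules without any spontaneously active cell are excluded.
    """
    spont_vals, other_vals = [], []
    for cap_id, df in events_by_capsule.items():
        resp = df[df["is_responder"] & np.isfinite(df[column])]
        if resp.empty or not resp["is_spontaneous"].any() \
                or resp["is_spontaneous"].all():
            continue
        norm = resp[column] / resp[column].mean()
        spont_vals.extend(norm[resp["is_spontaneous"]])
        other_vals.extend(norm[~resp["is_spontaneous"]])
    if len(spont_vals) < 2 or len(other_vals) < 2:
        raise ValueError("no qualifying capsules for the spontaneous comparison")
    res = one_way_anova([spont_vals, other_vals],
                        ("spontaneous", "non_spontaneous"),
                        variable=f"{column}_normalized")
    return res.adjust(1)


def cohort_table(rows: list[dict]) -> pd.DataFrame:
    """Per-capsule summary rows -> CohortTable (one row per capsule)."""
    df = pd.DataFrame(rows)
    if df["capsule_id"].duplicated().any():
        raise ValueError("duplicate capsule_id in cohort table")
    return df


def run_full_comparison(table: pd.DataFrame,
                        variables: Sequence[str],
                        group_column: str = "group",
                        contrast: tuple[str, str] | None = None,
                        alpha: float = ALPHA) -> list[ComparisonResult]:
    """One ANOVA per variable for a two-group contrast, one Bonferroni family.

    ``contrast`` selects the two group labels (defaults to all labels
    present, which must then number two or more).
    """
    labels = list(contrast) if contrast else sorted(table[group_column].unique())
    missing = set(labels) - set(table[group_column].unique())
    if missing:
        raise ValueError(f"unknown group labels: {sorted(missing)}")
    results = []
    for var in variables:
        groups, names = [], []
        for lab in labels:
            vals = table.loc[table[group_column] == lab, var].dropna()
            groups.append(vals.to_numpy())
            names.append(str(lab))
        results.append(one_way_anova(groups, names, variable=var))
    return adjust_family(results, alpha)


def comparison_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variable": r.variable,
        "contrast": " vs ".join(r.groups),
        "F": r.f_stat,
        "df1": r.df_between,
        "df2": r.df_within,
        "p": r.p_value,
        "p_adj": r.p_adjusted,
        "significant": r.significant,
    } for r in results])
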