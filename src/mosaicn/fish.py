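"""Chromosome-21 aneusomy statistics from dual point-paint FISH counts.

Each nucleus is scored by spot count into monosomy / disomy / trisomy /
tetrasomy classes (dual labeling with a whole-q-arm paint and a regional
point probe; counting itself is upstream of this module). Counts arrive
per brain and per observer; rates are averaged across observers within a
brain, and groups (diseased vs non-diseased) are compared per class with
an unpaired two-tailed t-test on per-brain rates — matching brain-level
error bars — with a pooled chi-squared reported as a secondary check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ANEUSOMY_CLASSES", "aneusomy_rates", "group_rate_summary", "compare_aneusomy"]

ANEUSOMY_CLASSES = ["monosomy", "disomy", "trisomy", "tetrasomy"]


def aneusomy_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Per-brain class rates, averaged over observers.

    Input columns: brain_id, group, observer_id, monosomy, disomy,
    trisomy, tetrasomy, n_nuclei; class counts must sum to n_nuclei for
    every row. Any number of observers per brain is accepted. Returns one
    row per brain with per-class rate columns (summing to 1), the group
    label, and the total nuclei counted across observers.
    """
    required = {"brain_id", "group", "observer_id", "n_nuclei", *ANEUSOMY_CLASSES}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    sums = table[ANEUSOMY_CLASSES].sum(axis=1)
    bad = table.loc[sums != table["n_nuclei"]]
    if not bad.empty:
        raise ValueError(
            f"class counts do not sum to n_nuclei for rows {bad.index.tolist()}"
        )
    rows = []
    for brain, sub in table.groupby("brain_id", sort=True):
        per_observer = sub[ANEUSOMY_CLASSES].div(sub["n_nuclei"], axis=0)
        rates = per_observer.mean(axis=0)
        rows.append({
            "brain_id": brain,
            "group": sub["group"].iloc[0],
            **{c: float(rates[c]) for c in ANEUSOMY_CLASSES},
            "n_nuclei_total": int(sub["n_nuclei"].sum()),
            "n_observers": int(sub["observer_id"].nunique()),
        })
    return pd.DataFrame(rows)


def group_rate_summary(rates: pd.DataFrame) -> pd.DataFrame:
    """Group mean rate and SEM per aneusomy class from per-brain rates."""
    rows = []
    for group, sub in rates.groupby("group", sort=True):
        for cls in ANEUSOMY_CLASSES:
            v = sub[cls].to_numpy(dtype=float)
            rows.append({
                "group": group, "class": cls, "n_brains": int(v.size),
                "mean_rate": float(np.mean(v)),
                "sem": float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan"),
            })
    return pd.DataFrame(rows)


def compare_aneusomy(
    rates: pd.DataFrame,
    counts: pd.DataFrame | None = None,
) -> dict:
    """Two-group comparison of aneusomy rates, class by class.

    Primary: unpaired two-tailed t-test on per-brain rates. Secondary,
    when the raw count table is supplied: chi-squared on pooled counts
    per class (class vs rest, group x status contingency). A group with a
    single brain yields NaN p-values with a warning rather than an error.
    """
    groups = sorted(rates["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"exactly 2 groups required, got {groups}")
    ga = rates[rates["group"] == groups[0]]
    gb = rates[rates["group"] == groups[1]]
    out: dict = {"groups": groups, "per_class": {}}
    degenerate = len(ga) < 2 or len(gb) < 2
    if degenerate:
        import warnings

        warnings.warn("a group has a single brain; t-tests reported as NaN", stacklevel=2)
    for cls in ANEUSOMY_CLASSES:
        entry: dict = {}
        if degenerate:
            entry["t_stat"], entry["p_value"] = float("nan"), float("nan")
        else:
            a = ga[cls].to_numpy(dtype=float)
            b = gb[cls].to_numpy(dtype=float)
            if np.ptp(np.concatenate([a, b])) == 0:
                entry["t_stat"], entry["p_value"] = float("nan"), 1.0
            else:
                t, p = stats.ttest_ind(a, b, equal_var=True)
                entry["t_stat"], entry["p_value"] = float(t), float(p)
        if counts is not None:
            pooled = counts.groupby("group")[[cls, "n_nuclei"]].sum()
            tabs = np.array([
                [pooled.loc[g, cls], pooled.loc[g, "n_nuclei"] - pooled.loc[g, cls]]
                for g in groups
            ])
            if (tabs.sum(axis=0) > 0).all():
                chi2, p_chi, _, _ = stats.chi2_contingency(tabs)
                entry["chi2"], entry["chi2_p"] = float(chi2), float(p_chi)
            else:
                entry["chi2"], entry["chi2_p"] = float("nan"), float("nan")
        out["per_class"][cls] = entry
    return out
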