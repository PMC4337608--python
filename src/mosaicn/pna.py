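"""PNA-FISH quantification: dot-blot linearity and puncta thresholding.

Pooled peptide-nucleic-acid probes against multiple sites of one locus
produce a punctate nuclear signal only when local copy number exceeds a
detection threshold. Two quantitative steps are covered:

* dot-blot validation that fluorescence rises linearly with the number
  of probe binding sites (and with template amount);
* per-nucleus intensity thresholding into positive / negative with
  per-group positive fractions.

Exclusion rules applied before thresholding: nuclei lacking a telomere
control signal are dropped (hybridization failure), and lipofuscin-
flagged puncta — autofluorescent age pigment lighting up in every
channel — are excluded from quantification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "dotblot_linearity",
    "apply_exclusions",
    "nucleus_intensity",
    "positive_fraction",
    "compare_positive_fractions",
]


def dotblot_linearity(
    copies,
    intensities,
    r_squared_threshold: float = 0.95,
) -> dict:
    """Least-squares fit of blot intensity against probe binding sites.

    Requires >= 3 distinct copy levels (e.g. 0, 3, 6, 9 sites). The
    intercept estimates channel background. Returns the fit and a
    ``linear`` flag (R^2 above threshold).
    """
    x = np.asarray(copies, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("linearity check requires >= 3 distinct copy levels")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue) ** 2
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": r2,
        "linear": bool(r2 >= r_squared_threshold),
    }


def apply_exclusions(records: pd.DataFrame) -> pd.DataFrame:
    """Drop hybridization failures and lipofuscin artifacts.

    Nuclei with ``telomere_present == False`` are excluded entirely;
    rows flagged ``lipofuscin`` are excluded from intensity
    quantification. Idempotent and order-independent.
    """
    out = records
    if "telomere_present" in out.columns:
        out = out[out["telomere_present"].astype(bool)]
    if "lipofuscin" in out.columns:
        out = out[~out["lipofuscin"].astype(bool)]
    return out


def nucleus_intensity(records: pd.DataFrame) -> pd.Series:
    """Per-nucleus intensity: max over its non-excluded puncta.

    Nuclei typically carry 0-2 puncta; the brightest punctum represents
    the nucleus in threshold calls.
    """
    clean = apply_exclusions(records)
    return clean.groupby("unit_id")["intensity"].max()


def positive_fraction(
    records: pd.DataFrame,
    threshold: float | str = "auto",
    control_quantile: float = 1.0,
) -> pd.DataFrame:
    """Per-group fraction of nuclei with signal at or above threshold.

    ``threshold="auto"`` sets the detection limit from designated
    negative-control records (``is_negative_control`` column): the
    ``control_quantile`` of their per-nucleus intensities, default the
    maximum. Returns one row per group with n_positive, n_total,
    fraction.
    """
    clean = apply_exclusions(records)
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"unknown threshold spec {threshold!r}")
        if "is_negative_control" not in clean.columns:
            raise ValueError('"auto" threshold needs an is_negative_control column')
        ctrl = clean[clean["is_negative_control"].astype(bool)]
        if ctrl.empty:
            raise ValueError('"auto" threshold needs negative-control records')
        ctrl_int = ctrl.groupby("unit_id")["intensity"].max()
        thr = float(np.quantile(ctrl_int.to_numpy(), control_quantile))
    else:
        thr = float(threshold)
    if "is_negative_control" in clean.columns:
        clean = clean[~clean["is_negative_control"].astype(bool)]
    rows = []
    for group, sub in clean.groupby("group", sort=True):
        per_nucleus = sub.groupby("unit_id")["intensity"].max()
        n_pos = int((per_nucleus >= thr).sum())
        n_tot = int(per_nucleus.size)
        rows.append({
            "group": group, "n_positive": n_pos, "n_total": n_tot,
            "fraction": n_pos / n_tot if n_tot else float("nan"),
            "threshold": thr,
        })
    return pd.DataFrame(rows)


def compare_positive_fractions(fractions: pd.DataFrame) -> dict:
    """Pairwise two-proportion z-tests between group positive fractions."""
    out = {}
    recs = fractions.to_dict("records")
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            p_pool = (a["n_positive"] + b["n_positive"]) / (a["n_total"] + b["n_total"])
            se = np.sqrt(p_pool * (1 - p_pool) * (1 / a["n_total"] + 1 / b["n_total"]))
            if se == 0:
                z, p = float("nan"), 1.0
            else:
                z = (a["fraction"] - b["fraction"]) / se
                p = float(2 * stats.norm.sf(abs(z)))
            out[f"{a['group']} vs {b['group']}"] = {"z": float(z), "p_value": p}
    return out
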