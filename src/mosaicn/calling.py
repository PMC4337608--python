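"""Copy-number bin calling from RCN confidence intervals.

A modeled acceptance interval is built for every integer copy number
k = 1..6 by propagating the system CI through the RCN formula:

    lower(k) = k * 2**(-CI_log),   upper(k) = k * 2**(+CI_log),
    CI_log   = t_crit(df) * system_sd / sqrt(n_reps)

(for base efficiency E = 1 the modeled RCN of k copies is exactly k, and
the bounds scale multiplicatively in k). Under the defaults — SD 0.25,
18 replicates, df 68 — consecutive intervals are disjoint up to k = 6 and
first overlap at 6 vs 7, which is why calls are reported as bins 1-6 plus
a single ">6" class.

A nucleus is assigned the bin whose modeled interval its RCN confidence
interval overlaps. CIs overlapping two intervals, or falling in the gap
between intervals, are resolved to the nearest k on the log2 scale and
flagged (``ambiguous`` / ``gap_assigned``) rather than dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qpcr import (
    DEFAULT_ALPHA,
    DEFAULT_DF,
    DEFAULT_NOMINAL_REPS,
    DEFAULT_SYSTEM_SD,
    RCNEstimate,
    TCritMode,
    t_critical,
)

__all__ = [
    "GT_BIN",
    "CopyNumberCall",
    "build_bounds_table",
    "call_copy_number",
    "call_table",
    "exon_concordance",
    "cohort_summary",
]

GT_BIN = ">6"  # label of the open top bin
_GT_DISTANCE_K = 7  # ">6" treated as 7 copies for concordance distance


@dataclass(frozen=True)
class CopyNumberCall:
    unit_id: str
    target_assay: str
    rcn: float
    ci_low: float
    ci_high: float
    bin: str  # "1".."6" or ">6"
    ambiguous: bool
    gap_assigned: bool

    @property
    def bin_numeric(self) -> int:
        return _GT_DISTANCE_K if self.bin == GT_BIN else int(self.bin)


def build_bounds_table(
    k_max: int = 6,
    system_sd: float = DEFAULT_SYSTEM_SD,
    df: int = DEFAULT_DF,
    n_reps: int = DEFAULT_NOMINAL_REPS,
    alpha: float = DEFAULT_ALPHA,
    efficiency: float = 1.0,
    t_mode: TCritMode = "rounded2",
) -> pd.DataFrame:
    """Modeled RCN acceptance interval per integer copy number.

    Returns a DataFrame with columns ``k``, ``lower``, ``upper`` where
    ``lower(k) = k * (1+E)**(-CI_log_base)`` evaluated in base 2 for
    E = 1; generally the modeled RCN of k copies is k (the ddCt that
    produces k copies is plugged into the same formula), so bounds scale
    exactly multiplicatively in k.

    ``t_mode`` defaults to the rounded critical value 2.000, which is the
    convention of the published per-copy bound table; ``"exact"`` uses the
    Student-t quantile (agreement within ~2e-4 relative at df = 68).
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    ci_log = t_critical(df, alpha, t_mode) * system_sd / math.sqrt(n_reps)
    base = 1.0 + efficiency
    half = base ** ci_log  # multiplicative half-width of the interval
    ks = np.arange(1, k_max + 1)
    table = pd.DataFrame({
        "k": ks,
        "lower": ks / half,
        "upper": ks * half,
    })
    table.attrs.update(
        system_sd=system_sd, df=df, n_reps=n_reps, alpha=alpha,
        efficiency=efficiency, t_mode=t_mode, ci_log=ci_log,
    )
    return table


def _nearest_k_log2(rcn: float, candidates: np.ndarray) -> int:
    """Candidate copy number minimizing |log2(rcn) - log2(k)|."""
    d = np.abs(np.log2(rcn) - np.log2(candidates.astype(float)))
    return int(candidates[int(np.argmin(d))])


def call_copy_number(
    est: RCNEstimate | pd.Series,
    bounds: pd.DataFrame,
    gt_rule: str = "ci",
) -> CopyNumberCall:
    """Assign a copy-number bin to one RCN estimate by CI overlap.

    Decision rule:

    * collect every k whose modeled interval intersects [ci_low, ci_high];
    * exactly one -> that bin;
    * several -> nearest k on the log2 scale, flagged ``ambiguous``;
    * none, with the estimate above the top interval -> ">6" when the CI
      lower bound (``gt_rule="ci"``, default) or the point estimate
      (``gt_rule="point"``) clears upper(k_max);
    * none otherwise (CI in an inter-bin gap, or below lower(1)) ->
      nearest k, flagged ``gap_assigned``. Estimates below the bottom
      interval call bin 1 with the gap flag; no "<1" bin is emitted.
    """
    rcn = float(est.rcn if hasattr(est, "rcn") else est["rcn"])
    lo = float(est.ci_low if hasattr(est, "ci_low") else est["ci_low"])
    hi = float(est.ci_high if hasattr(est, "ci_high") else est["ci_high"])
    unit = str(getattr(est, "unit_id", "") or (est.get("unit_id", "") if isinstance(est, pd.Series) else ""))
    assay = str(getattr(est, "target_assay", "") or (est.get("target_assay", "") if isinstance(est, pd.Series) else ""))
    if not (np.isfinite(rcn) and np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError(f"non-finite RCN estimate for unit {unit!r}")

    ks = bounds["k"].to_numpy()
    lowers = bounds["lower"].to_numpy(dtype=float)
    uppers = bounds["upper"].to_numpy(dtype=float)
    k_max = int(ks.max())
    overlap = (lo <= uppers) & (hi >= lowers)
    hits = ks[overlap]

    ambiguous = False
    gap = False
    if gt_rule == "point" and rcn > float(uppers[ks == k_max][0]):
        # point-estimate variant: a point beyond the top interval is an
        # open-bin call even when the CI still brushes it
        return CopyNumberCall(
            unit_id=unit, target_assay=assay, rcn=rcn, ci_low=lo, ci_high=hi,
            bin=GT_BIN, ambiguous=False, gap_assigned=False,
        )
    if hits.size == 1:
        k = int(hits[0])
        label = str(k)
    elif hits.size > 1:
        ambiguous = True
        k = _nearest_k_log2(rcn, hits)
        label = str(k)
    else:
        top = float(uppers[ks == k_max][0])
        exceeds = (lo > top) if gt_rule == "ci" else (rcn > top)
        if exceeds:
            label = GT_BIN
        else:
            gap = True
            k = _nearest_k_log2(rcn, ks)
            label = str(k)
    return CopyNumberCall(
        unit_id=unit, target_assay=assay, rcn=rcn, ci_low=lo, ci_high=hi,
        bin=label, ambiguous=ambiguous, gap_assigned=gap,
    )


def call_table(
    estimates: pd.DataFrame,
    bounds: pd.DataFrame | None = None,
    gt_rule: str = "ci",
) -> pd.DataFrame:
    """Vector form of :func:`call_copy_number` over an estimates table.

    Carries through brain/region/group metadata columns when present.
    """
    if bounds is None:
        bounds = build_bounds_table()
    carry = [c for c in ("brain_id", "region", "group") if c in estimates.columns]
    rows = []
    for _, row in estimates.iterrows():
        call = call_copy_number(row, bounds, gt_rule=gt_rule)
        rec = {
            "unit_id": call.unit_id, "target_assay": call.target_assay,
            "rcn": call.rcn, "ci_low": call.ci_low, "ci_high": call.ci_high,
            "bin": call.bin, "ambiguous": call.ambiguous,
            "gap_assigned": call.gap_assigned,
        }
        for c in carry:
            rec[c] = row[c]
        rows.append(rec)
    return pd.DataFrame(rows)


def _bin_to_int(label: str) -> int:
    return _GT_DISTANCE_K if label == GT_BIN else int(label)


def exon_concordance(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
) -> tuple[int, int, int]:
    """Dual-assay agreement: calls within one copy-number bin.

    Both tables must be keyed by ``unit_id``; only shared units are
    compared. ">6" counts as 7 copies for the distance. Returns
    ``(n_within_one, n_total, n_both_gain)`` where the last counts, among
    the discordant pairs, those where both assays still call a gain
    (> 2 copies).
    """
    a = calls_a.set_index("unit_id")["bin"]
    b = calls_b.set_index("unit_id")["bin"]
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ValueError("no shared unit_ids between call sets")
    ka = a.loc[shared].map(_bin_to_int).to_numpy()
    kb = b.loc[shared].map(_bin_to_int).to_numpy()
    within = np.abs(ka - kb) <= 1
    both_gain_discordant = (~within) & (ka > 2) & (kb > 2)
    return int(within.sum()), int(shared.size), int(both_gain_discordant.sum())


def cohort_summary(
    calls: pd.DataFrame,
    group: str | None = None,
    region: str | None = None,
    confidence: float = 0.95,
) -> dict:
    """Group/region cohort summary of copy-number calls.

    Reports mean RCN with a t-based CI of the mean, the bin histogram,
    the fractions of nuclei below / at / above two copies, and the mean
    RCN among the gained (> 2 copies) subset.
    """
    sub = calls
    if group is not None:
        sub = sub[sub["group"] == group]
    if region is not None:
        sub = sub[sub["region"] == region]
    if len(sub) < 2:
        raise ValueError("cohort summary requires >= 2 units")
    rcn = sub["rcn"].to_numpy(dtype=float)
    n = rcn.size
    mean = float(np.mean(rcn))
    sem = float(np.std(rcn, ddof=1) / math.sqrt(n))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1))
    hist = sub["bin"].value_counts().to_dict()
    k = sub["bin"].map(_bin_to_int).to_numpy()
    frac_gt2 = float(np.mean(k > 2))
    frac_lt2 = float(np.mean(k < 2))
    gained = rcn[k > 2]
    return {
        "group": group, "region": region, "n_units": int(n),
        "mean_rcn": mean,
        "ci95": (mean - tcrit * sem, mean + tcrit * sem),
        "bin_histogram": {str(b): int(c) for b, c in sorted(hist.items())},
        "frac_gt2": frac_gt2,
        "frac_lt2": frac_lt2,
        "frac_eq2": float(np.mean(k == 2)),
        "mean_rcn_gt2": float(np.mean(gained)) if gained.size else float("nan"),
    }
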