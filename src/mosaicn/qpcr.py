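"""Standard-curve calibration and ddCt-based relative copy number (RCN).

Implements the quantification chain used for locus copy-number estimation
in single nuclei and small neuronal cohorts:

1. amplification efficiency ``E`` from a standard curve
   (``E = 10**(-1/slope) - 1``; curves usable only when ``R^2 > 0.99``);
2. replicate-mean Ct per (unit, assay) with a minimum-replicate QC rule
   (nominal design: 3 sample loads x 6 assay replicates = 18; units with
   fewer than 10 surviving replicates for an assay are dropped);
3. dCt (target minus reference, default reference gene *SEMA4A*) and
   ddCt against a paired-cerebellum calibrator;
4. ``RCN = 2 * (1 + E)**(-ddCt)`` with a 95% confidence interval obtained
   on the ddCt scale from a fixed system standard deviation (0.25 cycles)
   and a Student-t critical value (df = 68 by default).

Cohort mode runs the identical arithmetic on triplicate bulk reactions and
compares cortex vs cerebellum ddCt per individual with an unpaired t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_SYSTEM_SD",
    "DEFAULT_DF",
    "DEFAULT_NOMINAL_REPS",
    "DEFAULT_MIN_REPS",
    "DEFAULT_REFERENCE_ASSAY",
    "QCFailure",
    "DegenerateCurveError",
    "StandardCurve",
    "DeltaCt",
    "RCNEstimate",
    "t_critical",
    "fit_standard_curve",
    "mean_ct",
    "delta_ct",
    "delta_delta_ct",
    "rcn_point_and_ci",
    "rcn_two_efficiency",
    "quantify_nuclei",
    "cohort_compare",
]

# System-level defaults of the CI model: a fixed replicate standard
# deviation of 0.25 cycles and 68 degrees of freedom for the critical t.
DEFAULT_SYSTEM_SD: float = 0.25
DEFAULT_DF: int = 68
DEFAULT_NOMINAL_REPS: int = 18  # 3 sample loads x 6 assay replicates
DEFAULT_MIN_REPS: int = 10
DEFAULT_REFERENCE_ASSAY: str = "SEMA4A"
DEFAULT_ALPHA: float = 0.05
R_SQUARED_USABLE: float = 0.99

TCritMode = Literal["exact", "rounded2"]


class QCFailure(ValueError):
    """A (unit, assay) pair failed replicate quality control."""


class DegenerateCurveError(ValueError):
    """Standard curve has a non-negative slope (no amplification signal)."""


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares dilution curve of Ct vs log10 template copies."""

    assay_id: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n_points: int

    @property
    def usable(self) -> bool:
        return self.r_squared > R_SQUARED_USABLE


@dataclass(frozen=True)
class DeltaCt:
    """Target-minus-reference mean Ct for one analysis unit."""

    unit_id: str
    target_assay: str
    reference_assay: str
    delta_ct: float
    n_reps: int


@dataclass(frozen=True)
class RCNEstimate:
    """Relative copy number with a symmetric-on-log-scale 95% CI."""

    unit_id: str
    target_assay: str
    ddct: float
    efficiency: float
    rcn: float
    ci_low: float
    ci_high: float
    ci_halfwidth_log: float
    n_reps: int


def t_critical(
    df: int = DEFAULT_DF,
    alpha: float = DEFAULT_ALPHA,
    mode: TCritMode = "exact",
) -> float:
    """Two-tailed Student-t critical value.

    ``mode="rounded2"`` uses the value 2.000; the published per-copy bound
    table is consistent with that rounding, so the bounds builder defaults
    to it while per-nucleus CIs default to the exact quantile.
    """
    if mode == "rounded2":
        return 2.0
    if mode == "exact":
        return float(stats.t.ppf(1.0 - alpha / 2.0, df))
    raise ValueError(f"unknown t_crit mode: {mode!r}")


# ---------------------------------------------------------------------------
# Standard curves
# ---------------------------------------------------------------------------

def fit_standard_curve(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
    assay_id: str = "",
) -> StandardCurve:
    """Fit Ct against log10 copy number and derive amplification efficiency.

    Parameters
    ----------
    points
        Sequence of ``(log10_copies, ct)`` pairs or a DataFrame with
        ``log10_copies`` and ``ct`` columns. At least 3 distinct dilution
        levels are required.

    Returns
    -------
    StandardCurve
        With ``efficiency = 10**(-1/slope) - 1`` and the regression R^2.
        The curve is flagged usable only when R^2 exceeds 0.99.

    Raises
    ------
    ValueError
        Fewer than 3 distinct dilution levels.
    DegenerateCurveError
        Non-negative slope (Ct must fall as template increases).
    """
    if isinstance(points, pd.DataFrame):
        x = np.asarray(points["log10_copies"], dtype=float)
        y = np.asarray(points["ct"], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("points must be (log10_copies, ct) pairs")
        x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 3:
        raise ValueError("standard curve requires >= 3 distinct dilution levels")
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise DegenerateCurveError(
            f"standard curve slope {res.slope:.4f} >= 0: Ct must decrease "
            "with template amount"
        )
    efficiency = 10.0 ** (-1.0 / res.slope) - 1.0
    return StandardCurve(
        assay_id=assay_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        efficiency=float(efficiency),
        n_points=int(x.size),
    )


# ---------------------------------------------------------------------------
# Replicate aggregation and ddCt
# ---------------------------------------------------------------------------

def mean_ct(
    table: pd.DataFrame,
    unit_id: str,
    assay_id: str,
    min_reps: int = DEFAULT_MIN_REPS,
    mad_filter: bool = False,
    mad_threshold: float = 3.5,
) -> tuple[float, int]:
    """Replicate-mean Ct for one (unit, assay) with minimum-replicate QC.

    Plain arithmetic mean; no outlier rejection by default. When
    ``mad_filter`` is set, replicates whose modified z-score (median
    absolute deviation based) exceeds ``mad_threshold`` are dropped before
    the QC count is applied.

    Raises
    ------
    QCFailure
        Fewer than ``min_reps`` replicates survive; the unit is dropped
        from single-nucleus analysis for this assay.
    KeyError
        The (unit, assay) pair is absent from the table.
    """
    sel = table[(table["unit_id"] == unit_id) & (table["assay_id"] == assay_id)]
    if sel.empty:
        raise KeyError(f"no replicates for unit {unit_id!r} assay {assay_id!r}")
    cts = np.asarray(sel["ct"], dtype=float)
    if mad_filter and cts.size >= 3:
        med = np.median(cts)
        mad = np.median(np.abs(cts - med))
        if mad > 0:
            keep = 0.6745 * np.abs(cts - med) / mad <= mad_threshold
            cts = cts[keep]
    if cts.size < min_reps:
        raise QCFailure(
            f"unit {unit_id!r} assay {assay_id!r}: {cts.size} replicates "
            f"< required {min_reps}"
        )
    return float(np.mean(cts)), int(cts.size)


def delta_ct(
    table: pd.DataFrame,
    unit_id: str,
    target_assay: str,
    reference_assay: str = DEFAULT_REFERENCE_ASSAY,
    min_reps: int = DEFAULT_MIN_REPS,
) -> DeltaCt:
    """dCt = mean Ct(target) - mean Ct(reference) for one unit.

    ``n_reps`` records the target-assay replicate count, which drives the
    CI width downstream.
    """
    tgt_mean, tgt_n = mean_ct(table, unit_id, target_assay, min_reps=min_reps)
    ref_mean, _ = mean_ct(table, unit_id, reference_assay, min_reps=min_reps)
    return DeltaCt(
        unit_id=unit_id,
        target_assay=target_assay,
        reference_assay=reference_assay,
        delta_ct=tgt_mean - ref_mean,
        n_reps=tgt_n,
    )


def delta_delta_ct(sample: DeltaCt, calibrator_units: Sequence[DeltaCt]) -> float:
    """ddCt = sample dCt minus the mean calibrator dCt.

    The calibrator is the set of paired cerebellar units from the same
    brain; their dCt values are averaged.
    """
    if not calibrator_units:
        raise ValueError("calibrator list must be non-empty")
    for cal in calibrator_units:
        if (cal.target_assay != sample.target_assay
                or cal.reference_assay != sample.reference_assay):
            raise ValueError(
                "calibrator assays must match sample: "
                f"{cal.target_assay}/{cal.reference_assay} vs "
                f"{sample.target_assay}/{sample.reference_assay}"
            )
    cal_mean = float(np.mean([c.delta_ct for c in calibrator_units]))
    return sample.delta_ct - cal_mean


# ---------------------------------------------------------------------------
# RCN and its confidence interval
# ---------------------------------------------------------------------------

def rcn_point_and_ci(
    ddct: float,
    efficiency: float,
    n_reps: int,
    system_sd: float = DEFAULT_SYSTEM_SD,
    df: int = DEFAULT_DF,
    alpha: float = DEFAULT_ALPHA,
    t_mode: TCritMode = "exact",
    unit_id: str = "",
    target_assay: str = "",
) -> RCNEstimate:
    """RCN = 2 (1+E)^(-ddCt) with a 95% CI symmetric on the ddCt scale.

    The CI half-width on the ddCt scale is
    ``t_crit(df, alpha) * system_sd / sqrt(n_reps)``; the RCN bounds are
    the formula evaluated at ``ddct -/+ CI`` and then ordered so that
    ``ci_low <= rcn <= ci_high`` (for E > 0 the map is decreasing in ddCt,
    so the lower RCN bound comes from the larger ddCt).

    A single efficiency — the target assay's — is used, assuming the
    reference assay amplifies at a near-identical rate (observed TaqMan
    efficiencies span 0.992-1.040). :func:`rcn_two_efficiency` provides
    the ratio form when the assumption is not acceptable.
    """
    if efficiency <= -1:
        raise ValueError("efficiency must exceed -1")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ci_log = t_critical(df, alpha, t_mode) * system_sd / math.sqrt(n_reps)
    base = 1.0 + efficiency
    point = 2.0 * base ** (-ddct)
    bound_a = 2.0 * base ** (-(ddct + ci_log))
    bound_b = 2.0 * base ** (-(ddct - ci_log))
    lo, hi = (bound_a, bound_b) if bound_a <= bound_b else (bound_b, bound_a)
    return RCNEstimate(
        unit_id=unit_id,
        target_assay=target_assay,
        ddct=float(ddct),
        efficiency=float(efficiency),
        rcn=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        ci_halfwidth_log=float(ci_log),
        n_reps=int(n_reps),
    )


def rcn_two_efficiency(
    dct_calibrator_minus_sample_target: float,
    dct_calibrator_minus_sample_reference: float,
    target_efficiency: float,
    reference_efficiency: float,
) -> float:
    """Efficiency-ratio relative quantity, scaled to 2 for a diploid locus.

    ``2 * (1+E_tgt)^dCt_tgt / (1+E_ref)^dCt_ref`` where each exponent is
    the calibrator-minus-sample mean Ct for that assay. Reduces to the
    single-efficiency form when both efficiencies are equal.
    """
    num = (1.0 + target_efficiency) ** dct_calibrator_minus_sample_target
    den = (1.0 + reference_efficiency) ** dct_calibrator_minus_sample_reference
    return 2.0 * num / den


# ---------------------------------------------------------------------------
# Tables in, tables out
# ---------------------------------------------------------------------------

def quantify_nuclei(
    table: pd.DataFrame,
    target_assay: str,
    reference_assay: str = DEFAULT_REFERENCE_ASSAY,
    efficiency: float = 1.0,
    calibrator_region: str = "CBL",
    sample_region: str = "CTX",
    min_reps: int = DEFAULT_MIN_REPS,
    system_sd: float = DEFAULT_SYSTEM_SD,
    df: int = DEFAULT_DF,
    alpha: float = DEFAULT_ALPHA,
    t_mode: TCritMode = "exact",
    include_calibrators: bool = True,
    calibrator_units: set[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Run the full quantification chain over a Ct replicate table.

    For every unit the paired-cerebellum calibrator is the mean dCt of
    the calibrator units from the same brain: by default every
    calibrator-region (cerebellum) unit, or, when ``calibrator_units``
    names a dedicated calibrator set, only those. Calibrator-region
    units are themselves quantified against that same mean (so a typical
    calibrator cohort centres on RCN 2). Units failing replicate QC for
    either assay are dropped and reported in the returned log.

    Returns
    -------
    (estimates, dropped)
        ``estimates``: one row per unit with columns
        unit_id, brain_id, region, group, target_assay, ddct, efficiency,
        rcn, ci_low, ci_high, n_reps.
        ``dropped``: log lines naming QC-failed units.
    """
    required = {"unit_id", "brain_id", "region", "group", "assay_id", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ct table missing columns: {sorted(missing)}")

    dropped: list[str] = []
    dcts: dict[str, DeltaCt] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for unit, sub in table.groupby("unit_id", sort=True):
        try:
            dcts[str(unit)] = delta_ct(
                table, str(unit), target_assay, reference_assay, min_reps=min_reps
            )
        except QCFailure as exc:
            dropped.append(str(exc))
            continue
        except KeyError:
            continue  # unit not measured for this assay pair
        row = sub.iloc[0]
        meta[str(unit)] = (str(row["brain_id"]), str(row["region"]), str(row["group"]))

    rows = []
    for unit, dct in dcts.items():
        brain, region, group = meta[unit]
        calibrators = [
            d for u, d in dcts.items()
            if meta[u][0] == brain and meta[u][1] == calibrator_region
            and (calibrator_units is None or u in calibrator_units)
        ]
        if not calibrators:
            dropped.append(f"unit {unit!r}: no {calibrator_region} calibrator for brain {brain!r}")
            continue
        if region == calibrator_region and not include_calibrators:
            continue
        ddct = delta_delta_ct(dct, calibrators)
        est = rcn_point_and_ci(
            ddct, efficiency, dct.n_reps,
            system_sd=system_sd, df=df, alpha=alpha, t_mode=t_mode,
            unit_id=unit, target_assay=target_assay,
        )
        rows.append({
            "unit_id": unit, "brain_id": brain, "region": region, "group": group,
            "target_assay": target_assay, "ddct": est.ddct,
            "efficiency": est.efficiency, "rcn": est.rcn,
            "ci_low": est.ci_low, "ci_high": est.ci_high, "n_reps": est.n_reps,
        })
    estimates = pd.DataFrame(
        rows, columns=["unit_id", "brain_id", "region", "group", "target_assay",
                       "ddct", "efficiency", "rcn", "ci_low", "ci_high", "n_reps"],
    )
    return estimates, dropped


def cohort_compare(
    estimates: pd.DataFrame,
    region_a: str = "CTX",
    region_b: str = "CBL",
) -> pd.DataFrame:
    """Per-brain unpaired two-tailed t-test on ddCt, region A vs region B.

    Cohort mode for small bulk populations: triplicate reactions per
    cohort give a handful of ddCt values per region; an amplified locus in
    the cortex shows as a significantly more negative cortical ddCt.
    """
    rows = []
    for brain, sub in estimates.groupby("brain_id", sort=True):
        a = sub.loc[sub["region"] == region_a, "ddct"].to_numpy()
        b = sub.loc[sub["region"] == region_b, "ddct"].to_numpy()
        if a.size < 2 or b.size < 2:
            rows.append({"brain_id": brain, "t_stat": np.nan, "p_value": np.nan,
                         "n_a": a.size, "n_b": b.size,
                         "mean_rcn_a": np.nan, "mean_rcn_b": np.nan})
            continue
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({
            "brain_id": brain, "t_stat": float(t), "p_value": float(p),
            "n_a": int(a.size), "n_b": int(b.size),
            "mean_rcn_a": float(sub.loc[sub["region"] == region_a, "rcn"].mean()),
            "mean_rcn_b": float(sub.loc[sub["region"] == region_b, "rcn"].mean()),
        })
    return pd.DataFrame(rows)
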