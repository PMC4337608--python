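"""Modeled bounds table and CI-overlap copy-number bin assignment."""

import numpy as np
import pandas as pd
import pytest

from mosaicn.calling import (
    GT_BIN,
    build_bounds_table,
    call_copy_number,
    call_table,
    cohort_summary,
    exon_concordance,
)
from mosaicn.qpcr import RCNEstimate

# Published per-copy acceptance intervals under the defaults
# (SD 0.25, 18 replicates, df 68, alpha 0.05, critical value 2.000).
MODELED_BOUNDS = {
    1: (0.92156, 1.08512),
    2: (1.84312, 2.17023),
    3: (2.76468, 3.25535),
    4: (3.68624, 4.34047),
    5: (4.60780, 5.42559),
    6: (5.52936, 6.51070),
}


def _estimate(rcn, ci_low, ci_high, unit="u1", assay="APP_ex3"):
    return RCNEstimate(unit, assay, 0.0, 1.0, rcn, ci_low, ci_high, 0.1, 18)


class TestBoundsTable:
    def test_reproduces_published_table_with_rounded_t(self):
        table = build_bounds_table(t_mode="rounded2").set_index("k")
        for k, (lo, hi) in MODELED_BOUNDS.items():
            assert table.loc[k, "lower"] == pytest.approx(lo, abs=5e-6)
            assert table.loc[k, "upper"] == pytest.approx(hi, abs=5e-6)

    def test_exact_t_quantile_agrees_within_5e4_relative(self):
        table = build_bounds_table(t_mode="exact").set_index("k")
        for k, (lo, hi) in MODELED_BOUNDS.items():
            assert table.loc[k, "lower"] == pytest.approx(lo, rel=5e-4)
            assert table.loc[k, "upper"] == pytest.approx(hi, rel=5e-4)

    def test_multiplicative_scaling_in_k(self):
        table = build_bounds_table(k_max=8)
        lo1 = table.loc[table.k == 1, "lower"].item()
        hi1 = table.loc[table.k == 1, "upper"].item()
        assert np.allclose(table["lower"], table["k"] * lo1)
        assert np.allclose(table["upper"], table["k"] * hi1)

    def test_intervals_disjoint_through_6_overlap_at_7(self):
        table = build_bounds_table(k_max=8).set_index("k")
        for k in range(1, 6):
            assert table.loc[k, "upper"] < table.loc[k + 1, "lower"]
        # first overlap: upper(6) exceeds lower(7)
        assert table.loc[6, "upper"] > table.loc[7, "lower"]
        assert table.loc[7, "lower"] == pytest.approx(6.4509, abs=1e-3)

    def test_invalid_k_max(self):
        with pytest.raises(ValueError):
            build_bounds_table(k_max=0)


@pytest.fixture(scope="module")
def bounds():
    return build_bounds_table()


class TestCallCopyNumber:

    def test_contained_ci_single_bin(self, bounds):
        call = call_copy_number(_estimate(2.0, 1.9, 2.1), bounds)
        assert (call.bin, call.ambiguous, call.gap_assigned) == ("2", False, False)

    def test_ci_partially_overlapping_one_interval(self, bounds):
        # CI [3.1, 3.3] intersects only the CN-3 interval (2.76468, 3.25535)
        call = call_copy_number(_estimate(3.2, 3.1, 3.3), bounds)
        assert call.bin == "3"
        assert not call.ambiguous

    def test_high_estimate_above_top_interval(self, bounds):
        call = call_copy_number(_estimate(12.0, 10.5, 13.7), bounds)
        assert call.bin == GT_BIN

    def test_gt_rule_point_vs_ci(self, bounds):
        # CI lower bound below upper(6): CI rule cannot call ">6"
        est = _estimate(7.0, 6.45, 7.6)
        assert call_copy_number(est, bounds, gt_rule="ci").bin != GT_BIN
        assert call_copy_number(est, bounds, gt_rule="point").bin == GT_BIN

    def test_wide_ci_ambiguous_nearest_log2(self, bounds):
        # spans CN 5 and 6; rcn 5.51 is nearer 6 than 5 on log2 scale
        call = call_copy_number(_estimate(5.51, 5.08, 5.98), bounds)
        assert call.ambiguous
        assert call.bin == "6"

    def test_gap_value_flagged(self, bounds):
        # 1.2 sits between upper(1)=1.085 and lower(2)=1.843
        call = call_copy_number(_estimate(1.2, 1.11, 1.30), bounds)
        assert call.gap_assigned
        assert call.bin in {"1", "2"}

    def test_below_bottom_interval_calls_bin_1_with_gap_flag(self, bounds):
        call = call_copy_number(_estimate(0.5, 0.46, 0.54), bounds)
        assert call.bin == "1"
        assert call.gap_assigned

    def test_non_finite_rejected(self, bounds):
        with pytest.raises(ValueError):
            call_copy_number(_estimate(float("nan"), 1.0, 2.0), bounds)

    def test_oracle_equivalence_on_random_estimates(self, bounds, rng):
        """Decision rule matches a brute-force interval scan, 10k cases."""
        ks = bounds["k"].to_numpy()
        lowers = bounds["lower"].to_numpy()
        uppers = bounds["upper"].to_numpy()
        k_max = int(ks.max())

        def brute_force(rcn, lo, hi):
            hits = [int(k) for k, l, u in zip(ks, lowers, uppers)
                    if lo <= u and hi >= l]
            if len(hits) == 1:
                return str(hits[0])
            if hits:
                d = [abs(np.log2(rcn) - np.log2(k)) for k in hits]
                return str(hits[int(np.argmin(d))])
            if lo > uppers[k_max - 1]:
                return GT_BIN
            d = [abs(np.log2(rcn) - np.log2(k)) for k in ks]
            return str(int(ks[int(np.argmin(d))]))

        rcn = rng.uniform(0.3, 14.0, 10_000)
        half = np.exp(rng.uniform(np.log(1.01), np.log(1.6), 10_000))
        for r, h in zip(rcn, half):
            est = _estimate(r, r / h, r * h)
            assert call_copy_number(est, bounds).bin == brute_force(r, r / h, r * h)


class TestConcordance:
    @staticmethod
    def _calls(bins, units=None):
        units = units or [f"n{i}" for i in range(len(bins))]
        return pd.DataFrame({"unit_id": units, "bin": bins})

    def test_identical_lists_fully_concordant(self):
        bins = ["2"] * 100 + ["4"] * 10 + [GT_BIN] * 5
        a = self._calls(bins)
        assert exon_concordance(a, a.copy()) == (115, 115, 0)

    def test_hand_enumerated_mixed_case(self):
        a = self._calls(["2", "4", GT_BIN])
        b = self._calls(["3", "2", "6"])
        # |2-3|=1 in; |4-2|=2 out (b=2 not a gain); |7-6|=1 in
        assert exon_concordance(a, b) == (2, 3, 0)

    def test_both_gain_discordant_counted(self):
        a = self._calls(["6", "2"])
        b = self._calls(["3", "2"])
        n_within, n_total, n_both_gain = exon_concordance(a, b)
        assert (n_within, n_total, n_both_gain) == (1, 2, 1)

    def test_no_shared_units_rejected(self):
        a = self._calls(["2"], units=["x"])
        b = self._calls(["2"], units=["y"])
        with pytest.raises(ValueError):
            exon_concordance(a, b)


class TestCohortSummary:
    def test_all_diploid(self):
        calls = pd.DataFrame({
            "unit_id": [f"n{i}" for i in range(10)],
            "rcn": [2.0] * 10, "bin": ["2"] * 10,
            "group": "ND", "region": "CBL",
        })
        s = cohort_summary(calls, "ND", "CBL")
        assert s["mean_rcn"] == pytest.approx(2.0)
        assert s["frac_gt2"] == 0.0
        assert s["frac_eq2"] == 1.0
        assert np.isnan(s["mean_rcn_gt2"])

    def test_mixture_fractions_and_gain_mean(self):
        rcn = [1.0, 2.0, 2.0, 5.0, 5.0, 6.0]
        bins = ["1", "2", "2", "5", "5", "6"]
        calls = pd.DataFrame({
            "unit_id": [f"n{i}" for i in range(6)], "rcn": rcn, "bin": bins,
            "group": "AD", "region": "CTX",
        })
        s = cohort_summary(calls, "AD", "CTX")
        assert s["frac_gt2"] == pytest.approx(0.5)
        assert s["frac_lt2"] == pytest.approx(1 / 6)
        assert s["mean_rcn_gt2"] == pytest.approx(np.mean([5, 5, 6]))
        assert s["ci95"][0] < s["mean_rcn"] < s["ci95"][1]
        assert sum(s["bin_histogram"].values()) == s["n_units"]

    def test_single_unit_rejected(self):
        calls = pd.DataFrame({"unit_id": ["n0"], "rcn": [2.0], "bin": ["2"],
                              "group": "AD", "region": "CTX"})
        with pytest.raises(ValueError):
            cohort_summary(calls)
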