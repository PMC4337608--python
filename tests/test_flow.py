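"""DNA content variation: peak detection, DNA index, gating, statistics."""

import numpy as np
import pandas as pd
import pytest

from mosaicn.flow import (
    PeakStats,
    chromosome_gain_percent,
    detect_g0g1_peak,
    dna_index,
    group_compare,
    neun_gate,
    peak_skew,
    unpaired_t,
    covariate_regression,
)
from mosaicn.simulate import SimulationConfig, simulate_flow_events


def _events(values, tag="sample"):
    return pd.DataFrame({"pi_intensity": values, "species_tag": tag})


class TestPeakDetection:
    def test_pure_gaussian_mode_and_cv(self, rng):
        x = rng.normal(100.0, 5.0, 20_000)
        peak = detect_g0g1_peak(_events(x))
        assert peak.mode == pytest.approx(100.0, abs=2.0)
        assert peak.cv_percent == pytest.approx(5.0, abs=1.0)
        assert peak.gate[0] <= peak.mode <= peak.gate[1]

    def test_mixture_picks_diploid_mode(self, rng):
        x = np.concatenate([
            rng.normal(100.0, 5.0, 18_000),
            rng.normal(180.0, 5.0, 2_000),
        ])
        peak = detect_g0g1_peak(_events(x))
        assert peak.mode == pytest.approx(100.0, abs=3.0)

    def test_balanced_bimodal_prefers_lower_mode(self, rng):
        x = np.concatenate([
            rng.normal(100.0, 4.0, 10_000),
            rng.normal(200.0, 4.0, 10_000),
        ])
        with pytest.warns(UserWarning, match="diploid assumption"):
            peak = detect_g0g1_peak(_events(x))
        assert peak.mode < 150.0

    def test_constant_intensity_zero_cv(self):
        peak = detect_g0g1_peak(_events(np.full(600, 100.0)))
        assert peak.cv_percent == 0.0
        assert peak.mode == 100.0

    def test_too_few_events_rejected(self, rng):
        with pytest.raises(ValueError, match="events"):
            detect_g0g1_peak(_events(rng.normal(100, 5, 499)))


class TestDNAIndex:
    def _peak(self, mean):
        return PeakStats(mean=mean, mode=mean, sd=1.0, cv_percent=1.0,
                         n_events=1000, gate=(0, 2 * mean))

    def test_identity(self):
        res = dna_index(self._peak(100), self._peak(35), self._peak(100), self._peak(35))
        assert res.di == pytest.approx(1.0)
        assert res.percent_change == pytest.approx(0.0)

    def test_eight_percent_shift(self):
        res = dna_index(self._peak(108), self._peak(35), self._peak(100), self._peak(35))
        assert res.di == pytest.approx(1.08)
        assert res.percent_change == pytest.approx(8.0)

    @pytest.mark.parametrize("gain", [0.5, 1.0, 3.7])
    def test_gain_invariance(self, gain):
        # common detector gain on a tube cancels through its CEN peak
        base = dna_index(self._peak(108), self._peak(35), self._peak(100), self._peak(35))
        scaled = dna_index(self._peak(108 * gain), self._peak(35 * gain),
                           self._peak(100), self._peak(35))
        assert scaled.di == pytest.approx(base.di, rel=1e-12)

    def test_percent_change_linear_in_di(self):
        r1 = dna_index(self._peak(105), self._peak(35), self._peak(100), self._peak(35))
        r2 = dna_index(self._peak(110), self._peak(35), self._peak(100), self._peak(35))
        assert r2.percent_change - r1.percent_change == pytest.approx(
            100 * (r2.di - r1.di)
        )

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            dna_index(self._peak(100), self._peak(35), self._peak(100),
                      PeakStats(0.0, 0.0, 1.0, 1.0, 1000, (0, 1)))


class TestSkew:
    def test_arithmetic(self):
        peak = PeakStats(mean=105.0, mode=100.0, sd=10.0, cv_percent=9.5,
                         n_events=1000, gate=(75, 125))
        assert peak_skew(peak) == pytest.approx(0.5)

    def test_symmetric_gaussian_near_zero(self, rng):
        peak = detect_g0g1_peak(_events(rng.normal(100, 5, 20_000)))
        assert abs(peak_skew(peak)) < 0.25

    def test_right_shoulder_positive(self):
        cfg = SimulationConfig(seed=7, flow_n_events=20_000)
        events = simulate_flow_events(cfg, true_di=1.0, shoulder_fraction=0.3,
                                      rng=np.random.default_rng(7))
        sample = events[events["species_tag"] == "sample"]
        peak = detect_g0g1_peak(sample)
        assert peak_skew(peak) > 0.0

    def test_zero_sd_undefined(self):
        peak = PeakStats(100.0, 100.0, 0.0, 0.0, 1000, (75, 125))
        with pytest.raises(ValueError):
            peak_skew(peak)


class TestNeunGate:
    def test_all_below_control_max_pos_empty(self, rng):
        control = pd.DataFrame({"neun_intensity": rng.normal(50, 10, 5000)})
        events = pd.DataFrame({"neun_intensity": np.full(100, 10.0)})
        pos, neg = neun_gate(events, control)
        assert pos.empty and len(neg) == 100

    def test_bimodal_recovers_positive_fraction(self):
        cfg = SimulationConfig(seed=11, flow_n_events=20_000,
                               flow_neun_positive_fraction=0.7)
        events = simulate_flow_events(cfg, with_neun=True,
                                      rng=np.random.default_rng(11))
        sample = events[events["species_tag"] == "sample"]
        control = pd.DataFrame({
            "neun_intensity": np.random.default_rng(12).normal(50, 15, 10_000).clip(0)
        })
        pos, neg = neun_gate(sample, control)
        true_frac = sample["neun_true_positive"].mean()
        got_frac = len(pos) / len(sample)
        assert got_frac == pytest.approx(true_frac, abs=0.02)

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            neun_gate(pd.DataFrame({"neun_intensity": [1.0]}),
                      pd.DataFrame({"neun_intensity": []}))


class TestGroupStats:
    def test_identical_groups_not_significant(self):
        v = list(np.linspace(-1, 1, 12))
        res = group_compare({"A": v, "B": v, "C": v})
        assert res["anova_p"] > 0.9
        assert all(p > 0.9 for p in res["tukey"].values())

    def test_large_shift_detected(self, rng):
        a = rng.normal(0.0, 1.0, 15)
        b = rng.normal(3.0, 1.0, 15)  # 3 SD shift, n = 15: power ~ 1
        res = group_compare({"A": a, "B": b})
        assert res["anova_p"] < 0.05
        assert unpaired_t(a, b)["p_value"] < 0.05

    def test_degenerate_variance_reports_nan(self):
        res = group_compare({"A": [1.0, 1.0, 1.0], "B": [1.0, 1.0, 1.0]})
        assert np.isnan(res["anova_p"])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare({"A": [1.0, 2.0]})

    def test_regression_recovers_slope(self, rng):
        age = rng.uniform(60, 95, 30)
        pct = 0.1 * age + rng.normal(0, 0.1, 30)
        res = covariate_regression(age, pct)
        assert res["slope"] == pytest.approx(0.1, abs=0.02)
        assert res["p_value"] < 1e-6


def test_chromosome_gain_bound_is_3_9_percent():
    """Largest-chromosome gain: 250 Mb over half a 12,800 Mb tetraploid."""
    assert chromosome_gain_percent() == pytest.approx(3.90625)
    assert round(chromosome_gain_percent(), 1) == 3.9
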