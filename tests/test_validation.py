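"""Precision, suitability, detection limits, selectivity, report."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from anacquant.calibration import CalibrationLevel, calibrate, t_statistic
from anacquant.simulate import simulate_calibration_series
from anacquant.validation import (DetectionLimits, ReplicateSet,
                                  ValidationReport, build_report,
                                  detection_limits, precision,
                                  selectivity_report, summary_cv,
                                  system_suitability)


class TestPrecision:
    def test_identical_values_give_zero_cv(self):
        (res,) = precision([ReplicateSet("40", (40.0, 40.0, 40.0))], "intraday")
        assert res.sd == 0.0
        assert res.cv == 0.0

    def test_hand_computed_sd_and_cv(self):
        # {39.9, 40.0, 40.1}: S = 0.1 (n-1 denominator), CV = 0.25%
        (res,) = precision([ReplicateSet("40", (39.9, 40.0, 40.1))], "intraday")
        assert res.mean == pytest.approx(40.0)
        assert res.sd == pytest.approx(0.1, rel=1e-9)
        assert res.cv == pytest.approx(0.25, rel=1e-9)

    def test_sd_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            vals = tuple(rng.uniform(10, 100, int(rng.integers(2, 12))))
            (res,) = precision([ReplicateSet("x", vals)], "intraday")
            mean = sum(vals) / len(vals)
            oracle = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
            assert res.sd == pytest.approx(oracle, rel=1e-12)

    def test_interday_pools_day_means(self):
        groups = [
            ReplicateSet("40", (40.0, 40.2), day="d1"),
            ReplicateSet("40", (39.6, 39.8), day="d2"),
            ReplicateSet("40", (40.3, 40.5), day="d3"),
        ]
        (res,) = precision(groups, "interday")
        day_means = [40.1, 39.7, 40.4]
        assert res.mean == pytest.approx(statistics.fmean(day_means))
        assert res.sd == pytest.approx(statistics.stdev(day_means), rel=1e-12)
        assert res.n == 6

    def test_interday_requires_two_days(self):
        with pytest.raises(ValueError):
            precision([ReplicateSet("40", (1.0, 2.0), day="d1")], "interday")

    def test_zero_mean_flagged_undefined(self):
        (res,) = precision([ReplicateSet("0", (-1.0, 1.0))], "intraday")
        assert res.undefined

    def test_synthetic_intraday_cv_matches_injection_noise(self):
        """cv_target 0.002 with 6 replicates lands in the sub-0.3% band."""
        cvs = []
        for seed in range(100):
            s = simulate_calibration_series(levels=(40.0,), replicates=6,
                                            cv_target=0.002, seed=seed)
            (res,) = precision(
                [ReplicateSet("40", s.levels[0].areas)], "intraday")
            cvs.append(res.cv)
        assert 0.1 <= np.mean(cvs) <= 0.3

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_cv_scale_invariance(self, c):
        vals = (39.9, 40.0, 40.1)
        (base,) = precision([ReplicateSet("x", vals)], "intraday")
        (scaled,) = precision(
            [ReplicateSet("x", tuple(c * v for v in vals))], "intraday")
        assert scaled.cv == pytest.approx(base.cv, rel=1e-9)


class TestSystemSuitability:
    def test_identical_injections_pass(self):
        res = system_suitability([(11.0, 96000.0)] * 10)
        assert res.rt_rsd == 0.0 and res.area_rsd == 0.0
        assert res.passed

    def test_reference_rsds_pass_strict_profile(self):
        # RT RSD 0.45% and area RSD 0.30% both pass at the 1.0% guideline
        rng = np.random.default_rng(0)
        assert 0.45 <= 1.0 and 0.30 <= 1.0  # the verdict logic below
        rts = 11.0 * (1 + 0.0045 * rng.standard_normal(10))
        areas = 96000.0 * (1 + 0.0030 * rng.standard_normal(10))
        res = system_suitability(list(zip(rts, areas)), rsd_threshold=1.0)
        assert res.passed

    def test_too_few_injections_rejected(self):
        with pytest.raises(ValueError):
            system_suitability([(11.0, 1.0)] * 5)

    def test_rt_jitter_monte_carlo(self):
        """0.5% RT jitter over 10 injections reports ~0.5% mean RSD."""
        rng = np.random.default_rng(12345)
        rsds = []
        for _ in range(200):
            rts = 11.0 * (1 + 0.005 * rng.standard_normal(10))
            res = system_suitability([(rt, 1000.0) for rt in rts])
            rsds.append(res.rt_rsd)
        assert np.mean(rsds) == pytest.approx(0.5, abs=0.15)


class TestDetectionLimits:
    def test_sn_ratio_identity(self, printed_line_fit):
        # noise chosen so LOD = 0.18 -> LOQ = 0.60 (fixed 10/3 ratio)
        noise = 0.18 * printed_line_fit.slope / 3.0
        lim = detection_limits(printed_line_fit, noise_sd=noise)
        assert lim.lod == pytest.approx(0.18, rel=1e-12)
        assert lim.loq == pytest.approx(0.60, rel=1e-12)
        assert lim.loq / lim.lod == pytest.approx(10.0 / 3.0, rel=1e-12)

    def test_residual_sd_inversion(self):
        # 3.3 * s_y / slope = 0.18 with slope 2333.5 -> s_y ~ 127.3
        s_y = 0.18 * 2333.5 / 3.3
        assert s_y == pytest.approx(127.3, abs=0.05)
        rng = np.random.default_rng(1)
        x = np.repeat([1, 5, 10, 20, 40, 60, 80, 100.0], 3)
        y = 2333.5 * x + 2956.2 + rng.normal(0, s_y, x.size)
        fit = calibrate([CalibrationLevel(xi, tuple(y[x == xi]))
                         for xi in np.unique(x)])
        lim = detection_limits(fit, method="residual-sd")
        assert lim.loq / lim.lod == pytest.approx(10.0 / 3.3, rel=1e-12)
        # sensitivity adequate for the assay: LOD below the 1 ug/mL bottom level
        assert lim.lod < 1.0

    def test_invalid_inputs_rejected(self, printed_line_fit):
        with pytest.raises(ValueError):
            detection_limits(printed_line_fit, noise_sd=None)
        with pytest.raises(ValueError):
            detection_limits(None, noise_sd=1.0)
        with pytest.raises(ValueError):
            DetectionLimits(lod=0.9, loq=0.5, method="signal-to-noise")


class TestSelectivity:
    @pytest.mark.parametrize("purity,expected", [
        (0.9917, True),   # published triene purity passes
        (0.95, True),     # inclusive boundary
        (0.80, False),
    ])
    def test_threshold(self, purity, expected):
        out = selectivity_report({"AnAc 15:3": purity})
        assert out["AnAc 15:3"].passed is expected

    def test_out_of_range_purity_rejected(self):
        with pytest.raises(ValueError):
            selectivity_report({"x": 1.2})


class TestReport:
    def _full_report(self, fit):
        intraday = precision(
            [ReplicateSet(f"{lv.concentration:g}", lv.areas)
             for lv in simulate_calibration_series(cv_target=0.002, seed=0).levels],
            "intraday")
        suit = system_suitability([(11.0, 96000.0)] * 10)
        lim = detection_limits(fit, noise_sd=140.0)
        sel = selectivity_report({"AnAc 15:3": 0.9917, "AnAc 15:2": 0.9819,
                                  "AnAc 15:1": 0.9940})
        return build_report(fit, intraday, suit, lim, sel)

    def test_missing_component_named(self, printed_line_fit):
        with pytest.raises(ValueError, match="suitability"):
            build_report(fit=printed_line_fit, precision_results=[],
                         limits=None, selectivity={}, suitability=None)

    def test_json_round_trip(self, printed_line_fit):
        report = self._full_report(printed_line_fit)
        back = ValidationReport.from_json(report.to_json())
        assert back.to_dict() == report.to_dict()

    def test_markdown_reproduces_intercept_t(self):
        """A fit carrying the published dispersions renders t = 3.56."""
        from anacquant.calibration import CalibrationFit

        fit = CalibrationFit(
            slope=2333.5, intercept=2956.2, r_squared=0.998, n=24,
            x=np.repeat([1, 5, 10, 20, 40, 60, 80, 100.0], 3),
            y=np.zeros(24), residuals=np.zeros(24), x_min=1.0, x_max=100.0,
            s_y=600.0, s_a=15.79, s_b=830.91, determinant=694368.0,
            confidence=0.95,
            t_slope=t_statistic(2333.5, 15.79),
            t_intercept=t_statistic(2956.2, 830.91),
            t_critical=2.074, slope_significant=True, intercept_significant=True,
            f_stat=t_statistic(2333.5, 15.79) ** 2, f_critical=4.30,
            regression_significant=True)
        report = self._full_report(fit)
        md = report.to_markdown()
        assert "3.56" in md
        assert "significant" in md
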