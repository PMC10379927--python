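"""Peak processing against simulator ground truth."""

import math

import numpy as np
import pytest

from anacquant.catalog import AnalyteDef, default_catalog
from anacquant.peaks import (Peak, detect_peaks, estimate_baseline,
                             extract_spectrum, integrate_peak, match_peaks,
                             peak_purity, process_chromatogram)
from anacquant.simulate import SimulationRecipe, simulate_chromatogram
from anacquant.spectra import cosine_similarity, make_uv_spectrum

TIMES = np.linspace(0.0, 30.0, 3001)


class TestBaseline:
    def test_flat_trace(self):
        base = estimate_baseline(np.full_like(TIMES, 5.0), TIMES, window=2.0)
        assert np.max(np.abs(base - 5.0)) < 0.01

    def test_linear_drift_recovered(self):
        drift = np.linspace(0.0, 30.0, TIMES.size)
        base = estimate_baseline(drift, TIMES, window=2.0)
        assert np.max(np.abs(base - drift)) < 0.01 * 30.0

    def test_sits_below_peaks_and_leaves_zero_mean_noise(self):
        rng = np.random.default_rng(0)
        peak = 500.0 * np.exp(-0.5 * ((TIMES - 15.0) / 0.1) ** 2)
        noise = rng.normal(0, 0.05, TIMES.size)
        trace = 2.0 + 0.3 * TIMES + peak + noise
        base = estimate_baseline(trace, TIMES, window=2.0)
        assert np.mean(base <= trace) >= 0.45  # ~half the noise sits below
        quiet = np.abs(TIMES - 15.0) > 1.0
        resid = (trace - base)[quiet]
        assert abs(np.mean(resid)) < 0.05  # re-centred on the noise

    def test_corrected_peak_area_on_drift(self):
        rec = SimulationRecipe(concentrations=(40.0, 0.0, 0.0), noise_sd=0.05,
                               baseline_offset=5.0, baseline_drift=1.0, seed=7)
        chrom, truths = simulate_chromatogram(rec)
        truth = truths[0]
        trace = chrom.trace()
        base = estimate_baseline(trace, chrom.times, window=2.0)
        area = integrate_peak(trace, base, chrom.times,
                              truth.true_rt - 0.5, truth.true_rt + 0.5)
        assert area == pytest.approx(truth.true_area, rel=0.02)

    def test_rejects_window_longer_than_run(self):
        with pytest.raises(ValueError):
            estimate_baseline(np.zeros_like(TIMES), TIMES, window=60.0)


class TestDetectPeaks:
    def _triplet(self, noise_sd, seed=0):
        rec = SimulationRecipe(concentrations=(20.0, 15.0, 60.0),
                               noise_sd=noise_sd, seed=seed)
        return simulate_chromatogram(rec)

    def test_three_disjoint_peaks_found_at_true_rts(self):
        chrom, truths = self._triplet(noise_sd=0.5)  # SNR >> 100
        corrected = chrom.trace()  # baseline is zero here
        found = detect_peaks(corrected, chrom.times, min_snr=5.0)
        assert len(found) == 3
        dt = float(np.median(np.diff(chrom.times)))
        for (apex, _s, _e), truth in zip(found, truths):
            assert abs(apex - truth.true_rt) <= dt + 1e-12

    def test_all_zero_trace_gives_empty_list(self):
        assert detect_peaks(np.zeros_like(TIMES), TIMES) == []

    def test_sub_threshold_peak_not_reported(self):
        # declared noise floor of 1 mAU: a 3 mAU peak is below 5x SNR
        small = 3.0 * np.exp(-0.5 * ((TIMES - 15.0) / 0.1) ** 2)
        assert detect_peaks(small, TIMES, min_snr=5.0, noise_sd=1.0) == []
        tall = 10.0 * np.exp(-0.5 * ((TIMES - 15.0) / 0.1) ** 2)
        assert len(detect_peaks(tall, TIMES, min_snr=5.0, noise_sd=1.0)) == 1

    def test_false_positive_rate_on_pure_noise(self):
        # mean false detections per run well below 0.1 at min_snr = 5
        count = 0
        n_runs = 400
        t = np.linspace(0, 15, 1501)
        for seed in range(n_runs):
            noise = np.random.default_rng(seed).normal(0, 1.0, t.size)
            count += len(detect_peaks(noise, t, min_snr=5.0))
        assert count / n_runs < 0.1


class TestIntegratePeak:
    def test_noiseless_gaussian_against_analytic_area(self):
        y = 1000.0 * np.exp(-0.5 * ((TIMES - 15.0) / 0.1) ** 2)
        area = integrate_peak(y, np.zeros_like(y), TIMES, 14.5, 15.5)
        assert area == pytest.approx(1000.0 * 0.1 * math.sqrt(2 * math.pi),
                                     abs=0.25)

    def test_zero_width_interval(self):
        y = np.ones_like(TIMES)
        assert integrate_peak(y, np.zeros_like(y), TIMES, 15.0, 15.0) == 0.0

    def test_reversed_bounds_rejected(self):
        y = np.ones_like(TIMES)
        with pytest.raises(ValueError):
            integrate_peak(y, np.zeros_like(y), TIMES, 16.0, 15.0)

    def test_triplet_areas_within_one_percent_of_truth(self):
        rec = SimulationRecipe(concentrations=(20.0, 15.0, 60.0),
                               noise_sd=0.05, seed=11)
        chrom, truths = simulate_chromatogram(rec)
        trace = chrom.trace()
        base = estimate_baseline(trace, chrom.times)
        for truth in truths:
            area = integrate_peak(trace, base, chrom.times,
                                  truth.true_rt - 0.5, truth.true_rt + 0.5)
            assert area == pytest.approx(truth.true_area, rel=0.01)

    def test_doubling_concentration_doubles_area(self):
        # proportional (zero-intercept) response, noiseless
        areas = {}
        for scale in (1.0, 2.0):
            rec = SimulationRecipe(
                concentrations=(20.0 * scale, 15.0 * scale, 60.0 * scale),
                response_intercept=0.0, noise_sd=0.0, seed=0)
            chrom, truths = simulate_chromatogram(rec)
            trace = chrom.trace()
            zero = np.zeros_like(trace)
            areas[scale] = [
                integrate_peak(trace, zero, chrom.times,
                               t.true_rt - 0.5, t.true_rt + 0.5)
                for t in truths
            ]
        for a1, a2 in zip(areas[1.0], areas[2.0]):
            assert a2 == pytest.approx(2.0 * a1, rel=1e-3)


def _peak(apex, start, end, height=10.0, area=1.0):
    return Peak(apex, start, end, height, area)


class TestMatchPeaks:
    def test_exact_and_out_of_tolerance(self, catalog):
        peaks = [_peak(11.0, 10.5, 11.5), _peak(13.5 + 0.75, 13.8, 14.8)]
        match_peaks(peaks, catalog, rt_tolerance=0.5)
        assert peaks[0].assigned_analyte.name == "AnAc 15:3"
        assert peaks[1].assigned_analyte is None  # 1.5x tolerance away

    def test_tie_broken_by_larger_area_symmetrically(self, catalog):
        for order in ((0, 1), (1, 0)):
            candidates = [_peak(10.8, 10.3, 11.3, area=1.0),
                          _peak(11.2, 10.7, 11.7, area=5.0)]
            peaks = [candidates[i] for i in order]
            match_peaks(peaks, catalog, rt_tolerance=0.5)
            winners = [p for p in peaks if p.assigned_analyte is not None]
            assert len(winners) == 1
            assert winners[0].area == 5.0
            loser = next(p for p in peaks if p.assigned_analyte is None)
            assert any("ambiguous" in f for f in loser.flags)

    def test_crowded_catalog_rejected(self, catalog):
        with pytest.raises(ValueError):
            match_peaks([], catalog, rt_tolerance=2.0)


class TestExtractSpectrum:
    def test_peakless_region_is_near_zero(self):
        rec = SimulationRecipe(concentrations=(40.0, 0.0, 0.0),
                               noise_sd=0.05, seed=3)
        chrom, _ = simulate_chromatogram(rec)
        spec = extract_spectrum(chrom, 25.0)
        n = chrom.wavelengths.size
        assert np.linalg.norm(spec.values) < 3 * 0.05 * math.sqrt(n)

    def test_between_samples_takes_nearest_row(self):
        rec = SimulationRecipe(concentrations=(40.0, 0.0, 0.0),
                               noise_sd=0.0, seed=0)
        chrom, _ = simulate_chromatogram(rec)
        dt = float(np.median(np.diff(chrom.times)))
        spec = extract_spectrum(chrom, 11.0 + 0.3 * dt)
        np.testing.assert_array_equal(
            spec.values, chrom.absorbance[chrom.time_index(11.0)])

    def test_time_outside_run_rejected(self):
        rec = SimulationRecipe(concentrations=(40.0, 0.0, 0.0), noise_sd=0.0)
        chrom, _ = simulate_chromatogram(rec)
        with pytest.raises(ValueError):
            extract_spectrum(chrom, 31.0)


def _coelution_chromatogram(contaminant_rel_amplitude):
    """Main peak plus a co-eluting contaminant 0.3 sigma later whose single
    UV band sits 50 nm to the red; built directly as a brute-force mixture
    of time profiles x spectra."""
    from anacquant.chromatogram import Chromatogram

    times = np.linspace(9.0, 13.0, 401)
    wavelengths = np.arange(200.0, 401.0)
    main_spec = make_uv_spectrum([280.0], [15.0], [1.0], wavelengths)
    contam_spec = make_uv_spectrum([330.0], [15.0], [1.0], wavelengths)
    sigma = 0.1
    g_main = 1000.0 * np.exp(-0.5 * ((times - 11.0) / sigma) ** 2)
    g_contam = (1000.0 * contaminant_rel_amplitude
                * np.exp(-0.5 * ((times - (11.0 + 0.3 * sigma)) / sigma) ** 2))
    absorb = (g_main[:, None] * main_spec.values[None, :]
              + g_contam[:, None] * contam_spec.values[None, :])
    return Chromatogram(times, wavelengths, absorb), main_spec


class TestPeakPurity:
    def _detected_peak(self, chrom):
        trace = chrom.trace()
        found = detect_peaks(trace, chrom.times, min_snr=5.0)
        apex, start, end = found[0]
        h = trace[chrom.time_index(apex)]
        return Peak(apex, start, end, float(h), 1.0)

    def test_pure_peak_scores_high(self, catalog):
        rec = SimulationRecipe(concentrations=(40.0, 0.0, 0.0),
                               noise_sd=0.02, seed=5)
        chrom, _ = simulate_chromatogram(rec)
        peak = self._detected_peak(chrom)
        res = peak_purity(chrom, peak, catalog[0].uv_profile)
        assert res.purity > 0.99

    def test_reference_equal_to_apex_spectrum_gives_unity_at_apex(self):
        chrom, main_spec = _coelution_chromatogram(0.0)
        peak = self._detected_peak(chrom)
        res = peak_purity(chrom, peak, main_spec)
        assert res.similarities[1] == pytest.approx(1.0, abs=1e-9)

    def test_coeluting_contaminant_fails_threshold(self):
        chrom, main_spec = _coelution_chromatogram(1.0)
        peak = self._detected_peak(chrom)
        res = peak_purity(chrom, peak, main_spec)
        assert res.purity < 0.95

    def test_purity_non_increasing_in_contaminant_amplitude(self):
        purities = []
        for rel in np.linspace(0.0, 1.8, 10):
            chrom, main_spec = _coelution_chromatogram(float(rel))
            peak = self._detected_peak(chrom)
            purities.append(peak_purity(chrom, peak, main_spec).purity)
        diffs = np.diff(purities)
        assert np.all(diffs <= 1e-9)


class TestPipeline:
    def test_pipeline_accuracy_over_seeds(self, catalog):
        """Median area error < 1% and no missed peaks at SNR >= 50."""
        errors = []
        for seed in range(25):
            rec = SimulationRecipe(concentrations=(20.0, 15.0, 60.0),
                                   noise_sd=0.5, baseline_offset=2.0,
                                   baseline_drift=0.2, seed=seed)
            chrom, truths = simulate_chromatogram(rec)
            peaks = process_chromatogram(chrom, catalog)
            by_name = {p.assigned_analyte.name: p for p in peaks
                       if p.assigned_analyte is not None}
            for truth in truths:
                assert truth.analyte.name in by_name, "missed peak"
                p = by_name[truth.analyte.name]
                errors.append(abs(p.area - truth.true_area) / truth.true_area)
        assert np.median(errors) < 0.01
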