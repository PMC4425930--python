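"""Processing chain: each step against its independent oracle, then the batch."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wcms.preprocess import (
    PreprocessParams,
    anchor_prealign,
    baseline_tophat,
    detect_peaks,
    estimate_noise,
    normalize_median_to_one,
    preprocess_experiment,
    smooth_savitzky_golay,
    sqrt_transform,
    warp_align,
)
from wcms.simulate import PeakSpec, SimDesign, make_default_panel, simulate_experiment
from wcms.spectrum import PeakList, RawSpectrum


def _spec(intensity, start=3000.0):
    intensity = np.asarray(intensity, dtype=float)
    return RawSpectrum(start + np.arange(intensity.size), intensity)


# ---------------------------------------------------------------------------
# oracles


def tophat_oracle(x: np.ndarray, half: int) -> np.ndarray:
    """Brute-force morphological opening with truncated edge windows."""
    n = x.size
    eroded = np.array([x[max(0, i - half): i + half + 1].min() for i in range(n)])
    return np.array(
        [eroded[max(0, i - half): i + half + 1].max() for i in range(n)]
    )


def savgol_oracle(x: np.ndarray, window: int, order: int) -> np.ndarray:
    """Per-window least-squares polynomial fit evaluated at the centre."""
    half = window // 2
    out = x.astype(float).copy()
    t = np.arange(window) - half
    for i in range(half, x.size - half):
        coeffs = np.polyfit(t, x[i - half: i + half + 1], order)
        out[i] = np.polyval(coeffs, 0.0)
    return out


# ---------------------------------------------------------------------------


class TestSqrt:
    def test_values(self):
        s = sqrt_transform(_spec([0.0, 4.0, 9.0]))
        assert np.array_equal(s.intensity, [0.0, 2.0, 3.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sqrt_transform(RawSpectrum(np.array([1.0, 2.0]), np.array([1.0, -0.5])))

    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=50))
    @settings(max_examples=30, derandomize=True)
    def test_preserves_intensity_order(self, values):
        s = sqrt_transform(_spec(values))
        orig = np.argsort(np.asarray(values), kind="stable")
        assert np.array_equal(np.argsort(s.intensity, kind="stable"), orig)


class TestSavitzkyGolay:
    def test_polynomials_reproduced_exactly(self):
        x = np.arange(101, dtype=float)
        for order, poly in [(2, 1 + 2 * x + 3 * x**2), (3, x**3 / 50 - x)]:
            sm = smooth_savitzky_golay(_spec(poly), 11, 3)
            interior = slice(5, -5)
            assert np.allclose(sm.intensity[interior], poly[interior], rtol=1e-9)

    def test_constant_unchanged(self):
        sm = smooth_savitzky_golay(_spec(np.full(60, 7.0)), 21, 3)
        assert np.allclose(sm.intensity, 7.0)

    def test_matches_local_least_squares_oracle(self, rng):
        x = rng.random(101)
        sm = smooth_savitzky_golay(_spec(x), 7, 3)
        expected = savgol_oracle(x, 7, 3)
        assert np.allclose(sm.intensity[3:-3], expected[3:-3], atol=1e-10)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            smooth_savitzky_golay(_spec(np.ones(50)), 10, 3)  # even window
        with pytest.raises(ValueError):
            smooth_savitzky_golay(_spec(np.ones(50)), 7, 9)  # order >= window
        with pytest.raises(ValueError):
            smooth_savitzky_golay(_spec(np.ones(5)), 21, 3)  # too short


class TestTopHat:
    def test_constant_signal_fully_removed(self):
        baseline, corrected = baseline_tophat(_spec(np.full(300, 5.0)), 20.0)
        assert np.allclose(baseline, 5.0)
        assert np.allclose(corrected.intensity, 0.0)

    def test_narrow_peak_preserved_on_zero_baseline(self):
        x = np.zeros(400)
        x[200] = 10.0  # far narrower than the structuring element
        baseline, corrected = baseline_tophat(_spec(x), 50.0)
        assert np.allclose(baseline, 0.0)
        assert corrected.intensity[200] == pytest.approx(10.0)

    def test_triangular_peak_on_ramp_matches_oracle(self):
        n = 500
        ramp = 0.01 * np.arange(n)
        tri = np.clip(30 - np.abs(np.arange(n) - 250), 0, None) / 3
        x = ramp + tri
        baseline, corrected = baseline_tophat(_spec(x), 75.0)
        expected = tophat_oracle(x, 75)
        assert np.allclose(baseline, expected, atol=1e-12)
        assert np.allclose(corrected.intensity, np.clip(x - expected, 0, None))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_random_spectra_match_oracle_and_stay_below_signal(self, seed):
        g = np.random.default_rng(seed)
        x = g.random(300) + np.sin(np.arange(300) / 40)
        x -= x.min()
        half = int(g.integers(3, 40))
        baseline, corrected = baseline_tophat(_spec(x), float(half))
        assert np.allclose(baseline, tophat_oracle(x, half), atol=1e-12)
        assert np.all(baseline <= x + 1e-12)

    def test_half_window_below_grid_step_rejected(self):
        with pytest.raises(ValueError):
            baseline_tophat(_spec(np.ones(100)), 0.2)


class TestNoise:
    def test_all_zero_spectrum_gets_positive_floor(self):
        noise = estimate_noise(_spec(np.zeros(1000)), 200.0)
        assert np.all(noise > 0)

    def test_gaussian_noise_level_recovered(self, rng):
        x = rng.standard_normal(8000)
        noise = estimate_noise(_spec(x), 2000.0)
        interior = noise[1000:-1000]
        assert 0.9 <= interior.mean() <= 1.1

    def test_homogeneous_in_scale(self, rng):
        x = rng.standard_normal(2000)
        n1 = estimate_noise(_spec(x), 300.0)
        n2 = estimate_noise(_spec(7.0 * x), 300.0)
        assert np.allclose(n2, 7.0 * n1, rtol=1e-9)


class TestDetectPeaks:
    def test_flat_spectrum_yields_no_peaks(self):
        peaks = detect_peaks(_spec(np.zeros(500)))
        assert len(peaks) == 0

    def test_default_snr_threshold_is_three(self):
        assert PreprocessParams().snr_threshold == 3.0

    def test_planted_gaussians_at_snr_ten_all_found_no_extras(self, rng):
        # baseline-corrected signal (the documented precondition): planted
        # Gaussians at SNR 10 on clipped unit noise
        n = 8000
        mz = 3000.0 + np.arange(n)
        x = rng.standard_normal(n)
        centers = np.linspace(4000, 10500, 10)
        for c in centers:
            x += 10.0 * np.exp(-0.5 * ((mz - c) / 2.0) ** 2)
        s = RawSpectrum(mz, np.clip(x, 0.0, None))
        peaks = detect_peaks(s, PreprocessParams(), noise=np.ones(n))
        found = [np.min(np.abs(peaks.mz - c)) <= 1.0 for c in centers]
        assert all(found)
        strong = peaks.mz[peaks.snr >= 5]
        assert all(np.min(np.abs(centers - m)) <= 10.0 for m in strong)


class TestNormalize:
    def test_median_definition(self):
        s = _spec(np.ones(10))
        peaks = PeakList(
            np.array([3001.0, 3004.0, 3007.0]),
            np.array([2.0, 4.0, 8.0]),
            np.ones(3),
        )
        s2, p2 = normalize_median_to_one(s, peaks)
        assert np.array_equal(p2.intensity, [0.5, 1.0, 2.0])
        assert np.median(p2.intensity) == 1.0
        assert np.allclose(s2.intensity, 0.25)

    def test_idempotent_once_normalized(self):
        peaks = PeakList(np.array([3001.0, 3004.0]), np.array([0.5, 1.0]), np.ones(2))
        s = _spec(np.ones(10))
        s2, p2 = normalize_median_to_one(s, peaks)
        s3, p3 = normalize_median_to_one(s2, p2)
        assert np.allclose(p3.intensity, p2.intensity)

    @given(st.floats(1e-6, 1e6))
    @settings(max_examples=30, derandomize=True)
    def test_scale_invariant(self, k):
        base = np.array([1.0, 3.0, 9.0])
        peaks = PeakList(np.array([3001.0, 3004.0, 3007.0]), base, np.ones(3))
        scaled = PeakList(np.array([3001.0, 3004.0, 3007.0]), k * base, np.ones(3))
        _, p1 = normalize_median_to_one(_spec(np.ones(10)), peaks)
        _, p2 = normalize_median_to_one(_spec(np.ones(10)), scaled)
        assert np.allclose(p1.intensity, p2.intensity, rtol=1e-12)

    def test_empty_or_zero_median_rejected(self):
        s = _spec(np.ones(10))
        with pytest.raises(ValueError):
            normalize_median_to_one(s, PeakList(np.array([]), np.array([]), np.array([])))
        zero = PeakList(np.array([3001.0]), np.array([0.0]), np.ones(1))
        with pytest.raises(ValueError):
            normalize_median_to_one(s, zero)


class TestAnchorPrealign:
    def _peaks_at(self, masses):
        masses = np.asarray(masses, dtype=float)
        return PeakList(masses, np.ones(masses.size), np.full(masses.size, 10.0))

    def test_already_aligned_is_identity(self):
        s = RawSpectrum(np.linspace(3000, 30000, 2701), np.ones(2701))
        peaks = self._peaks_at([4078.8, 14019.1])
        s2, _, info = anchor_prealign(s, peaks)
        assert info["slope"] == pytest.approx(1.0, abs=1e-9)
        assert info["offset"] == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(s2.mz, s.mz)

    def test_constant_shift_recovered(self):
        s = RawSpectrum(np.linspace(3000, 30000, 2701) + 2.0, np.ones(2701))
        peaks = self._peaks_at([4080.8, 14021.1])  # anchors shifted by +2
        s2, p2, info = anchor_prealign(s, peaks)
        assert info["offset"] == pytest.approx(-2.0, abs=0.51)
        assert abs(p2.mz[0] - 4078.8) <= 0.5
        assert abs(p2.mz[1] - 14019.1) <= 0.5

    def test_default_anchor_masses(self):
        assert PreprocessParams().anchor_masses == (4078.8, 14019.1)

    def test_no_match_falls_back_to_identity(self):
        s = RawSpectrum(np.linspace(3000, 30000, 2701), np.ones(2701))
        peaks = self._peaks_at([9999.0])
        s2, _, info = anchor_prealign(s, peaks)
        assert info["slope"] == 1.0 and info["offset"] == 0.0
        assert np.array_equal(s2.mz, s.mz)


class TestWarpAlign:
    def test_identical_spectra_align_to_identity(self):
        mz = np.linspace(3000, 30000, 2701)
        masses = np.linspace(4000, 28000, 30)
        peaks = PeakList(masses, np.ones(30), np.full(30, 10.0))
        spectra = [RawSpectrum(mz, np.ones(2701)) for _ in range(4)]
        peaklists = [
            PeakList(masses.copy(), np.ones(30), np.full(30, 10.0)) for _ in range(4)
        ]
        aligned, aligned_peaks, infos = warp_align(spectra, peaklists)
        for s, p in zip(aligned, aligned_peaks):
            assert np.allclose(s.mz, mz, atol=1e-9)
            assert np.allclose(p.mz, masses, atol=1e-9)

    def test_quadratic_warps_recovered_without_noise(self):
        """The simulator's bounded quadratic warps are undone to <= 0.5 Da."""
        design = SimDesign(
            n_donors=2,
            seed=13,
            noise_sigma_rel=0.0,
            population_effect_sd=0.0,
            donor_sd=0.0,
            donor_peak_sd=0.0,
            replicate_sd=0.0,
            peak_jitter_sd=0.0,
        )
        panel = make_default_panel(30, 0, 0, 0, seed=13)
        spectra, truth = simulate_experiment(design, panel)
        _, peaklists = preprocess_experiment(spectra)
        true_masses = truth.true_masses()
        residuals = []
        for pk in peaklists:
            for m in true_masses:
                j = np.argmin(np.abs(pk.mz - m))
                if abs(pk.mz[j] - m) < 10:
                    residuals.append(abs(pk.mz[j] - m))
        assert np.median(residuals) <= 0.5
        assert np.quantile(residuals, 0.95) <= 1.0

    def test_alignment_shrinks_reference_peak_spread(self):
        design = SimDesign(n_donors=2, seed=17, population_effect_sd=0.0)
        panel = make_default_panel(25, 0, 0, 0, seed=17)
        spectra, truth = simulate_experiment(design, panel)
        states, peaklists = preprocess_experiment(spectra)
        true_masses = truth.true_masses()

        def spread(lists):
            out = []
            for m in true_masses:
                obs = []
                for pk in lists:
                    j = np.argmin(np.abs(pk.mz - m))
                    if abs(pk.mz[j] - m) < 15:
                        obs.append(pk.mz[j])
                if len(obs) > 2:
                    out.append(np.std(obs))
            return np.mean(out)

        assert spread(peaklists) <= 2.0  # aligned spread is small in absolute terms

    def test_warped_axes_strictly_increasing(self, study):
        truth, peaklists, _ = study
        for pk in peaklists:
            assert np.all(np.diff(pk.mz) > 0)


class TestChainContract:
    def test_provenance_records_pipeline_order(self):
        design = SimDesign(n_donors=1, seed=19)
        panel = make_default_panel(15, 0, 0, 0, seed=19)
        spectra, _ = simulate_experiment(design, panel)
        states, _ = preprocess_experiment(spectra[:4])
        steps = [step for step, _ in states[0].provenance]
        assert steps == [
            "crop",
            "sqrt_transform",
            "smooth_savitzky_golay",
            "baseline_tophat",
            "estimate_noise",
            "detect_peaks_provisional",
            "normalize_median_to_one",
            "anchor_prealign",
            "warp_align",
            "detect_peaks_final",
        ]

    def test_end_to_end_recovery_and_false_discovery(self, study):
        """>= 95% of planted SNR>=5 peaks recovered; per-spectrum FDR <= 10%."""
        from wcms.evaluate import match_within

        truth, peaklists, _ = study
        masses = truth.true_masses()
        _, min_snr = truth.min_planted_snr()
        rec, fdr = [], []
        for pk in peaklists:
            meta = pk.meta
            fdr.append(1.0 - match_within(pk.mz, masses, 0.002).mean())
        # recovery at the feature level is checked in the acceptance suite;
        # here: per-spectrum detection of confidently planted peaks
        strong = masses[min_snr >= 5]
        for pk in peaklists[:20]:
            rec.append(match_within(strong, pk.mz, 0.002).mean())
        assert np.mean(rec) >= 0.95
        assert np.mean(fdr) <= 0.10
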