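"""Load-response analysis: threshold rule, stability, trend, Spearman."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import tremorkit as tk
from tremorkit.exceptions import DataError


def steps_from(dominances, loads=None, freqs=None, heights=None):
    loads = loads or [10.0 * (i + 1) for i in range(len(dominances))]
    freqs = freqs or [15.0] * len(dominances)
    heights = heights or [1.0] * len(dominances)
    return [
        tk.LoadStep(
            load_kg=l,
            result=tk.TremorPeakResult(
                peak_frequency_hz=f, peak_height=h, dominance=d,
                tremor_present=d >= 0.5,
            ),
        )
        for l, d, f, h in zip(loads, dominances, freqs, heights)
    ]


class TestDetectLoadThreshold:
    def test_sustained_onset(self, cfg):
        steps = steps_from([0.1, 0.1, 0.2, 0.8, 0.9, 0.95])
        assert tk.detect_load_threshold(steps, cfg) == 40.0

    def test_never_sustained_is_absent(self, cfg):
        steps = steps_from([0.1, 0.2, 0.3, 0.4, 0.45, 0.2, 0.1, 0.3, 0.2, 0.1])
        assert tk.detect_load_threshold(steps, cfg) is None

    def test_isolated_exceedance_does_not_count(self, cfg):
        steps = steps_from([0.1, 0.8, 0.2, 0.9, 0.9])
        assert tk.detect_load_threshold(steps, cfg) == 40.0

    def test_empty_series_raises(self, cfg):
        with pytest.raises(DataError):
            tk.detect_load_threshold([], cfg)

    @given(
        doms=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10),
        cut_lo=st.floats(0.05, 0.9),
        delta=st.floats(0.0, 0.09),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_threshold_monotone_in_cutoff(self, doms, cut_lo, delta):
        """Raising the dominance cutoff never lowers the detected threshold."""
        steps = steps_from(doms)
        lo = tk.detect_load_threshold(steps, tk.AnalysisConfig(dominance_cutoff=cut_lo))
        hi = tk.detect_load_threshold(
            steps, tk.AnalysisConfig(dominance_cutoff=cut_lo + delta)
        )
        if hi is not None:
            assert lo is not None and lo <= hi


class TestFrequencyStability:
    def test_all_within_tolerance(self, cfg):
        steps = steps_from(
            [0.1, 0.8, 0.9, 0.9], freqs=[12.0, 15.3, 15.4, 15.3]
        )
        assert tk.frequency_stability(steps, 15.31, threshold_kg=20.0, cfg=cfg)

    def test_one_outlier_fails(self, cfg):
        steps = steps_from([0.1, 0.8, 0.9], freqs=[12.0, 17.2, 15.3])
        assert not tk.frequency_stability(steps, 15.31, threshold_kg=20.0, cfg=cfg)

    def test_no_supra_threshold_steps_is_error(self, cfg):
        steps = steps_from([0.1, 0.2])
        with pytest.raises(DataError):
            tk.frequency_stability(steps, 15.0, threshold_kg=50.0, cfg=cfg)


class TestAmplitudeTrend:
    def test_strictly_increasing_heights(self):
        steps = steps_from([0.9] * 5, heights=[1, 2, 3, 4, 5])
        assert tk.amplitude_trend(steps, threshold_kg=10.0) == pytest.approx(1.0)

    def test_strictly_decreasing_heights(self):
        steps = steps_from([0.9] * 5, heights=[5, 4, 3, 2, 1])
        assert tk.amplitude_trend(steps, threshold_kg=10.0) == pytest.approx(-1.0)

    def test_insufficient_steps_returns_none(self):
        steps = steps_from([0.9, 0.9], heights=[1, 2])
        assert tk.amplitude_trend(steps, threshold_kg=10.0) is None


class TestSpearmanCorrelation:
    def test_perfect_monotone_with_exact_p(self):
        rho, p = tk.spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)  # 2 of 4! orderings reach |rho| = 1

    def test_perfect_antitone(self):
        rho, _ = tk.spearman_correlation([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_matches_brute_force(self, n):
        """Exact permutation p equals enumeration over all n! orderings of
        the raw data (independent route: scipy rho per permutation)."""
        rng = np.random.default_rng(n)
        a, b = rng.normal(size=n), rng.normal(size=n)
        rho, p = tk.spearman_correlation(a, b)
        obs = abs(stats.spearmanr(a, b).statistic)
        hits = sum(
            abs(stats.spearmanr(a, perm).statistic) >= obs - 1e-12
            for perm in permutations(b)
        )
        assert rho == pytest.approx(stats.spearmanr(a, b).statistic, abs=1e-12)
        assert p == pytest.approx(hits / math.factorial(n), abs=1e-12)

    def test_tie_free_rho_matches_closed_form(self):
        rng = np.random.default_rng(99)
        a, b = rng.normal(size=6), rng.normal(size=6)
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        d2 = float(np.sum((ra - rb) ** 2))
        expected = 1 - 6 * d2 / (6 * 35)  # 1 - 6*sum d^2 / (n(n^2-1))
        rho, _ = tk.spearman_correlation(a, b)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_ties_use_average_ranks(self):
        a = [1, 2, 2, 3, 4]
        b = [5, 5, 7, 8, 9]
        rho, _ = tk.spearman_correlation(a, b, exact_p=False)
        assert rho == pytest.approx(stats.spearmanr(a, b).statistic, abs=1e-12)

    def test_large_sample_p_matches_t_approximation(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=30), rng.normal(size=30)
        rho, p = tk.spearman_correlation(a, b)
        ref = stats.spearmanr(a, b)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_undefined(self):
        rho, p = tk.spearman_correlation([1.0, 1.0, 1.0], [1, 2, 3])
        assert math.isnan(rho) and math.isnan(p)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            tk.spearman_correlation([1, 2, 3], [1, 2])


class TestAnalyzeLoadSeries:
    def test_responder_end_to_end(self, cfg, scenario):
        prof = tk.SubjectProfile("s2", 14.89, threshold_kg=40.0)
        recs = tk.simulate_load_series(prof, scenario, seed=21, include_standing=True)
        res = tk.analyze_load_series(recs[1:], cfg, standing=recs[0])
        assert res.threshold_kg in (40.0, 50.0)
        assert res.stable_frequency is True
        assert res.amplitude_trend_rho is not None and -1 <= res.amplitude_trend_rho <= 1
        assert [s.load_kg for s in res.steps] == sorted(s.load_kg for s in res.steps)

    def test_non_responder_has_absent_threshold(self, cfg, scenario):
        prof = tk.SubjectProfile("s5", 15.41, threshold_kg=None)
        recs = tk.simulate_load_series(prof, scenario, seed=22)
        res = tk.analyze_load_series(recs, cfg)
        assert res.threshold_kg is None
        assert res.stable_frequency is None
        assert res.amplitude_trend_rho is None

    def test_rejects_mislabelled_recordings(self, cfg, scenario):
        prof = tk.SubjectProfile("s1", 15.0)
        rec = tk.simulate_recording(
            prof, tk.RecordingLabel("s1", "standing"), scenario, seed=23
        )
        with pytest.raises(DataError):
            tk.analyze_load_series([rec], cfg)
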