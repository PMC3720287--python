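"""Chromatogram correction, peak detection and alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbomirror.chrom import (
    AlignedPeakMatrix,
    Chromatogram,
    PeakList,
    align_peaks,
    correct_baseline,
    detect_peaks,
    estimate_noise,
    peak_count_summary,
    smooth,
)
from herbomirror.synth import SyntheticDesign, generate_chromatograms


def make_chrom(y, sample_id="s", rt=None):
    y = np.asarray(y, dtype=float)
    if rt is None:
        rt = np.arange(y.size, dtype=float)
    return Chromatogram(rt, y, sample_id)


class TestChromatogramValidation:
    def test_rejects_nonmonotone_rt(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Chromatogram(np.array([0, 1, 1, 2, 3, 4, 5, 6.0]), np.zeros(8), "s")

    def test_rejects_short_trace(self):
        with pytest.raises(ValueError, match="8 points"):
            Chromatogram(np.arange(5.0), np.zeros(5), "s")

    def test_rejects_unknown_technique(self):
        with pytest.raises(ValueError, match="technique"):
            Chromatogram(np.arange(8.0), np.zeros(8), "s", technique="GC-FID")


class TestSmooth:
    def test_single_spike_window3(self):
        # hand computation: centered mean spreads a spike of 3 into 1,1,1
        c = make_chrom([0, 0, 3, 0, 0, 0, 0, 0])
        out = smooth(c, 3)
        np.testing.assert_allclose(out.intensity[:5], [0, 1, 1, 1, 0])

    def test_constant_trace_unchanged(self):
        c = make_chrom(np.full(20, 7.5))
        np.testing.assert_allclose(smooth(c, 5).intensity, 7.5)

    def test_window_one_is_identity(self):
        c = make_chrom(np.arange(10.0) ** 2)
        np.testing.assert_array_equal(smooth(c, 1).intensity, c.intensity)

    @pytest.mark.parametrize("window", [2, 4, 101])
    def test_invalid_window_fails(self, window):
        c = make_chrom(np.zeros(12))
        with pytest.raises(ValueError):
            smooth(c, window)

    def test_rt_unchanged(self):
        c = make_chrom(np.random.default_rng(0).normal(size=30))
        np.testing.assert_array_equal(smooth(c, 7).rt, c.rt)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_mean_preserved_in_interior(self, seed):
        # away from the shrinking ends the moving average is exact
        y = np.random.default_rng(seed).normal(size=50)
        c = make_chrom(y)
        out = smooth(c, 5).intensity
        i = 25
        assert out[i] == pytest.approx(y[i - 2 : i + 3].mean())


class TestBaseline:
    def test_linear_ramp_mostly_removed(self):
        n = 1000
        slope_per_point = 0.01
        c = make_chrom(slope_per_point * np.arange(n))
        out = correct_baseline(c, 0.10).intensity
        # the rolling-min envelope lags a ramp by about half a window
        grid_error = 0.10 * n * slope_per_point
        assert np.max(np.abs(out)) <= 2 * grid_error

    def test_peak_height_preserved_offset_removed(self):
        rt = np.linspace(0, 20, 2000)
        peak = 80.0 * np.exp(-0.5 * ((rt - 10) / 0.1) ** 2)
        c = Chromatogram(rt, peak + 5.0, "s")
        out = correct_baseline(c, 0.10)
        assert out.intensity.max() == pytest.approx(80.0, rel=0.01)
        assert abs(np.median(out.intensity)) < 0.5  # offset gone

    def test_baseline_free_trace_unchanged(self):
        rt = np.linspace(0, 20, 2000)
        peak = 60.0 * np.exp(-0.5 * ((rt - 8) / 0.1) ** 2)
        c = Chromatogram(rt, peak, "s")
        out = correct_baseline(c, 0.10)
        np.testing.assert_allclose(out.intensity, peak, atol=0.5)

    def test_invalid_fraction_fails(self):
        c = make_chrom(np.zeros(20))
        with pytest.raises(ValueError):
            correct_baseline(c, 0.0)

    def test_clip_negative(self):
        y = np.sin(np.linspace(0, 10, 100))
        out = correct_baseline(make_chrom(y), 0.2, clip_negative=True)
        assert np.all(out.intensity >= 0)


def brute_force_peaks(rt, y, snr_min, min_separation):
    """Independent exhaustive scan: strict local maxima, SNR filter,
    tall-first merge within min_separation."""
    noise = 1.4826 * np.median(np.abs(np.diff(y))) / np.sqrt(2)
    maxima = [
        i
        for i in range(1, len(y) - 1)
        if y[i] > y[i - 1] and y[i] > y[i + 1] and y[i] > 0 and y[i] >= snr_min * noise
    ]
    kept = []
    for i in sorted(maxima, key=lambda i: -y[i]):
        if all(abs(rt[i] - rt[j]) >= min_separation for j in kept):
            kept.append(i)
    return sorted(kept)


class TestDetectPeaks:
    def test_flat_trace_no_peaks(self):
        assert len(detect_peaks(make_chrom(np.zeros(50)))) == 0

    def test_single_gaussian(self, clean_peak_trace):
        pl = detect_peaks(clean_peak_trace)
        assert len(pl) == 1
        grid = clean_peak_trace.rt[1] - clean_peak_trace.rt[0]
        assert abs(pl.apex_rt[0] - 4.0) <= grid
        assert pl.height[0] == pytest.approx(50.0, rel=0.01)

    def test_matches_brute_force_oracle(self):
        design = SyntheticDesign(
            seed=3, n_marker_peaks_per_group=0, baseline_amplitude=0.0,
            rt_jitter_sd=0.0, noise_sd=0.3,
        )
        chroms, _ = generate_chromatograms(design)
        for c in chroms[:4]:
            pl = detect_peaks(c, 3.0, 0.1)
            oracle = brute_force_peaks(c.rt, c.intensity, 3.0, 0.1)
            assert len(pl) == len(oracle)
            np.testing.assert_allclose(pl.height, c.intensity[oracle])

    def test_recovers_planted_count(self):
        # 20 backbone peaks, tiny noise, no jitter: exactly 20 apexes each
        design = SyntheticDesign(
            seed=11, n_backbone_peaks=20, n_marker_peaks_per_group=0,
            baseline_amplitude=0.0, rt_jitter_sd=0.0,
            noise_sd=0.01 * 30.0, within_group_cv=0.0,
        )
        chroms, _ = generate_chromatograms(design)
        for c in chroms:
            # pipeline composition: smoothing suppresses noise maxima, the
            # SNR threshold uses the raw-trace noise estimate
            noise = estimate_noise(c.intensity)
            assert len(detect_peaks(smooth(c, 5), 3.0, 0.1, noise=noise)) == 20

    def test_scale_equivariance(self, clean_peak_trace):
        rng = np.random.default_rng(5)
        y = clean_peak_trace.intensity + rng.normal(0, 0.5, clean_peak_trace.rt.size)
        base = detect_peaks(make_chrom(y, rt=clean_peak_trace.rt))
        for c_factor in (0.1, 7.0):
            scaled = detect_peaks(make_chrom(c_factor * y, rt=clean_peak_trace.rt))
            assert len(scaled) == len(base)
            np.testing.assert_allclose(scaled.apex_rt, base.apex_rt)
            np.testing.assert_allclose(scaled.height, c_factor * base.height, rtol=1e-12)

    def test_close_maxima_merged_keeping_taller(self):
        rt = np.linspace(0, 1, 100)
        y = np.zeros(100)
        y[[40, 43]] = [5.0, 8.0]
        pl = detect_peaks(Chromatogram(rt, y, "s"), snr_min=0.1, min_separation=0.1)
        assert len(pl) == 1
        assert pl.height[0] == 8.0


class TestAlignPeaks:
    def make_list(self, rts, heights, sid):
        rts = np.asarray(rts, float)
        h = np.asarray(heights, float)
        return PeakList(rts, h, np.full(rts.size, 10.0), sid)

    def test_identical_lists_dense(self):
        pl = self.make_list([1.0, 2.0, 3.0], [5, 6, 7], "a")
        m = align_peaks({s: self.make_list([1, 2, 3.0], [5, 6, 7], s) for s in "abc"})
        assert m.n_peaks == 3
        assert np.all(m.heights > 0)
        np.testing.assert_allclose(m.consensus_rt, [1, 2, 3])

    def test_jitter_below_half_tol_keeps_columns(self, rng):
        base = np.array([1.0, 3.0, 5.0, 7.0])
        lists = {}
        for s in range(6):
            jit = rng.uniform(-0.09, 0.09, base.size)  # < rt_tol/2 = 0.1
            lists[f"s{s}"] = self.make_list(np.sort(base + jit), np.full(4, 5.0), f"s{s}")
        m = align_peaks(lists, rt_tol=0.2)
        assert m.n_peaks == 4

    def test_disjoint_lists_complementary(self):
        a = self.make_list([1.0, 2.0], [5, 5], "a")
        b = self.make_list([10.0, 20.0, 30.0], [5, 5, 5], "b")
        m = align_peaks({"a": a, "b": b}, rt_tol=0.2)
        assert m.n_peaks == 5
        assert np.all((m.heights > 0).sum(axis=0) == 1)

    def test_order_invariance(self, default_chrom_set):
        _, chroms, _ = default_chrom_set
        pls = {c.sample_id: detect_peaks(correct_baseline(c), noise=estimate_noise(c.intensity))
               for c in chroms}
        m1 = align_peaks(pls, 0.2)
        shuffled = {k: pls[k] for k in reversed(list(pls))}
        m2 = align_peaks(shuffled, 0.2)
        assert m1.n_peaks == m2.n_peaks
        df1 = m1.to_frame().sort_index()
        df2 = m2.to_frame().sort_index()
        np.testing.assert_allclose(df1.to_numpy(), df2[df1.columns].to_numpy())

    def test_empty_input_fails(self):
        with pytest.raises(ValueError):
            align_peaks({})


class TestPeakCountSummary:
    def test_no_spread(self):
        pls = [PeakList(np.arange(9.0), np.ones(9), np.ones(9), str(i)) for i in range(3)]
        out = peak_count_summary({"LC-MS": pls})
        assert out.loc["LC-MS", "mean_peaks"] == 9
        assert out.loc["LC-MS", "sd_peaks"] == 0

    def test_hand_computed_sd(self):
        def pl(n):
            return PeakList(np.arange(float(n)), np.ones(n), np.ones(n))

        out = peak_count_summary({"HPTLC": [pl(8), pl(10), pl(12)]})
        assert out.loc["HPTLC", "mean_peaks"] == 10
        assert out.loc["HPTLC", "sd_peaks"] == 2  # sample sd of (8,10,12)

    def test_single_sample_flagged(self):
        out = peak_count_summary({"LC-PDA": [PeakList(np.arange(4.0), np.ones(4), np.ones(4))]})
        assert out.loc["LC-PDA", "sd_peaks"] == 0
        assert bool(out.loc["LC-PDA", "single_sample"])
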