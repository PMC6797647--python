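"""Power spectra, spectral smoothing and respiration-rejecting peak selection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pulsecam import (
    EstimationError,
    Peak,
    PowerSpectrum,
    estimate_hr,
    find_peaks,
    power_spectrum,
    select_hr_peak,
    smooth_spectrum,
)
from pulsecam.ica import ComponentSet


def _spectrum(power, bin_width=2.5):
    power = np.asarray(power, dtype=float)
    return PowerSpectrum(
        bpm=np.arange(len(power)) * bin_width, power=power, bin_width_bpm=bin_width
    )


def _component_set(signals, fps=30.0):
    arr = np.atleast_2d(np.asarray(signals, dtype=float))
    return ComponentSet(components=arr, fps=fps, mixing=np.zeros((3, arr.shape[0])))


class TestPowerSpectrum:
    def test_on_bin_sinusoid_peak_location(self):
        t = np.arange(720) / 30.0
        spec = power_spectrum(np.sin(2 * np.pi * 1.25 * t), fps=30)
        assert spec.bin_width_bpm == pytest.approx(2.5)
        assert spec.bpm[np.argmax(spec.power)] == pytest.approx(75.0)

    def test_oracle_discrete_fourier_sum(self):
        """Peak power agrees with the directly computed Fourier sum."""
        t = np.arange(720) / 30.0
        x = np.sin(2 * np.pi * 1.25 * t)
        spec = power_spectrum(x, fps=30)
        k = int(round(1.25 * 720 / 30))
        dft_k = np.sum((x - x.mean()) * np.exp(-2j * np.pi * k * np.arange(720) / 720))
        assert spec.power[k] == pytest.approx(np.abs(dft_k) ** 2, rel=1e-10)

    def test_parseval_white_noise(self, rng):
        x = rng.normal(size=1024)
        spec = power_spectrum(x, fps=30)
        xc = x - x.mean()
        # one-sided: double every bin except DC and Nyquist
        w = np.full(len(spec.power), 2.0)
        w[0] = 1.0
        w[-1] = 1.0  # even length: last bin is Nyquist
        total = np.sum(w * spec.power) / len(x)
        assert total == pytest.approx(np.sum(xc**2), rel=0.05)

    def test_zero_signal_zero_power(self):
        spec = power_spectrum(np.zeros(128), fps=30)
        assert np.all(spec.power == 0)

    def test_too_short(self):
        with pytest.raises(ValueError, match="64"):
            power_spectrum(np.zeros(32), fps=30)


class TestSmoothSpectrum:
    def test_constant_unchanged(self):
        spec = _spectrum(np.full(400, 3.3))
        out = smooth_spectrum(spec)
        np.testing.assert_allclose(out.power, 3.3, atol=1e-6)

    def test_isolated_delta_does_not_shift(self):
        p = np.zeros(400)
        p[30] = 1.0
        out = smooth_spectrum(_spectrum(p))
        assert abs(int(np.argmax(out.power)) - 30) <= 1
        assert out.power[30] < 1.0  # widened, lower bump

    def test_doublet_merges_to_single_maximum(self):
        p = np.zeros(400)
        p[30] = 1.0
        p[32] = 1.0
        out = smooth_spectrum(_spectrum(p))
        peaks = find_peaks(out, band_bpm=(out.bpm[25], out.bpm[37]))
        assert len(peaks) == 1
        assert out.bpm[30] <= peaks[0].bpm <= out.bpm[32]

    def test_delta_response_superposition(self):
        """Smoothing is linear (before clipping): the doublet response is
        the sum of shifted single-delta responses."""
        single = np.zeros(400)
        single[30] = 1.0
        r1 = smooth_spectrum(_spectrum(single)).power
        shifted = np.roll(single, 2)
        r2 = smooth_spectrum(_spectrum(shifted)).power
        both = single + shifted
        r12 = smooth_spectrum(_spectrum(both)).power
        # compare only around the deltas, where no negative ripple is clipped
        np.testing.assert_allclose(r12[28:35], (r1 + r2)[28:35], atol=1e-8)

    def test_nonnegative_output(self, rng):
        p = rng.exponential(size=300)
        out = smooth_spectrum(_spectrum(p))
        assert np.all(out.power >= 0)

    def test_gain_matches_analytic_butterworth(self):
        """Ripple attenuation along the bin axis follows the analytic
        zero-phase Butterworth response from passband through cutoff."""
        order, wn = 3, 0.2
        fc = wn / 2.0  # cycles per bin
        n = 4096
        k = np.arange(n)
        for u in [0.0125, 0.025, 0.05, 0.075, 0.1]:
            p = 10.0 + np.sin(2 * np.pi * u * k)
            out = smooth_spectrum(_spectrum(p), order=order, cutoff_setting=wn)
            sl = slice(n // 4, -n // 4)
            basis = np.column_stack([np.sin(2 * np.pi * u * k), np.cos(2 * np.pi * u * k)])
            coef, *_ = np.linalg.lstsq(basis[sl], out.power[sl] - 10.0, rcond=None)
            gain = float(np.hypot(*coef))
            expected = 1.0 / (1.0 + (u / fc) ** (2 * order))  # |H|^2: zero-phase
            assert gain == pytest.approx(expected, abs=0.02)

    def test_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            smooth_spectrum(_spectrum(np.ones(8)))


class TestFindPeaks:
    def test_monotone_spectrum_empty(self):
        assert find_peaks(_spectrum(np.linspace(0, 1, 200))) == []

    def test_single_interior_bump(self):
        p = np.exp(-0.5 * ((np.arange(200) - 40) / 3.0) ** 2)
        peaks = find_peaks(_spectrum(p))
        assert len(peaks) == 1
        assert peaks[0].bpm == pytest.approx(100.0)  # bin 40 * 2.5

    def test_two_bumps_sorted_by_height(self):
        x = np.arange(200)
        p = 1.0 * np.exp(-0.5 * ((x - 24) / 2.0) ** 2) + 0.8 * np.exp(
            -0.5 * ((x - 48) / 2.0) ** 2
        )
        peaks = find_peaks(_spectrum(p))
        assert [round(q.bpm) for q in peaks] == [60, 120]
        assert peaks[0].height == pytest.approx(1.0, abs=0.01)
        assert peaks[1].height == pytest.approx(0.8, abs=0.01)

    def test_plateau_reported_once_at_center(self):
        p = np.zeros(200)
        p[40:45] = 1.0
        peaks = find_peaks(_spectrum(p))
        assert len(peaks) == 1
        assert peaks[0].bpm == pytest.approx(42 * 2.5)

    def test_band_edge_is_not_a_peak(self):
        p = np.linspace(1, 0, 200)  # decreasing: max at the band's left edge
        assert find_peaks(_spectrum(p), band_bpm=(40, 200)) == []


def _rule_oracle(peaks, cutoff=90.0, ratio=0.70):
    """Direct transcription of the selection rule, independent of the
    implementation's structure."""
    top = max(peaks, key=lambda p: p.height)
    candidates = [p for p in peaks if p.bpm > cutoff and p.height >= ratio * top.height]
    if top.bpm < cutoff and candidates:
        return max(candidates, key=lambda p: p.height).bpm, True
    return top.bpm, False


class TestSelectHrPeak:
    @pytest.mark.parametrize(
        "peaks,expected",
        [
            ([(60, 1.0), (120, 0.8)], (120, True)),
            ([(60, 1.0), (120, 0.6)], (60, False)),
            ([(72, 1.0)], (72, False)),
            ([(100, 1.0), (150, 0.9)], (100, False)),
        ],
    )
    def test_truth_table(self, peaks, expected):
        bpm, fired = select_hr_peak([Peak(bpm=b, height=h) for b, h in peaks])
        assert bpm == pytest.approx(expected[0])
        assert fired == expected[1]

    def test_empty_errors(self):
        with pytest.raises(EstimationError):
            select_hr_peak([])

    def test_randomized_against_transcription_oracle(self, rng):
        for _ in range(1000):
            n = rng.integers(1, 7)
            peaks = [
                Peak(bpm=float(rng.uniform(24, 200)), height=float(rng.uniform(0.01, 2)))
                for _ in range(n)
            ]
            assert select_hr_peak(peaks) == _rule_oracle(peaks)

    @given(
        heights=st.lists(st.floats(0.01, 10), min_size=1, max_size=6),
        bpms=st.lists(st.floats(24, 200), min_size=6, max_size=6),
        e=st.integers(-10, 10),
    )
    def test_scale_invariance(self, heights, bpms, e):
        c = 2.0**e  # power-of-two scale: exact in floating point
        peaks = [Peak(bpm=b, height=h) for b, h in zip(bpms, heights)]
        assert select_hr_peak(peaks) == select_hr_peak(
            [Peak(p.bpm, p.height * c) for p in peaks]
        )

    def test_raising_above_cutoff_peak_monotone(self):
        """Growing the above-cutoff peak can only flip the decision from
        below-cutoff to above-cutoff, never back."""
        lows = [Peak(60.0, 1.0)]
        prev_above = False
        for h in np.linspace(0.1, 1.5, 29):
            bpm, _ = select_hr_peak(lows + [Peak(120.0, float(h))])
            above = bpm > 90
            if prev_above:
                assert above  # never flips back below once fired
            prev_above = above


class TestEstimateHr:
    def test_sine_component_beats_noise(self, rng):
        t = np.arange(720) / 30.0
        comps = _component_set([np.sin(2 * np.pi * 1.25 * t), rng.normal(size=720)])
        res = estimate_hr(comps)
        assert res.hr_bpm == pytest.approx(75.0)
        assert res.component_index == 0
        assert not res.respiration_rule_fired

    def test_respiration_peak_rejected(self):
        # respiration at 30 BPM dominates; cardiac peak at 120 BPM holds
        # ~81% of its power after smoothing
        t = np.arange(720) / 30.0
        comp = np.sin(2 * np.pi * 0.5 * t) + 0.9 * np.sin(2 * np.pi * 2.0 * t)
        res = estimate_hr(_component_set([comp]))
        assert res.hr_bpm == pytest.approx(120.0)
        assert res.respiration_rule_fired

    def test_empty_component_set(self):
        with pytest.raises(EstimationError, match="empty"):
            estimate_hr(_component_set(np.empty((0, 720))))

    @pytest.mark.parametrize("f_bpm", [42.5, 60.0, 75.0, 117.5, 160.0, 197.5])
    def test_noiseless_accuracy_within_one_bin(self, f_bpm):
        t = np.arange(720) / 30.0
        comps = _component_set([np.sin(2 * np.pi * f_bpm / 60.0 * t)])
        res = estimate_hr(comps)
        assert abs(res.hr_bpm - f_bpm) <= 2.5  # one bin at 24 s

    def test_no_inband_peak_errors(self):
        comps = _component_set([np.zeros(720)])
        with pytest.raises(EstimationError):
            estimate_hr(comps)

    def test_pure_respiration_component_falls_back(self, rng):
        """A component whose only peak is sub-band cannot supply the HR;
        the next component is used."""
        t = np.arange(720) / 30.0
        resp = np.sin(2 * np.pi * 0.5 * t)  # 30 BPM only
        card = np.sin(2 * np.pi * 2.0 * t) * 0.5 + rng.normal(0, 0.05, 720)
        res = estimate_hr(_component_set([resp, card]))
        assert res.hr_bpm == pytest.approx(120.0, abs=2.5)
        assert res.component_index == 1
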