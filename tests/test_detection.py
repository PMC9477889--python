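"""Filtering, robust thresholding, waveform cutting/alignment, and
ground-truth matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from ldadp.detection import (
    DetectionParams,
    bandpass_filter,
    detect_and_align,
    detection_threshold,
    match_ground_truth,
)
from ldadp.synthgen import generate_recording, make_templates

FS = 24000.0


def _filtfilt_gain(freq, fs=FS, band=(300.0, 3000.0), order=4):
    """Analytic magnitude response of the forward-backward Butterworth."""
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq], fs=fs)
    return np.abs(h[0]) ** 2  # applied twice


class TestBandpassFilter:
    def test_passband_tone_preserved(self):
        t = np.arange(int(FS)) / FS
        x = np.sin(2 * np.pi * 1000.0 * t)
        y = bandpass_filter(x, FS)
        amp = np.abs(y[2000:-2000]).max()
        assert abs(amp - _filtfilt_gain(1000.0)) < 0.05 * _filtfilt_gain(1000.0)
        assert abs(amp - 1.0) < 0.05

    def test_dc_removed(self):
        y = bandpass_filter(np.full(10000, 3.7), FS)
        assert np.abs(y).max() < 1e-6 * 3.7

    def test_stopband_attenuated_below_passband(self):
        t = np.arange(int(FS)) / FS
        g10k = np.abs(bandpass_filter(np.sin(2 * np.pi * 10000.0 * t), FS)[2000:-2000]).max()
        g1k = np.abs(bandpass_filter(np.sin(2 * np.pi * 1000.0 * t), FS)[2000:-2000]).max()
        assert g10k < g1k
        assert g10k < _filtfilt_gain(10000.0) * 1.1

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(np.zeros(100), 4000.0, band=(300.0, 3000.0))


class TestDetectionThreshold:
    def test_alternating_trace(self):
        x = np.tile([0.6745, -0.6745], 500)
        assert detection_threshold(x, 4.0) == 4.0

    def test_gaussian_noise_calibration(self, rng):
        """median(|N(0,1)|) = 0.6745, so unit noise gives a threshold of
        the multiplier itself."""
        x = rng.standard_normal(100_000)
        assert abs(detection_threshold(x, 4.0) - 4.0) < 0.05

    def test_degenerate_zero_trace_warns(self):
        with pytest.warns(UserWarning):
            assert detection_threshold(np.zeros(100)) == 0.0


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.floats(min_value=1e-3, max_value=1e3), st.integers(0, 2**31 - 1))
def test_threshold_scale_homogeneity(c, seed):
    x = np.random.default_rng(seed).standard_normal(512)
    assert np.isclose(detection_threshold(c * x), c * detection_threshold(x), rtol=1e-9)


def _template():
    t = np.arange(64.0)
    w = np.exp(-0.5 * ((t - 19) / 1.2) ** 2) - 0.6 * np.exp(-0.5 * ((t - 26) / 4.0) ** 2)
    return w / w[19]


class TestDetectAndAlign:
    def test_flat_trace_no_spikes(self):
        spikes = detect_and_align(np.zeros(1000), FS, vth=1.0)
        assert spikes.n_spikes == 0

    def test_single_inserted_template(self, rng):
        x = 0.01 * rng.standard_normal(4000)
        vth = detection_threshold(x, 4.0)
        x[2000:2064] += 5 * vth * _template()
        spikes = detect_and_align(x, FS, DetectionParams())
        assert spikes.n_spikes == 1
        assert spikes.times[0] == 2019  # insertion peak, found by construction
        assert int(np.argmax(np.abs(spikes.waves[0]))) == 19

    def test_refractory_merges_nearby_pulses(self):
        x = np.zeros(2000)
        x[1000] = x[1003] = 1.0  # identical pulses 3 samples apart
        params = DetectionParams(refractory_ms=32 / FS * 1e3)
        spikes = detect_and_align(x, FS, params, vth=0.5)
        assert spikes.n_spikes == 1
        assert spikes.times[0] == 1000  # ties keep the earlier peak

    def test_detection_count_nonincreasing_in_multiplier(self, rng):
        bank = make_templates(3, similarity="low", seed=3)
        rec = generate_recording(bank, rates=8.0, duration=4.0, noise_level=0.1, seed=3)
        counts = []
        for mult in (2.0, 3.0, 4.0, 5.0, 6.0):
            vth = detection_threshold(rec.trace, mult)
            counts.append(detect_and_align(rec.trace, rec.fs, vth=vth).n_spikes)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_recovers_inserted_spikes_at_low_noise(self):
        """At noise 0.1 (relative to unit peak), at least 95% of
        non-overlapping ground-truth spikes are found within 2 samples."""
        bank = make_templates(3, similarity="low", seed=7)
        rec = generate_recording(bank, rates=4.0, duration=8.0, noise_level=0.1, seed=7)
        spikes = detect_and_align(rec.trace, rec.fs, DetectionParams())
        gaps = np.diff(rec.gt_times, prepend=-10**9, append=10**9)
        isolated = (gaps[:-1] > 64) & (gaps[1:] > 64)
        hits = sum(
            np.min(np.abs(spikes.times - t)) <= 2 for t in rec.gt_times[isolated]
        )
        assert hits / isolated.sum() >= 0.95

    def test_alignment_invariant(self, rng):
        bank = make_templates(3, similarity="low", seed=5)
        rec = generate_recording(bank, rates=6.0, duration=4.0, noise_level=0.15, seed=5)
        spikes = detect_and_align(rec.trace, rec.fs, DetectionParams())
        assert spikes.n_spikes > 0
        peaks = np.argmax(np.abs(spikes.waves), axis=1)
        assert np.all(peaks == 19)
        assert np.all(np.diff(spikes.times) > 0)


class TestMatchGroundTruth:
    def test_within_tolerance_matched(self):
        # 0.2 ms apart at 24 kHz = 4.8 samples, tol 0.3 ms = 7.2 samples
        marked, pairs = match_ground_truth([1000], [1005], FS, tol_ms=0.3)
        assert marked[0] and pairs == [(0, 0)]

    def test_beyond_tolerance_unmatched(self):
        marked, pairs = match_ground_truth([1000], [1010], FS, tol_ms=0.3)  # 0.42 ms
        assert not marked[0] and pairs == []

    def test_nearest_candidate_wins(self):
        # candidates at 0.1 ms (2.4 samp) and 0.25 ms (6 samp) from one peak
        marked, pairs = match_ground_truth([998, 1006], [1000], FS, tol_ms=0.3)
        assert marked.tolist() == [True, False]
        assert pairs == [(0, 0)]

    def test_one_to_one_matches_exhaustive_oracle(self, rng):
        """Greedy nearest-first matching agrees with the brute-force
        assignment minimizing total |dt| on small instances."""
        import itertools

        for _ in range(20):
            extra = np.sort(rng.choice(2000, size=5, replace=False))
            intra = np.sort(rng.choice(2000, size=4, replace=False))
            tol = 0.3e-3 * FS
            marked, pairs = match_ground_truth(extra, intra, FS)
            # oracle: best one-to-one assignment within tolerance
            best_n, best_cost = 0, np.inf
            for r in range(min(len(extra), len(intra)) + 1):
                for es in itertools.permutations(range(len(extra)), r):
                    for js in itertools.combinations(range(len(intra)), r):
                        if all(abs(extra[e] - intra[j]) <= tol for e, j in zip(es, js)):
                            cost = sum(abs(extra[e] - intra[j]) for e, j in zip(es, js))
                            if r > best_n or (r == best_n and cost < best_cost):
                                best_n, best_cost = r, cost
            assert len(pairs) == best_n
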