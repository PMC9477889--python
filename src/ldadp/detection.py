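"""Spike detection: band-pass filtering, amplitude thresholding, waveform
cutting/alignment, and matching against intracellular ground-truth peaks.

The detector follows the classic sparse-electrode recipe: a zero-phase
Butterworth band-pass (300–3000 Hz by default), a robust threshold of
``mult * median(|x|) / 0.6745`` applied at both polarities (0.6745 is the
median of |N(0,1)|, so the divisor turns the median absolute value into a
noise-sigma estimate), and a fixed-length window cut around each peak so
that the absolute maximum of every waveform sits at a common sample index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "DetectionParams",
    "SpikeWaveformMatrix",
    "bandpass_filter",
    "detection_threshold",
    "detect_and_align",
    "match_ground_truth",
]

#: median of the absolute value of a standard normal variate
NORMAL_MAD_SCALE = 0.6745


@dataclass
class DetectionParams:
    """Parameters of the detection stage.

    band : (low, high) pass band in Hz.
    thresh_mult : multiplier of the robust noise sigma (default 4).
    wave_len : samples per cut waveform (default 64).
    peak_index : 0-based column at which the absolute peak is aligned
        (default 19, i.e. the 20th sample).
    refractory_ms : minimum separation between detections; within this
        window only the largest peak survives.
    """

    band: tuple[float, float] = (300.0, 3000.0)
    thresh_mult: float = 4.0
    wave_len: int = 64
    peak_index: int = 19
    refractory_ms: float = 1.0

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high):
            raise ValueError(f"invalid band {self.band}")
        if not (0 <= self.peak_index < self.wave_len):
            raise ValueError("peak_index must lie inside the waveform window")


@dataclass
class SpikeWaveformMatrix:
    """Aligned spike waveforms: ``waves[i]`` is the i-th spike, with its
    absolute peak at column ``peak_index``.

    ``times`` (optional) holds the peak sample index of each spike in the
    source trace, strictly increasing.
    """

    waves: np.ndarray
    fs: float = 24000.0
    peak_index: int = 19
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.waves = np.atleast_2d(np.asarray(self.waves, dtype=float))
        if self.times is not None:
            self.times = np.asarray(self.times)
            if len(self.times) != self.n_spikes:
                raise ValueError("times length does not match number of spikes")
            if self.n_spikes > 1 and not np.all(np.diff(self.times) > 0):
                raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.waves.shape[0]

    @property
    def wave_len(self) -> int:
        return self.waves.shape[1]


def bandpass_filter(
    trace: np.ndarray,
    fs: float,
    band: tuple[float, float] = (300.0, 3000.0),
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of ``trace``.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    effective magnitude response is the squared Butterworth response and the
    phase is zero — spike peak times are not shifted.
    """
    trace = np.asarray(trace, dtype=float)
    low, high = band
    if high >= fs / 2:
        raise ValueError(
            f"band upper edge {high} Hz is not below the Nyquist frequency {fs / 2} Hz"
        )
    if not (0 < low < high):
        raise ValueError(f"invalid band {band}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, trace)


def detection_threshold(filtered: np.ndarray, mult: float = 4.0) -> float:
    """Robust detection threshold ``mult * median(|x|) / 0.6745``.

    Returns the positive magnitude; detection applies it at both polarities.
    """
    x = np.asarray(filtered, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    vth = mult * float(np.median(np.abs(x))) / NORMAL_MAD_SCALE
    if vth == 0.0:
        warnings.warn("degenerate trace: detection threshold is 0", stacklevel=2)
    return vth


def _excursion_peaks(absx: np.ndarray, vth: float) -> list[int]:
    """Peak sample (argmax |x|) of each contiguous supra-threshold excursion."""
    above = absx > vth
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]
    return [int(s + np.argmax(absx[s:e])) for s, e in zip(starts, stops)]


def detect_and_align(
    filtered: np.ndarray,
    fs: float,
    params: DetectionParams | None = None,
    vth: float | None = None,
) -> SpikeWaveformMatrix:
    """Detect threshold crossings of either polarity and cut aligned waveforms.

    Within each supra-threshold excursion the sample of maximal ``|x|`` is the
    candidate peak; the window is then re-centred on the absolute maximum it
    contains until stable, so the returned rows always satisfy
    ``argmax |row| == peak_index``. Peaks closer than the refractory window
    are merged, keeping the larger (earlier on ties). Events whose window
    would overrun the trace edges are dropped.
    """
    params = params or DetectionParams()
    x = np.asarray(filtered, dtype=float)
    if vth is None:
        vth = detection_threshold(x, params.thresh_mult)
    pre = params.peak_index
    post = params.wave_len - params.peak_index
    n = x.size
    absx = np.abs(x)

    candidates = _excursion_peaks(absx, vth) if vth > 0 else []

    refined: list[int] = []
    for p in candidates:
        for _ in range(params.wave_len):  # bounded walk; each step strictly increases |x[p]|
            lo, hi = p - pre, p + post
            if lo < 0 or hi > n:
                break
            q = lo + int(np.argmax(absx[lo:hi]))
            if q == p:
                break
            p = q
        if p - pre >= 0 and p + post <= n and int(np.argmax(absx[p - pre : p + post])) == pre:
            refined.append(p)

    # refractory suppression: larger peak wins, earlier on ties
    refractory = int(round(params.refractory_ms * 1e-3 * fs))
    kept: list[int] = []
    for p in sorted(set(refined), key=lambda p: (-absx[p], p)):
        if all(abs(p - q) > refractory for q in kept):
            kept.append(p)
    kept.sort()

    waves = np.array([x[p - pre : p + post] for p in kept], dtype=float)
    if waves.size == 0:
        waves = np.empty((0, params.wave_len))
    return SpikeWaveformMatrix(
        waves=waves, fs=fs, peak_index=params.peak_index, times=np.array(kept, dtype=int)
    )


def match_ground_truth(
    extra_times: np.ndarray,
    intra_times: np.ndarray,
    fs: float,
    tol_ms: float = 0.3,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """One-to-one matching of extracellular spikes to intracellular peaks.

    A pair is admissible when |Δt| ≤ ``tol_ms``; admissible pairs are
    accepted greedily in order of increasing |Δt| (ties: earlier spike),
    so each intracellular peak claims its nearest free extracellular spike.

    Returns (marked, pairs): ``marked[i]`` is True when extracellular spike
    i matched some intracellular peak; ``pairs`` lists (extra_idx, intra_idx).
    """
    extra = np.asarray(extra_times, dtype=float)
    intra = np.asarray(intra_times, dtype=float)
    tol = tol_ms * 1e-3 * fs
    admissible = [
        (abs(e - i), ei, ii)
        for ei, e in enumerate(extra)
        for ii, i in enumerate(intra)
        if abs(e - i) <= tol
    ]
    admissible.sort()
    marked = np.zeros(len(extra), dtype=bool)
    intra_used = np.zeros(len(intra), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for _, ei, ii in admissible:
        if not marked[ei] and not intra_used[ii]:
            marked[ei] = True
            intra_used[ii] = True
            pairs.append((ei, ii))
    pairs.sort()
    return marked, pairs
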