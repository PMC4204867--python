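"""Perceptual front-end.

Gammatone-like spectrogram analysis (an STFT weighted by 4th-order gammatone
magnitude responses on an ERB-rate frequency axis), autocorrelation F0
estimation, band-weighted salience, energy-based activity detection and a
dynamic-time-warping distance between auditory representations.

Band energies are compressed with a square root, so scaling the input
waveform by ``g`` scales every time-frequency value by ``g`` (power-law
compression with exponent 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from numba import njit
from scipy.signal import stft

EARQ = 9.26449  # Glasberg & Moore ERB-rate constants
MINBW = 24.7


class AuditoryError(ValueError):
    pass


@dataclass
class AuditoryRepresentation:
    """channels x frames matrix of non-negative band energies."""

    tf_matrix: np.ndarray
    center_freqs: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.tf_matrix = np.asarray(self.tf_matrix, dtype=float)
        self.center_freqs = np.asarray(self.center_freqs, dtype=float)
        if np.any(self.tf_matrix < 0):
            raise AuditoryError("tf energies must be non-negative")
        if np.any(np.diff(self.center_freqs) <= 0):
            raise AuditoryError("center frequencies must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.tf_matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.tf_matrix.shape[1]


@dataclass
class SalienceWeights:
    """Weights of the low-band / high-band / touch salience components."""

    w_low: float = 1.0
    w_high: float = 1.0
    w_touch: float = 1.0
    low_high_boundary: float = 2500.0

    def __post_init__(self) -> None:
        if min(self.w_low, self.w_high, self.w_touch) < 0:
            raise AuditoryError("salience weights must be >= 0")


@dataclass(frozen=True)
class Segment:
    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AuditoryError(f"invalid segment [{self.start}, {self.end}]")

    @property
    def duration(self) -> float:
        return self.end - self.start


# ---------------------------------------------------------------------------
# gammatone spectrogram
# ---------------------------------------------------------------------------

def erb_space(fmin: float, fmax: float, n: int) -> np.ndarray:
    """n center frequencies equally spaced on the ERB-rate scale."""
    lo = EARQ * np.log(1 + fmin / (EARQ * MINBW))
    hi = EARQ * np.log(1 + fmax / (EARQ * MINBW))
    erbs = np.linspace(lo, hi, n)
    return EARQ * MINBW * (np.exp(erbs / EARQ) - 1.0)


def erb_bandwidth(fc: np.ndarray) -> np.ndarray:
    return MINBW + fc / EARQ


def hz_to_erb_rate(f: float) -> float:
    return EARQ * np.log(1 + f / (EARQ * MINBW))


_WEIGHT_CACHE: dict = {}


def _gammatone_weights(fft_freqs: np.ndarray, center_freqs: np.ndarray) -> np.ndarray:
    """4th-order gammatone magnitude response sampled on the FFT grid."""
    key = (len(fft_freqs), float(fft_freqs[-1]),
           len(center_freqs), float(center_freqs[0]), float(center_freqs[-1]))
    if key in _WEIGHT_CACHE:
        return _WEIGHT_CACHE[key]
    bw = 1.019 * erb_bandwidth(center_freqs)
    df = fft_freqs[None, :] - center_freqs[:, None]
    # |H|^2 of a 4th-order gammatone: (1 + (df/b)^2)^-4
    resp = (1.0 + (df / bw[:, None]) ** 2) ** -4.0
    # normalize each channel to unit peak
    resp = resp / resp.max(axis=1, keepdims=True)
    _WEIGHT_CACHE[key] = resp
    return resp


def gammatone_analyze(
    waveform,
    sample_rate: int,
    n_channels: int = 64,
    frame_rate: float = 100.0,
) -> AuditoryRepresentation:
    """Gammatone-like spectrogram of a waveform.

    ERB-spaced channels between 80 Hz and 0.45 * sample_rate; band powers are
    square-root compressed.  Deterministic.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size == 0:
        raise AuditoryError("empty waveform")
    hop = int(round(sample_rate / frame_rate))
    nperseg = min(max(4 * hop, 256), max(len(waveform), 8))
    _, _, z = stft(
        waveform, fs=sample_rate, nperseg=nperseg, noverlap=nperseg - hop,
        boundary=None, padded=True,
    )
    power = np.abs(z) ** 2
    fft_freqs = np.fft.rfftfreq(nperseg, 1.0 / sample_rate)
    fc = erb_space(80.0, 0.45 * sample_rate, n_channels)
    weights = _gammatone_weights(fft_freqs, fc)
    band_power = weights @ power
    return AuditoryRepresentation(np.sqrt(band_power), fc, frame_rate)


# ---------------------------------------------------------------------------
# F0 estimation
# ---------------------------------------------------------------------------

def estimate_f0(
    waveform,
    sample_rate: int,
    fmin: float = 80.0,
    fmax: float = 600.0,
    frame_length: float = 0.04,
    hop: float = 0.01,
    voicing_threshold: float = 0.5,
) -> np.ndarray:
    """Frame-wise autocorrelation F0 track (Hz); 0 marks unvoiced frames.

    A frame is voiced when its energy is non-negligible and the normalized
    autocorrelation peak inside the [fmin, fmax] lag range exceeds
    ``voicing_threshold``.
    """
    if fmin >= fmax:
        raise AuditoryError("fmin must be < fmax")
    x = np.asarray(waveform, dtype=float)
    n = int(frame_length * sample_rate)
    h = int(hop * sample_rate)
    if len(x) < n:
        x = np.pad(x, (0, n - len(x)))
    lag_min = max(1, int(sample_rate / fmax))
    lag_max = min(n - 1, int(sample_rate / fmin))
    global_peak = np.max(np.abs(x)) if x.size else 0.0
    out = []
    for start in range(0, len(x) - n + 1, h):
        frame = x[start : start + n]
        frame = frame - frame.mean()
        energy = np.dot(frame, frame)
        if energy < 1e-10 or np.max(np.abs(frame)) < 1e-3 * max(global_peak, 1e-9):
            out.append(0.0)
            continue
        ac = np.correlate(frame, frame, mode="full")[n - 1 :]
        ac = ac / (ac[0] + 1e-12)
        if lag_max <= lag_min:
            out.append(0.0)
            continue
        seg = ac[lag_min : lag_max + 1]
        best = int(np.argmax(seg))
        if seg[best] < voicing_threshold:
            out.append(0.0)
            continue
        lag = lag_min + best
        # parabolic interpolation around the peak
        if 1 <= lag < len(ac) - 1:
            y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                lag = lag + 0.5 * (y0 - y2) / denom
        out.append(sample_rate / lag)
    return np.array(out)


# ---------------------------------------------------------------------------
# salience
# ---------------------------------------------------------------------------

def band_powers(rep: AuditoryRepresentation, boundary: float):
    """Mean (low, high) band power below/above the boundary frequency."""
    low_mask = rep.center_freqs < boundary
    power = rep.tf_matrix ** 2  # undo sqrt compression
    low = float(power[low_mask].mean()) if np.any(low_mask) else 0.0
    high = float(power[~low_mask].mean()) if np.any(~low_mask) else 0.0
    return low, high


def estimate_salience(
    result,
    weights: SalienceWeights,
    rep: Optional[AuditoryRepresentation] = None,
) -> float:
    """Sensory salience of a synthesis result.

    salience = w_low * mean low-band power + w_high * mean high-band power
             + w_touch * mean touch indicator.
    ``result`` is a SynthResult (or any object with .waveform/.touch_indicator
    /.sample_rate); a precomputed auditory representation may be passed to
    avoid re-analysis.
    """
    if rep is None:
        rep = gammatone_analyze(result.waveform, result.sample_rate)
    low, high = band_powers(rep, weights.low_high_boundary)
    touch = float(np.mean(result.touch_indicator)) if len(result.touch) else 0.0
    return weights.w_low * low + weights.w_high * high + weights.w_touch * touch


# ---------------------------------------------------------------------------
# activity detection
# ---------------------------------------------------------------------------

def short_term_power(waveform, sample_rate: int, frame: float = 0.01) -> np.ndarray:
    x = np.asarray(waveform, dtype=float)
    n = max(1, int(frame * sample_rate))
    n_frames = len(x) // n
    if n_frames == 0:
        return np.zeros(0)
    return (x[: n_frames * n].reshape(n_frames, n) ** 2).mean(axis=1)


def estimate_noise_floor(waveform, sample_rate: int, lead: float = 0.2) -> float:
    """Median short-term power of the leading assumed-silent region."""
    p = short_term_power(waveform, sample_rate)
    k = max(1, int(lead / 0.01))
    return float(np.median(p[:k])) if p.size else 0.0


def detect_activity(
    waveform,
    sample_rate: int,
    noise_floor: float,
    min_gap: float = 0.2,
    min_len: float = 0.05,
    threshold_factor: float = 4.0,
) -> List[Segment]:
    """Segments where short-term power exceeds the background noise level.

    Gaps shorter than ``min_gap`` are merged; segments shorter than
    ``min_len`` are dropped.  Segments are disjoint and time-ordered.
    """
    if noise_floor < 0:
        raise AuditoryError("noise_floor must be >= 0")
    frame = 0.01
    p = short_term_power(waveform, sample_rate, frame)
    thresh = max(noise_floor * threshold_factor, 1e-8)
    active = p > thresh
    segments: List[Segment] = []
    start = None
    for i, a in enumerate(active):
        if a and start is None:
            start = i
        elif not a and start is not None:
            segments.append(Segment(start * frame, i * frame))
            start = None
    if start is not None:
        segments.append(Segment(start * frame, len(active) * frame))
    # merge gaps shorter than min_gap
    merged: List[Segment] = []
    for seg in segments:
        if merged and seg.start - merged[-1].end < min_gap:
            merged[-1] = Segment(merged[-1].start, seg.end)
        else:
            merged.append(seg)
    return [s for s in merged if s.duration >= min_len]


# ---------------------------------------------------------------------------
# DTW
# ---------------------------------------------------------------------------

@njit(cache=False)
def _dtw_core(dist: np.ndarray):
    n, m = dist.shape
    acc = np.empty((n, m))
    steps = np.empty((n, m), dtype=np.int64)
    acc[0, 0] = dist[0, 0]
    steps[0, 0] = 1
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + dist[0, j]
        steps[0, j] = steps[0, j - 1] + 1
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + dist[i, 0]
        steps[i, 0] = steps[i - 1, 0] + 1
        for j in range(1, m):
            best = acc[i - 1, j - 1]
            st = steps[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
                st = steps[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
                st = steps[i, j - 1]
            acc[i, j] = best + dist[i, j]
            steps[i, j] = st + 1
    return acc[n - 1, m - 1], steps[n - 1, m - 1]


def dtw_distance(a: AuditoryRepresentation, b: AuditoryRepresentation) -> float:
    """Path-length-normalized DTW distance between two auditory reps.

    Symmetric step pattern (1,0), (0,1), (1,1) over a Euclidean frame
    metric; the accumulated cost is divided by the optimal path length.
    Zero iff the two matrices are frame-wise identical.
    """
    if a.n_channels != b.n_channels:
        raise AuditoryError(
            f"channel mismatch: {a.n_channels} vs {b.n_channels}"
        )
    xa = np.ascontiguousarray(a.tf_matrix.T)
    xb = np.ascontiguousarray(b.tf_matrix.T)
    from scipy.spatial.distance import cdist

    dist = cdist(xa, xb, metric="euclidean")
    cost, path_len = _dtw_core(dist)
    return float(cost / path_len)
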