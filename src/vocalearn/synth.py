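"""Articulatory speech synthesizer.

A Maeda-style linear-component model maps ten control parameters onto a
vocal-tract area function (glottis to lips).  The first seven parameters are
articulatory (jaw, tongue dorsum position/shape, tongue apex, lip aperture,
lip protrusion, larynx height), P8 is glottal area, P9 fundamental frequency
and P10 the opening of the velo-pharyngeal port.  Acoustics are produced by a
reflection-line (Kelly-Lochbaum) tube model realized as a per-frame all-pole
lattice filter excited by an LF-style glottal pulse train, with band-passed
noise injected at narrow constrictions to simulate frication.  Any tract
section whose cross-sectional area reaches zero is reported as touch
(proprioceptive contact feedback).

The articulatory coefficients are synthetic (constructed for this package,
not fitted to cineradiographic data) and live in ``data/articulatory_model.json``
so they can be swapped for measured ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.signal import lfilter

SPEED_OF_SOUND_CM_S = 35000.0

PARAM_NAMES = (
    "p1_jaw",
    "p2_dorsum_pos",
    "p3_dorsum_shape",
    "p4_apex",
    "p5_lip_aperture",
    "p6_lip_protrusion",
    "p7_larynx_height",
    "p8_glottal_area",
    "p9_f0",
    "p10_nasality",
)


class SynthValidationError(ValueError):
    """Raised when a control frame or configuration is out of range."""


@dataclass(frozen=True)
class ControlFrame:
    """One 10-parameter control vector; every value dimensionless in [-1, 1]."""

    p1_jaw: float = 0.0
    p2_dorsum_pos: float = 0.0
    p3_dorsum_shape: float = 0.0
    p4_apex: float = 0.0
    p5_lip_aperture: float = 0.0
    p6_lip_protrusion: float = 0.0
    p7_larynx_height: float = 0.0
    p8_glottal_area: float = 0.0
    p9_f0: float = 0.0
    p10_nasality: float = -1.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or not (-1.0 <= v <= 1.0):
                raise SynthValidationError(
                    f"parameter {name} = {v!r} outside [-1, 1]"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @staticmethod
    def from_array(vec) -> "ControlFrame":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (10,):
            raise SynthValidationError(f"expected 10 values, got shape {vec.shape}")
        return ControlFrame(**dict(zip(PARAM_NAMES, vec.tolist())))


@dataclass
class SynthConfig:
    """Synthesizer settings.

    ``tract_scale`` shrinks the physical dimensions of the (adult female)
    tract to approximate an infant's; ``f0_midrange`` is the fundamental
    frequency produced at P9 = 0.
    """

    sample_rate: int = 24000
    tract_scale: float = 0.8
    f0_midrange: float = 400.0
    n_tube_sections: int = 20
    frame_period: float = 0.005
    noise_gain: float = 0.02
    reynolds_threshold: float = 0.0
    constriction_area_cm2: float = 0.15  # frication below this area
    max_nasal_port_cm2: float = 0.8
    voice_amplitude: float = 0.25
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise SynthValidationError("sample_rate must be positive")
        if not (0.0 < self.tract_scale <= 1.0):
            raise SynthValidationError("tract_scale must be in (0, 1]")
        if self.n_tube_sections < 8:
            raise SynthValidationError("n_tube_sections must be >= 8")

    @property
    def samples_per_frame(self) -> int:
        return int(round(self.frame_period * self.sample_rate))


@dataclass
class AreaFunction:
    """Vocal-tract cross sections from glottis to lips, in cm / cm^2."""

    section_areas: np.ndarray
    section_lengths: np.ndarray
    nasal_port_area: float = 0.0

    def __post_init__(self) -> None:
        self.section_areas = np.asarray(self.section_areas, dtype=float)
        self.section_lengths = np.asarray(self.section_lengths, dtype=float)
        if self.section_areas.shape != self.section_lengths.shape:
            raise SynthValidationError("areas and lengths must have equal length")
        if np.any(self.section_areas < 0):
            raise SynthValidationError("section areas must be >= 0")
        if np.any(self.section_lengths <= 0):
            raise SynthValidationError("section lengths must be > 0")

    @property
    def closed(self) -> bool:
        return bool(np.any(self.section_areas == 0.0))

    @property
    def closure_index(self) -> int:
        """Index of the contact location, or -1 when the tract is open."""
        if not self.closed:
            return -1
        return int(np.argmin(self.section_areas))


@dataclass
class SynthResult:
    """Sensory consequence of executing a motor pattern."""

    waveform: np.ndarray
    touch: np.ndarray  # per-frame contact section index, -1 = no contact
    areas: list  # per-frame AreaFunction
    sample_rate: int = 24000
    frame_period: float = 0.005

    @property
    def touch_indicator(self) -> np.ndarray:
        """Per-frame boolean contact signal."""
        return self.touch >= 0


# ---------------------------------------------------------------------------
# articulatory model
# ---------------------------------------------------------------------------

def _load_model() -> dict:
    path = resources.files("vocalearn.data") / "articulatory_model.json"
    with path.open("r") as fh:
        return json.load(fh)


_MODEL = _load_model()


def _gaussian(s: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((s - center) / width) ** 2)


def _model_profiles(n_sections: int):
    """Precompute (per-parameter deviation profiles, neutral areas, lengths)."""
    s = (np.arange(n_sections) + 0.5) / n_sections
    neutral = np.interp(
        s,
        (np.arange(len(_MODEL["neutral_areas_cm2"])) + 0.5)
        / len(_MODEL["neutral_areas_cm2"]),
        _MODEL["neutral_areas_cm2"],
    )
    profiles = np.zeros((10, n_sections))
    for comp in _MODEL["area_components"]:
        idx = PARAM_NAMES.index(comp["param"])
        profiles[idx] += comp["amplitude"] * _gaussian(
            s, comp["center"], comp["width"]
        )
    base_len = _MODEL["total_length_cm"] / n_sections
    return s, neutral, profiles, base_len


_PROFILE_CACHE: dict = {}


def _profiles_for(n_sections: int):
    if n_sections not in _PROFILE_CACHE:
        _PROFILE_CACHE[n_sections] = _model_profiles(n_sections)
    return _PROFILE_CACHE[n_sections]


def compute_area_function(frame: ControlFrame, config: SynthConfig) -> AreaFunction:
    """Map one control frame onto a vocal-tract area function.

    Deterministic; areas and lengths are scaled by ``config.tract_scale``.
    A closure (zero cross-sectional area) is reported through the returned
    object's ``closed`` / ``closure_index`` properties.
    """
    n = config.n_tube_sections
    s, neutral, profiles, base_len = _profiles_for(n)
    p = frame.as_array()
    areas = neutral + profiles[:7].T @ p[:7]
    areas = np.clip(areas, 0.0, None) * config.tract_scale

    lengths = np.full(n, base_len) * config.tract_scale
    for mod in _MODEL["length_modifiers"]:
        lo, hi = mod["region"]
        mask = (s >= lo) & (s <= hi)
        value = getattr(frame, mod["param"])
        lengths[mask] *= 1.0 + mod["gain"] * value

    port = (frame.p10_nasality + 1.0) / 2.0 * config.max_nasal_port_cm2
    return AreaFunction(areas, lengths, nasal_port_area=port)


# ---------------------------------------------------------------------------
# glottal source
# ---------------------------------------------------------------------------

def generate_glottal_source(f0_track, amplitude_track, config: SynthConfig):
    """LF-style glottal excitation: derivative of a raised-cosine flow pulse.

    Both tracks are sample-rate sequences of equal length.  The local pulse
    period is 1/f0; samples with zero amplitude are exactly zero.  The four
    LF shape parameters are fixed (open quotient 0.6).
    """
    f0 = np.asarray(f0_track, dtype=float)
    amp = np.asarray(amplitude_track, dtype=float)
    if f0.shape != amp.shape:
        raise SynthValidationError("f0 and amplitude tracks must be equal length")
    if np.any(f0 <= 0):
        raise SynthValidationError("f0 must be positive everywhere")
    open_quotient = 0.6
    phase = np.cumsum(f0 / config.sample_rate) % 1.0
    pulse = np.where(
        phase < open_quotient,
        np.sin(2.0 * np.pi * phase / open_quotient),
        0.0,
    )
    return pulse * amp


def p9_to_f0(p9: float, config: SynthConfig) -> float:
    """Linear P9 -> F0 mapping centred on ``f0_midrange`` (octave span)."""
    return config.f0_midrange * (1.0 + 0.5 * p9)


def voicing_amplitude(p8: float) -> float:
    """Phonation envelope over glottal area P8.

    Phonation peaks at slight adduction (P8 = -0.3) and vanishes both at
    full closure (P8 <= -0.9) and with a wide-open glottis (P8 >= +0.3).
    """
    return float(max(0.0, 1.0 - abs(p8 + 0.3) / 0.6))


# ---------------------------------------------------------------------------
# tube filter
# ---------------------------------------------------------------------------

from numba import njit


@njit(cache=False)
def _stepup_core(k: np.ndarray) -> np.ndarray:
    # a^(n+1) = [a^(n), 0] + k_n * [0, reverse(a^(n))]
    m = k.shape[0]
    a = np.zeros(m + 1)
    b = np.zeros(m + 1)
    a[0] = 1.0
    order = 0
    for idx in range(m):
        ki = k[idx]
        for j in range(order + 2):
            first = a[j] if j <= order else 0.0
            second = a[order + 1 - j] if j >= 1 else 0.0
            b[j] = first + ki * second
        order += 1
        for j in range(order + 1):
            a[j] = b[j]
    return a


def reflection_to_polynomial(k) -> np.ndarray:
    """Convert lattice reflection coefficients to a direct-form denominator."""
    k = np.ascontiguousarray(np.asarray(k, dtype=float))
    return _stepup_core(k)


def _tract_polynomial(areas: np.ndarray, config: SynthConfig) -> np.ndarray:
    """Area function -> all-pole vocal tract filter denominator.

    The model areas are resampled onto a lattice whose section count follows
    the physical tract length at the configured sample rate, so shortening
    the tract (smaller ``tract_scale``) raises all resonances.
    """
    total_len = _MODEL["total_length_cm"] * config.tract_scale
    n_lat = int(np.clip(round(2.0 * total_len * config.sample_rate
                              / SPEED_OF_SOUND_CM_S), 6, 64))
    src = (np.arange(len(areas)) + 0.5) / len(areas)
    dst = (np.arange(n_lat) + 0.5) / n_lat
    lat_areas = np.interp(dst, src, np.clip(areas, 1e-4, None))
    # glottis -> lips, terminated by a large radiation area
    a_ext = np.concatenate([lat_areas, [30.0]])
    k = (a_ext[1:] - a_ext[:-1]) / (a_ext[1:] + a_ext[:-1])
    k = np.clip(k, -0.98, 0.98)
    a = reflection_to_polynomial(k)
    # bandwidth expansion: mild damping of every pole for realistic formant widths
    gamma = 0.995 ** np.arange(len(a))
    return a * gamma


_MURMUR_CACHE: dict = {}


def _nasal_murmur_polynomial(sample_rate: int) -> np.ndarray:
    """Fixed low-frequency nasal resonator (~300 Hz) used when the oral tract
    is occluded but the velo-pharyngeal port is open."""
    if sample_rate not in _MURMUR_CACHE:
        w = 2.0 * np.pi * 300.0 / sample_rate
        r = 0.98
        _MURMUR_CACHE[sample_rate] = np.array([1.0, -2.0 * r * np.cos(w), r * r])
    return _MURMUR_CACHE[sample_rate]


# ---------------------------------------------------------------------------
# synthesis
# ---------------------------------------------------------------------------

def synthesize(frames, config: SynthConfig | None = None) -> SynthResult:
    """Render a control-frame sequence to audio with touch feedback.

    Each frame drives the tract filter for one ``frame_period``.  Voiced
    excitation follows the P8 phonation envelope and the P9 -> F0 mapping;
    frication noise is injected when a supraglottal constriction narrows
    below ``constriction_area_cm2`` while the glottis passes air.  A fully
    occluded oral tract radiates (near) silence unless the nasal port is
    open, in which case a low-frequency nasal murmur is produced.
    """
    if config is None:
        config = SynthConfig()
    frames = list(frames)
    if not frames:
        raise SynthValidationError("need at least one control frame")
    spf = config.samples_per_frame
    n_frames = len(frames)
    n_samples = n_frames * spf
    rng = np.random.default_rng(config.noise_seed)

    # steady postures repeat identical frames; dedupe the articulatory map
    af_cache: dict = {}
    areas_per_frame = []
    for f in frames:
        fkey = f.as_array().tobytes()
        if fkey not in af_cache:
            af_cache[fkey] = compute_area_function(f, config)
        areas_per_frame.append(af_cache[fkey])
    touch = np.array([af.closure_index for af in areas_per_frame], dtype=int)

    # tube polynomials repeat across steady frames; cache by area content
    poly_cache: dict = {}

    def tract_poly(af: AreaFunction) -> np.ndarray:
        key = np.round(af.section_areas, 4).tobytes()
        if key not in poly_cache:
            poly_cache[key] = _tract_polynomial(af.section_areas, config)
        return poly_cache[key]

    # sample-rate excitation tracks
    f0_frames = np.array([p9_to_f0(f.p9_f0, config) for f in frames])
    amp_frames = np.array([voicing_amplitude(f.p8_glottal_area) for f in frames])
    f0_track = np.repeat(f0_frames, spf)
    amp_track = np.repeat(amp_frames, spf)
    source = generate_glottal_source(f0_track, amp_track, config)
    source *= config.voice_amplitude

    # per-frame excitation (glottal source + release bursts)
    excitation = source.copy()
    for t in range(1, n_frames):
        if touch[t - 1] >= 0 and touch[t] < 0:
            sl = slice(t * spf, (t + 1) * spf)
            burst = rng.standard_normal(spf) * config.noise_gain * 3.0
            burst *= np.exp(-np.arange(spf) / (0.004 * config.sample_rate))
            excitation[sl] += burst

    # frame -> (polynomial, output gate); consecutive frames with the same
    # filter are processed in one lfilter call
    frame_polys = []
    frame_gates = []
    for af in areas_per_frame:
        closed = af.closed
        port_open = af.nasal_port_area > 0.05
        if closed and port_open:
            frame_polys.append(_nasal_murmur_polynomial(config.sample_rate))
            frame_gates.append(1.0)
        else:
            frame_polys.append(tract_poly(af))
            # occluded oral tract radiates almost nothing
            frame_gates.append(0.02 if closed else 1.0)

    out = np.zeros(n_samples)
    zi = None
    prev_len = None
    t = 0
    while t < n_frames:
        poly = frame_polys[t]
        gate = frame_gates[t]
        t_end = t + 1
        while (
            t_end < n_frames
            and frame_polys[t_end] is poly
            and frame_gates[t_end] == gate
        ):
            t_end += 1
        sl = slice(t * spf, t_end * spf)
        if zi is None or prev_len != len(poly):
            zi = np.zeros(len(poly) - 1)
        prev_len = len(poly)
        y, zi = lfilter([1.0], poly, excitation[sl], zi=zi)
        out[sl] = y * gate
        t = t_end

    # lip radiation: first difference
    radiated = lfilter([1.0, -0.98], [1.0], out)

    # frication noise, injected post-tract (anterior-cavity approximation)
    fric = np.zeros(n_samples)
    min_supraglottal = np.array(
        [np.min(af.section_areas[2:]) for af in areas_per_frame]
    )
    open_glottis = np.array(
        [max(0.0, f.p8_glottal_area) for f in frames]
    )
    fric_gate = (
        (min_supraglottal < config.constriction_area_cm2)
        & (min_supraglottal > 0.0)
        & (open_glottis > config.reynolds_threshold)
    )
    if np.any(fric_gate):
        noise = rng.standard_normal(n_samples)
        from scipy.signal import butter, sosfilt

        sos = butter(4, [2500.0, 0.42 * config.sample_rate],
                     btype="band", fs=config.sample_rate, output="sos")
        noise = sosfilt(sos, noise)
        gate = np.repeat(fric_gate.astype(float) * open_glottis, spf)
        fric = noise * gate * config.noise_gain * 20.0

    waveform = radiated + fric
    peak = np.max(np.abs(waveform))
    if peak > 1.0:
        waveform = waveform / peak
    return SynthResult(
        waveform=waveform,
        touch=touch,
        areas=areas_per_frame,
        sample_rate=config.sample_rate,
        frame_period=config.frame_period,
    )


def write_wav(path, waveform, sample_rate: int = 24000) -> None:
    """Write mono float waveform as 16-bit PCM WAV."""
    from scipy.io import wavfile

    data = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(path, sample_rate, (data * 32767).astype(np.int16))


def read_wav(path):
    """Read a mono WAV to (float waveform in [-1, 1], sample_rate)."""
    from scipy.io import wavfile

    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype.kind == "i":
        data = data.astype(float) / np.iinfo(data.dtype).max
    else:
        data = data.astype(float)
    return data, sr
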