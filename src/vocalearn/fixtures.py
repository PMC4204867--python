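"""Synthetic caregiver data.

Formant-synthesized vowel and CV tokens stand in for recorded caregiver
speech so that interaction and word-learning experiments can run without a
human or any audio download.  Tokens are generated by a source-filter
scheme: an impulse-train source with a chosen F0 contour, filtered through
three cascaded resonators at the category's formant targets (plus a burst
or frication noise for consonant onsets).  Also generates paired
transcription datasets with a controllable agreement level for the
labeling-comparison analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.signal import lfilter

DEFAULT_VOWELS: Dict[str, Tuple[float, float, float]] = {
    # adult-female-like formant targets (F1, F2, F3) in Hz
    "a": (850.0, 1220.0, 2810.0),
    "i": (310.0, 2790.0, 3310.0),
    "u": (370.0, 950.0, 2670.0),
    "e": (610.0, 2330.0, 2990.0),
    "o": (500.0, 1000.0, 2830.0),
}

DEFAULT_CONSONANTS: Dict[str, Tuple[float, bool]] = {
    # burst/frication spectral centroid proxy (Hz), voiced flag
    "b": (800.0, True),
    "t": (4200.0, False),
    "s": (6500.0, False),
}


class FixtureError(ValueError):
    pass


@dataclass
class CaregiverLanguageSpec:
    """A miniature native-language inventory for the simulated caregiver."""

    vowel_prototypes: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VOWELS)
    )
    consonant_classes: Dict[str, Tuple[float, bool]] = field(
        default_factory=lambda: dict(DEFAULT_CONSONANTS)
    )
    f0_range: Tuple[float, float] = (180.0, 260.0)
    sample_rate: int = 24000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.vowel_prototypes) < 2:
            raise FixtureError("need at least 2 vowel prototypes")
        for label, (f1, f2, f3) in self.vowel_prototypes.items():
            if not (0 < f1 < f2 < f3):
                raise FixtureError(
                    f"formants must satisfy F1 < F2 < F3 for vowel {label!r}"
                )

    @property
    def labels(self) -> List[str]:
        return list(self.vowel_prototypes) + list(self.consonant_classes)


def _resonator(freq: float, bw: float, fs: int):
    r = np.exp(-np.pi * bw / fs)
    w = 2.0 * np.pi * freq / fs
    a = np.array([1.0, -2.0 * r * np.cos(w), r * r])
    b = np.array([1.0 - r])  # rough unity-ish gain at resonance
    return b, a


def formant_synthesize(
    formants: Tuple[float, float, float],
    duration: float = 0.35,
    f0: float = 220.0,
    f0_end: Optional[float] = None,
    sample_rate: int = 24000,
    bandwidths: Tuple[float, float, float] = (80.0, 110.0, 160.0),
    amplitude: float = 0.3,
) -> np.ndarray:
    """Three-formant vowel-like token from an impulse-train source."""
    n = int(duration * sample_rate)
    if f0_end is None:
        f0_end = f0
    f0_track = np.linspace(f0, f0_end, n)
    phase = np.cumsum(f0_track / sample_rate)
    impulses = np.zeros(n)
    impulses[np.diff(np.floor(phase), prepend=0.0) > 0] = 1.0
    x = impulses
    for freq, bw in zip(formants, bandwidths):
        b, a = _resonator(freq, bw, sample_rate)
        x = lfilter(b, a, x)
    # gentle onset/offset ramps to avoid clicks
    ramp = min(n // 10, int(0.02 * sample_rate))
    env = np.ones(n)
    env[:ramp] = np.linspace(0, 1, ramp)
    env[-ramp:] = np.linspace(1, 0, ramp)
    x = x * env
    peak = np.max(np.abs(x))
    return amplitude * x / peak if peak > 0 else x


def consonant_onset(
    centroid: float,
    voiced: bool,
    duration: float = 0.08,
    sample_rate: int = 24000,
    rng: Optional[np.random.Generator] = None,
    amplitude: float = 0.25,
) -> np.ndarray:
    """Burst/frication noise onset whose spectrum centers near ``centroid``."""
    if rng is None:
        rng = np.random.default_rng(0)
    n = int(duration * sample_rate)
    noise = rng.standard_normal(n)
    b, a = _resonator(min(centroid, 0.45 * sample_rate), 0.5 * centroid + 400.0,
                      sample_rate)
    x = lfilter(b, a, noise)
    env = np.exp(-np.arange(n) / (0.4 * n))
    x = x * env
    if voiced:
        # voice bar: weak low-frequency periodicity under the burst
        t = np.arange(n) / sample_rate
        x = x + 0.15 * np.sin(2 * np.pi * 150.0 * t) * env
    peak = np.max(np.abs(x))
    return amplitude * x / peak if peak > 0 else x


def synthesize_token(
    label: str,
    spec: CaregiverLanguageSpec,
    rng: Optional[np.random.Generator] = None,
    formant_jitter: float = 0.03,
    f0_jitter: float = 0.05,
) -> np.ndarray:
    """One labeled token: a vowel, or a CV with the consonant-class onset."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    f0_lo, f0_hi = spec.f0_range
    f0 = rng.uniform(f0_lo, f0_hi)
    f0 = f0 * (1 + f0_jitter * rng.standard_normal())
    if label in spec.vowel_prototypes:
        f = np.array(spec.vowel_prototypes[label])
        f = f * (1 + formant_jitter * rng.standard_normal(3))
        return formant_synthesize(tuple(np.sort(f)), f0=max(80.0, f0),
                                  sample_rate=spec.sample_rate)
    if label in spec.consonant_classes:
        centroid, voiced = spec.consonant_classes[label]
        onset = consonant_onset(
            centroid * (1 + formant_jitter * rng.standard_normal()),
            voiced, sample_rate=spec.sample_rate, rng=rng,
        )
        # a neutral following vowel
        vowel = formant_synthesize(
            DEFAULT_VOWELS["a"], duration=0.25, f0=max(80.0, f0),
            sample_rate=spec.sample_rate,
        )
        return np.concatenate([onset, vowel])
    raise FixtureError(f"unknown label {label!r}")


def generate_caregiver_templates(
    spec: CaregiverLanguageSpec,
    n_per_category: int,
) -> List[Tuple[str, np.ndarray]]:
    """Deterministic labeled waveform inventory, ``n_per_category`` each."""
    rng = np.random.default_rng(spec.seed)
    out: List[Tuple[str, np.ndarray]] = []
    for label in spec.labels:
        for _ in range(n_per_category):
            out.append((label, synthesize_token(label, spec, rng)))
    return out


def generate_transcription_dataset(
    n_tokens: int,
    agreement: float,
    labels: Optional[List[str]] = None,
    seed: int = 0,
) -> Tuple[Dict[str, str], Dict[str, str]]:
    """Two token-id -> archiphoneme-label maps with a target agreement rate.

    A fraction ``agreement`` of tokens receive the same label in both
    datasets; the rest receive a label drawn from the remaining
    categories.
    """
    if not (0.0 <= agreement <= 1.0):
        raise FixtureError("agreement must be in [0, 1]")
    if labels is None:
        labels = ["|A|", "|ie|", "|O|", "|UV|", "|&|"]
    if len(labels) < 2:
        raise FixtureError("need at least 2 labels")
    rng = np.random.default_rng(seed)
    a: Dict[str, str] = {}
    b: Dict[str, str] = {}
    for i in range(n_tokens):
        tid = f"tok{i:05d}"
        la = labels[rng.integers(len(labels))]
        a[tid] = la
        if rng.random() < agreement:
            b[tid] = la
        else:
            others = [l for l in labels if l != la]
            b[tid] = others[rng.integers(len(others))]
    return a, b
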