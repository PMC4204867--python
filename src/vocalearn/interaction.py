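"""Caregiver-response protocol.

The learner presents each discovered motor pattern as audio, listens for a
short window, and uses the presence of a caregiver response as a selection
signal: responded-to patterns are reinforced and associated with the
response audio; ignored patterns are deselected.  No judgment of acoustic
similarity is made by the learner — the caregiver's decision to respond
carries all the information.

``SimulatedCaregiver`` is a fully synthetic stand-in for a human caregiver:
it classifies the learner's output against formant-synthesized category
prototypes and, when the best match is close enough, answers with a stored
"reformulation" token of that category.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Protocol, Sequence, Set, Tuple

import numpy as np

from .auditory import (
    AuditoryRepresentation,
    Segment,
    detect_activity,
    gammatone_analyze,
    dtw_distance,
)
from .fixtures import CaregiverLanguageSpec, generate_caregiver_templates
from .motor import MotorDynamicsConfig, MotorPattern, interpolate_trajectory
from .synth import SynthConfig, synthesize

LISTENING_WINDOW_S = 3.0


class InteractionError(RuntimeError):
    pass


@dataclass
class AssociationEntry:
    response_waveform: np.ndarray
    response_rep: AuditoryRepresentation
    label: Optional[str] = None
    timestamp: float = 0.0


@dataclass
class AssociationMemory:
    """Motor-pattern id -> caregiver response; plus the deselected set."""

    entries: Dict[str, AssociationEntry] = field(default_factory=dict)
    deselected: Set[str] = field(default_factory=set)

    def associate(self, pattern_id: str, entry: AssociationEntry) -> None:
        if len(entry.response_waveform) == 0:
            raise InteractionError("association requires non-empty audio")
        self.deselected.discard(pattern_id)
        self.entries[pattern_id] = entry

    def deselect(self, pattern_id: str) -> None:
        if pattern_id in self.entries:
            del self.entries[pattern_id]
        self.deselected.add(pattern_id)

    def __len__(self) -> int:
        return len(self.entries)


class CaregiverInterface(Protocol):
    """Anything that can (optionally) respond to an utterance."""

    def respond(self, waveform: np.ndarray) -> Optional[Tuple[np.ndarray, Optional[str]]]:
        """Return (response waveform, optional label), or None to ignore."""
        ...


@dataclass
class SimulatedCaregiverConfig:
    response_probability: float = 1.0
    acceptance_radius: float = float("inf")
    language: CaregiverLanguageSpec = field(default_factory=CaregiverLanguageSpec)
    n_tokens_per_category: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.response_probability <= 1.0):
            raise InteractionError("response_probability must be in [0, 1]")


class SimulatedCaregiver:
    """Caregiver emulation: classify, then reformulate into the nearest
    native category.

    The caregiver holds a small inventory of formant-synthesized category
    prototypes.  An incoming utterance is compared (DTW over gammatone
    representations) with one reference token per category; if the best
    distance is within ``acceptance_radius`` and a response-probability
    draw succeeds, the caregiver answers with a token of that category —
    a reformulation, not an acoustic copy.
    """

    def __init__(self, config: SimulatedCaregiverConfig):
        if not config.language.vowel_prototypes and not config.language.consonant_classes:
            raise InteractionError("caregiver needs at least one prototype")
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        inventory = generate_caregiver_templates(
            config.language, config.n_tokens_per_category
        )
        self.tokens: Dict[str, List[np.ndarray]] = {}
        for label, wav in inventory:
            self.tokens.setdefault(label, []).append(wav)
        sr = config.language.sample_rate
        self.sample_rate = sr
        # energy-normalized references: the caregiver judges spectral shape,
        # not loudness (the learner's voice is much quieter than hers)
        self._reference_reps = {
            label: [self._norm_rep(gammatone_analyze(w, sr)) for w in wavs]
            for label, wavs in self.tokens.items()
        }
        self._next_token_idx = {label: 0 for label in self.tokens}

    @staticmethod
    def _norm_rep(rep: AuditoryRepresentation) -> AuditoryRepresentation:
        scale = np.linalg.norm(rep.tf_matrix)
        if scale <= 0:
            return rep
        return AuditoryRepresentation(
            rep.tf_matrix / scale, rep.center_freqs, rep.frame_rate
        )

    def classify(self, waveform: np.ndarray) -> Tuple[str, float]:
        """Nearest category label and its DTW distance (energy-normalized)."""
        rep = self._norm_rep(gammatone_analyze(waveform, self.sample_rate))
        best_label, best_d = None, np.inf
        for label, refs in self._reference_reps.items():
            for ref in refs:
                d = dtw_distance(rep, ref)
                if d < best_d:
                    best_label, best_d = label, d
        return best_label, float(best_d)

    def respond(self, waveform: np.ndarray):
        if len(waveform) == 0 or not np.any(waveform):
            return None
        label, dist = self.classify(waveform)
        if dist > self.config.acceptance_radius:
            return None
        if self.rng.random() >= self.config.response_probability:
            return None
        # rotate through the category's stored reformulation tokens
        idx = self._next_token_idx[label]
        self._next_token_idx[label] = (idx + 1) % len(self.tokens[label])
        return self.tokens[label][idx], label


def simulate_caregiver_response(
    waveform: np.ndarray, config: SimulatedCaregiverConfig
):
    """One-shot functional wrapper around ``SimulatedCaregiver.respond``."""
    return SimulatedCaregiver(config).respond(waveform)


# ---------------------------------------------------------------------------
# response detection and sessions
# ---------------------------------------------------------------------------

def detect_response(
    recording: np.ndarray,
    sample_rate: int,
    noise_floor: float,
    window: float = LISTENING_WINDOW_S,
) -> Optional[Segment]:
    """First supra-threshold segment in the listening window, if any."""
    import warnings

    if len(recording) < window * sample_rate:
        warnings.warn(
            "recording shorter than the listening window; processing as-is",
            stacklevel=2,
        )
    segments = detect_activity(recording, sample_rate, noise_floor)
    return segments[0] if segments else None


@dataclass
class SessionEvent:
    pattern_id: str
    responded: bool
    label: Optional[str]
    skipped: bool = False


def run_response_session(
    inventory: Sequence[MotorPattern],
    caregiver: CaregiverInterface,
    memory: Optional[AssociationMemory] = None,
    synth_config: Optional[SynthConfig] = None,
    dynamics: Optional[MotorDynamicsConfig] = None,
) -> Tuple[AssociationMemory, List[SessionEvent]]:
    """Present every pattern once; associate or deselect each.

    A caregiver exception skips the pattern (logged, not deselected), so
    after a session every inventory id is associated, deselected or
    skipped.
    """
    if not inventory:
        raise InteractionError("inventory must be non-empty")
    if memory is None:
        memory = AssociationMemory()
    if synth_config is None:
        synth_config = SynthConfig()
    if dynamics is None:
        dynamics = MotorDynamicsConfig()
    log: List[SessionEvent] = []
    for pattern in inventory:
        frames = interpolate_trajectory(
            pattern, dynamics, synth_config.frame_period, synth_config
        )
        result = synthesize(frames, synth_config)
        try:
            response = caregiver.respond(result.waveform)
        except Exception:  # noqa: BLE001 - skip, do not deselect
            log.append(SessionEvent(pattern.id, False, None, skipped=True))
            continue
        if response is None:
            memory.deselect(pattern.id)
            log.append(SessionEvent(pattern.id, False, None))
        else:
            wav, label = response
            rep = gammatone_analyze(wav, synth_config.sample_rate)
            memory.associate(
                pattern.id,
                AssociationEntry(
                    response_waveform=np.asarray(wav, dtype=float),
                    response_rep=rep,
                    label=label,
                    timestamp=time.time(),
                ),
            )
            log.append(SessionEvent(pattern.id, True, label))
    return memory, log


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_memory(memory: AssociationMemory, directory) -> None:
    """Persist as a directory of WAVs plus a JSON index."""
    from .synth import write_wav

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {"entries": {}, "deselected": sorted(memory.deselected)}
    for pid, entry in memory.entries.items():
        fname = f"{pid}.wav"
        write_wav(directory / fname, entry.response_waveform)
        index["entries"][pid] = {"wav": fname, "label": entry.label}
    with open(directory / "index.json", "w") as fh:
        json.dump(index, fh, indent=1)


def load_memory(directory, sample_rate: int = 24000) -> AssociationMemory:
    from .synth import read_wav

    directory = Path(directory)
    with open(directory / "index.json") as fh:
        index = json.load(fh)
    memory = AssociationMemory(deselected=set(index["deselected"]))
    for pid, meta in index["entries"].items():
        wav, sr = read_wav(directory / meta["wav"])
        memory.entries[pid] = AssociationEntry(
            response_waveform=wav,
            response_rep=gammatone_analyze(wav, sr),
            label=meta["label"],
        )
    return memory


def save_session_log(log: Sequence[SessionEvent], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pattern_id", "responded", "label", "skipped"])
        for ev in log:
            writer.writerow([ev.pattern_id, int(ev.responded), ev.label or "",
                             int(ev.skipped)])
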