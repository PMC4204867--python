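"""Word learning by serial imitation.

A caregiver word (spoken with pauses between syllables) is segmented into
syllable-sized chunks; each chunk is matched against the stored caregiver
responses by a two-pass DTW recognizer (pass 1 over up to 100 cluster-center
templates, pass 2 over all members of the best 5 clusters).  The motor
pattern associated with the winning response is recalled, its F0 targets and
duration overwritten from the segment's intonation (straight-line F0 fit,
duration clamped to 250-600 ms), and the recalled patterns are concatenated
and synthesized as the learner's imitation.  A session loop gives up to 4
imitation attempts per spoken prompt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .auditory import (
    AuditoryRepresentation,
    Segment,
    detect_activity,
    dtw_distance,
    estimate_f0,
    gammatone_analyze,
)
from .discovery import kmedoids_from_distances, dtw_matrix
from .interaction import AssociationMemory
from .motor import (
    MotorDynamicsConfig,
    MotorPattern,
    SubPattern,
    interpolate_trajectory,
)
from .synth import SynthConfig, synthesize

DURATION_MIN_S = 0.250
DURATION_MAX_S = 0.600
PARAM_RANGE = (-0.9, 0.9)
F0_RANGE_MALE = (100.0, 300.0)
F0_RANGE_FEMALE = (150.0, 400.0)
PASS1_TEMPLATES = 100
PASS2_BEST_CLUSTERS = 5
MAX_ATTEMPTS = 4


class ImitationError(RuntimeError):
    pass


@dataclass
class IntonationSpec:
    """Straight-line F0 approximation plus clamped duration."""

    start_f0: float
    end_f0: float
    duration: float
    caregiver_sex: str = "female"
    flat_default: bool = False  # True when no voiced frames were found

    def __post_init__(self) -> None:
        self.duration = float(np.clip(self.duration, DURATION_MIN_S, DURATION_MAX_S))
        if self.start_f0 <= 0 or self.end_f0 <= 0:
            raise ImitationError("f0 values must be positive")


@dataclass
class SegmentTrace:
    segment: Segment
    pass1: List[Tuple[str, float]]          # (response id, DTW score), ranked
    pass2: List[Tuple[str, float]]          # ranked over best-cluster members
    chosen_id: Optional[str]


@dataclass
class RecognitionTrace:
    segments: List[SegmentTrace] = field(default_factory=list)


# ---------------------------------------------------------------------------
# F0 <-> parameter mapping
# ---------------------------------------------------------------------------

def _f0_range(caregiver_sex: str) -> Tuple[float, float]:
    if caregiver_sex == "male":
        return F0_RANGE_MALE
    if caregiver_sex == "female":
        return F0_RANGE_FEMALE
    raise ImitationError(f"unknown caregiver sex {caregiver_sex!r}")


def frequency_to_param(f0: float, caregiver_sex: str) -> float:
    """Affine map from caregiver F0 to the source F0 parameter.

    (-0.9, 0.9) spans 100-300 Hz for a male caregiver, 150-400 Hz for a
    female one; out-of-range frequencies clip to the parameter bounds.
    """
    if f0 <= 0:
        raise ImitationError("f0 must be positive")
    lo, hi = _f0_range(caregiver_sex)
    p_lo, p_hi = PARAM_RANGE
    p = p_lo + (f0 - lo) * (p_hi - p_lo) / (hi - lo)
    return float(np.clip(p, p_lo, p_hi))


def param_to_frequency(p: float, caregiver_sex: str) -> float:
    lo, hi = _f0_range(caregiver_sex)
    p_lo, p_hi = PARAM_RANGE
    return float(lo + (p - p_lo) * (hi - lo) / (p_hi - p_lo))


# ---------------------------------------------------------------------------
# segmentation and intonation
# ---------------------------------------------------------------------------

def segment_word(
    waveform: np.ndarray,
    sample_rate: int,
    noise_floor: float,
    min_gap: float = 0.15,
    min_len: float = 0.06,
) -> List[Segment]:
    """Syllable-sized chunks in temporal order (empty = nothing heard)."""
    return detect_activity(
        waveform, sample_rate, noise_floor, min_gap=min_gap, min_len=min_len
    )


def extract_intonation(
    segment_audio: np.ndarray,
    sample_rate: int,
    caregiver_sex: str = "female",
) -> IntonationSpec:
    """Least-squares straight-line fit to the voiced F0 track.

    Start/end are the fitted line at the segment edges; the duration is
    the segment length clamped to 250-600 ms.  Without voiced frames a
    flat contour at the mapping midpoint is returned and flagged.
    """
    duration = len(segment_audio) / sample_rate
    f0 = estimate_f0(segment_audio, sample_rate, fmin=80.0, fmax=500.0)
    voiced = f0 > 0
    lo, hi = _f0_range(caregiver_sex)
    if np.count_nonzero(voiced) < 2:
        mid = 0.5 * (lo + hi)
        return IntonationSpec(mid, mid, duration, caregiver_sex,
                              flat_default=True)
    t = np.nonzero(voiced)[0].astype(float)
    slope, intercept = np.polyfit(t, f0[voiced], 1)
    n = len(f0) - 1
    start = float(intercept)
    end = float(intercept + slope * n)
    start = float(np.clip(start, 50.0, 600.0))
    end = float(np.clip(end, 50.0, 600.0))
    return IntonationSpec(start, end, duration, caregiver_sex)


def apply_intonation(pattern: MotorPattern, spec: IntonationSpec) -> MotorPattern:
    """Overwrite the pattern's F0 targets and rescale its duration.

    P9 targets at the first and last sub-patterns take the mapped start
    and end frequencies (linear across intermediate sub-patterns); hold
    durations are rescaled proportionally so the pattern's extent matches
    the clamped segment duration.
    """
    p_start = frequency_to_param(spec.start_f0, spec.caregiver_sex)
    p_end = frequency_to_param(spec.end_f0, spec.caregiver_sex)
    source_subs = list(pattern.sub_patterns)
    if len(source_subs) == 1:
        # a single gesture carries no F0 boundary; split it at the midpoint
        # so the contour can glide from start to end
        sp = source_subs[0]
        half = SubPattern(
            sp.targets.copy(), sp.start_times * 0.5,
            sp.hold_durations * 0.5, sp.speed_scaling,
        )
        source_subs = [half, half]
    n_sub = len(source_subs)
    scale = spec.duration / max(
        MotorPattern(source_subs, category=pattern.category,
                     voiced=pattern.voiced,
                     nasal_port_open=pattern.nasal_port_open).extent,
        1e-6,
    )
    subs = []
    for i, sp in enumerate(source_subs):
        frac = i / (n_sub - 1) if n_sub > 1 else 0.0
        targets = sp.targets.copy()
        targets[8] = p_start + frac * (p_end - p_start)
        subs.append(
            SubPattern(
                targets,
                sp.start_times * scale,
                sp.hold_durations * scale,
                sp.speed_scaling,
            )
        )
    return MotorPattern(
        subs, category=pattern.category, voiced=pattern.voiced,
        nasal_port_open=pattern.nasal_port_open, id=pattern.id,
    )


# ---------------------------------------------------------------------------
# two-pass recognition
# ---------------------------------------------------------------------------

@dataclass
class TemplateIndex:
    """Pass-1 cluster exemplars and their member response ids."""

    ids: List[str]
    reps: Dict[str, AuditoryRepresentation]
    clusters: List[dict]  # {"exemplar": id, "members": [ids]}


def build_template_index(
    memory: AssociationMemory,
    n_centers: int = PASS1_TEMPLATES,
    seed: int = 0,
) -> TemplateIndex:
    """Cluster stored responses (DTW k-medoids) into pass-1 templates."""
    if not memory.entries:
        raise ImitationError("association memory is empty")
    ids = sorted(memory.entries)
    reps = {pid: memory.entries[pid].response_rep for pid in ids}
    k = min(n_centers, len(ids))
    dist = dtw_matrix([reps[pid] for pid in ids])
    medoids, assign = kmedoids_from_distances(dist, k, seed)
    clusters = []
    for c in range(k):
        members = [ids[i] for i in np.where(assign == c)[0]]
        if not members:
            continue
        clusters.append({"exemplar": ids[medoids[c]], "members": members})
    return TemplateIndex(ids=ids, reps=reps, clusters=clusters)


def recognize_two_pass(
    segment_audio: np.ndarray,
    sample_rate: int,
    index: TemplateIndex,
    segment: Optional[Segment] = None,
) -> SegmentTrace:
    """Score pass-1 exemplars, then all members of the best 5 clusters."""
    if not index.clusters:
        raise ImitationError("template index is empty")
    rep = gammatone_analyze(segment_audio, sample_rate)
    pass1 = []
    for cl in index.clusters:
        d = dtw_distance(rep, index.reps[cl["exemplar"]])
        pass1.append((cl["exemplar"], d))
    order = np.argsort([d for _, d in pass1], kind="stable")
    best_clusters = [index.clusters[i] for i in order[:PASS2_BEST_CLUSTERS]]
    pool = []
    seen = set()
    for cl in best_clusters:
        for pid in cl["members"]:
            if pid not in seen:
                seen.add(pid)
                pool.append(pid)
    pass2 = sorted(
        ((pid, dtw_distance(rep, index.reps[pid])) for pid in pool),
        key=lambda t: t[1],
    )
    chosen = pass2[0][0] if pass2 else None
    if segment is None:
        segment = Segment(0.0, max(len(segment_audio) / sample_rate, 1e-3))
    return SegmentTrace(
        segment=segment,
        pass1=sorted(pass1, key=lambda t: t[1]),
        pass2=pass2,
        chosen_id=chosen,
    )


# ---------------------------------------------------------------------------
# imitation
# ---------------------------------------------------------------------------

def imitate_word(
    word_audio: np.ndarray,
    sample_rate: int,
    memory: AssociationMemory,
    index: TemplateIndex,
    patterns_by_id: Dict[str, MotorPattern],
    caregiver_sex: str = "female",
    noise_floor: float = 1e-7,
    synth_config: Optional[SynthConfig] = None,
    dynamics: Optional[MotorDynamicsConfig] = None,
    alternate_rank: int = 0,
) -> Tuple[np.ndarray, RecognitionTrace]:
    """Segment, recognize, recall, transfer intonation, and speak.

    ``alternate_rank`` selects the n-th-best pass-2 candidate per segment
    (retry attempts walk down the ranking).  Segments whose chosen
    response has no recallable motor pattern are skipped.
    """
    if synth_config is None:
        synth_config = SynthConfig()
    if dynamics is None:
        dynamics = MotorDynamicsConfig()
    segments = segment_word(word_audio, sample_rate, noise_floor)
    if not segments:
        raise ImitationError("nothing heard: no segments above noise floor")
    trace = RecognitionTrace()
    recalled: List[MotorPattern] = []
    for seg in segments:
        a = int(seg.start * sample_rate)
        b = int(seg.end * sample_rate)
        seg_audio = word_audio[a:b]
        st = recognize_two_pass(seg_audio, sample_rate, index, seg)
        rank = min(alternate_rank, len(st.pass2) - 1)
        st.chosen_id = st.pass2[rank][0]
        trace.segments.append(st)
        pattern = patterns_by_id.get(st.chosen_id)
        if pattern is None:
            continue
        spec = extract_intonation(seg_audio, sample_rate, caregiver_sex)
        recalled.append(apply_intonation(pattern, spec))
    if not recalled:
        return np.zeros(0), trace
    frames: List = []
    for pat in recalled:
        frames.extend(
            interpolate_trajectory(pat, dynamics, synth_config.frame_period,
                                   synth_config)
        )
    result = synthesize(frames, synth_config)
    return result.waveform, trace


@dataclass
class WordOutcome:
    word: str
    accepted: bool
    attempts: int
    chosen_ids: List[str] = field(default_factory=list)


def run_word_session(
    word_list: Sequence[str],
    speak_word,
    evaluate_attempt,
    memory: AssociationMemory,
    index: TemplateIndex,
    patterns_by_id: Dict[str, MotorPattern],
    caregiver_sex: str = "female",
    max_attempts: int = MAX_ATTEMPTS,
    synth_config: Optional[SynthConfig] = None,
) -> List[WordOutcome]:
    """Teach each word in a repetitive accept/reject loop.

    ``speak_word(word) -> (waveform, sample_rate)`` produces the caregiver
    prompt; ``evaluate_attempt(word, waveform) -> bool`` is the caregiver's
    accept judgment.  Rejections try the next-ranked recognition
    alternates; after ``max_attempts`` the caregiver gives up on the word.
    """
    outcomes: List[WordOutcome] = []
    for word in word_list:
        prompt, sr = speak_word(word)
        accepted = False
        attempts = 0
        chosen: List[str] = []
        for rank in range(max_attempts):
            attempts += 1
            try:
                out, trace = imitate_word(
                    prompt, sr, memory, index, patterns_by_id,
                    caregiver_sex, synth_config=synth_config,
                    alternate_rank=rank,
                )
            except ImitationError:
                break
            chosen = [st.chosen_id for st in trace.segments]
            if len(out) and evaluate_attempt(word, out):
                accepted = True
                break
        outcomes.append(WordOutcome(word, accepted, attempts, chosen))
    return outcomes
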