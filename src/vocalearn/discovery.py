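"""Unsupervised discovery of sound-producing motor patterns.

Candidate gestural targets are drawn uniformly from the valid range and
improved by a few iterations of bounded quasi-Newton ascent on a scalar
reward

    R = w_sal * salience + w_div * diversity - w_eff * effort - w_sens * sensitivity.

Salience rewards sensory consequences (band-weighted acoustic power and
touch); diversity rewards novelty relative to the patterns already kept
(minimum distance in acoustic, tactile and motor space); effort penalizes
articulator movement and voicing loudness; sensitivity penalizes
articulations whose acoustics change strongly under small (+0.1) parameter
perturbations, favoring the stable regions of articulatory space that
quantal theories of speech predict.

Attention presets re-weight salience and diversity so separate runs find
vowels (low-frequency power), fricatives (high-frequency power) and
plosives/nasals (touch).  The numeric preset weights here are this
package's own calibration — they are not published constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from . import auditory
from .auditory import (
    AuditoryRepresentation,
    SalienceWeights,
    dtw_distance,
    estimate_salience,
    gammatone_analyze,
)
from .motor import (
    MAX_SUB_PATTERNS,
    MotorDynamicsConfig,
    MotorPattern,
    SubPattern,
    interpolate_trajectory,
)
from .synth import ControlFrame, SynthConfig, SynthResult, synthesize

logger = logging.getLogger(__name__)

TOUCH_PROFILE_LEN = 32
MOTOR_VECTOR_LEN = MAX_SUB_PATTERNS * 31

# articulatory parameter indices searched by discovery; P8-P10 are set by
# the preset (voicing and nasality are enabled or disabled explicitly,
# never left to the optimizer)
SEARCH_PARAMS = slice(0, 7)

PRESETS = {
    "vowel": dict(
        salience=SalienceWeights(w_low=1.0, w_high=0.1, w_touch=0.0),
        diversity_space=(1.0, 0.1, 0.1),
        p8=-0.3, p10=-1.0, voiced=True, category="vowel",
    ),
    "fricative": dict(
        salience=SalienceWeights(w_low=0.05, w_high=1.0, w_touch=0.0),
        diversity_space=(1.0, 0.1, 0.1),
        p8=0.6, p10=-1.0, voiced=False, category="fricative",
    ),
    "plosive": dict(
        salience=SalienceWeights(w_low=0.2, w_high=0.1, w_touch=1.0),
        diversity_space=(0.2, 1.0, 0.2),
        p8=-0.3, p10=-1.0, voiced=True, category="plosive",
    ),
}


@dataclass
class RewardBreakdown:
    """The four reward terms and their weighted total."""

    salience: float
    diversity: float
    effort: float
    sensitivity: float
    total: float

    @staticmethod
    def combine(salience, diversity, effort, sensitivity, weights) -> "RewardBreakdown":
        w_sal, w_div, w_eff, w_sens = weights
        total = (
            w_sal * salience + w_div * diversity
            - w_eff * effort - w_sens * sensitivity
        )
        return RewardBreakdown(salience, diversity, effort, sensitivity, total)


@dataclass
class DiscoveryConfig:
    """Settings of a discovery run."""

    attention_preset: str = "vowel"
    term_weights: Tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    diversity_space_weights: Optional[Tuple[float, float, float]] = None
    perturbation_delta: float = 0.1
    optimizer_iterations: int = 3
    caps: Dict[str, int] = field(
        default_factory=lambda: {"vowels": 15, "plosives": 15, "fricatives": 10}
    )
    seed: int = 0
    diversity_ceiling: float = 1.0
    hold_duration: float = 0.25
    # salience normalization: band powers of the synthesizer output are tiny
    # relative to full scale; this gain brings the salience term to O(1)
    salience_gain: float = 2e4
    effort_weight_per_param: float = 0.02
    effort_voice_weight: float = 0.01
    sensitivity_gain: float = 100.0
    # artifact filter
    max_clip_fraction: float = 0.001
    max_silent_fraction: float = 0.5
    max_flux_spike: float = 20.0

    def __post_init__(self) -> None:
        if self.attention_preset not in PRESETS:
            raise ValueError(f"unknown preset {self.attention_preset!r}")
        if self.perturbation_delta <= 0:
            raise ValueError("perturbation_delta must be > 0")
        if any(c <= 0 for c in self.caps.values()):
            raise ValueError("caps must be positive")
        if any(w < 0 for w in self.term_weights):
            raise ValueError("term weights must be >= 0")


@dataclass
class PatternRecord:
    """A kept pattern with its cached sensory representations."""

    pattern: MotorPattern
    reward: RewardBreakdown
    rep: AuditoryRepresentation
    touch_profile: np.ndarray
    motor_vector: np.ndarray
    init_reward: float = float("-inf")  # reward of the uniform initialization


# ---------------------------------------------------------------------------
# reward terms
# ---------------------------------------------------------------------------

def compute_effort(
    pattern: MotorPattern,
    frames: Sequence[ControlFrame],
    config: Optional[DiscoveryConfig] = None,
) -> float:
    """Movement cost plus voicing loudness.

    effort = sum_t sum_param w_param |dparam/dt| + w_voice * sum_t phonation(P8).
    Zero for a static, silent posture.
    """
    if config is None:
        config = DiscoveryConfig()
    arr = np.array([f.as_array() for f in frames])
    if len(arr) < 2:
        movement = 0.0
    else:
        movement = float(
            config.effort_weight_per_param * np.sum(np.abs(np.diff(arr, axis=0)))
        )
    from .synth import voicing_amplitude

    voice = config.effort_voice_weight * float(
        sum(voicing_amplitude(f.p8_glottal_area) for f in frames)
    )
    return movement + voice


def touch_profile(result: SynthResult, length: int = TOUCH_PROFILE_LEN) -> np.ndarray:
    """Touch indicator resampled to a fixed length (tactile space)."""
    t = result.touch_indicator.astype(float)
    if len(t) == 0:
        return np.zeros(length)
    src = np.linspace(0, 1, len(t))
    dst = np.linspace(0, 1, length)
    return np.interp(dst, src, t)


def motor_vector(pattern: MotorPattern) -> np.ndarray:
    """Serialized pattern padded with zeros to the 3-sub-pattern length."""
    v = pattern.serialize()
    out = np.zeros(MOTOR_VECTOR_LEN)
    out[: len(v)] = v
    return out


def compute_diversity(
    pattern_or_record,
    memory: Sequence[PatternRecord],
    space_weights: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    ceiling: float = 1.0,
    rep: Optional[AuditoryRepresentation] = None,
    touch: Optional[np.ndarray] = None,
) -> float:
    """Weighted minimum distance to every previously kept pattern.

    Components: acoustic (DTW on auditory reps), tactile (Euclidean on
    fixed-length touch profiles) and motor (Euclidean on serialized
    vectors).  An empty memory returns the configured ceiling.
    """
    if not memory:
        return float(ceiling)
    if isinstance(pattern_or_record, PatternRecord):
        rep = pattern_or_record.rep
        touch = pattern_or_record.touch_profile
        mvec = pattern_or_record.motor_vector
    else:
        mvec = motor_vector(pattern_or_record)
    w_ac, w_tac, w_mot = space_weights
    d_ac = min(dtw_distance(rep, m.rep) for m in memory) if w_ac > 0 else 0.0
    d_tac = (
        min(float(np.linalg.norm(touch - m.touch_profile)) for m in memory)
        if w_tac > 0 else 0.0
    )
    d_mot = (
        min(float(np.linalg.norm(mvec - m.motor_vector)) for m in memory)
        if w_mot > 0 else 0.0
    )
    return w_ac * d_ac + w_tac * d_tac + w_mot * d_mot


def _posture_frames(targets10: np.ndarray, synth_config: SynthConfig,
                    duration: float = 0.15) -> List[ControlFrame]:
    n = max(2, int(round(duration / synth_config.frame_period)))
    frame = ControlFrame.from_array(np.clip(targets10, -1, 1))
    return [frame] * n


_SENS_CACHE: dict = {}


def compute_sensitivity(
    pattern: MotorPattern,
    delta: float = 0.1,
    synth_config: Optional[SynthConfig] = None,
    gain: float = 100.0,
) -> float:
    """Acoustic sensitivity to small articulatory perturbations.

    Parameters P1..P5 of the pattern's (first) target posture are each
    increased by ``delta`` (clipped to +1); the remaining parameters are
    held at the evaluation constants.  Each perturbed posture is
    synthesized and analyzed, and the sensitivity is the root sum of
    squares of the five auditory distances.  Perturbed postures are
    discarded afterwards.
    """
    if delta == 0:
        return 0.0
    if synth_config is None:
        synth_config = SynthConfig()
    base = pattern.sub_patterns[0].targets.copy()
    # evaluation constants for the non-articulatory parameters
    base[7] = -0.3   # phonation
    base[8] = 0.0
    base[9] = 1.0 if pattern.nasal_port_open else -1.0
    cache_key = (np.round(base, 6).tobytes(), delta, gain,
                 synth_config.tract_scale, synth_config.sample_rate)
    if cache_key in _SENS_CACHE:
        return _SENS_CACHE[cache_key]
    ref = synthesize(_posture_frames(base, synth_config), synth_config)
    ref_rep = gammatone_analyze(ref.waveform, synth_config.sample_rate)
    dists = []
    for i in range(5):
        pert = base.copy()
        pert[i] = min(1.0, pert[i] + delta)
        res = synthesize(_posture_frames(pert, synth_config), synth_config)
        rep = gammatone_analyze(res.waveform, synth_config.sample_rate)
        dists.append(dtw_distance(ref_rep, rep))
    value = gain * float(np.sqrt(np.sum(np.square(dists))))
    if len(_SENS_CACHE) > 4096:
        _SENS_CACHE.clear()
    _SENS_CACHE[cache_key] = value
    return value


def passes_artifact_filter(result: SynthResult, rep: AuditoryRepresentation,
                           config: DiscoveryConfig) -> bool:
    """Automated replacement for hand-removal of implausible sounds.

    Rejects clipping, mostly-silent output and spectral-flux spikes
    (clicks).
    """
    x = result.waveform
    if np.mean(np.abs(x) >= 0.999) > config.max_clip_fraction:
        return False
    frame_energy = rep.tf_matrix.sum(axis=0)
    peak = frame_energy.max() if frame_energy.size else 0.0
    if peak <= 0:
        return True  # silent patterns are judged by salience, not artifacts
    silent_frac = np.mean(frame_energy < 0.01 * peak)
    if silent_frac > config.max_silent_fraction and result.touch.max() < 0:
        return False
    flux = np.linalg.norm(np.diff(rep.tf_matrix, axis=1), axis=0)
    if flux.size and np.mean(flux) > 0:
        if flux.max() / (np.mean(flux) + 1e-12) > config.max_flux_spike:
            return False
    return True


# ---------------------------------------------------------------------------
# reward evaluation
# ---------------------------------------------------------------------------

def evaluate_reward(
    pattern: MotorPattern,
    memory: Sequence[PatternRecord],
    config: DiscoveryConfig,
    synth_config: Optional[SynthConfig] = None,
    dynamics: Optional[MotorDynamicsConfig] = None,
    with_sensitivity: bool = True,
    return_record: bool = False,
):
    """Synthesize a pattern once and score all four reward terms."""
    if synth_config is None:
        synth_config = SynthConfig()
    if dynamics is None:
        dynamics = MotorDynamicsConfig()
    preset = PRESETS[config.attention_preset]
    try:
        frames = interpolate_trajectory(
            pattern, dynamics, synth_config.frame_period, synth_config
        )
        result = synthesize(frames, synth_config)
    except Exception as exc:  # noqa: BLE001 - propagate with pattern id
        raise RuntimeError(f"synthesis failed for pattern {pattern.id!r}") from exc
    rep = gammatone_analyze(result.waveform, synth_config.sample_rate)
    sw = preset["salience"]
    low, high = auditory.band_powers(rep, sw.low_high_boundary)
    touch_mean = float(np.mean(result.touch_indicator))
    # acoustic band powers are tiny relative to the touch indicator, so the
    # acoustic part is brought to O(1) by salience_gain while touch is not
    sal = (
        config.salience_gain * (sw.w_low * low + sw.w_high * high)
        + sw.w_touch * touch_mean
    )
    tprof = touch_profile(result)
    space_w = config.diversity_space_weights or preset["diversity_space"]
    div = compute_diversity(
        pattern, memory, space_w, config.diversity_ceiling,
        rep=rep, touch=tprof,
    )
    eff = compute_effort(pattern, frames, config)
    sens = (
        compute_sensitivity(
            pattern, config.perturbation_delta, synth_config,
            gain=config.sensitivity_gain,
        )
        if with_sensitivity
        else 0.0
    )
    breakdown = RewardBreakdown.combine(sal, div, eff, sens, config.term_weights)
    if return_record:
        record = PatternRecord(
            pattern=pattern, reward=breakdown, rep=rep,
            touch_profile=tprof, motor_vector=motor_vector(pattern),
        )
        return breakdown, record, result
    return breakdown


# ---------------------------------------------------------------------------
# discovery loop
# ---------------------------------------------------------------------------

def _make_pattern(targets7: np.ndarray, preset: dict, config: DiscoveryConfig,
                  voiced: bool, nasal: bool, pid: str) -> MotorPattern:
    targets = np.zeros(10)
    targets[SEARCH_PARAMS] = np.clip(targets7, -1, 1)
    targets[7] = preset["p8"] if voiced else 0.6
    if preset["category"] != "vowel" and voiced:
        targets[7] = -0.3
    targets[8] = 0.0
    targets[9] = 1.0 if nasal else -1.0
    category = preset["category"]
    if nasal:
        category = "nasal"
    sp = SubPattern(
        targets=targets,
        start_times=np.zeros(10),
        hold_durations=np.full(10, config.hold_duration),
        speed_scaling=1.0,
    )
    return MotorPattern(
        [sp], category=category, voiced=voiced,
        nasal_port_open=nasal, id=pid,
    )


def discover_patterns(
    config: DiscoveryConfig,
    n_candidates: int,
    synth_config: Optional[SynthConfig] = None,
    memory: Optional[List[PatternRecord]] = None,
) -> List[PatternRecord]:
    """Run seeded candidate initialization + quasi-Newton reward ascent.

    Each candidate starts from uniform(-1, 1) articulatory targets and is
    refined by ``optimizer_iterations`` outer iterations of bounded
    L-BFGS-B (finite-difference gradients) on the total reward.  Voicing
    and nasality are toggled per candidate according to the preset rather
    than optimized.  Kept patterns must pass the automated artifact
    filter.
    """
    if synth_config is None:
        synth_config = SynthConfig()
    rng = np.random.default_rng(config.seed)
    preset = PRESETS[config.attention_preset]
    kept: List[PatternRecord] = list(memory) if memory else []
    n_prior = len(kept)
    for ci in range(n_candidates):
        if config.attention_preset == "vowel":
            voiced, nasal = True, False
        elif config.attention_preset == "fricative":
            voiced, nasal = (ci % 2 == 0), False
        else:  # plosive preset: alternate voicing and velo-pharyngeal port
            voiced = ci % 2 == 0
            nasal = ci % 4 >= 2
        pid = f"{config.attention_preset}-{config.seed}-{ci}"
        x0 = rng.uniform(-1, 1, 7)

        def objective(x: np.ndarray) -> float:
            pat = _make_pattern(x, preset, config, voiced, nasal, pid)
            bd = evaluate_reward(pat, kept, config, synth_config)
            return -bd.total

        init_reward = -objective(x0)
        res = minimize(
            objective, x0, method="L-BFGS-B",
            bounds=[(-1, 1)] * 7,
            options={
                "maxiter": config.optimizer_iterations,
                "maxfun": 40 * config.optimizer_iterations,
                "eps": 0.05,
            },
        )
        x_best = res.x if -res.fun >= init_reward else x0
        pat = _make_pattern(x_best, preset, config, voiced, nasal, pid)
        breakdown, record, result = evaluate_reward(
            pat, kept, config, synth_config, return_record=True
        )
        record.init_reward = float(init_reward)
        if not passes_artifact_filter(result, record.rep, config):
            logger.info("artifact filter rejected %s", pid)
            continue
        kept.append(record)
    return kept[n_prior:]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def dtw_matrix(reps: Sequence[AuditoryRepresentation]) -> np.ndarray:
    n = len(reps)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dtw_distance(reps[i], reps[j])
    return d


def kmedoids_from_distances(dist: np.ndarray, k: int, seed: int = 0,
                            max_iter: int = 50):
    """Plain k-medoids (PAM-style alternation) on a distance matrix."""
    n = len(dist)
    if k > n:
        raise ValueError(f"k = {k} exceeds number of items {n}")
    rng = np.random.default_rng(seed)
    medoids = rng.choice(n, size=k, replace=False)
    assign = np.argmin(dist[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.where(assign == c)[0]
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        new_assign = np.argmin(dist[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_assign, assign):
            break
        medoids, assign = new_medoids, new_assign
    return medoids, assign


def cluster_patterns(
    records: Sequence[PatternRecord],
    mode: str,
    k: int,
    seed: int = 0,
):
    """Cluster kept patterns; returns list of {exemplar, members} dicts.

    ``motor_kmeans`` runs Lloyd's algorithm on serialized motor vectors
    (used for plosive configurations); ``acoustic_dtw`` runs k-medoids on
    DTW distances between auditory representations (vocalic and fricative
    sounds).  The exemplar of a k-means cluster is the member nearest the
    centroid; of a DTW cluster, the medoid.
    """
    n = len(records)
    if k > n:
        raise ValueError(f"k = {k} exceeds number of patterns {n}")
    if mode == "motor_kmeans":
        from sklearn.cluster import KMeans

        x = np.array([r.motor_vector for r in records])
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(x)
        clusters = []
        for c in range(k):
            members = np.where(km.labels_ == c)[0]
            d = np.linalg.norm(x[members] - km.cluster_centers_[c], axis=1)
            clusters.append(
                {"exemplar": int(members[np.argmin(d)]),
                 "members": members.tolist()}
            )
        return clusters
    if mode == "acoustic_dtw":
        dist = dtw_matrix([r.rep for r in records])
        medoids, assign = kmedoids_from_distances(dist, k, seed)
        return [
            {"exemplar": int(medoids[c]),
             "members": np.where(assign == c)[0].tolist()}
            for c in range(k)
        ]
    raise ValueError(f"unknown clustering mode {mode!r}")


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------

CV_TEMPLATES = ("CvV", "CuV", "FvV", "FuV", "NV")
VC_TEMPLATES = ("VCv", "VCu", "VFv", "VFu", "VN")


def _classify(patterns: Sequence[MotorPattern]) -> Dict[str, List[MotorPattern]]:
    classes: Dict[str, List[MotorPattern]] = {
        "V": [], "Cv": [], "Cu": [], "Fv": [], "Fu": [], "N": []
    }
    for p in patterns:
        if p.category == "vowel":
            classes["V"].append(p)
        elif p.category == "nasal":
            classes["N"].append(p)
        elif p.category == "plosive":
            classes["Cv" if p.voiced else "Cu"].append(p)
        elif p.category == "fricative":
            classes["Fv" if p.voiced else "Fu"].append(p)
    return classes


def generate_composites(patterns: Sequence[MotorPattern],
                        gap: float = 0.0) -> List[MotorPattern]:
    """Cross-products of the CV / VC / VV templates over the inventory.

    CV: CvV, CuV, FvV, FuV, NV; VC: VCv, VCu, VFv, VFu, VN; VV: ordered
    vowel pairs excluding self-pairs.  Template families whose consonant
    class is missing are skipped with a warning.
    """
    from .motor import concatenate_patterns

    classes = _classify(patterns)
    out: List[MotorPattern] = []
    for tmpl in CV_TEMPLATES:
        cclass = tmpl[:-1]
        if not classes[cclass]:
            logger.warning("no %s patterns; skipping %s composites", cclass, tmpl)
            continue
        for c in classes[cclass]:
            for v in classes["V"]:
                out.append(concatenate_patterns(c, v, gap))
    for tmpl in VC_TEMPLATES:
        cclass = tmpl[1:]
        if not classes[cclass]:
            logger.warning("no %s patterns; skipping %s composites", cclass, tmpl)
            continue
        for v in classes["V"]:
            for c in classes[cclass]:
                out.append(concatenate_patterns(v, c, gap))
    vowels = classes["V"]
    for v1 in vowels:
        for v2 in vowels:
            if v1 is v2:
                continue
            out.append(concatenate_patterns(v1, v2, gap))
    return out
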