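"""Gestural-score motor patterns and articulator dynamics.

A motor pattern is a sequence of up to three sub-patterns.  Each sub-pattern
holds a 10-element target vector, a 10-element starting-time vector, a
10-element hold-duration vector and one overall transition-speed scaling —
31 scalars in all.  Articulators move between targets along the step
response of a critically damped second-order system,

    x(t) = x1 + (x0 - x1) (1 + w t) exp(-w t),

which reaches the target as fast as possible without overshoot.  The base
rate constant ``omega_default`` (40 s^-1, a typical articulation speed; not
a measured constant) is swapped for ``omega_post_closure`` (160 s^-1) on
frames immediately following a closure release, reflecting the rapid
transitions of plosive releases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .synth import ControlFrame, SynthConfig, compute_area_function

SUB_PATTERN_SIZE = 31
MAX_SUB_PATTERNS = 3

CATEGORIES = ("vowel", "plosive", "fricative", "nasal", "composite")


class MotorValidationError(ValueError):
    pass


@dataclass
class SubPattern:
    """One gestural target: per-parameter targets, onsets, holds + speed."""

    targets: np.ndarray
    start_times: np.ndarray
    hold_durations: np.ndarray
    speed_scaling: float = 1.0

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        self.start_times = np.asarray(self.start_times, dtype=float)
        self.hold_durations = np.asarray(self.hold_durations, dtype=float)
        for name, vec in (
            ("targets", self.targets),
            ("start_times", self.start_times),
            ("hold_durations", self.hold_durations),
        ):
            if vec.shape != (10,):
                raise MotorValidationError(f"{name} must have 10 elements")
        if np.any(np.abs(self.targets) > 1.0):
            raise MotorValidationError("targets must lie in [-1, 1]")
        if np.any(self.start_times < 0) or np.any(self.hold_durations < 0):
            raise MotorValidationError("times must be non-negative")
        if self.speed_scaling <= 0:
            raise MotorValidationError("speed_scaling must be positive")

    @property
    def extent(self) -> float:
        """Time from sub-pattern onset until the last hold ends (s)."""
        return float(np.max(self.start_times + self.hold_durations))


def serialize_sub_pattern(sp: SubPattern) -> np.ndarray:
    """Flatten to exactly 31 scalars (targets, starts, holds, speed)."""
    return np.concatenate(
        [sp.targets, sp.start_times, sp.hold_durations, [sp.speed_scaling]]
    )


def deserialize_sub_pattern(vec) -> SubPattern:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (SUB_PATTERN_SIZE,):
        raise MotorValidationError(
            f"sub-pattern vector must have {SUB_PATTERN_SIZE} elements, "
            f"got {vec.shape}"
        )
    return SubPattern(vec[:10], vec[10:20], vec[20:30], float(vec[30]))


@dataclass
class MotorPattern:
    """A discovered (or composite) vocal motor scheme."""

    sub_patterns: List[SubPattern]
    category: str = "vowel"
    voiced: bool = True
    nasal_port_open: bool = False
    id: str = ""

    def __post_init__(self) -> None:
        if not (1 <= len(self.sub_patterns) <= MAX_SUB_PATTERNS):
            raise MotorValidationError(
                f"need 1..{MAX_SUB_PATTERNS} sub-patterns, "
                f"got {len(self.sub_patterns)}"
            )
        if self.category not in CATEGORIES:
            raise MotorValidationError(f"unknown category {self.category!r}")

    @property
    def extent(self) -> float:
        t = 0.0
        end = 0.0
        for sp in self.sub_patterns:
            end = max(end, t + sp.extent)
            t += sp.extent
        return end

    def serialize(self) -> np.ndarray:
        return np.concatenate([serialize_sub_pattern(sp) for sp in self.sub_patterns])

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "category": self.category,
            "voiced": self.voiced,
            "nasal_port_open": self.nasal_port_open,
            "sub_patterns": [
                {
                    "targets": sp.targets.tolist(),
                    "start_times": sp.start_times.tolist(),
                    "hold_durations": sp.hold_durations.tolist(),
                    "speed_scaling": sp.speed_scaling,
                }
                for sp in self.sub_patterns
            ],
        }

    @staticmethod
    def from_dict(d: dict) -> "MotorPattern":
        return MotorPattern(
            sub_patterns=[
                SubPattern(
                    np.array(sp["targets"]),
                    np.array(sp["start_times"]),
                    np.array(sp["hold_durations"]),
                    sp["speed_scaling"],
                )
                for sp in d["sub_patterns"]
            ],
            category=d.get("category", "vowel"),
            voiced=d.get("voiced", True),
            nasal_port_open=d.get("nasal_port_open", False),
            id=d.get("id", ""),
        )


@dataclass
class MotorDynamicsConfig:
    """Rate constants of the critically damped articulator dynamics (s^-1)."""

    omega_default: float = 40.0
    omega_post_closure: float = 160.0

    def __post_init__(self) -> None:
        if self.omega_default <= 0 or self.omega_post_closure <= 0:
            raise MotorValidationError("omega values must be positive")
        if self.omega_post_closure < self.omega_default:
            raise MotorValidationError(
                "omega_post_closure must be >= omega_default"
            )


def critically_damped_step(x0: float, x1: float, omega: float, t) -> np.ndarray:
    """Closed-form step response x(t) = x1 + (x0-x1)(1+wt)exp(-wt), t >= 0."""
    t = np.asarray(t, dtype=float)
    return x1 + (x0 - x1) * (1.0 + omega * t) * np.exp(-omega * t)


def interpolate_trajectory(
    pattern: MotorPattern,
    dynamics: MotorDynamicsConfig | None = None,
    frame_period: float = 0.005,
    synth_config: Optional[SynthConfig] = None,
    tail: float = 0.05,
) -> List[ControlFrame]:
    """Convert a motor pattern to a control-frame sequence.

    Every parameter starts from the neutral resting state (all zeros) and,
    once its target activates, relaxes toward it along the critically damped
    closed form with effective omega = omega_base * speed_scaling.  Before
    activation a parameter holds its previous value, so trajectories are
    monotone between states and never overshoot.  Frames immediately
    following a closure release (contact at t-1 gone at t) are recomputed
    with ``omega_post_closure``, producing the fast transitions of plosive
    releases.  ``tail`` extends the sequence past the last hold so releases
    can play out.
    """
    if dynamics is None:
        dynamics = MotorDynamicsConfig()
    if frame_period <= 0:
        raise MotorValidationError("frame_period must be positive")
    if synth_config is None:
        synth_config = SynthConfig(frame_period=frame_period)

    # absolute activation times per (sub-pattern, parameter)
    events = []  # (activation_time, param_index, target, speed)
    offset = 0.0
    for sp in pattern.sub_patterns:
        for i in range(10):
            events.append(
                (offset + sp.start_times[i], i, sp.targets[i], sp.speed_scaling)
            )
        offset += sp.extent
    total = pattern.extent + tail
    n_frames = max(1, int(round(total / frame_period)))

    events.sort(key=lambda e: e[0])
    times = np.arange(n_frames) * frame_period

    def render(omega_base: float):
        """Evaluate the piecewise closed form frame by frame."""
        active_target = np.zeros(10)
        active = np.zeros(10, dtype=bool)
        seg_start = np.zeros(10)  # time the current segment began
        seg_x0 = np.zeros(10)
        omega_eff = np.full(10, omega_base)
        traj = np.zeros((n_frames, 10))
        ev = 0
        for fi, t in enumerate(times):
            while ev < len(events) and events[ev][0] <= t:
                _, pi, tgt, speed = events[ev]
                # re-anchor segment at current value
                seg_x0[pi] = traj[fi - 1, pi] if fi > 0 else 0.0
                seg_start[pi] = events[ev][0]
                active_target[pi] = tgt
                active[pi] = True
                omega_eff[pi] = omega_base * speed
                ev += 1
            for pi in range(10):
                if active[pi]:
                    traj[fi, pi] = critically_damped_step(
                        seg_x0[pi], active_target[pi],
                        omega_eff[pi], t - seg_start[pi],
                    )
                else:
                    traj[fi, pi] = seg_x0[pi]
        return traj

    traj = render(dynamics.omega_default)

    frames = [ControlFrame.from_array(np.clip(row, -1, 1)) for row in traj]

    # closure-release speedup: recompute frames after a release with the
    # fast omega, re-anchored at the release frame
    touch = np.array(
        [compute_area_function(f, synth_config).closed for f in frames]
    )
    release_idx = [
        i for i in range(1, n_frames) if touch[i - 1] and not touch[i]
    ]
    if release_idx:
        for ri in release_idx:
            t_rel = times[ri - 1]
            x_rel = traj[ri - 1]
            for fi in range(ri, n_frames):
                dt = times[fi] - t_rel
                for pi in range(10):
                    # target currently driving this parameter
                    tgt = traj[-1, pi]
                    traj[fi, pi] = critically_damped_step(
                        x_rel[pi], tgt, dynamics.omega_post_closure, dt
                    )
                # stop once the fast trajectory has converged
                if np.max(np.abs(traj[fi] - traj[-1])) < 1e-4:
                    break
        frames = [ControlFrame.from_array(np.clip(row, -1, 1)) for row in traj]
    return frames


def concatenate_patterns(a: MotorPattern, b: MotorPattern, gap: float = 0.0) -> MotorPattern:
    """Join two patterns into a composite utterance (CV, VC, VV ...).

    b's sub-patterns follow a's, offset by a's extent plus ``gap``.  The
    combined sub-pattern count may not exceed three.
    """
    if gap < 0:
        raise MotorValidationError("gap must be >= 0")
    combined = len(a.sub_patterns) + len(b.sub_patterns)
    if combined > MAX_SUB_PATTERNS:
        raise MotorValidationError(
            f"combined sub-pattern count {combined} exceeds {MAX_SUB_PATTERNS}"
        )
    subs = [
        SubPattern(
            sp.targets.copy(), sp.start_times.copy(),
            sp.hold_durations.copy(), sp.speed_scaling,
        )
        for sp in a.sub_patterns
    ]
    first_b = True
    for sp in b.sub_patterns:
        starts = sp.start_times.copy()
        if first_b and gap > 0:
            starts = starts + gap
            first_b = False
        subs.append(
            SubPattern(sp.targets.copy(), starts,
                       sp.hold_durations.copy(), sp.speed_scaling)
        )
    return MotorPattern(
        sub_patterns=subs,
        category="composite",
        voiced=a.voiced or b.voiced,
        nasal_port_open=a.nasal_port_open or b.nasal_port_open,
        id=f"{a.id}+{b.id}" if (a.id or b.id) else "",
    )


def save_inventory(patterns: List[MotorPattern], path) -> None:
    """Persist a motor-pattern inventory as JSON."""
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in patterns], fh, indent=1)


def load_inventory(path) -> List[MotorPattern]:
    with open(path) as fh:
        return [MotorPattern.from_dict(d) for d in json.load(fh)]
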