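"""Reward terms, discovery loop, clustering, and composite generation."""

import numpy as np
import pytest

import vocalearn.discovery as D
from vocalearn.discovery import (
    DiscoveryConfig,
    PatternRecord,
    RewardBreakdown,
    cluster_patterns,
    compute_diversity,
    compute_effort,
    compute_sensitivity,
    discover_patterns,
    evaluate_reward,
    generate_composites,
    kmedoids_from_distances,
    motor_vector,
)
from vocalearn.motor import MotorPattern, SubPattern
from vocalearn.synth import ControlFrame


def make_pattern(targets=None, category="vowel", voiced=True, nasal=False, pid="p"):
    t = np.zeros(10) if targets is None else np.asarray(targets, dtype=float)
    sp = SubPattern(t, np.zeros(10), np.full(10, 0.2), 1.0)
    return MotorPattern([sp], category=category, voiced=voiced,
                        nasal_port_open=nasal, id=pid)


def make_record(pattern, rep, touch=None):
    return PatternRecord(
        pattern=pattern, reward=RewardBreakdown(0, 0, 0, 0, 0), rep=rep,
        touch_profile=np.zeros(32) if touch is None else touch,
        motor_vector=motor_vector(pattern),
    )


class TestEffort:
    def test_static_silent_posture_is_zero(self):
        frames = [ControlFrame(p8_glottal_area=1.0)] * 10
        assert compute_effort(make_pattern(), frames) == 0.0

    def test_faster_movement_costs_more(self):
        cfg = DiscoveryConfig()
        slow = [ControlFrame.from_array(np.full(10, v))
                for v in np.linspace(0, 0.5, 20)]
        fast = [ControlFrame.from_array(np.full(10, v))
                for v in np.linspace(0, 0.5, 20)] * 2  # same path twice
        assert compute_effort(make_pattern(), fast, cfg) \
            > compute_effort(make_pattern(), slow, cfg)

    def test_matches_hand_computed_sum(self):
        cfg = DiscoveryConfig(effort_weight_per_param=1.0, effort_voice_weight=0.0)
        arrs = [np.zeros(10), np.full(10, 0.1), np.full(10, 0.3)]
        frames = [ControlFrame.from_array(a) for a in arrs]
        # sum |delta| = 10*0.1 + 10*0.2 = 3.0
        assert compute_effort(make_pattern(), frames, cfg) == pytest.approx(3.0)

    def test_voicing_contributes(self):
        cfg = DiscoveryConfig(effort_weight_per_param=0.0, effort_voice_weight=1.0)
        voiced = [ControlFrame(p8_glottal_area=-0.3)] * 5
        assert compute_effort(make_pattern(), voiced, cfg) == pytest.approx(5.0)


class TestDiversity:
    def test_empty_memory_returns_ceiling(self):
        assert compute_diversity(make_pattern(), [], ceiling=1.0) == 1.0
        assert compute_diversity(make_pattern(), [], ceiling=2.5) == 2.5

    def test_identical_pattern_scores_zero(self, rng):
        from vocalearn.auditory import AuditoryRepresentation

        rep = AuditoryRepresentation(
            rng.uniform(0, 1, (4, 6)), 100.0 * 2 ** np.arange(4), 100.0
        )
        pat = make_pattern(rng.uniform(-1, 1, 10))
        mem = [make_record(pat, rep)]
        d = compute_diversity(pat, mem, (1.0, 1.0, 1.0), rep=rep,
                              touch=np.zeros(32))
        assert d == 0.0

    def test_equals_brute_force_minimum(self, rng):
        from vocalearn.auditory import AuditoryRepresentation, dtw_distance

        def rand_rep():
            return AuditoryRepresentation(
                rng.uniform(0, 1, (4, 5)), 100.0 * 2 ** np.arange(4), 100.0
            )

        probe_pat = make_pattern(rng.uniform(-1, 1, 10))
        probe_rep = rand_rep()
        probe_touch = rng.uniform(0, 1, 32)
        mem = [
            make_record(make_pattern(rng.uniform(-1, 1, 10), pid=f"m{i}"),
                        rand_rep(), rng.uniform(0, 1, 32))
            for i in range(2)
        ]
        got = compute_diversity(probe_pat, mem, (1.0, 1.0, 1.0),
                                rep=probe_rep, touch=probe_touch)
        expected = (
            min(dtw_distance(probe_rep, m.rep) for m in mem)
            + min(np.linalg.norm(probe_touch - m.touch_profile) for m in mem)
            + min(np.linalg.norm(motor_vector(probe_pat) - m.motor_vector)
                  for m in mem)
        )
        assert got == pytest.approx(expected)


class TestSensitivity:
    def test_zero_delta_is_zero(self):
        assert compute_sensitivity(make_pattern(), delta=0.0) == 0.0

    def test_pythagorean_identity_with_stubbed_distances(self, monkeypatch):
        distances = iter([3.0, 4.0, 0.0, 0.0, 0.0])
        monkeypatch.setattr(D, "dtw_distance", lambda a, b: next(distances))
        D._SENS_CACHE.clear()
        value = compute_sensitivity(make_pattern(), delta=0.1, gain=1.0)
        assert value == pytest.approx(5.0)
        D._SENS_CACHE.clear()

    def test_all_zero_distances_give_zero(self, monkeypatch):
        monkeypatch.setattr(D, "dtw_distance", lambda a, b: 0.0)
        D._SENS_CACHE.clear()
        assert compute_sensitivity(make_pattern(), delta=0.1) == 0.0
        D._SENS_CACHE.clear()

    def test_matches_brute_force_resynthesis(self, rng):
        """Spot-check against an independent re-implementation."""
        from vocalearn.auditory import dtw_distance, gammatone_analyze
        from vocalearn.synth import SynthConfig, synthesize

        sc = SynthConfig()
        for _ in range(2):
            pat = make_pattern(rng.uniform(-0.5, 0.5, 10))
            base = pat.sub_patterns[0].targets.copy()
            base[7], base[8], base[9] = -0.3, 0.0, -1.0

            def posture_rep(vec):
                frames = [ControlFrame.from_array(np.clip(vec, -1, 1))] * 30
                res = synthesize(frames, sc)
                return gammatone_analyze(res.waveform, sc.sample_rate)

            ref = posture_rep(base)
            dists = []
            for i in range(5):
                pert = base.copy()
                pert[i] = min(1.0, pert[i] + 0.1)
                dists.append(dtw_distance(ref, posture_rep(pert)))
            expected = 100.0 * np.sqrt(np.sum(np.square(dists)))
            D._SENS_CACHE.clear()
            assert compute_sensitivity(pat, 0.1, sc) == pytest.approx(
                expected, rel=1e-6
            )


class TestReward:
    def test_all_zero_weights_give_zero_total(self):
        cfg = DiscoveryConfig(term_weights=(0, 0, 0, 0))
        bd = evaluate_reward(make_pattern(), [], cfg, with_sensitivity=False)
        assert bd.total == 0.0

    def test_silent_static_pattern_cannot_score_positive(self):
        cfg = DiscoveryConfig(term_weights=(1.0, 0.0, 1.0, 1.0))
        silent = make_pattern(np.array([0, 0, 0, 0, 0, 0, 0, 1.0, 0, -1.0]))
        bd = evaluate_reward(silent, [], cfg)
        assert bd.total <= 1e-9

    def test_total_reconstructs_from_terms(self, vowel_records):
        w = DiscoveryConfig().term_weights
        for rec in vowel_records:
            b = rec.reward
            expected = (w[0] * b.salience + w[1] * b.diversity
                        - w[2] * b.effort - w[3] * b.sensitivity)
            assert b.total == pytest.approx(expected, abs=1e-12)


class TestDiscovery:
    def test_seeded_run_is_reproducible(self):
        cfg = DiscoveryConfig(attention_preset="vowel", seed=77)
        a = discover_patterns(cfg, 2)
        b = discover_patterns(DiscoveryConfig(attention_preset="vowel", seed=77), 2)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert np.allclose(ra.pattern.serialize(), rb.pattern.serialize())
            assert ra.reward.total == pytest.approx(rb.reward.total)

    def test_zero_candidates_gives_empty_list(self):
        assert discover_patterns(DiscoveryConfig(), 0) == []

    def test_optimizer_never_loses_to_initialization(self, vowel_records,
                                                     plosive_records):
        for rec in list(vowel_records) + list(plosive_records):
            assert rec.reward.total >= rec.init_reward - 1e-9

    def test_vowel_preset_yields_voiced_low_band_output(self, vowel_records):
        from vocalearn.auditory import band_powers

        assert vowel_records, "discovery kept no vowels"
        for rec in vowel_records:
            assert rec.pattern.voiced
            low, high = band_powers(rec.rep, 2500.0)
            assert low > high


class TestClustering:
    def _records(self, rng, n):
        from vocalearn.auditory import AuditoryRepresentation

        recs = []
        for i in range(n):
            pat = make_pattern(rng.uniform(-1, 1, 10), pid=f"c{i}")
            rep = AuditoryRepresentation(
                rng.uniform(0, 1, (4, 5)), 100.0 * 2 ** np.arange(4), 100.0
            )
            recs.append(make_record(pat, rep))
        return recs

    def test_k_equals_n_gives_singletons(self, rng):
        recs = self._records(rng, 5)
        for mode in ("motor_kmeans", "acoustic_dtw"):
            clusters = cluster_patterns(recs, mode, 5, seed=0)
            assert sorted(c["exemplar"] for c in clusters) == list(range(5))
            assert all(len(c["members"]) == 1 for c in clusters)

    def test_separable_blobs_recovered(self, rng):
        recs = []
        for i in range(6):
            offset = -0.8 if i < 3 else 0.8
            t = np.clip(offset + 0.05 * rng.standard_normal(10), -1, 1)
            recs.append(make_record(make_pattern(t, pid=f"b{i}"),
                                    self._records(rng, 1)[0].rep))
        clusters = cluster_patterns(recs, "motor_kmeans", 2, seed=0)
        groups = [sorted(c["members"]) for c in clusters]
        assert sorted(groups) == [[0, 1, 2], [3, 4, 5]]

    def test_every_pattern_assigned_once(self, rng):
        recs = self._records(rng, 7)
        clusters = cluster_patterns(recs, "acoustic_dtw", 3, seed=1)
        members = sorted(m for c in clusters for m in c["members"])
        assert members == list(range(7))

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_patterns(self._records(rng, 3), "motor_kmeans", 4)

    def test_kmedoids_deterministic(self, rng):
        d = rng.uniform(0, 1, (8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        assert kmedoids_from_distances(d, 3, seed=5)[1].tolist() \
            == kmedoids_from_distances(d, 3, seed=5)[1].tolist()


class TestComposites:
    def test_cv_counts(self):
        vowels = [make_pattern(pid=f"v{i}") for i in range(2)]
        cv = make_pattern(category="plosive", voiced=True, pid="b")
        out = generate_composites(vowels + [cv])
        cvv = [p for p in out if p.id.startswith("b+")]
        assert len(cvv) == 2  # CvV over 2 vowels

    def test_vv_excludes_self_pairs(self):
        vowels = [make_pattern(pid=f"v{i}") for i in range(2)]
        out = generate_composites(vowels)
        assert len(out) == 2  # ordered pairs minus self-pairs
        assert {p.id for p in out} == {"v0+v1", "v1+v0"}

    def test_missing_fricatives_skip_only_their_family(self):
        vowels = [make_pattern(pid=f"v{i}") for i in range(2)]
        plos = make_pattern(category="plosive", voiced=False, pid="t")
        out = generate_composites(vowels + [plos])
        # CuV (2) + VCu (2) + VV (2); no fricative or nasal families
        assert len(out) == 6

    def test_composites_respect_sub_pattern_cap(self):
        vowels = [make_pattern(pid=f"v{i}") for i in range(3)]
        out = generate_composites(vowels)
        assert all(len(p.sub_patterns) <= 3 for p in out)
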