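"""Word segmentation, two-pass recognition, intonation transfer, sessions."""

import numpy as np
import pytest

from vocalearn.auditory import gammatone_analyze
from vocalearn.fixtures import CaregiverLanguageSpec, formant_synthesize, synthesize_token
from vocalearn.imitation import (
    ImitationError,
    IntonationSpec,
    apply_intonation,
    build_template_index,
    extract_intonation,
    frequency_to_param,
    imitate_word,
    param_to_frequency,
    recognize_two_pass,
    run_word_session,
    segment_word,
)
from vocalearn.interaction import AssociationEntry, AssociationMemory

SR = 24000


def memory_from_tokens(tokens):
    mem = AssociationMemory()
    for i, (label, wav) in enumerate(tokens):
        mem.associate(
            f"pat-{label}-{i}",
            AssociationEntry(wav, gammatone_analyze(wav, SR), label),
        )
    return mem


@pytest.fixture(scope="module")
def small_memory():
    spec = CaregiverLanguageSpec(seed=21)
    rng = np.random.default_rng(21)
    tokens = [(lab, synthesize_token(lab, spec, rng))
              for lab in ("a", "i", "u") for _ in range(2)]
    return memory_from_tokens(tokens)


class TestF0Mapping:
    @pytest.mark.parametrize(
        "param,sex,f0",
        [(-0.9, "male", 100.0), (0.9, "male", 300.0),
         (-0.9, "female", 150.0), (0.9, "female", 400.0)],
    )
    def test_parameter_range_anchors(self, param, sex, f0):
        assert param_to_frequency(param, sex) == pytest.approx(f0)
        assert frequency_to_param(f0, sex) == pytest.approx(param)

    def test_male_midpoint(self):
        assert frequency_to_param(200.0, "male") == pytest.approx(0.0)

    def test_out_of_range_clips_to_bounds(self):
        assert frequency_to_param(50.0, "male") == -0.9
        assert frequency_to_param(1000.0, "female") == 0.9

    def test_round_trip_within_bounds(self, rng):
        for _ in range(20):
            p = rng.uniform(-0.9, 0.9)
            assert frequency_to_param(
                param_to_frequency(p, "female"), "female"
            ) == pytest.approx(p)

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(ImitationError):
            frequency_to_param(0.0, "male")


class TestIntonation:
    def test_linear_glide_recovered(self):
        wav = formant_synthesize((700, 1200, 2600), duration=0.4,
                                 f0=300.0, f0_end=200.0)
        spec = extract_intonation(wav, SR, "female")
        assert spec.start_f0 == pytest.approx(300.0, rel=0.05)
        assert spec.end_f0 == pytest.approx(200.0, rel=0.05)
        assert not spec.flat_default

    @pytest.mark.parametrize("length,expected", [(0.7, 0.600), (0.1, 0.250)])
    def test_duration_clamped(self, length, expected):
        wav = formant_synthesize((700, 1200, 2600), duration=length, f0=220.0)
        spec = extract_intonation(wav, SR, "female")
        assert spec.duration == pytest.approx(expected)

    def test_unvoiced_segment_flags_flat_default(self, rng):
        noise = 0.1 * rng.standard_normal(int(0.3 * SR))
        spec = extract_intonation(noise, SR, "male")
        assert spec.flat_default
        assert spec.start_f0 == pytest.approx(200.0)  # male mapping midpoint

    def test_apply_rescales_duration(self, vowel_records):
        pat = vowel_records[0].pattern
        spec = IntonationSpec(200.0, 300.0, 0.5, "female")
        out = apply_intonation(pat, spec)
        assert out.extent == pytest.approx(0.5, rel=1e-6)
        assert out.sub_patterns[0].targets[8] == pytest.approx(
            frequency_to_param(200.0, "female")
        )


class TestSegmentation:
    def test_two_bursts_two_segments(self):
        a = formant_synthesize((700, 1200, 2600), duration=0.3, f0=220.0)
        b = formant_synthesize((300, 2500, 3200), duration=0.3, f0=220.0)
        word = np.concatenate([a, np.zeros(int(0.35 * SR)), b])
        segs = segment_word(word, SR, noise_floor=1e-7)
        assert len(segs) == 2

    def test_silence_is_empty(self):
        assert segment_word(np.zeros(SR), SR, noise_floor=1e-7) == []

    def test_continuous_token_is_one_segment(self):
        wav = formant_synthesize((700, 1200, 2600), duration=0.5, f0=220.0)
        assert len(segment_word(wav, SR, noise_floor=1e-7)) == 1


class TestTemplateIndex:
    def test_cap_inactive_below_100(self, small_memory):
        index = build_template_index(small_memory, seed=0)
        assert len(index.clusters) == len(small_memory.entries)

    def test_n_centers_caps_clusters(self, small_memory):
        index = build_template_index(small_memory, n_centers=3, seed=0)
        assert len(index.clusters) == 3
        members = sorted(m for c in index.clusters for m in c["members"])
        assert members == sorted(small_memory.entries)

    def test_deterministic_given_seed(self, small_memory):
        a = build_template_index(small_memory, n_centers=3, seed=4)
        b = build_template_index(small_memory, n_centers=3, seed=4)
        assert [c["exemplar"] for c in a.clusters] \
            == [c["exemplar"] for c in b.clusters]

    def test_empty_memory_rejected(self):
        with pytest.raises(ImitationError):
            build_template_index(AssociationMemory())


class TestTwoPassRecognition:
    def test_stored_response_is_fixed_point(self, small_memory):
        index = build_template_index(small_memory, seed=0)
        for pid, ent in small_memory.entries.items():
            trace = recognize_two_pass(ent.response_waveform, SR, index)
            assert trace.chosen_id == pid
            assert trace.pass2[0][1] == pytest.approx(0.0, abs=1e-9)

    def test_pass2_pool_is_five_singleton_clusters(self):
        spec = CaregiverLanguageSpec(seed=8)
        rng = np.random.default_rng(8)
        tokens = [("a", synthesize_token("a", spec, rng)) for _ in range(6)]
        mem = memory_from_tokens(tokens)
        index = build_template_index(mem, seed=0)
        assert len(index.clusters) == 6  # singletons under the min rule
        trace = recognize_two_pass(tokens[0][1], SR, index)
        assert len(trace.pass2) == 5

    def test_pass2_winner_at_least_as_good_as_pass1_winner(self, small_memory):
        index = build_template_index(small_memory, n_centers=3, seed=0)
        probe = synthesize_token(
            "a", CaregiverLanguageSpec(seed=99), np.random.default_rng(99)
        )
        trace = recognize_two_pass(probe, SR, index)
        pass1_winner = trace.pass1[0][0]
        pass1_winner_pass2_score = dict(trace.pass2).get(pass1_winner)
        if pass1_winner_pass2_score is not None:
            assert trace.pass2[0][1] <= pass1_winner_pass2_score + 1e-12


class TestImitateWord:
    def test_two_segment_word_recalls_two_patterns(self, caregiver_session):
        patterns, memory, _ = caregiver_session
        if len(memory.entries) < 2:
            pytest.skip("not enough associations")
        index = build_template_index(memory, seed=0)
        by_id = {p.id: p for p in patterns}
        ids = sorted(memory.entries)[:2]
        word = np.concatenate([
            memory.entries[ids[0]].response_waveform,
            np.zeros(int(0.4 * SR)),
            memory.entries[ids[1]].response_waveform,
        ])
        out, trace = imitate_word(word, SR, memory, index, by_id)
        assert len(trace.segments) == 2
        assert len(out) > 0

    def test_silent_word_raises_nothing_heard(self, caregiver_session):
        patterns, memory, _ = caregiver_session
        index = build_template_index(memory, seed=0)
        with pytest.raises(ImitationError):
            imitate_word(np.zeros(SR), SR, memory, index, {})

    def test_rising_prompt_yields_rising_output(self, caregiver_session):
        from vocalearn.auditory import estimate_f0

        patterns, memory, _ = caregiver_session
        index = build_template_index(memory, seed=0)
        by_id = {p.id: p for p in patterns}
        word = formant_synthesize((700, 1200, 2600), duration=0.4,
                                  f0=180.0, f0_end=380.0)
        out, trace = imitate_word(word, SR, memory, index, by_id,
                                  caregiver_sex="female")
        assert len(out) > 0
        f0 = estimate_f0(out, SR, 150, 650)
        voiced = np.nonzero(f0 > 0)[0]
        assert voiced.size >= 4
        slope = np.polyfit(voiced, f0[voiced], 1)[0]
        assert slope > 0


class TestWordSession:
    def _session(self, caregiver_session, evaluate):
        patterns, memory, _ = caregiver_session
        index = build_template_index(memory, seed=0)
        by_id = {p.id: p for p in patterns}
        spec = CaregiverLanguageSpec(seed=31)
        rng = np.random.default_rng(31)

        def speak(word):
            return synthesize_token("a", spec, rng), SR

        return run_word_session(
            ["wa", "wb"], speak, evaluate, memory, index, by_id,
        )

    def test_accepting_caregiver_learns_all_words(self, caregiver_session):
        outcomes = self._session(caregiver_session, lambda w, x: True)
        assert all(o.accepted for o in outcomes)
        assert all(o.attempts == 1 for o in outcomes)

    def test_rejecting_caregiver_gives_up_within_max_attempts(
        self, caregiver_session
    ):
        outcomes = self._session(caregiver_session, lambda w, x: False)
        assert all(not o.accepted for o in outcomes)
        assert all(o.attempts <= 4 for o in outcomes)
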