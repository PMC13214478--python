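import numpy as np
import pytest

import srtkit as sk
from srtkit.adaptive_track import compute_srt

from conftest import scripted_track


class TestSentenceCorrect:
    @pytest.mark.parametrize(
        "k,rule,expected",
        [
            (3, "majority", True),
            (2, "majority", True),
            (2, "all", False),
            (3, "all", True),
            (1, "majority", False),
            (0, "majority", False),
        ],
    )
    def test_rules(self, k, rule, expected):
        assert sk.sentence_correct(k, rule) is expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            sk.sentence_correct(4)


class TestStartAndEscalation:
    def test_first_presentation_at_zero_snr(self):
        track = sk.start_track([(i, 0.0) for i in range(1, 21)])
        assert track.pending.nominal_snr_db == 0.0
        assert track.pending.phase == 1
        assert track.running and not track.presentations

    def test_offset_shifts_adjusted_level_only(self):
        sentences = [(1, 2.7)] + [(i, 0.0) for i in range(2, 21)]
        track = sk.start_track(sentences)
        assert track.pending.nominal_snr_db == 0.0
        assert track.pending.adjusted_snr_db == pytest.approx(2.7)

    def test_wrong_list_size_raises(self):
        with pytest.raises(ValueError):
            sk.start_track([(1, 0.0)] * 19)

    def test_escalation_ladder(self):
        track = sk.start_track([(i, 0.0) for i in range(1, 21)])
        track.score(1)  # not completely correct at 0 dB
        assert track.pending.is_escalation_replay
        assert track.pending.nominal_snr_db == 5.0
        assert track.pending.sentence_id == 1
        track.score(2)  # still not all three keywords
        assert track.pending.nominal_snr_db == 10.0
        track.score(3)  # resolved; proceed down to sentence 2
        assert track.pending.sentence_id == 2
        assert not track.pending.is_escalation_replay
        assert track.pending.nominal_snr_db == 5.0  # 10 - 5 dB step

    def test_correct_first_sentence_skips_escalation(self):
        track = sk.start_track([(i, 0.0) for i in range(1, 21)])
        track.score(3)
        assert track.pending.sentence_id == 2
        assert track.pending.nominal_snr_db == -5.0


class TestStepping:
    def test_phase1_step_is_5db(self):
        track = sk.start_track([(i, 0.0) for i in range(1, 21)])
        track.score(3)
        assert track.pending.nominal_snr_db == -5.0
        track.score(0)
        assert track.pending.nominal_snr_db == 0.0

    def test_monotone_run_stays_in_phase_1(self):
        # without a reversal, phase 1 persists past 4 sentences
        track = sk.start_track([(i, 0.0) for i in range(1, 21)])
        for _ in range(8):
            track.score(3)
        assert track.phase == 1
        assert track.pending.phase == 1

    def test_phase_sequence_and_step_sizes(self):
        # alternating responses force an early reversal and fast settling
        responses = [True, True, False, True, False, True, False, True,
                     False, True, False, True, False, True, False, True,
                     False, True, False, True]
        track = scripted_track(responses)
        frame = track.to_frame()
        assert track.status == "complete"
        phases = frame["phase"].to_numpy()
        assert (np.diff(phases) >= 0).all()  # monotone 1 -> 2 -> 3
        assert set(phases) <= {1, 2, 3}
        # each adjustment equals the step size of the just-scored phase
        steps = {1: 5.0, 2: 2.0, 3: 1.0}
        levels = frame["nominal_snr_db"].to_numpy()
        for i in range(len(frame) - 1):
            assert abs(levels[i + 1] - levels[i]) == steps[phases[i]]

    def test_phase2_exit_requires_low_se(self):
        # phase-2 presented levels {-4,-6,-4,-6}: SE = SD/sqrt(4) ~ 0.577 < 1
        lv = [-4.0, -6.0, -4.0, -6.0]
        assert np.std(lv, ddof=1) / 2 == pytest.approx(0.5774, abs=1e-4)
        responses = [True, True, False, True] + [False, True, False, True] * 4
        track = scripted_track(responses)
        assert 3 in track.to_frame()["phase"].to_numpy()

    def test_completed_track_rejects_scoring(self):
        track = scripted_track([True, False] * 10)
        with pytest.raises(RuntimeError):
            track.score(3)

    def test_first_four_correct_warns(self):
        track = sk.start_track([(i, 0.0) for i in range(1, 21)])
        with pytest.warns(UserWarning, match="first four"):
            for _ in range(4):
                track.score(3)


class TestComputeSrt:
    def test_constant_levels(self):
        track = scripted_track([True, False] * 10)
        srt, se = compute_srt(track)
        levels = [
            p.nominal_snr_db for p in track.scored(phases=(2, 3))
        ]
        assert srt == pytest.approx(np.mean(levels))

    def test_hand_computed_example(self):
        # independent of the state machine: inject phase-2 levels directly
        track = scripted_track([True, False] * 10)
        for p, level in zip(track.scored(phases=(2, 3)),
                            [-4.0, -6.0, -5.0, -5.0, -6.0, -6.0]):
            p.nominal_snr_db = level
        extra = track.scored(phases=(2, 3))[6:]
        for p in extra:
            p.phase = 1  # keep exactly six phase-2/3 presentations
        srt, se = compute_srt(track)
        assert srt == pytest.approx(-16.0 / 3.0)
        assert se == pytest.approx(np.std([-4, -6, -5, -5, -6, -6], ddof=1)
                                   / np.sqrt(6))
        assert se == pytest.approx(0.3333, abs=1e-3)

    def test_translation_equivariance(self):
        responses = [True, False] * 10
        base = scripted_track(responses)
        shifted = scripted_track(responses, start_snr_db=7.0)
        assert compute_srt(shifted)[0] - compute_srt(base)[0] == pytest.approx(7.0)

    def test_offsets_do_not_touch_srt(self):
        responses = [True, False] * 10
        rng = np.random.default_rng(1)
        offsets = rng.uniform(-3, 3, 20)
        plain = scripted_track(responses)
        offset_track = scripted_track(
            responses, sentences=[(i + 1, o) for i, o in enumerate(offsets)]
        )
        frame = offset_track.to_frame()
        assert (frame["adjusted_snr_db"] != frame["nominal_snr_db"]).any()
        assert compute_srt(offset_track) == compute_srt(plain)

    def test_never_left_phase_1_raises(self):
        track = scripted_track([True] * 20)  # monotone: no reversal ever
        with pytest.raises(ValueError, match="phase 2"):
            compute_srt(track)

    def test_running_track_raises(self):
        track = sk.start_track([(i, 0.0) for i in range(1, 21)])
        with pytest.raises(RuntimeError):
            compute_srt(track)


class TestRecovery:
    def test_mean_srt_tracks_listener_midpoint(self, steep_list):
        sentences, reference = steep_list
        listener = sk.VirtualListener(1, srt_shift_db=0.0)
        srts = []
        for i in range(100):
            rng = np.random.default_rng(np.random.SeedSequence([4, i]))
            track = sk.simulate_track(sentences, listener, rng)
            srts.append(compute_srt(track)[0])
        assert abs(np.mean(srts) - reference) < 0.6
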