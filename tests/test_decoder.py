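"""Online decoder: baseline correction, gates, dead-band, Triad mapping."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mibci import decoder as dec


class TestBaselineAndSmoothing:
    def test_offset_and_scale_arithmetic(self):
        out = dec.correct_baseline(np.array([1.0, 2.0, 3.0]), offset=2.0, scale=2.0)
        np.testing.assert_allclose(out, [-2.0, 0.0, 2.0])

    def test_identity_when_offset_zero_scale_one(self):
        x = np.array([0.5, -1.0, 2.0])
        np.testing.assert_array_equal(dec.correct_baseline(x, 0.0, 1.0), x)

    def test_median_offset_zeroes_a_constant_rest_segment(self):
        x = np.concatenate([np.full(50, 3.0), np.random.default_rng(0).normal(size=50)])
        off = dec.estimate_offset(x, rest_slice=slice(0, 50))
        assert dec.correct_baseline(x, off)[:50].max() == 0.0

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError):
            dec.correct_baseline(np.zeros(3), 0.0, 0.0)

    def test_moving_average_constant_unchanged(self):
        x = np.full(100, 4.2)
        np.testing.assert_allclose(dec.smooth_ma(x), x)

    def test_unit_step_ramps_over_one_window(self):
        x = np.ones(60)
        out = dec.smooth_ma(x, window_s=1.0, rate_hz=25.0)
        np.testing.assert_allclose(out, 1.0)  # full history is the step itself
        # a step arriving mid-stream ramps linearly across 25 frames
        x2 = np.concatenate([np.zeros(50), np.ones(50)])
        out2 = dec.smooth_ma(x2)
        assert out2[49] == 0.0
        assert out2[50] == pytest.approx(1 / 25)
        assert out2[74] == pytest.approx(1.0)
        assert np.all(out2[74:] == 1.0)

    def test_single_frame_window_is_identity(self):
        x = np.random.default_rng(1).normal(size=30)
        np.testing.assert_array_equal(dec.smooth_ma(x, window_s=0.04), x)


class TestGate1:
    def test_agreeing_l_votes_pass(self):
        assert dec.gate1(lr_sign=+1, fr_sign=-1, lf_sign=+1, tx_sign=+1) == "L"

    def test_relax_state_blocks_everything(self):
        for lr, fr, lf in itertools.product([-1, 1], repeat=3):
            assert dec.gate1(lr, fr, lf, tx_sign=-1) is None

    def test_exhaustive_vote_patterns(self):
        """Of the 8 task-vs-task sign patterns, 6 have a class with both
        its votes and 2 are cyclic."""
        winners = [
            dec.gate1(lr, fr, lf, +1) for lr, fr, lf in itertools.product([-1, 1], repeat=3)
        ]
        assert sum(w is not None for w in winners) == 6
        assert sum(w is None for w in winners) == 2

    def test_permutation_consistency(self):
        """Swapping the roles of L and R (negating LR, swapping the FR/LF
        classifiers' votes accordingly) swaps the decoded labels."""
        swap = {"L": "R", "R": "L", "F": "F", None: None}
        for lr, fr, lf in itertools.product([-1, 1], repeat=3):
            orig = dec.gate1(lr, fr, lf, +1)
            # under L<->R: LR flips sign; FR (F vs R) becomes F vs L = LF
            # with its F-polarity preserved, and vice versa
            swapped = dec.gate1(-lr, -lf, -fr, +1)
            assert swapped == swap[orig]


class TestStabilityGate:
    def test_seven_frames_insufficient(self):
        stream = ["L"] * 7 + [None] * 5
        assert dec.stability_gate(stream, n_frames=8) == []

    def test_eight_frames_fire_once(self):
        stream = ["L"] * 12
        events = dec.stability_gate(stream, n_frames=8)
        assert events == [(7, "L")]  # fires on the 8th consecutive frame

    def test_alternating_candidates_never_fire(self):
        stream = ["L", "R"] * 20
        assert dec.stability_gate(stream, n_frames=8) == []

    def test_stability_frames_from_config(self):
        assert dec.DecoderConfig().stability_frames == math.ceil(0.3 * 25)
        assert dec.DecoderConfig().stability_frames == 8


def deadband_oracle(events, config):
    """Independent step-through reference for the dead-band controller.

    ``events``: list of (time, stabilized label or None, tx_is_task).
    Returns the times at which commands are emitted.
    """
    emitted = []
    last_emit = None
    tx_since = None
    for t, stab, tx in events:
        tx_since = (tx_since if tx_since is not None else t) if tx else None
        if stab is None:
            continue
        if last_emit is None or t - last_emit >= config.deadband_s:
            emitted.append(t)
            last_emit = t
        elif (
            t - last_emit >= config.deadband_break_s
            and tx_since is not None
            and t - tx_since >= config.break_hold_s
        ):
            emitted.append(t)
            last_emit = t
    return emitted


def _run_machine(events, config):
    state = dec.DecoderState()
    out = []
    for t, stab, tx in events:
        state, cmd = dec.deadband_step(state, config, stab, tx, t)
        if cmd is not None:
            out.append(cmd.time_s)
    return out


class TestDeadband:
    CFG = dec.DecoderConfig(deadband_s=6.0, deadband_break_s=3.0)

    def test_first_command_always_passes(self):
        events = [(0.0, "L", True)]
        assert _run_machine(events, self.CFG) == [0.0]

    def test_command_within_break_delay_suppressed(self):
        events = [(0.0, "L", True), (2.0, "R", True)]
        assert _run_machine(events, self.CFG) == [0.0]

    def test_break_after_sustained_task(self):
        # command at 0; TX task continuously from 3.0; event at 4.2
        events = [(0.0, "L", True)] + [
            (t, None, t >= 3.0) for t in np.arange(0.04, 4.2, 0.04)
        ] + [(4.2, "R", True)]
        assert _run_machine(events, self.CFG) == [0.0, 4.2]

    def test_break_requires_full_hold(self):
        # TX task only from 3.5 -> at 4.2 streak is 0.7 s < 1 s: suppressed
        events = [(0.0, "L", True)] + [
            (t, None, t >= 3.5) for t in np.arange(0.04, 4.2, 0.04)
        ] + [(4.2, "R", True)]
        assert _run_machine(events, self.CFG) == [0.0]

    def test_deadband_expiry_reopens(self):
        events = [(0.0, "L", False), (6.0, "R", False)]
        assert _run_machine(events, self.CFG) == [0.0, 6.0]

    def test_non_monotone_time_rejected(self):
        state = dec.DecoderState()
        state, _ = dec.deadband_step(state, self.CFG, None, False, 1.0)
        with pytest.raises(ValueError):
            dec.deadband_step(state, self.CFG, None, False, 0.5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            dec.DecoderConfig(deadband_s=2.0, deadband_break_s=3.0)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_step_through_oracle_on_random_traces(self, seed):
        """State machine agrees with the independent reference on seeded
        random candidate/TX traces."""
        rng = np.random.default_rng(seed)
        events = []
        for i in range(300):
            t = i * 0.04
            stab = rng.choice(["L", "R", "F", None], p=[0.05, 0.05, 0.05, 0.85])
            tx = bool(rng.random() < 0.6)
            events.append((t, stab, tx))
        assert _run_machine(events, self.CFG) == deadband_oracle(events, self.CFG)


def random_stream(seed, n=800, rate=25.0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    # smooth correlated TSDs so candidates persist long enough to emit
    def walk():
        return dec.smooth_ma(rng.standard_normal(n) * 2.0, window_s=0.6, rate_hz=rate)

    return pd.DataFrame(
        {"time": t, "lr": walk(), "fr": walk(), "lf": walk(), "tx": walk()}
    )


class TestDecodeStream:
    def test_replay_is_byte_identical(self):
        stream = random_stream(3)
        cfg = dec.DecoderConfig()
        log1 = dec.decode_stream(stream, cfg)
        log2 = dec.decode_stream(stream.copy(), cfg)
        assert log1.to_csv() == log2.to_csv()

    @pytest.mark.parametrize("seed", range(40))
    def test_deadband_spacing_contract(self, seed):
        """Consecutive emissions are >= deadband_break_s apart always, and
        >= deadband_s apart unless a break was logged between them."""
        cfg = dec.DecoderConfig(deadband_s=4.0, deadband_break_s=2.0)
        log = dec.decode_stream(random_stream(seed), cfg)
        times = log["time"].to_numpy()
        breaks = log["break_flag"].to_numpy()
        gaps = np.diff(times)
        assert np.all(gaps >= cfg.deadband_break_s - 1e-9)
        assert np.all(gaps[~breaks[1:]] >= cfg.deadband_s - 1e-9)

    def test_commands_are_translated_labels(self):
        log = dec.decode_stream(random_stream(11))
        assert set(log["command"]) <= {"LEFT", "RIGHT", "LIGHT"}


class TestTranslate:
    @pytest.mark.parametrize("label,command", [("L", "LEFT"), ("R", "RIGHT"), ("F", "LIGHT")])
    def test_default_map(self, label, command):
        assert dec.translate(label).command == command

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            dec.translate("X")


class TestTriad:
    def test_zero_tsds_map_to_centroid(self):
        point, state = dec.triad_position(0.0, 0.0, 0.0, -0.5)
        np.testing.assert_allclose(point, [0.0, 0.0], atol=1e-12)
        assert state == "relax"

    def test_full_l_votes_pull_toward_l_vertex(self):
        """lr=+1 and lf=+1 put both L-edges at the L vertex; with fr=0 the
        composite is the closest achievable point to the L vertex."""
        point, state = dec.triad_position(1.0, 0.0, 1.0, 0.5)
        expected = (
            dec.TRIAD_VERTICES["L"]
            + dec.TRIAD_VERTICES["L"]
            + (dec.TRIAD_VERTICES["F"] + dec.TRIAD_VERTICES["R"]) / 2.0
        ) / 3.0
        np.testing.assert_allclose(point, expected, atol=1e-12)
        assert state == "task"
        # oracle: no TSD assignment gets closer to the L vertex
        target = dec.TRIAD_VERTICES["L"]
        best = min(
            np.linalg.norm(dec.triad_position(a, b, c, 1)[0] - target)
            for a in np.linspace(-1, 1, 9)
            for b in np.linspace(-1, 1, 9)
            for c in np.linspace(-1, 1, 9)
        )
        assert np.linalg.norm(point - target) <= best + 1e-9

    def test_points_stay_inside_triangle(self):
        rng = np.random.default_rng(0)
        verts = np.array(list(dec.TRIAD_VERTICES.values()))
        for _ in range(50):
            p, _ = dec.triad_position(*rng.uniform(-2, 2, size=4))
            # barycentric coordinates of p w.r.t. the triangle are in [0,1]
            A = np.c_[verts[1] - verts[0], verts[2] - verts[0]]
            lam = np.linalg.solve(A, p - verts[0])
            bary = np.array([1 - lam.sum(), *lam])
            assert np.all(bary >= -1e-9) and np.all(bary <= 1 + 1e-9)
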