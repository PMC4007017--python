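import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bimocon.schedule import ANTI_PHASE, IN_PHASE, generate_schedule
from bimocon.scoring import (
    CORRECT,
    EXCLUDED,
    INCORRECT,
    AccuracyRecord,
    PressEvent,
    ScoreConfig,
    accuracy_rate,
    classify_events,
    classify_press,
    config_for_pacing,
    select_frequency,
)
from bimocon.synth import BehaviorProfile, simulate_presses


def _press(hand, finger, t, **kw):
    return PressEvent(subject_id="s1", run_id="r1", hand=hand, finger=finger,
                      time_s=t, **kw)


class TestCorrectnessRule:
    """The per-press rule: paired-finger latency beats unpaired-finger latency."""

    cfg = ScoreConfig(match_window_s=0.5)

    def test_right_index_nearest_left_index_in_phase_correct(self):
        # RI at 10.00 with LI at 10.02 and LM at 10.30: same finger closer
        left = [_press("L", "index", 10.02), _press("L", "middle", 10.30)]
        got = classify_press(_press("R", "index", 10.0), left, IN_PHASE, self.cfg)
        assert got == CORRECT

    def test_same_timings_anti_phase_incorrect(self):
        left = [_press("L", "index", 10.02), _press("L", "middle", 10.30)]
        got = classify_press(_press("R", "index", 10.0), left, ANTI_PHASE, self.cfg)
        assert got == INCORRECT

    def test_exact_tie_counts_incorrect_by_default(self):
        left = [_press("L", "index", 10.10), _press("L", "middle", 9.90)]
        got = classify_press(_press("R", "index", 10.0), left, IN_PHASE, self.cfg)
        assert got == INCORRECT

    def test_exact_tie_excluded_when_configured(self):
        cfg = ScoreConfig(match_window_s=0.5, tie_policy="exclude")
        left = [_press("L", "index", 10.10), _press("L", "middle", 9.90)]
        got = classify_press(_press("R", "index", 10.0), left, IN_PHASE, cfg)
        assert got == EXCLUDED

    def test_unmatched_press_excluded_when_configured(self):
        cfg = ScoreConfig(match_window_s=0.5, unmatched_policy="exclude")
        got = classify_press(_press("R", "index", 10.0), [], IN_PHASE, cfg)
        assert got == EXCLUDED

    def test_same_hand_events_rejected(self):
        with pytest.raises(ValueError, match="same hand"):
            classify_press(
                _press("R", "index", 10.0), [_press("R", "middle", 10.1)],
                IN_PHASE, self.cfg,
            )

    def test_one_sided_match_decides(self):
        # only the different finger is inside the window: anti-phase correct
        left = [_press("L", "middle", 10.05), _press("L", "index", 12.0)]
        assert classify_press(_press("R", "index", 10.0), left, ANTI_PHASE, self.cfg) == CORRECT
        assert classify_press(_press("R", "index", 10.0), left, IN_PHASE, self.cfg) == INCORRECT


class TestAccuracyRate:
    def test_synchronous_mirror_pressing_is_perfect_in_phase(self):
        events = []
        for k in range(10):
            f = "index" if k % 2 == 0 else "middle"
            events += [_press("L", f, float(k)), _press("R", f, float(k))]
        rec = accuracy_rate(events, IN_PHASE, ScoreConfig(match_window_s=0.5))
        assert rec.accuracy == 1.0
        assert rec.n_presses == 20

    def test_six_of_eight_correct_gives_three_quarters(self):
        # 4 mirrored pairs; flip one pair's left finger -> that pair's 2
        # presses become incorrect
        events = []
        for k in range(4):
            lf = "middle" if k == 0 else "index"
            events += [_press("L", lf, 10.0 * k), _press("R", "index", 10.0 * k)]
        rec = accuracy_rate(events, IN_PHASE, ScoreConfig(match_window_s=0.5))
        assert rec.n_presses == 8
        assert rec.n_correct == 6
        assert rec.accuracy == 0.75

    def test_empty_input_warns_and_flags_zero(self):
        with pytest.warns(UserWarning, match="no events"):
            rec = accuracy_rate([], IN_PHASE)
        assert rec.n_presses == 0
        assert rec.accuracy == 0.0

    def test_generator_swap_rate_matches_binomial_expectation(self):
        # 500 cycles at swap_prob 0.2: accuracy within 3 binomial SE of 0.8
        q = 0.2
        sched = generate_schedule(
            2.0, rest_block_s=25.0, n_rest_blocks=10, n_task_blocks=10,
            mode_sequence=(ANTI_PHASE,) * 10,
        )
        n_cycles = sum(len(sched.cue_times(b)) for b in sched.task_blocks())
        assert n_cycles == 500
        profile = BehaviorProfile(timing_sd_s=0.0, swap_prob=q, miss_prob=0.0,
                                  extra_prob=0.0)
        events = simulate_presses(sched, profile, seed=11)
        rec = accuracy_rate(events, ANTI_PHASE, config_for_pacing(2.0))
        se = np.sqrt(q * (1 - q) / n_cycles)
        assert abs(rec.accuracy - (1 - q)) < 3 * se

    def test_record_invariants(self):
        rec = AccuracyRecord("s", IN_PHASE, 1.5, n_correct=3, n_presses=4)
        assert rec.n_correct <= rec.n_presses
        assert rec.accuracy == 0.75


@settings(deadline=None, derandomize=True)
@given(shift=st.floats(min_value=0.0, max_value=1000.0, allow_nan=False))
def test_accuracy_invariant_under_global_time_shift(shift):
    sched = generate_schedule(1.5, n_rest_blocks=2, n_task_blocks=2,
                              mode_sequence=(IN_PHASE, ANTI_PHASE))
    profile = BehaviorProfile(timing_sd_s=0.08, swap_prob=0.3, miss_prob=0.1,
                              extra_prob=0.1)
    events = simulate_presses(sched, profile, seed=5)
    cfg = config_for_pacing(1.5)
    shifted = [
        PressEvent(e.subject_id, e.run_id, e.hand, e.finger, e.time_s + shift,
                   e.block_index, e.mode)
        for e in events
    ]
    for mode in (IN_PHASE, ANTI_PHASE):
        base = accuracy_rate(events, mode, cfg)
        moved = accuracy_rate(shifted, mode, cfg)
        assert (base.n_correct, base.n_presses) == (moved.n_correct, moved.n_presses)


@pytest.mark.parametrize("mode,other", [(IN_PHASE, ANTI_PHASE), (ANTI_PHASE, IN_PHASE)])
def test_mode_duality_under_within_hand_finger_swap(mode, other):
    """Flipping one hand's finger labels exchanges the two modes' verdicts."""
    sched = generate_schedule(1.5, n_rest_blocks=3, n_task_blocks=3,
                              mode_sequence=(mode,) * 3)
    profile = BehaviorProfile(timing_sd_s=0.1, swap_prob=0.25, miss_prob=0.05,
                              extra_prob=0.05)
    events = simulate_presses(sched, profile, seed=17)
    flip = {"index": "middle", "middle": "index"}
    swapped = [
        PressEvent(e.subject_id, e.run_id, e.hand,
                   flip[e.finger] if e.hand == "L" else e.finger,
                   e.time_s, e.block_index, e.mode)
        for e in events
    ]
    cfg = config_for_pacing(1.5)
    for (e, lab), (s, lab_swapped) in zip(
        classify_events(events, mode, cfg), classify_events(swapped, other, cfg)
    ):
        assert lab == lab_swapped


def _records(young_anti, elderly_anti, in_acc=0.98):
    rows = []
    for g, table in (("young", young_anti), ("elderly", elderly_anti)):
        for f, acc in table.items():
            rows.append({"group": g, "mode": ANTI_PHASE, "pacing_hz": f,
                         "accuracy": acc})
            rows.append({"group": g, "mode": IN_PHASE, "pacing_hz": f,
                         "accuracy": in_acc})
    return pd.DataFrame(rows)


class TestSelectFrequency:
    def test_fastest_manageable_pace_wins(self):
        # the fastest pace clearing the reference group's floor maximizes
        # divergence: 2.0 Hz fails the floor, 1.5 Hz beats 1.0 Hz
        records = _records(
            {1.0: 0.96, 1.5: 0.92, 2.0: 0.66},
            {1.0: 0.45, 1.5: 0.39, 2.0: 0.35},
        )
        assert select_frequency(records) == 1.5

    def test_identical_groups_tie_break_to_lowest(self):
        records = _records({1.0: 0.9, 1.5: 0.9, 2.0: 0.9},
                           {1.0: 0.9, 1.5: 0.9, 2.0: 0.9})
        assert select_frequency(records) == 1.0

    def test_floor_zero_equals_argmax_of_difference(self, rng):
        for _ in range(25):
            freqs = [1.0, 1.5, 2.0]
            ya = {f: rng.uniform() for f in freqs}
            ea = {f: rng.uniform() for f in freqs}
            got = select_frequency(_records(ya, ea), young_floor=0.0)
            # brute-force oracle over all cells, ties toward lower frequency
            best = max(freqs, key=lambda f: (ya[f] - ea[f], -f))
            assert got == best

    def test_missing_cells_reported(self):
        records = _records({1.0: 0.9, 1.5: 0.9}, {1.0: 0.5, 1.5: 0.5})
        records = records[~((records.group == "elderly") & (records.pacing_hz == 1.5))]
        with pytest.raises(ValueError, match="missing condition cells"):
            select_frequency(records)

    def test_single_frequency_rejected(self):
        records = _records({1.5: 0.9}, {1.5: 0.5})
        with pytest.raises(ValueError, match="two pacing frequencies"):
            select_frequency(records)
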