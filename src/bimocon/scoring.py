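"""Correctness scoring of bimanual button presses.

A press is correct when it lands closer in time to the opposite hand's
*paired* finger than to the unpaired one.  In the in-phase (mirror) mode the
paired finger is the same finger (left index with right index); in the
anti-phase mode it is the different finger (left index with right middle).
The accuracy rate is the number of correct presses divided by the total
number of presses.

Pairing itself is under-determined by that rule alone, so each press is
matched to the nearest opposite-hand press per finger label within a
configurable window (default: half the cue period).  Exact ties and presses
with no counterpart in the window are resolved by policy, both defaulting
to "incorrect".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schedule import ANTI_PHASE, IN_PHASE, MODES

HANDS = ("L", "R")
FINGERS = ("index", "middle")

CORRECT = "correct"
INCORRECT = "incorrect"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class PressEvent:
    """One button press: which hand/finger, when (seconds from run start)."""

    subject_id: str
    run_id: str
    hand: str
    finger: str
    time_s: float
    block_index: int = -1
    mode: str | None = None

    def __post_init__(self) -> None:
        if self.hand not in HANDS:
            raise ValueError(f"hand must be one of {HANDS}, got {self.hand!r}")
        if self.finger not in FINGERS:
            raise ValueError(f"finger must be one of {FINGERS}, got {self.finger!r}")
        if self.time_s < 0:
            raise ValueError(f"time_s must be >= 0, got {self.time_s}")


@dataclass(frozen=True)
class ScoreConfig:
    """Matching window and tie/unmatched policies for the correctness rule."""

    match_window_s: float = 1.0 / 3.0  # half the cue period at 1.5 Hz
    tie_policy: str = "incorrect"  # "incorrect" | "exclude"
    unmatched_policy: str = "incorrect"  # "incorrect" | "exclude"

    def __post_init__(self) -> None:
        if self.match_window_s <= 0:
            raise ValueError("match_window_s must be positive")
        if self.tie_policy not in ("incorrect", "exclude"):
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")
        if self.unmatched_policy not in ("incorrect", "exclude"):
            raise ValueError(f"unknown unmatched_policy {self.unmatched_policy!r}")


def config_for_pacing(pacing_hz: float, **overrides) -> ScoreConfig:
    """Default scoring config for a pacing frequency: window = half cue period."""
    return ScoreConfig(match_window_s=0.5 / pacing_hz, **overrides)


@dataclass(frozen=True)
class AccuracyRecord:
    """Accuracy of one subject x mode (x pacing) cell."""

    subject_id: str
    mode: str
    pacing_hz: float
    n_correct: int
    n_presses: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_presses if self.n_presses > 0 else 0.0


def _nearest_gap(t: float, times: np.ndarray) -> float:
    """Distance from t to the nearest value in a sorted array (inf if empty)."""
    if times.size == 0:
        return np.inf
    i = np.searchsorted(times, t)
    best = np.inf
    if i < times.size:
        best = times[i] - t
    if i > 0:
        best = min(best, t - times[i - 1])
    return float(best)


def classify_press(
    event: PressEvent,
    other_hand_events: Sequence[PressEvent],
    mode: str,
    config: ScoreConfig | None = None,
) -> str:
    """Classify one press as correct / incorrect / excluded.

    ``other_hand_events`` must all come from the opposite hand.  The press is
    compared against the nearest same-finger and different-finger presses of
    that hand; a finger with no press inside the window counts as infinitely
    far away.
    """
    config = config or ScoreConfig()
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    same_t, diff_t = [], []
    for o in other_hand_events:
        if o.hand == event.hand:
            raise ValueError(
                f"other_hand_events contains a press from the same hand "
                f"({event.hand}) as the press being classified"
            )
        (same_t if o.finger == event.finger else diff_t).append(o.time_s)
    d_same = _nearest_gap(event.time_s, np.sort(np.asarray(same_t)))
    d_diff = _nearest_gap(event.time_s, np.sort(np.asarray(diff_t)))
    return _classify_distances(d_same, d_diff, mode, config)


def _classify_distances(
    d_same: float, d_diff: float, mode: str, config: ScoreConfig
) -> str:
    w = config.match_window_s
    d_same = d_same if d_same <= w else np.inf
    d_diff = d_diff if d_diff <= w else np.inf
    if np.isinf(d_same) and np.isinf(d_diff):
        return INCORRECT if config.unmatched_policy == "incorrect" else EXCLUDED
    if d_same == d_diff:
        return INCORRECT if config.tie_policy == "incorrect" else EXCLUDED
    paired_closer = d_same < d_diff
    if mode == IN_PHASE:
        return CORRECT if paired_closer else INCORRECT
    return CORRECT if not paired_closer else INCORRECT


def classify_events(
    events: Iterable[PressEvent], mode: str, config: ScoreConfig | None = None
) -> list[tuple[PressEvent, str]]:
    """Classify every press against the opposite hand's presses."""
    config = config or ScoreConfig()
    events = list(events)
    by_hand: dict[str, dict[str, np.ndarray]] = {}
    for hand in HANDS:
        by_hand[hand] = {
            f: np.sort(
                np.asarray(
                    [e.time_s for e in events if e.hand == hand and e.finger == f]
                )
            )
            for f in FINGERS
        }
    out = []
    for e in events:
        opp = by_hand["L" if e.hand == "R" else "R"]
        other_finger = FINGERS[1 - FINGERS.index(e.finger)]
        d_same = _nearest_gap(e.time_s, opp[e.finger])
        d_diff = _nearest_gap(e.time_s, opp[other_finger])
        out.append((e, _classify_distances(d_same, d_diff, mode, config)))
    return out


def accuracy_rate(
    events: Iterable[PressEvent],
    mode: str,
    config: ScoreConfig | None = None,
    pacing_hz: float = float("nan"),
) -> AccuracyRecord:
    """Accuracy = correct presses / all non-excluded presses for one cell."""
    events = list(events)
    subject = events[0].subject_id if events else "<empty>"
    if not events:
        warnings.warn("accuracy_rate called with no events", stacklevel=2)
        return AccuracyRecord(subject, mode, pacing_hz, 0, 0)
    labels = [lab for _, lab in classify_events(events, mode, config)]
    n_correct = sum(1 for lab in labels if lab == CORRECT)
    n_presses = sum(1 for lab in labels if lab != EXCLUDED)
    return AccuracyRecord(subject, mode, pacing_hz, n_correct, n_presses)


def records_to_frame(records: Iterable[AccuracyRecord], **extra) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "mode": r.mode,
            "pacing_hz": r.pacing_hz,
            "n_correct": r.n_correct,
            "n_presses": r.n_presses,
            "accuracy": r.accuracy,
            **extra,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def select_frequency(
    records: pd.DataFrame,
    group_order: tuple[str, str] = ("young", "elderly"),
    young_floor: float = 0.8,
) -> float:
    """Pick the pacing frequency that maximizes the between-group divergence.

    The selected frequency maximizes the (first group - second group)
    difference in mean anti-phase accuracy, among frequencies where the
    first group's mean anti-phase accuracy stays at or above ``young_floor``
    (i.e. the fastest pace that group still manages).  Ties break toward the
    lower frequency.  If no frequency clears the floor, all are eligible and
    a warning is issued.

    ``records`` needs columns group, mode, pacing_hz, accuracy.
    """
    required = {"group", "mode", "pacing_hz", "accuracy"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValueError(f"records missing columns: {sorted(missing_cols)}")
    freqs = sorted(records["pacing_hz"].unique())
    if len(freqs) < 2:
        raise ValueError("need at least two pacing frequencies to select among")
    absent = [
        (g, m, f)
        for g in group_order
        for m in MODES
        for f in freqs
        if records[
            (records["group"] == g)
            & (records["mode"] == m)
            & (records["pacing_hz"] == f)
        ].empty
    ]
    if absent:
        raise ValueError(f"missing condition cells: {absent}")

    anti = records[records["mode"] == ANTI_PHASE]
    means = anti.groupby(["group", "pacing_hz"])["accuracy"].mean()
    ref, other = group_order
    eligible = [f for f in freqs if means[(ref, f)] >= young_floor]
    if not eligible:
        warnings.warn(
            f"no frequency keeps {ref} anti-phase accuracy >= {young_floor}; "
            "selecting over all frequencies",
            stacklevel=2,
        )
        eligible = freqs
    # max difference; ties toward the lower frequency (eligible is sorted)
    best = max(eligible, key=lambda f: (means[(ref, f)] - means[(other, f)], -f))
    return float(best)
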