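"""Block/cue timing structure of a bimanual finger-movement run.

A run alternates rest and task blocks of equal length (default 20 s rest,
nine rest blocks interleaved with eight task blocks, 340 s total).  Task
blocks carry a coupling mode (in-phase or anti-phase) and a visual pacing
frequency; each cue is one alternation of the pacing picture pair, so cue
onsets fall at k / pacing_hz from block onset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

IN_PHASE = "in_phase"
ANTI_PHASE = "anti_phase"
MODES = (IN_PHASE, ANTI_PHASE)


@dataclass(frozen=True)
class Block:
    """One rest or task block with absolute run timing in seconds."""

    index: int
    kind: str  # "rest" | "task"
    start_s: float
    end_s: float
    mode: str | None = None  # set for task blocks


@dataclass(frozen=True)
class TaskSchedule:
    """Timing of one run: alternating rest/task blocks plus scanner geometry.

    ``n_volumes`` defaults to 113 at TR = 3 s, i.e. 339 s of acquisition
    inside the 340 s run; the trailing partial volume is not acquired.
    """

    run_id: str = "run-1"
    rest_block_s: float = 20.0
    n_rest_blocks: int = 9
    n_task_blocks: int = 8
    mode_sequence: tuple[str, ...] | None = None
    pacing_hz: float = 1.5
    tr_s: float = 3.0
    n_volumes: int | None = None  # None -> floor(total / TR); 113 at defaults

    def __post_init__(self) -> None:
        if self.n_volumes is None:
            total = self.rest_block_s * (self.n_rest_blocks + self.n_task_blocks)
            object.__setattr__(self, "n_volumes", int(np.floor(total / self.tr_s)))
        if self.mode_sequence is None:
            # alternate in/anti over however many task blocks there are
            seq = tuple(MODES[i % 2] for i in range(self.n_task_blocks))
            object.__setattr__(self, "mode_sequence", seq)
        else:
            object.__setattr__(self, "mode_sequence", tuple(self.mode_sequence))
        if self.rest_block_s <= 0:
            raise ValueError(f"rest_block_s must be positive, got {self.rest_block_s}")
        if self.n_rest_blocks <= 0 or self.n_task_blocks < 0:
            raise ValueError(
                "block counts must be positive (rest) / non-negative (task), "
                f"got rest={self.n_rest_blocks}, task={self.n_task_blocks}"
            )
        if self.n_task_blocks > 0 and self.n_rest_blocks - self.n_task_blocks not in (0, 1):
            raise ValueError(
                "blocks must strictly alternate starting with rest: need "
                "n_rest_blocks - n_task_blocks in {0, 1}, got "
                f"{self.n_rest_blocks} rest / {self.n_task_blocks} task"
            )
        if self.pacing_hz <= 0:
            raise ValueError(f"pacing_hz must be positive, got {self.pacing_hz}")
        if self.tr_s <= 0 or self.n_volumes <= 0:
            raise ValueError("tr_s and n_volumes must be positive")
        if len(self.mode_sequence) != self.n_task_blocks:
            raise ValueError(
                f"mode_sequence length {len(self.mode_sequence)} != "
                f"n_task_blocks {self.n_task_blocks}"
            )
        for m in self.mode_sequence:
            if m not in MODES:
                raise ValueError(f"unknown mode {m!r}; expected one of {MODES}")
        if self.n_volumes * self.tr_s > self.total_duration_s + self.tr_s:
            raise ValueError(
                f"{self.n_volumes} volumes x {self.tr_s}s TR exceed the "
                f"{self.total_duration_s}s run by more than one TR"
            )

    @property
    def total_duration_s(self) -> float:
        return self.rest_block_s * (self.n_rest_blocks + self.n_task_blocks)

    @property
    def cue_period_s(self) -> float:
        return 1.0 / self.pacing_hz

    def blocks(self) -> list[Block]:
        """Alternating rest/task blocks, rest first."""
        out: list[Block] = []
        t = 0.0
        task_i = 0
        for i in range(self.n_rest_blocks + self.n_task_blocks):
            kind = "rest" if (self.n_task_blocks == 0 or i % 2 == 0) else "task"
            mode = None
            if kind == "task":
                mode = self.mode_sequence[task_i]
                task_i += 1
            out.append(Block(i, kind, t, t + self.rest_block_s, mode))
            t += self.rest_block_s
        return out

    def task_blocks(self, mode: str | None = None) -> list[Block]:
        return [
            b
            for b in self.blocks()
            if b.kind == "task" and (mode is None or b.mode == mode)
        ]

    def cue_times(self, block: Block) -> np.ndarray:
        """Cue onsets within one task block: k / pacing_hz from block start."""
        if block.kind != "task":
            raise ValueError("cues are only defined for task blocks")
        dur = block.end_s - block.start_s
        n = int(np.floor(dur * self.pacing_hz - 1e-9)) + 1
        return block.start_s + np.arange(n) / self.pacing_hz

    def volume_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_s


def generate_schedule(pacing_hz: float = 1.5, **overrides) -> TaskSchedule:
    """Build a validated :class:`TaskSchedule` (defaults: 20 s x 17 blocks = 340 s)."""
    sched = TaskSchedule(pacing_hz=pacing_hz, **overrides)
    return sched


def with_overrides(schedule: TaskSchedule, **overrides) -> TaskSchedule:
    return replace(schedule, **overrides)
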