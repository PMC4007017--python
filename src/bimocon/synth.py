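"""Synthetic press events, ROI observations, and BOLD-like ROI series.

Three generators cover the three stages of the analysis:

* :func:`simulate_presses` produces button-press streams for a run, with a
  behavioral error structure (timing jitter, whole-cycle phase slips,
  misses, spurious presses) whose slip rate maps directly onto the expected
  accuracy of the scorer (accuracy -> 1 - swap_prob as jitter -> 0).
* :func:`simulate_roi_observations` draws per-subject ROI activation
  vectors x = (I - A)^-1 zeta from a known directed path model, so the
  population covariance is exactly the model-implied Sigma(theta).
* :func:`simulate_bold` builds block-design ROI time series as
  HRF-convolved boxcars scaled by per-ROI amplitudes plus AR(1) noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schedule import ANTI_PHASE, IN_PHASE, TaskSchedule
from .scoring import FINGERS, HANDS, PressEvent

#: the ten bilateral motor-association regions entering the path analysis
DEFAULT_ROIS = (
    "L_M1", "R_M1",
    "L_S1", "R_S1",
    "L_PMd", "R_PMd",
    "L_SMA", "R_SMA",
    "L_SPL", "R_SPL",
)


@dataclass(frozen=True)
class BehaviorProfile:
    """Error structure of one group x condition's pressing behavior.

    ``swap_prob`` is the per-cycle probability of a phase slip: the whole
    cycle's finger assignment flips on one hand, turning an anti-phase
    pattern into the mirror-symmetric one (and vice versa).
    """

    timing_sd_s: float = 0.05
    swap_prob: float = 0.02
    miss_prob: float = 0.02
    extra_prob: float = 0.01

    def __post_init__(self) -> None:
        for name in ("swap_prob", "miss_prob", "extra_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.timing_sd_s < 0:
            raise ValueError("timing_sd_s must be >= 0")


def simulate_presses(
    schedule: TaskSchedule,
    profile: BehaviorProfile,
    seed: int | np.random.Generator,
    subject_id: str = "sub-01",
) -> list[PressEvent]:
    """Simulate the press stream of one subject over one run.

    Each cue requires one press per hand.  The cue parity alternates the
    finger pattern; in-phase cues cue the same finger on both hands,
    anti-phase cues opposite fingers.  Errors are injected per the profile,
    in a fixed draw order so a fixed seed reproduces the stream exactly.
    """
    rng = np.random.default_rng(seed)
    events: list[PressEvent] = []
    for block in schedule.task_blocks():
        for k, t_cue in enumerate(schedule.cue_times(block)):
            if block.mode == IN_PHASE:
                fingers = {"L": FINGERS[k % 2], "R": FINGERS[k % 2]}
            else:
                fingers = {"L": FINGERS[1 - k % 2], "R": FINGERS[k % 2]}
            if rng.random() < profile.swap_prob:
                # phase slip: the left hand mirrors the right instead
                fingers["L"] = FINGERS[1 - FINGERS.index(fingers["L"])]
            for hand in HANDS:
                if rng.random() < profile.miss_prob:
                    continue
                t = t_cue + rng.normal(0.0, profile.timing_sd_s)
                events.append(
                    PressEvent(
                        subject_id=subject_id,
                        run_id=schedule.run_id,
                        hand=hand,
                        finger=fingers[hand],
                        time_s=max(t, 0.0),
                        block_index=block.index,
                        mode=block.mode,
                    )
                )
            if rng.random() < profile.extra_prob:
                t = t_cue + rng.uniform(0.0, schedule.cue_period_s)
                events.append(
                    PressEvent(
                        subject_id=subject_id,
                        run_id=schedule.run_id,
                        hand=HANDS[rng.integers(2)],
                        finger=FINGERS[rng.integers(2)],
                        time_s=t,
                        block_index=block.index,
                        mode=block.mode,
                    )
                )
    events.sort(key=lambda e: (e.time_s, e.hand, e.finger))
    return events


@dataclass(frozen=True)
class ConnectivityGroundTruth:
    """A known directed path model over named ROI variables.

    ``path_matrix`` holds the coefficient from column-variable to
    row-variable (zero where no path); ``disturbance_var`` the diagonal of
    the disturbance covariance Psi.  Observations are x = (I - A)^-1 zeta
    with zeta ~ N(0, Psi), so cov(x) = (I - A)^-1 Psi (I - A)^-T.
    """

    variables: tuple[str, ...] = DEFAULT_ROIS
    path_matrix: np.ndarray = field(default_factory=lambda: np.zeros((10, 10)))
    disturbance_var: np.ndarray = field(default_factory=lambda: np.ones(10))

    def __post_init__(self) -> None:
        A = np.asarray(self.path_matrix, dtype=float)
        psi = np.asarray(self.disturbance_var, dtype=float)
        p = len(self.variables)
        if A.shape != (p, p):
            raise ValueError(f"path_matrix must be {p}x{p}, got {A.shape}")
        if psi.shape != (p,):
            raise ValueError(f"disturbance_var must have length {p}")
        if np.any(np.abs(np.diag(A)) > 0):
            raise ValueError("self-paths are not allowed (diag(A) must be 0)")
        if np.any(psi <= 0):
            raise ValueError("disturbance variances must be positive")
        if abs(np.linalg.det(np.eye(p) - A)) < 1e-12:
            raise ValueError("(I - A) is singular; the path model has a unit-gain cycle")
        object.__setattr__(self, "path_matrix", A)
        object.__setattr__(self, "disturbance_var", psi)

    @property
    def p(self) -> int:
        return len(self.variables)

    def implied_covariance(self) -> np.ndarray:
        """Population covariance (I - A)^-1 Psi (I - A)^-T of the observations."""
        B = np.eye(self.p) - self.path_matrix
        Binv = np.linalg.inv(B)
        sigma = Binv @ np.diag(self.disturbance_var) @ Binv.T
        return (sigma + sigma.T) / 2.0

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for i, to in enumerate(self.variables):
            for j, frm in enumerate(self.variables):
                if self.path_matrix[i, j] != 0.0:
                    out.append((frm, to, float(self.path_matrix[i, j])))
        return out

    def to_json_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "paths": [
                {"from": f, "to": t, "coef": c} for f, t, c in self.edges()
            ],
            "disturbance_vars": {
                v: float(d) for v, d in zip(self.variables, self.disturbance_var)
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ConnectivityGroundTruth":
        variables = tuple(d["variables"])
        idx = {v: i for i, v in enumerate(variables)}
        A = np.zeros((len(variables), len(variables)))
        for path in d["paths"]:
            A[idx[path["to"]], idx[path["from"]]] = path["coef"]
        psi = np.array([d["disturbance_vars"][v] for v in variables], dtype=float)
        return cls(variables=variables, path_matrix=A, disturbance_var=psi)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ConnectivityGroundTruth":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def simulate_roi_observations(
    truth: ConnectivityGroundTruth,
    n_subjects: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Draw ``n_subjects`` ROI vectors from the path model (rows = subjects)."""
    if n_subjects < 2:
        raise ValueError(f"need n_subjects >= 2, got {n_subjects}")
    rng = np.random.default_rng(seed)
    zeta = rng.normal(size=(n_subjects, truth.p)) * np.sqrt(truth.disturbance_var)
    B = np.eye(truth.p) - truth.path_matrix
    x = np.linalg.solve(B, zeta.T).T
    return pd.DataFrame(
        x,
        columns=list(truth.variables),
        index=[f"sub-{i + 1:03d}" for i in range(n_subjects)],
    )


def simulate_bold(
    schedule: TaskSchedule,
    amplitudes: pd.DataFrame,
    noise_sd: float,
    seed: int | np.random.Generator,
    ar_rho: float = 0.2,
    baseline: float = 0.0,
) -> pd.DataFrame:
    """Block-design ROI time series: amplitude x (boxcar * HRF) + AR(1) noise.

    ``amplitudes`` is a mode x ROI table (rows indexed by mode name).  The
    noise is stationary AR(1) with marginal standard deviation ``noise_sd``
    and lag-1 correlation ``ar_rho``, drawn independently per ROI.
    """
    from .glm import mode_regressors

    if not 0 <= ar_rho < 1:
        raise ValueError("ar_rho must be in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    regs = mode_regressors(schedule)  # mode -> (n_volumes,) HRF-convolved boxcar
    rois = list(amplitudes.columns)
    n = schedule.n_volumes
    signal = np.full((n, len(rois)), float(baseline))
    for mode, reg in regs.items():
        if mode in amplitudes.index:
            signal += np.outer(reg, amplitudes.loc[mode].to_numpy())
    noise = rng.normal(size=(n, len(rois)))
    if noise_sd > 0:
        e = np.empty_like(noise)
        e[0] = noise[0]
        innov = np.sqrt(1.0 - ar_rho**2)
        for t in range(1, n):
            e[t] = ar_rho * e[t - 1] + innov * noise[t]
        signal = signal + noise_sd * e
    return pd.DataFrame(
        signal, columns=rois, index=np.round(schedule.volume_times(), 6)
    )
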