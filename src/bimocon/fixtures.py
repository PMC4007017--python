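"""Bundled connectivity ground truths for the four study conditions.

Four synthetic path models (young/elderly x in-phase/anti-phase) over the
ten bilateral motor-association ROIs.  Each model has 26 directed paths,
so with 10 free disturbance variances the covariance-structure model has
t = 36 free parameters and 55 - 36 = 19 degrees of freedom.

The *pattern* of strong versus weak paths mirrors the qualitative
group/mode contrasts the analysis is designed to detect -- e.g. the young
models carry a reciprocal bilateral-PMd pair and (anti-phase only) a strong
left-PMd -> right-SPL path that the elderly models lack, while the elderly
models route left-hemisphere drive PMd -> M1 -> S1.  The coefficient values
themselves are synthetic choices, not estimates from any dataset.
"""

from __future__ import annotations

import numpy as np

from .synth import DEFAULT_ROIS, ConnectivityGroundTruth

STRONG = 0.5
WEAK = 0.1

# (from, to, coefficient); coefficient column -> row when assembled into A.
_YOUNG_SHARED = [
    ("L_PMd", "R_PMd", STRONG),
    ("R_PMd", "L_PMd", 0.45),  # reciprocal bilateral-PMd pair
    ("L_SMA", "R_SMA", STRONG),
    ("R_M1", "L_M1", STRONG),
    ("L_PMd", "R_M1", STRONG),
    ("L_PMd", "L_S1", STRONG),
    ("L_M1", "R_PMd", 0.4),
    ("L_SMA", "L_M1", WEAK),
    ("R_SMA", "R_M1", WEAK),
    ("L_S1", "L_M1", WEAK),
    ("R_S1", "R_M1", WEAK),
    ("L_SPL", "L_PMd", WEAK),
    ("R_SPL", "R_PMd", WEAK),
    ("L_SPL", "L_SMA", WEAK),
    ("L_SMA", "L_PMd", WEAK),
    ("R_SMA", "R_PMd", WEAK),
    ("L_S1", "L_SPL", WEAK),
    ("R_S1", "R_SPL", WEAK),
    ("R_M1", "R_S1", WEAK),
    ("L_SPL", "R_SPL", WEAK),
    ("L_S1", "R_S1", WEAK),
    ("L_SMA", "R_PMd", WEAK),
    ("R_SMA", "L_PMd", WEAK),
]

YOUNG_IN_PHASE_EDGES = _YOUNG_SHARED + [
    ("R_SPL", "L_PMd", STRONG),  # reversed relative to the anti-phase model
    ("R_SPL", "R_SMA", STRONG),
    ("L_PMd", "L_M1", WEAK),
]

YOUNG_ANTI_PHASE_EDGES = _YOUNG_SHARED + [
    ("L_PMd", "R_SPL", STRONG),  # absent from the elderly models
    ("R_SPL", "R_SMA", WEAK),    # strong only in the in-phase model
    ("L_PMd", "L_M1", STRONG),
]

_ELDERLY_SHARED = [
    ("R_SMA", "L_SMA", STRONG),
    ("R_PMd", "L_PMd", STRONG),
    ("L_PMd", "L_M1", STRONG),
    ("L_M1", "L_S1", STRONG),  # left-hemisphere drive routed PMd -> M1 -> S1
    ("R_PMd", "R_M1", STRONG),
    ("R_SPL", "R_SMA", STRONG),
    ("R_S1", "R_PMd", STRONG),
    ("L_SMA", "L_M1", WEAK),
    ("R_SMA", "R_M1", WEAK),
    ("L_S1", "L_SPL", WEAK),
    ("R_S1", "R_SPL", WEAK),
    ("L_SPL", "L_PMd", WEAK),
    ("R_SPL", "R_PMd", WEAK),
    ("L_SPL", "L_SMA", WEAK),
    ("L_SMA", "L_PMd", WEAK),
    ("R_SMA", "R_PMd", WEAK),
    ("L_SPL", "R_SPL", WEAK),
    ("L_S1", "R_S1", WEAK),
    ("L_PMd", "L_S1", WEAK),
    ("L_SMA", "R_PMd", WEAK),
    ("R_SMA", "L_PMd", WEAK),
]

ELDERLY_IN_PHASE_EDGES = _ELDERLY_SHARED + [
    ("R_S1", "L_PMd", STRONG),
    ("R_M1", "R_S1", STRONG),
    ("L_M1", "R_M1", WEAK),
    ("R_M1", "L_M1", WEAK),
    ("L_PMd", "R_M1", WEAK),
]

ELDERLY_ANTI_PHASE_EDGES = _ELDERLY_SHARED + [
    ("R_S1", "L_PMd", WEAK),
    ("R_M1", "R_S1", WEAK),
    ("L_M1", "R_M1", 0.4),  # reciprocal bilateral-M1 pair, anti-phase only
    ("R_M1", "L_M1", 0.4),
    ("L_PMd", "R_M1", STRONG),
]


def _build(edges) -> ConnectivityGroundTruth:
    idx = {v: i for i, v in enumerate(DEFAULT_ROIS)}
    A = np.zeros((len(DEFAULT_ROIS), len(DEFAULT_ROIS)))
    for frm, to, coef in edges:
        if A[idx[to], idx[frm]] != 0.0:
            raise ValueError(f"duplicate edge {frm}->{to}")
        A[idx[to], idx[frm]] = coef
    psi = np.full(len(DEFAULT_ROIS), 0.5)
    return ConnectivityGroundTruth(
        variables=DEFAULT_ROIS, path_matrix=A, disturbance_var=psi
    )


def ground_truth(group: str, mode: str) -> ConnectivityGroundTruth:
    """Bundled fixture for a group ('young'|'elderly') x mode condition."""
    key = (group, mode)
    edges = {
        ("young", "in_phase"): YOUNG_IN_PHASE_EDGES,
        ("young", "anti_phase"): YOUNG_ANTI_PHASE_EDGES,
        ("elderly", "in_phase"): ELDERLY_IN_PHASE_EDGES,
        ("elderly", "anti_phase"): ELDERLY_ANTI_PHASE_EDGES,
    }.get(key)
    if edges is None:
        raise KeyError(f"no bundled ground truth for {key}")
    return _build(edges)


def all_ground_truths() -> dict[tuple[str, str], ConnectivityGroundTruth]:
    return {
        (g, m): ground_truth(g, m)
        for g in ("young", "elderly")
        for m in ("in_phase", "anti_phase")
    }
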