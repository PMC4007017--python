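"""Significance tiers of standardized paths and cross-condition comparison.

Path strength is reported as a tier of the two-sided p-value of the raw
coefficient (p < 0.001, p < 0.01, or ns with ns meaning p >= 0.01).  Across
conditions only tiers are compared -- never raw coefficients, whose scale
is not comparable across different model topologies.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fit import SEMFit

TIER_STRONG = "p<0.001"
TIER_MODERATE = "p<0.01"
TIER_NS = "ns"
TIER_ABSENT = "absent"


def tier_of(p_value: float) -> str:
    if p_value < 0.001:
        return TIER_STRONG
    if p_value < 0.01:
        return TIER_MODERATE
    return TIER_NS


def classify_path_tiers(fit: SEMFit) -> dict[tuple[str, str], str]:
    """Significance tier per path of a converged fit."""
    if not fit.converged:
        raise ValueError("cannot tier paths of an unconverged fit")
    table = fit.path_table()
    return {
        (row["from"], row["to"]): tier_of(row["p"]) for _, row in table.iterrows()
    }


@dataclass(frozen=True)
class PathDifference:
    frm: str
    to: str
    tiers: dict[str, str]  # condition -> tier
    flagged: bool  # strong in one condition, ns/absent in another


def compare_groups(fits: dict[str, SEMFit]) -> pd.DataFrame:
    """Tier every path across conditions and flag strong-vs-absent contrasts.

    ``fits`` maps condition labels (e.g. "young_anti_phase") to fits over
    the same variable set.  A path is flagged when it is strong (p < 0.001)
    in at least one condition while non-significant or entirely absent in
    another.  Returns a table with one row per path that appears in any
    condition, columns per condition holding the tier, and a ``flagged``
    column.
    """
    if not fits:
        raise ValueError("no fits to compare")
    conditions = list(fits)
    varsets = {c: set(f.model.variables) for c, f in fits.items()}
    ref = varsets[conditions[0]]
    mismatched = [c for c, v in varsets.items() if v != ref]
    if mismatched:
        raise ValueError(
            f"variable sets differ across conditions: {mismatched} vs {conditions[0]}"
        )
    unconverged = [c for c, f in fits.items() if not f.converged]
    if unconverged:
        raise ValueError(f"cannot compare unconverged fits: {unconverged}")

    tiers = {c: classify_path_tiers(f) for c, f in fits.items()}
    all_paths = sorted({p for t in tiers.values() for p in t})
    rows = []
    for frm, to in all_paths:
        row: dict[str, object] = {"from": frm, "to": to}
        path_tiers = []
        for c in conditions:
            tier = tiers[c].get((frm, to), TIER_ABSENT)
            row[c] = tier
            path_tiers.append(tier)
        row["flagged"] = TIER_STRONG in path_tiers and any(
            t in (TIER_NS, TIER_ABSENT) for t in path_tiers
        )
        rows.append(row)
    return pd.DataFrame(rows)
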