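"""File dialects shared by the pipeline stages.

Stages communicate only through these plain-text formats, so each stage can
be rerun on real exports in the same dialect:

* press events -- TSV: subject_id, run_id, block_index, mode, hand, finger,
  time_s (seconds, 3 decimals)
* ROI time series -- TSV, volume x ROI with a ``time_s`` index column
* subject betas -- CSV, subject x ROI, one file per mode x group
* path models / ground truths -- JSON {variables, paths, disturbance_vars}
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .scoring import PressEvent

PRESS_COLUMNS = [
    "subject_id", "run_id", "block_index", "mode", "hand", "finger", "time_s",
]


def write_press_events(events: Iterable[PressEvent], path: str | Path) -> None:
    rows = [
        {
            "subject_id": e.subject_id,
            "run_id": e.run_id,
            "block_index": e.block_index,
            "mode": e.mode if e.mode is not None else "",
            "hand": e.hand,
            "finger": e.finger,
            "time_s": f"{e.time_s:.3f}",
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=PRESS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_press_events(path: str | Path) -> list[PressEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "run_id": str})
    missing = set(PRESS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"press-event file {path} missing columns {sorted(missing)}")
    return [
        PressEvent(
            subject_id=str(r.subject_id),
            run_id=str(r.run_id),
            hand=r.hand,
            finger=r.finger,
            time_s=float(r.time_s),
            block_index=int(r.block_index),
            mode=r.mode if isinstance(r.mode, str) and r.mode else None,
        )
        for r in df.itertuples()
    ]


def write_roi_series(series: pd.DataFrame, path: str | Path) -> None:
    series.to_csv(path, sep="\t", index_label="time_s", float_format="%.6f")


def read_roi_series(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="time_s")


def write_subject_betas(betas: pd.DataFrame, path: str | Path) -> None:
    betas.to_csv(path, index_label="subject_id", float_format="%.6f")


def read_subject_betas(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_fit_tables(fits: dict[str, "object"], out_dir: str | Path) -> None:
    """Fit-battery TSV (one row per condition) plus per-condition path TSVs."""
    from .sem.compare import tier_of

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for label, fit in fits.items():
        s = fit.fit_summary()
        rows.append(
            {
                "model": label,
                "chi_square": round(s["chi_square"], 3),
                "df": s["df"],
                "p": round(s["p_chi"], 3),
                "GFI": round(s["gfi"], 3),
                "CFI": round(s["cfi"], 3),
                "RMSEA": round(s["rmsea"], 3),
                "AIC": round(s["aic"], 3),
                "BIC": round(s["bic"], 3),
            }
        )
        table = fit.path_table().copy()
        table["tier"] = [tier_of(p) for p in table["p"]]
        table.to_csv(out_dir / f"paths_{label}.tsv", sep="\t", index=False,
                     float_format="%.4f")
    pd.DataFrame(rows).to_csv(out_dir / "fit_indices.tsv", sep="\t", index=False)
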