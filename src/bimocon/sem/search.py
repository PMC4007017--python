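"""Greedy specification search over single-edge modifications.

Starting from an initial path model, each step evaluates every single-edge
addition, deletion, and reversal, refits each candidate, and accepts the
move that most improves the selection criterion (AIC by default, BIC
selectable).  The search halts as soon as the incumbent model meets the
conventional acceptance battery (chi^2 p > 0.05, GFI > 0.95, CFI > 0.95,
RMSEA < 0.05), or when no move improves the criterion.  Candidate fits are
warm-started from the incumbent's estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fit import SEMFit, SingularPathModelError, UnidentifiedModelError, fit_ml
from .model import PathModel, SampleMoments


@dataclass(frozen=True)
class SearchCriteria:
    """Halting criteria for the specification search."""

    p_min: float = 0.05
    gfi_min: float = 0.95
    cfi_min: float = 0.95
    rmsea_max: float = 0.05
    criterion: str = "aic"  # "aic" | "bic"

    def __post_init__(self) -> None:
        if self.criterion not in ("aic", "bic"):
            raise ValueError(f"criterion must be 'aic' or 'bic', got {self.criterion!r}")

    def score(self, fit: SEMFit) -> float:
        return fit.aic if self.criterion == "aic" else fit.bic

    def satisfied(self, fit: SEMFit) -> bool:
        return fit.meets_criteria(
            p_min=self.p_min,
            gfi_min=self.gfi_min,
            cfi_min=self.cfi_min,
            rmsea_max=self.rmsea_max,
        )


@dataclass(frozen=True)
class SearchMove:
    kind: str  # "add" | "delete" | "reverse"
    frm: str
    to: str

    def apply(self, model: PathModel) -> PathModel:
        if self.kind == "add":
            return model.with_path(self.frm, self.to)
        if self.kind == "delete":
            return model.without_path(self.frm, self.to)
        if self.kind == "reverse":
            return model.reversed_path(self.frm, self.to)
        raise ValueError(f"unknown move kind {self.kind!r}")

    def __str__(self) -> str:
        sym = {"add": "+", "delete": "-", "reverse": "~"}[self.kind]
        return f"{sym}{self.frm}->{self.to}"


@dataclass
class SearchTraceEntry:
    step: int
    move: SearchMove | None  # None for the evaluation of the start model
    score: float
    chi_square: float
    df: int
    accepted: bool
    note: str = ""


@dataclass
class SearchResult:
    model: PathModel
    fit: SEMFit
    trace: list[SearchTraceEntry] = field(default_factory=list)
    n_steps: int = 0
    halted_on_criteria: bool = False


def _candidate_moves(
    model: PathModel, candidate_edges: set[tuple[str, str]]
) -> list[SearchMove]:
    present = set(model.paths)
    moves: list[SearchMove] = []
    for frm, to in sorted(candidate_edges):
        if (frm, to) not in present:
            moves.append(SearchMove("add", frm, to))
    for frm, to in model.paths:
        moves.append(SearchMove("delete", frm, to))
        if (to, frm) not in present and (to, frm) in candidate_edges:
            moves.append(SearchMove("reverse", frm, to))
    return moves


def _warm_start(new_model: PathModel, fit: SEMFit) -> np.ndarray:
    """Carry incumbent estimates over to a neighboring model's layout."""
    old = dict(zip(fit.model.paths, fit.estimates[: len(fit.model.paths)]))
    na = len(new_model.paths)
    start = np.zeros(new_model.n_free)
    for k, path in enumerate(new_model.paths):
        start[k] = old.get(path, 0.0)
    p = new_model.p
    start[na : na + p] = fit.estimates[len(fit.model.paths) : len(fit.model.paths) + p]
    return start


def specification_search(
    start: PathModel,
    moments: SampleMoments,
    candidate_edges: list[tuple[str, str]] | None = None,
    criteria: SearchCriteria | None = None,
    max_steps: int = 50,
) -> SearchResult:
    """Greedy hill-climb over single-edge moves, best criterion first.

    ``candidate_edges`` restricts which directed pairs may be added (or
    created by a reversal); by default every ordered pair without self-loops
    is allowed.  Ties on the criterion break toward fewer free parameters,
    then lexicographic edge order.  The trace records every evaluated move.
    """
    criteria = criteria or SearchCriteria()
    if candidate_edges is None:
        candidate_edges = [
            (a, b) for a in start.variables for b in start.variables if a != b
        ]
    cand = set(candidate_edges)
    unknown = {v for e in cand for v in e} - set(start.variables)
    if unknown:
        raise ValueError(f"candidate edges mention unknown variables: {sorted(unknown)}")

    current_fit = fit_ml(start, moments, low_n_warning=False)  # raises if unidentified
    trace: list[SearchTraceEntry] = [
        SearchTraceEntry(
            0, None, criteria.score(current_fit), current_fit.chi_square,
            current_fit.df, accepted=True, note="start model",
        )
    ]
    result = SearchResult(model=start, fit=current_fit, trace=trace)
    for step in range(1, max_steps + 1):
        if criteria.satisfied(current_fit):
            result.halted_on_criteria = True
            break
        best: tuple[float, int, str, SearchMove, SEMFit] | None = None
        for move in _candidate_moves(result.model, cand):
            try:
                new_model = move.apply(result.model)
            except (KeyError, ValueError):
                continue
            try:
                fit = fit_ml(
                    new_model,
                    moments,
                    start=_warm_start(new_model, current_fit),
                    low_n_warning=False,
                    stability_warning=False,
                    compute_se=False,  # only the criterion is needed here
                )
            except (UnidentifiedModelError, SingularPathModelError, ValueError) as exc:
                trace.append(
                    SearchTraceEntry(step, move, np.inf, np.nan, new_model.df,
                                     accepted=False, note=f"failed: {exc}")
                )
                continue
            score = criteria.score(fit)
            trace.append(
                SearchTraceEntry(step, move, score, fit.chi_square, fit.df,
                                 accepted=False)
            )
            key = (score, fit.model.n_free, str(move))
            if best is None or key < (best[0], best[1], best[2]):
                best = (score, fit.model.n_free, str(move), move, fit)
        if best is None or best[0] >= criteria.score(current_fit) - 1e-9:
            break  # no improving move
        _, _, _, move, fit = best
        for entry in reversed(trace):
            if entry.step == step and entry.move == move:
                entry.accepted = True
                break
        result.model = fit.model
        current_fit = fit
        result.fit = fit
        result.n_steps = step
    else:
        pass
    if result.n_steps > 0:
        # candidate fits skip standard errors; refit the winner with them
        result.fit = fit_ml(
            result.model,
            moments,
            start=result.fit.estimates,
            low_n_warning=False,
            check_identification=False,
        )
        current_fit = result.fit
    if criteria.satisfied(current_fit):
        result.halted_on_criteria = True
    return result
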