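"""Observed-variable path model (recursive or nonrecursive) specification.

A :class:`PathModel` fixes which directed path coefficients and disturbance
(co)variances are free.  Parameters are ordered: path coefficients in the
declared edge order, then disturbance variances in variable order, then any
free disturbance covariances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class PathModel:
    variables: tuple[str, ...]
    paths: tuple[tuple[str, str], ...]  # (from, to) directed pairs
    psi_covariances: tuple[tuple[str, str], ...] = ()  # free off-diagonal Psi

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "paths", tuple(tuple(p) for p in self.paths))
        object.__setattr__(
            self, "psi_covariances", tuple(tuple(p) for p in self.psi_covariances)
        )
        names = set(self.variables)
        if len(names) != len(self.variables):
            raise ValueError("variable names must be unique")
        seen = set()
        for frm, to in self.paths:
            if frm not in names or to not in names:
                raise ValueError(f"path {frm}->{to} uses unknown variables")
            if frm == to:
                raise ValueError(f"self-path {frm}->{to} is not allowed")
            if (frm, to) in seen:
                raise ValueError(f"duplicate path {frm}->{to}")
            seen.add((frm, to))
        for a, b in self.psi_covariances:
            if a not in names or b not in names or a == b:
                raise ValueError(f"bad disturbance covariance pair ({a}, {b})")
        if self.n_free > self.n_moments:
            raise ValueError(
                f"model has t={self.n_free} free parameters but only "
                f"{self.n_moments} distinct covariance moments"
            )

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def n_free(self) -> int:
        """Total free parameters t: paths + variances + covariances."""
        return len(self.paths) + self.p + len(self.psi_covariances)

    @property
    def n_moments(self) -> int:
        return self.p * (self.p + 1) // 2

    @property
    def df(self) -> int:
        """Degrees of freedom of the covariance-structure test."""
        return self.n_moments - self.n_free

    def index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variables)}

    def path_index_pairs(self) -> list[tuple[int, int]]:
        """(row, col) index of A for each free path, in parameter order."""
        idx = self.index()
        return [(idx[to], idx[frm]) for frm, to in self.paths]

    def psi_cov_index_pairs(self) -> list[tuple[int, int]]:
        idx = self.index()
        return [(idx[a], idx[b]) for a, b in self.psi_covariances]

    def parameter_names(self) -> list[str]:
        names = [f"{frm}->{to}" for frm, to in self.paths]
        names += [f"psi[{v}]" for v in self.variables]
        names += [f"psi[{a},{b}]" for a, b in self.psi_covariances]
        return names

    def parents(self, var: str) -> list[str]:
        return [frm for frm, to in self.paths if to == var]

    def has_path(self, frm: str, to: str) -> bool:
        return (frm, to) in set(self.paths)

    def with_path(self, frm: str, to: str) -> "PathModel":
        return PathModel(self.variables, self.paths + ((frm, to),), self.psi_covariances)

    def without_path(self, frm: str, to: str) -> "PathModel":
        rest = tuple(p for p in self.paths if p != (frm, to))
        if len(rest) == len(self.paths):
            raise KeyError(f"no path {frm}->{to} in model")
        return PathModel(self.variables, rest, self.psi_covariances)

    def reversed_path(self, frm: str, to: str) -> "PathModel":
        return self.without_path(frm, to).with_path(to, frm)

    def is_recursive(self) -> bool:
        """True when the path graph is acyclic (no feedback loops)."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.paths)
        return nx.is_directed_acyclic_graph(g)

    # -- JSON dialect shared with the synthetic ground-truth models --------

    def to_json_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "paths": [{"from": f, "to": t} for f, t in self.paths],
            "psi_covariances": [list(p) for p in self.psi_covariances],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PathModel":
        return cls(
            variables=tuple(d["variables"]),
            paths=tuple((p["from"], p["to"]) for p in d["paths"]),
            psi_covariances=tuple(tuple(p) for p in d.get("psi_covariances", [])),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PathModel":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def model_from_ground_truth(truth) -> PathModel:
    """Topology of a synthetic ground truth as a free-parameter PathModel."""
    return PathModel(
        variables=tuple(truth.variables),
        paths=tuple((frm, to) for frm, to, _ in truth.edges()),
    )


@dataclass(frozen=True)
class SampleMoments:
    """Sample covariance S (denominator N-1) and the number of observations."""

    S: np.ndarray
    N: int
    variables: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be square")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("S must be symmetric")
        if self.N < 2:
            raise ValueError("need N >= 2 observations")
        object.__setattr__(self, "S", (S + S.T) / 2.0)
        if not self.variables:
            object.__setattr__(
                self, "variables", tuple(f"x{i + 1}" for i in range(S.shape[0]))
            )

    @property
    def p(self) -> int:
        return self.S.shape[0]

    @classmethod
    def from_observations(cls, data) -> "SampleMoments":
        """Moments from a subjects x variables table (DataFrame or array)."""
        import pandas as pd

        if isinstance(data, pd.DataFrame):
            variables = tuple(data.columns)
            X = data.to_numpy(dtype=float)
        else:
            X = np.asarray(data, dtype=float)
            variables = ()
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D table with at least two rows")
        S = np.cov(X, rowvar=False, ddof=1)
        return cls(S=S, N=X.shape[0], variables=variables)
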