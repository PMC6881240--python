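"""Path-model representation for structural equation models.

A :class:`PathModel` stores a SEM in reticular-action-model (RAM) form:
a directed-edge matrix ``A`` (regressions and factor loadings), a
symmetric undirected-edge matrix ``S`` (variances and covariances), and a
mean/intercept vector ``M``.  Each cell holds either a fixed numeric
value or a free-parameter *label* (a string); cells sharing one label are
equality-constrained to a single free parameter.  Observed variables come
first in the variable ordering; everything after ``n_observed`` is latent.

The model implies, for the full variable vector ``v``,

    v = A v + M + u,      u ~ N(0, S)

so that ``mu = B M`` and ``Sigma = B S B'`` with ``B = (I - A)^{-1}``,
filtered to the observed block.  All degrees-of-freedom bookkeeping
(`count_df`) and structural edits (freeing/fixing cells, splitting
equality constraints) live here; numerical estimation lives in
:mod:`lcsm.estimation`.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PathModel",
    "Cell",
    "count_df",
    "edit_parameters",
    "free",
    "fix",
]

#: Address of one matrix cell: (matrix, row index, column index).
#: Matrix is "A" (directed), "S" (undirected, symmetric) or "M" (means,
#: where row == col).
Cell = tuple[str, int, int]


def _is_label(entry) -> bool:
    return isinstance(entry, str)


@dataclass
class PathModel:
    """Labeled parameter matrices of a structural equation model."""

    variable_names: list[str]
    n_observed: int
    A: np.ndarray  # object array (n, n); A[i, j] = effect of j on i
    S: np.ndarray  # object array (n, n), symmetric cell-for-cell
    M: np.ndarray  # object array (n,)
    #: optional label -> starting-value recipe, consumed by the estimator
    start_hints: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.variable_names)
        self.A = np.asarray(self.A, dtype=object).reshape(n, n)
        self.S = np.asarray(self.S, dtype=object).reshape(n, n)
        self.M = np.asarray(self.M, dtype=object).reshape(n)
        self._index = {v: i for i, v in enumerate(self.variable_names)}
        if len(self._index) != n:
            raise ValueError("duplicate variable names")
        if not 0 <= self.n_observed <= n:
            raise ValueError("n_observed out of range")

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    @property
    def n_variables(self) -> int:
        return len(self.variable_names)

    @property
    def observed_names(self) -> list[str]:
        return self.variable_names[: self.n_observed]

    @property
    def latent_names(self) -> list[str]:
        return self.variable_names[self.n_observed:]

    def index(self, name: str) -> int:
        return self._index[name]

    def cells(self) -> Iterable[tuple[Cell, object]]:
        """Yield every addressable cell with its entry.

        S cells are yielded once (upper triangle, row <= col); M cells as
        ("M", i, i).
        """
        n = self.n_variables
        for i in range(n):
            for j in range(n):
                yield ("A", i, j), self.A[i, j]
        for i in range(n):
            for j in range(i, n):
                yield ("S", i, j), self.S[i, j]
        for i in range(n):
            yield ("M", i, i), self.M[i]

    def constraint_map(self) -> dict[str, list[Cell]]:
        """Label -> canonical cells sharing that free parameter."""
        out: dict[str, list[Cell]] = {}
        for cell, entry in self.cells():
            if _is_label(entry):
                out.setdefault(entry, []).append(cell)
        return out

    def labels(self) -> list[str]:
        return sorted(self.constraint_map())

    def get(self, cell: Cell):
        mat, i, j = cell
        if mat == "A":
            return self.A[i, j]
        if mat == "S":
            return self.S[i, j]
        if mat == "M":
            return self.M[i]
        raise KeyError(mat)

    def _set(self, cell: Cell, entry) -> None:
        mat, i, j = cell
        if mat == "A":
            self.A[i, j] = entry
        elif mat == "S":
            self.S[i, j] = entry
            self.S[j, i] = entry
        elif mat == "M":
            self.M[i] = entry
        else:
            raise KeyError(mat)

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> None:
        n = self.n_variables
        for i in range(n):
            for j in range(n):
                if self.S[i, j] != self.S[j, i]:
                    raise ValueError(
                        f"undirected matrix not symmetric at ({i},{j})"
                    )
        if not self._acyclic():
            raise ValueError("directed-edge structure contains a cycle")

    def _acyclic(self) -> bool:
        n = self.n_variables
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                e = self.A[i, j]
                if _is_label(e) or (isinstance(e, (int, float)) and e != 0):
                    adj[i, j] = True  # j -> i
        # Kahn elimination on the j -> i graph
        indeg = adj.sum(axis=1)
        stack = [i for i in range(n) if indeg[i] == 0]
        seen = 0
        while stack:
            i = stack.pop()
            seen += 1
            for k in np.nonzero(adj[:, i])[0]:
                adj[k, i] = False
                if adj[k].sum() == 0:
                    stack.append(k)
        return seen == n

    # ------------------------------------------------------------------
    # degrees of freedom
    # ------------------------------------------------------------------
    def count_df(self) -> tuple[int, int, int]:
        """Return (free_parameter_count, moment_count, df).

        Moments counted over the observed block: p(p+1)/2 covariances
        plus p means.  Free parameters are distinct labels.
        """
        p = self.n_observed
        moments = p * (p + 1) // 2 + p
        free_count = len(self.constraint_map())
        return free_count, moments, moments - free_count

    # ------------------------------------------------------------------
    # edits
    # ------------------------------------------------------------------
    def copy(self) -> "PathModel":
        return PathModel(
            list(self.variable_names),
            self.n_observed,
            copy.deepcopy(self.A),
            copy.deepcopy(self.S),
            copy.deepcopy(self.M),
            dict(self.start_hints),
        )

    def fix(self, target: str | Cell, value: float) -> "PathModel":
        """Fix a label (all its cells) or a single cell to ``value``."""
        new = self.copy()
        if isinstance(target, str):
            cmap = new.constraint_map()
            if target not in cmap:
                raise KeyError(f"unknown label {target!r}")
            for cell in cmap[target]:
                new._set(cell, float(value))
        else:
            entry = new.get(_canonical(target))
            if not _is_label(entry) and float(entry) != float(value):
                raise ValueError(
                    f"cell {target} already fixed to {entry}; refusing to "
                    f"overwrite with {value} (free it first)"
                )
            new._set(_canonical(target), float(value))
        return new

    def free_cell(self, cell: Cell, label: str | None = None) -> "PathModel":
        """Give one cell its own fresh free parameter.

        If the cell currently shares an equality label, it is split off;
        if it holds a fixed value, it becomes free.
        """
        cell = _canonical(cell)
        new = self.copy()
        if label is None:
            mat, i, j = cell
            label = f"free:{mat}:{i}:{j}"
            k = 0
            existing = set(new.constraint_map())
            base = label
            while label in existing:
                k += 1
                label = f"{base}.{k}"
        new._set(cell, label)
        return new

    def by_name(self, mat: str, row: str, col: str | None = None) -> Cell:
        """Cell address from variable names."""
        i = self.index(row)
        j = self.index(col) if col is not None else i
        return _canonical((mat, i, j))

    # ------------------------------------------------------------------
    # serialization / display
    # ------------------------------------------------------------------
    def to_json(self) -> str:
        def enc(entry):
            return {"label": entry} if _is_label(entry) else {"value": float(entry)}

        doc = {
            "variables": self.variable_names,
            "n_observed": self.n_observed,
            "A": [
                {"row": self.variable_names[i], "col": self.variable_names[j], **enc(e)}
                for (m, i, j), e in self.cells()
                if m == "A" and (e != 0 or _is_label(e))
            ],
            "S": [
                {"row": self.variable_names[i], "col": self.variable_names[j], **enc(e)}
                for (m, i, j), e in self.cells()
                if m == "S" and (e != 0 or _is_label(e))
            ],
            "M": [
                {"row": self.variable_names[i], **enc(e)}
                for (m, i, j), e in self.cells()
                if m == "M" and (e != 0 or _is_label(e))
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PathModel":
        doc = json.loads(text)
        names = doc["variables"]
        n = len(names)
        idx = {v: i for i, v in enumerate(names)}
        A = np.full((n, n), 0.0, dtype=object)
        S = np.full((n, n), 0.0, dtype=object)
        M = np.full(n, 0.0, dtype=object)

        def dec(rec):
            return rec["label"] if "label" in rec else float(rec["value"])

        for rec in doc["A"]:
            A[idx[rec["row"]], idx[rec["col"]]] = dec(rec)
        for rec in doc["S"]:
            i, j = idx[rec["row"]], idx[rec["col"]]
            S[i, j] = S[j, i] = dec(rec)
        for rec in doc["M"]:
            M[idx[rec["row"]]] = dec(rec)
        return cls(names, doc["n_observed"], A, S, M)

    def summary(self) -> str:
        """Human-readable listing of the model's parameters."""
        names = self.variable_names
        lines = [
            f"PathModel: {self.n_observed} observed, "
            f"{self.n_variables - self.n_observed} latent variables",
        ]
        free, moments, df = self.count_df()
        lines.append(f"free parameters: {free}, moments: {moments}, df: {df}")
        lines.append("directed edges (col -> row):")
        for (m, i, j), e in self.cells():
            if m == "A" and (e != 0 or _is_label(e)):
                lines.append(f"  {names[j]} -> {names[i]}: {e}")
        lines.append("variances/covariances:")
        for (m, i, j), e in self.cells():
            if m == "S" and (e != 0 or _is_label(e)):
                lines.append(f"  {names[i]} ~~ {names[j]}: {e}")
        lines.append("means/intercepts:")
        for (m, i, j), e in self.cells():
            if m == "M" and (e != 0 or _is_label(e)):
                lines.append(f"  {names[i]} ~ 1: {e}")
        return "\n".join(lines)


def _canonical(cell: Cell) -> Cell:
    mat, i, j = cell
    if mat == "S" and j < i:
        return ("S", j, i)
    if mat == "M":
        return ("M", i, i)
    return (mat, i, j)


def count_df(model: PathModel) -> tuple[int, int, int]:
    """(free_parameter_count, moment_count, df) of a path model."""
    return model.count_df()


# ----------------------------------------------------------------------
# functional edit interface
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class free:
    """Edit action: give the addressed cell(s) a fresh free parameter."""

    label: str | None = None


@dataclass(frozen=True)
class fix:
    """Edit action: fix the addressed label or cell to a value."""

    value: float = 0.0


def edit_parameters(
    model: PathModel,
    edits: Sequence[tuple[str | Cell, free | fix]],
) -> PathModel:
    """Apply a sequence of free/fix edits, returning a new model.

    Targets are either a label (string) or a cell address.  Freeing a
    label-addressed target re-labels every cell of that label (a no-op for
    df); freeing a cell splits it off its equality constraint.  Fixing a
    cell that already holds a different fixed value is rejected.
    """
    out = model
    for target, action in edits:
        if isinstance(action, fix):
            out = out.fix(target, action.value)
        elif isinstance(action, free):
            if isinstance(target, str):
                cmap = out.constraint_map()
                if target not in cmap:
                    raise KeyError(f"unknown label {target!r}")
                for cell in cmap[target]:
                    out = out.free_cell(cell, action.label)
            else:
                out = out.free_cell(target, action.label)
        else:
            raise TypeError(f"unknown edit action {action!r}")
    return out
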