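"""Thin linear-programming layer over scipy's HiGHS backend.

Provides a named-variable model builder, a single-objective solve, a
lexicographic (staged) solve that freezes each stage's optimum before the
next, and export to LP file format for external inspection.  Variable order
is fixed by insertion (callers insert in sorted-id order), so solves are
deterministic and independent of any seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_UNBOUNDED = "unbounded"
STATUS_TOLERANCE = "tolerance"

_LINPROG_STATUS = {
    0: STATUS_OPTIMAL,
    1: STATUS_TOLERANCE,  # iteration limit
    2: STATUS_INFEASIBLE,
    3: STATUS_UNBOUNDED,
    4: STATUS_TOLERANCE,  # numerical difficulties
}


class ModelError(ValueError):
    pass


@dataclass
class SolveOutcome:
    status: str
    objective: float | None
    values: dict[str, float]
    message: str = ""


@dataclass
class LinearModel:
    """A named-variable LP: min c'x s.t. A_ub x <= b_ub, A_eq x = b_eq, l<=x<=u."""

    _names: list[str] = field(default_factory=list)
    _index: dict[str, int] = field(default_factory=dict)
    _lb: list[float] = field(default_factory=list)
    _ub: list[float | None] = field(default_factory=list)
    _le: list[tuple[dict[str, float], float, str]] = field(default_factory=list)
    _eq: list[tuple[dict[str, float], float, str]] = field(default_factory=list)

    def add_var(self, name: str, lb: float = 0.0, ub: float | None = None) -> str:
        if name in self._index:
            raise ModelError(f"duplicate variable {name!r}")
        self._index[name] = len(self._names)
        self._names.append(name)
        self._lb.append(lb)
        self._ub.append(ub)
        return name

    def has_var(self, name: str) -> bool:
        return name in self._index

    def add_le(self, coeffs: Mapping[str, float], rhs: float, name: str = "") -> None:
        self._check(coeffs)
        self._le.append((dict(coeffs), rhs, name))

    def add_eq(self, coeffs: Mapping[str, float], rhs: float, name: str = "") -> None:
        self._check(coeffs)
        self._eq.append((dict(coeffs), rhs, name))

    def add_ge(self, coeffs: Mapping[str, float], rhs: float, name: str = "") -> None:
        self.add_le({v: -c for v, c in coeffs.items()}, -rhs, name)

    def _check(self, coeffs: Mapping[str, float]) -> None:
        for v in coeffs:
            if v not in self._index:
                raise ModelError(f"constraint references unknown variable {v!r}")

    def _dense(self, rows: Sequence[tuple[dict[str, float], float, str]]):
        n = len(self._names)
        A = np.zeros((len(rows), n))
        b = np.zeros(len(rows))
        for r, (coeffs, rhs, _) in enumerate(rows):
            for v, c in coeffs.items():
                A[r, self._index[v]] = c
            b[r] = rhs
        return A, b

    def solve(self, objective: Mapping[str, float]) -> SolveOutcome:
        """Minimize the given linear objective over the current constraints."""
        self._check(objective)
        n = len(self._names)
        c = np.zeros(n)
        for v, coef in objective.items():
            c[self._index[v]] = coef
        A_ub, b_ub = self._dense(self._le) if self._le else (None, None)
        A_eq, b_eq = self._dense(self._eq) if self._eq else (None, None)
        bounds = list(zip(self._lb, self._ub))
        res = linprog(
            c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
            method="highs",
        )
        status = _LINPROG_STATUS.get(res.status, STATUS_TOLERANCE)
        values = (
            {name: float(res.x[i]) for i, name in enumerate(self._names)}
            if res.x is not None
            else {}
        )
        objective_value = float(res.fun) if res.status == 0 else None
        return SolveOutcome(
            status=status, objective=objective_value, values=values,
            message=str(res.message),
        )

    # -- export -------------------------------------------------------------

    def to_lp_string(self, objective: Mapping[str, float] | None = None) -> str:
        """Render the model in CPLEX LP file format."""

        def expr(coeffs: Mapping[str, float]) -> str:
            parts = []
            for v in sorted(coeffs):
                c = coeffs[v]
                if c == 0:
                    continue
                sign = "+" if c >= 0 else "-"
                parts.append(f"{sign} {abs(c):.12g} {v}")
            return " ".join(parts) if parts else "0 " + self._names[0]

        lines = ["Minimize", " obj: " + expr(objective or {}), "Subject To"]
        for k, (coeffs, rhs, name) in enumerate(self._le):
            lines.append(f" {name or f'c{k}'}: {expr(coeffs)} <= {rhs:.12g}")
        for k, (coeffs, rhs, name) in enumerate(self._eq):
            lines.append(f" {name or f'e{k}'}: {expr(coeffs)} = {rhs:.12g}")
        lines.append("Bounds")
        for i, name in enumerate(self._names):
            ub = "+inf" if self._ub[i] is None else f"{self._ub[i]:.12g}"
            lines.append(f" {self._lb[i]:.12g} <= {name} <= {ub}")
        lines.append("End")
        return "\n".join(lines) + "\n"


@dataclass
class StageResult:
    name: str
    status: str
    optimum: float | None


def lexicographic_solve(
    model: LinearModel,
    stage_objectives: Sequence[tuple[str, Mapping[str, float]]],
    tol: float = 1e-7,
) -> tuple[str, dict[str, float], list[StageResult]]:
    """Solve prioritized objectives sequentially.

    Stage k+1 is solved subject to objective_k <= optimum_k * (1 + tol) + tol.
    Returns the final status, the last solution vector, and per-stage optima.
    A failure at any stage stops the cascade and is reported with its stage.
    """
    if tol <= 0:
        raise ModelError("tol must be positive")
    stages: list[StageResult] = []
    values: dict[str, float] = {}
    for name, objective in stage_objectives:
        outcome = model.solve(objective)
        stages.append(StageResult(name=name, status=outcome.status,
                                  optimum=outcome.objective))
        if outcome.status != STATUS_OPTIMAL:
            return outcome.status, outcome.values or values, stages
        values = outcome.values
        bound = outcome.objective + abs(outcome.objective) * tol + tol
        model.add_le(objective, bound, name=f"lex_{name}")
    return STATUS_OPTIMAL, values, stages
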