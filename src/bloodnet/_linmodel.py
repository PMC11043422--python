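"""Minimal sparse MILP builder over scipy.optimize.milp (HiGHS backend)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, milp, Bounds


@dataclass
class LinearModel:
    """Named-variable sparse MILP: rows are (coeffs, lb, ub) with a label."""

    _names: dict[Hashable, int] = field(default_factory=dict)
    _integrality: list[int] = field(default_factory=list)
    _lb: list[float] = field(default_factory=list)
    _ub: list[float] = field(default_factory=list)
    _rows: list[dict[int, float]] = field(default_factory=list)
    _row_lb: list[float] = field(default_factory=list)
    _row_ub: list[float] = field(default_factory=list)
    _row_labels: list[str] = field(default_factory=list)
    _obj: dict[int, float] = field(default_factory=dict)

    def var(
        self,
        name: Hashable,
        lb: float = 0.0,
        ub: float = np.inf,
        integer: bool = False,
    ) -> Hashable:
        if name in self._names:
            raise ValueError(f"duplicate variable {name!r}")
        self._names[name] = len(self._names)
        self._integrality.append(1 if integer else 0)
        self._lb.append(lb)
        self._ub.append(ub)
        return name

    def binary(self, name: Hashable, fixed: bool | None = None) -> Hashable:
        if fixed is None:
            return self.var(name, 0.0, 1.0, integer=True)
        v = 1.0 if fixed else 0.0
        return self.var(name, v, v, integer=True)

    def has(self, name: Hashable) -> bool:
        return name in self._names

    @property
    def n_vars(self) -> int:
        return len(self._names)

    @property
    def n_rows(self) -> int:
        return len(self._rows)

    def add_row(
        self,
        coeffs: dict[Hashable, float],
        lb: float,
        ub: float,
        label: str = "",
    ) -> None:
        self._rows.append({self._names[k]: v for k, v in coeffs.items()})
        self._row_lb.append(lb)
        self._row_ub.append(ub)
        self._row_labels.append(label)

    def add_le(self, coeffs: dict[Hashable, float], rhs: float, label: str = "") -> None:
        self.add_row(coeffs, -np.inf, rhs, label)

    def add_ge(self, coeffs: dict[Hashable, float], rhs: float, label: str = "") -> None:
        self.add_row(coeffs, rhs, np.inf, label)

    def add_eq(self, coeffs: dict[Hashable, float], rhs: float, label: str = "") -> None:
        self.add_row(coeffs, rhs, rhs, label)

    def set_objective(self, coeffs: dict[Hashable, float]) -> None:
        self._obj = {self._names[k]: v for k, v in coeffs.items()}

    def row_labels(self) -> list[str]:
        return list(self._row_labels)

    def solve(
        self,
        mip_gap: float = 1e-6,
        time_limit: float | None = None,
    ) -> tuple[str, dict[Hashable, float], float]:
        """Solve; returns (status, values-by-name, objective).

        status is one of optimal / infeasible / unbounded / limit.
        """
        n = self.n_vars
        c = np.zeros(n)
        for j, v in self._obj.items():
            c[j] = v
        constraints = []
        if self._rows:
            data, ri, ci = [], [], []
            for r, row in enumerate(self._rows):
                for j, v in row.items():
                    ri.append(r)
                    ci.append(j)
                    data.append(v)
            A = sparse.csr_matrix(
                (data, (ri, ci)), shape=(len(self._rows), n)
            )
            constraints = [
                LinearConstraint(A, np.array(self._row_lb), np.array(self._row_ub))
            ]
        options: dict = {"mip_rel_gap": mip_gap, "presolve": True}
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        res = milp(
            c=c,
            constraints=constraints,
            integrality=np.array(self._integrality),
            bounds=Bounds(np.array(self._lb), np.array(self._ub)),
            options=options,
        )
        # scipy milp status codes: 0 optimal, 1 iteration/time limit,
        # 2 infeasible, 3 unbounded, 4 other
        status = {0: "optimal", 1: "limit", 2: "infeasible", 3: "unbounded"}.get(
            res.status, "limit"
        )
        if res.x is None:
            return status, {}, float("nan")
        values = {name: float(res.x[j]) for name, j in self._names.items()}
        return status, values, float(res.fun)
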