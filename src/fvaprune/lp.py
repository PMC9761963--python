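"""Persistent LP sessions with a vertex (basic feasible solution) contract.

The pruning logic upstream is only sound when the solver hands back a vertex
of the feasible polytope: at a basic feasible solution at least n constraints
(equality rows plus active bounds) hold with equality, which is exactly what
lets a single solution witness the attainability of many flux bounds at once.
Simplex solvers guarantee this; each adapter either is a simplex method or
explicitly certifies the active-constraint count and flags ``is_vertex``
accordingly so callers can skip inspection for uncertified solutions.

Adapters
--------
``glpk``
    GLPK via swiglpk. A persistent problem object keeps the factorized basis
    between solves, so consecutive objectives are warm started; the method is
    primal simplex by default (dual is selectable but slower when only the
    objective changes, since the previous solution stays primal-feasible but
    not dual-feasible).
``highs``
    HiGHS dual simplex through :func:`scipy.optimize.linprog`. Stateless
    (no warm start) but dependency-free; vertex status is verified from the
    active-constraint count.
``gurobi``
    Optional commercial adapter; requires ``gurobipy``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .model import MetabolicModel

__all__ = [
    "LPSolution",
    "LPSession",
    "LPNumericalError",
    "SolverUnavailableError",
    "open_session",
    "available_solvers",
    "bound_tolerance",
    "count_active_constraints",
]

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

DEFAULT_EPS_ABS = 1e-6
DEFAULT_EPS_REL = 1e-9


class SolverUnavailableError(RuntimeError):
    """The requested solver adapter cannot be used in this environment."""


class LPNumericalError(RuntimeError):
    """The solver failed for numerical reasons (singular basis, instability)."""


@dataclass
class LPSolution:
    """Outcome of one LP solve.

    ``v`` and ``objective_value`` are defined only when ``status`` is
    ``"optimal"``. ``is_vertex`` is True when the solution is certified basic
    (a vertex of the feasible polytope); only such solutions may be inspected
    for attained bounds.
    """

    status: str
    v: Optional[np.ndarray] = None
    objective_value: Optional[float] = None
    is_vertex: bool = False

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


def bound_tolerance(bound: float, eps_abs: float = DEFAULT_EPS_ABS,
                    eps_rel: float = DEFAULT_EPS_REL) -> float:
    """Attainment tolerance for a bound: absolute floor plus relative part."""
    if not np.isfinite(bound):
        return np.inf
    return eps_abs + eps_rel * max(1.0, abs(bound))


def count_active_constraints(
    v: np.ndarray,
    lower_bounds: np.ndarray,
    upper_bounds: np.ndarray,
    n_equality_rows: int,
    extra_row: Optional[tuple[np.ndarray, float]] = None,
    eps_abs: float = DEFAULT_EPS_ABS,
    eps_rel: float = DEFAULT_EPS_REL,
) -> int:
    """Count constraints active at ``v``: equality rows + bounds + extra row.

    Used to certify the vertex property: a basic feasible solution of an LP
    with n variables has at least n active constraints.
    """
    active = n_equality_rows
    for x, lo, hi in zip(v, lower_bounds, upper_bounds):
        tol_lo = bound_tolerance(lo, eps_abs, eps_rel)
        tol_hi = bound_tolerance(hi, eps_abs, eps_rel)
        if (np.isfinite(lo) and abs(x - lo) <= tol_lo) or (
            np.isfinite(hi) and abs(x - hi) <= tol_hi
        ):
            active += 1
    if extra_row is not None:
        coeffs, limit = extra_row
        if abs(float(np.dot(coeffs, v)) - limit) <= bound_tolerance(limit, eps_abs, eps_rel):
            active += 1
    return active


class LPSession:
    """Abstract persistent session over the system ``S v = 0`` plus bounds.

    The constraints are fixed at construction except for :meth:`add_row`,
    which appends the single phase-2 optimality row ``c^T v >= mu * Z0``.
    Only the objective changes between solves.
    """

    def __init__(self, model: MetabolicModel,
                 extra_row: Optional[tuple[Sequence[float], float]] = None):
        self.n = model.n
        self.m = model.m
        self._lb = model.lower_bounds.copy()
        self._ub = model.upper_bounds.copy()
        self._extra_row: Optional[tuple[np.ndarray, float]] = None
        if extra_row is not None:
            coeffs, limit = extra_row
            self._extra_row = (np.asarray(coeffs, dtype=float), float(limit))

    def solve(self, sense: str, c: Sequence[float]) -> LPSolution:
        """Optimize ``c^T v`` (sense "max" or "min") over the session's polytope."""
        if sense not in ("max", "min"):
            raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
        c = np.asarray(c, dtype=float).ravel()
        if c.shape != (self.n,):
            raise ValueError(f"objective has length {c.size}, expected {self.n}")
        if not np.all(np.isfinite(c)):
            raise ValueError("objective coefficients must be finite")
        if self.n == 0:
            return LPSolution(OPTIMAL, np.zeros(0), 0.0, is_vertex=True)
        return self._solve(sense, c)

    def add_row(self, coeffs: Sequence[float], lower_limit: float) -> None:
        """Append one inequality ``coeffs . v >= lower_limit`` (the phase-2 row)."""
        raise NotImplementedError

    def _solve(self, sense: str, c: np.ndarray) -> LPSolution:
        raise NotImplementedError

    def close(self) -> None:  # pragma: no cover - trivial default
        pass

    def __enter__(self) -> "LPSession":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


# ---------------------------------------------------------------------------
# GLPK adapter (swiglpk)
# ---------------------------------------------------------------------------

class GLPKSession(LPSession):
    """GLPK simplex with a persistent basis for warm starting.

    The ``glp_prob`` object retains the optimal basis of the previous solve;
    with the presolver disabled, ``glp_simplex`` restarts from that basis, so
    a sequence of solves that differ only in the objective is warm started
    for free. Simplex solutions are basic by construction, so ``is_vertex``
    is True for every optimal solve.
    """

    def __init__(self, model, extra_row=None, method: str = "primal"):
        try:
            import swiglpk as glp
        except ImportError as exc:
            raise SolverUnavailableError(
                "the 'glpk' adapter requires the swiglpk package"
            ) from exc
        super().__init__(model, extra_row)
        self._glp = glp
        if method not in ("primal", "dual"):
            raise ValueError(f"GLPK method must be 'primal' or 'dual', got {method!r}")
        self._method = method
        glp.glp_term_out(glp.GLP_OFF)
        self._prob = glp.glp_create_prob()
        if self.n == 0:
            return
        glp.glp_add_cols(self._prob, self.n)
        for j in range(self.n):
            self._set_col_bounds(j, self._lb[j], self._ub[j])
        S = model.S.tocoo()
        n_rows = self.m + (1 if self._extra_row is not None else 0)
        if n_rows:
            glp.glp_add_rows(self._prob, n_rows)
            for i in range(self.m):
                glp.glp_set_row_bnds(self._prob, i + 1, glp.GLP_FX, 0.0, 0.0)
        entries = list(zip(S.row + 1, S.col + 1, S.data))
        if self._extra_row is not None:
            coeffs, limit = self._extra_row
            glp.glp_set_row_bnds(self._prob, self.m + 1, glp.GLP_LO, limit, 0.0)
            entries += [
                (self.m + 1, j + 1, coeffs[j]) for j in range(self.n) if coeffs[j] != 0.0
            ]
        self._load_entries(entries)

    def _load_entries(self, entries) -> None:
        glp = self._glp
        nnz = len(entries)
        ia, ja = glp.intArray(nnz + 1), glp.intArray(nnz + 1)
        ar = glp.doubleArray(nnz + 1)
        for k, (i, j, x) in enumerate(entries, start=1):
            ia[k], ja[k], ar[k] = int(i), int(j), float(x)
        glp.glp_load_matrix(self._prob, nnz, ia, ja, ar)

    def _set_col_bounds(self, j: int, lo: float, hi: float) -> None:
        glp = self._glp
        lo_f, hi_f = np.isfinite(lo), np.isfinite(hi)
        if lo_f and hi_f:
            kind = glp.GLP_FX if lo == hi else glp.GLP_DB
            glp.glp_set_col_bnds(self._prob, j + 1, kind, lo, hi)
        elif lo_f:
            glp.glp_set_col_bnds(self._prob, j + 1, glp.GLP_LO, lo, 0.0)
        elif hi_f:
            glp.glp_set_col_bnds(self._prob, j + 1, glp.GLP_UP, 0.0, hi)
        else:
            glp.glp_set_col_bnds(self._prob, j + 1, glp.GLP_FR, 0.0, 0.0)

    def add_row(self, coeffs, lower_limit: float) -> None:
        glp = self._glp
        coeffs = np.asarray(coeffs, dtype=float).ravel()
        self._extra_row = (coeffs, float(lower_limit))
        if self.n == 0:
            return
        row = glp.glp_add_rows(self._prob, 1)
        glp.glp_set_row_bnds(self._prob, row, glp.GLP_LO, float(lower_limit), 0.0)
        nz = np.nonzero(coeffs)[0]
        ind, val = glp.intArray(nz.size + 1), glp.doubleArray(nz.size + 1)
        for k, j in enumerate(nz, start=1):
            ind[k], val[k] = int(j + 1), float(coeffs[j])
        glp.glp_set_mat_row(self._prob, row, nz.size, ind, val)

    def _solve(self, sense: str, c: np.ndarray) -> LPSolution:
        glp = self._glp
        glp.glp_set_obj_dir(
            self._prob, glp.GLP_MAX if sense == "max" else glp.GLP_MIN
        )
        for j in range(self.n):
            glp.glp_set_obj_coef(self._prob, j + 1, float(c[j]))
        parm = glp.glp_smcp()
        glp.glp_init_smcp(parm)
        parm.msg_lev = glp.GLP_MSG_OFF
        parm.meth = glp.GLP_PRIMAL if self._method == "primal" else glp.GLP_DUALP
        parm.presolve = glp.GLP_OFF  # keep the basis for warm starts
        ret = glp.glp_simplex(self._prob, parm)
        if ret == glp.GLP_EBADB:
            # basis invalidated by a structural edit; rebuild and retry once
            glp.glp_adv_basis(self._prob, 0)
            ret = glp.glp_simplex(self._prob, parm)
        if ret != 0:
            raise LPNumericalError(f"GLPK simplex failed with return code {ret}")
        status = glp.glp_get_status(self._prob)
        if status == glp.GLP_OPT:
            v = np.array(
                [glp.glp_get_col_prim(self._prob, j + 1) for j in range(self.n)]
            )
            return LPSolution(OPTIMAL, v, glp.glp_get_obj_val(self._prob), is_vertex=True)
        if status == glp.GLP_UNBND:
            return LPSolution(UNBOUNDED)
        if status == glp.GLP_NOFEAS:
            return LPSolution(INFEASIBLE)
        raise LPNumericalError(f"GLPK returned unexpected status {status}")

    def close(self) -> None:
        if getattr(self, "_prob", None) is not None:
            self._glp.glp_delete_prob(self._prob)
            self._prob = None


# ---------------------------------------------------------------------------
# HiGHS adapter (scipy.optimize.linprog)
# ---------------------------------------------------------------------------

class HighsSession(LPSession):
    """Stateless HiGHS dual-simplex adapter via scipy.

    Each solve is cold; scipy's interface does not expose a basis handle.
    Dual simplex still terminates at a basic solution, and we additionally
    certify ``is_vertex`` by counting active constraints, degrading to
    ``is_vertex=False`` (inspection disabled for that solution) if the
    certificate fails.
    """

    def __init__(self, model, extra_row=None, method: str = "highs-ds"):
        super().__init__(model, extra_row)
        self._A_eq = model.S.tocsr()
        self._method = method
        self._bounds = [
            (lo if np.isfinite(lo) else None, hi if np.isfinite(hi) else None)
            for lo, hi in zip(self._lb, self._ub)
        ]

    def add_row(self, coeffs, lower_limit: float) -> None:
        self._extra_row = (np.asarray(coeffs, dtype=float).ravel(), float(lower_limit))

    def _solve(self, sense: str, c: np.ndarray) -> LPSolution:
        from scipy.optimize import linprog

        cost = -c if sense == "max" else c
        A_ub = b_ub = None
        if self._extra_row is not None:
            coeffs, limit = self._extra_row
            A_ub = -coeffs.reshape(1, -1)  # coeffs.v >= limit  ->  -coeffs.v <= -limit
            b_ub = np.array([-limit])
        res = linprog(
            cost,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=self._A_eq if self.m else None,
            b_eq=np.zeros(self.m) if self.m else None,
            bounds=self._bounds,
            method=self._method,
        )
        if res.status == 0:
            v = np.asarray(res.x)
            obj = float(np.dot(c, v))
            active = count_active_constraints(
                v, self._lb, self._ub, self.m, self._extra_row
            )
            return LPSolution(OPTIMAL, v, obj, is_vertex=active >= self.n)
        if res.status == 2:
            return LPSolution(INFEASIBLE)
        if res.status == 3:
            return LPSolution(UNBOUNDED)
        raise LPNumericalError(f"HiGHS failed: {res.message}")


# ---------------------------------------------------------------------------
# Gurobi adapter (optional commercial backend)
# ---------------------------------------------------------------------------

class GurobiSession(LPSession):
    """Gurobi primal simplex with persistent model (warm start via basis)."""

    def __init__(self, model, extra_row=None, method: str = "primal"):
        try:
            import gurobipy as gp
        except ImportError as exc:
            raise SolverUnavailableError(
                "the 'gurobi' adapter requires the gurobipy package"
            ) from exc
        super().__init__(model, extra_row)
        self._gp = gp
        env = gp.Env(params={"OutputFlag": 0})
        self._model = gp.Model(env=env)
        self._model.Params.Method = 0 if method == "primal" else 1  # simplex only
        self._x = self._model.addMVar(self.n, lb=self._lb, ub=self._ub)
        if self.m:
            self._model.addConstr(model.S @ self._x == np.zeros(self.m))
        if self._extra_row is not None:
            coeffs, limit = self._extra_row
            self._model.addConstr(coeffs @ self._x >= limit)

    def add_row(self, coeffs, lower_limit: float) -> None:
        coeffs = np.asarray(coeffs, dtype=float).ravel()
        self._extra_row = (coeffs, float(lower_limit))
        self._model.addConstr(coeffs @ self._x >= float(lower_limit))

    def _solve(self, sense: str, c: np.ndarray) -> LPSolution:
        gp = self._gp
        self._model.setObjective(
            c @ self._x, gp.GRB.MAXIMIZE if sense == "max" else gp.GRB.MINIMIZE
        )
        self._model.optimize()
        status = self._model.Status
        if status == gp.GRB.OPTIMAL:
            v = np.asarray(self._x.X)
            return LPSolution(OPTIMAL, v, float(self._model.ObjVal), is_vertex=True)
        if status == gp.GRB.INFEASIBLE:
            return LPSolution(INFEASIBLE)
        if status in (gp.GRB.UNBOUNDED, gp.GRB.INF_OR_UNBD):
            return LPSolution(UNBOUNDED)
        raise LPNumericalError(f"Gurobi returned status {status}")


_ADAPTERS = {
    "glpk": GLPKSession,
    "highs": HighsSession,
    "gurobi": GurobiSession,
}


def available_solvers() -> list[str]:
    """Names of adapters usable in this environment."""
    out = ["highs"]  # scipy is a hard dependency
    try:
        import swiglpk  # noqa: F401
        out.insert(0, "glpk")
    except ImportError:  # pragma: no cover
        pass
    try:
        import gurobipy  # noqa: F401
        out.append("gurobi")
    except ImportError:
        pass
    return out


def default_solver() -> str:
    solvers = available_solvers()
    return "glpk" if "glpk" in solvers else solvers[0]


def open_session(
    model: MetabolicModel,
    extra_row: Optional[tuple[Sequence[float], float]] = None,
    solver: str = "auto",
    method: str = "primal",
) -> LPSession:
    """Open a persistent LP session over ``S v = 0`` plus bounds.

    Parameters
    ----------
    extra_row
        Optional single inequality ``(coeffs, lower_limit)`` meaning
        ``coeffs . v >= lower_limit`` — the phase-2 optimality-fraction row.
    solver
        ``"glpk"``, ``"highs"``, ``"gurobi"`` or ``"auto"`` (GLPK when
        available, else HiGHS).
    method
        Simplex variant for adapters that support the choice; primal is the
        default because it re-uses the previous solution when only the
        objective changes.
    """
    name = default_solver() if solver == "auto" else solver
    if name not in _ADAPTERS:
        raise SolverUnavailableError(
            f"unknown solver {name!r}; choose from {sorted(_ADAPTERS)}"
        )
    cls = _ADAPTERS[name]
    if cls is HighsSession:
        return HighsSession(model, extra_row)
    return cls(model, extra_row, method=method)
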