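"""Combinatorial vertex-enumeration oracle for tiny models.

Any bounded, feasible LP attains its optimum at a vertex of the feasible
polytope, and every vertex is a basic solution: pick a maximal independent
set of active constraints (the mass-balance rows, optionally the phase-2
optimality row, and enough variable bounds to reach n), fix the non-basic
variables at their bounds, and solve the remaining square linear system.
Enumerating every basis therefore enumerates every vertex, and per-reaction
flux extents are simply coordinate-wise minima/maxima over the feasible
vertices. This is exponential in n and exists purely as an independent
ground truth for the LP-based algorithms on small instances.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Iterator, Optional

import numpy as np

from .fva import FVAResult, InfeasibleModelError, conventional_lp_count
from .model import MetabolicModel

__all__ = ["fva_oracle_enumerate", "enumerate_vertices"]

_MAX_N = 12


def _independent_rows(A: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Row-select a full-row-rank submatrix via QR with column pivoting on A^T."""
    if A.shape[0] == 0:
        return A
    from scipy.linalg import qr

    _, R, piv = qr(A.T, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    scale = diag[0] if diag.size and diag[0] > 0 else 1.0
    rank = int(np.sum(diag > tol * scale))
    return A[np.sort(piv[:rank])]


def enumerate_vertices(
    A: np.ndarray,
    b: np.ndarray,
    lower_bounds: np.ndarray,
    upper_bounds: np.ndarray,
    tol: float = 1e-7,
) -> Iterator[np.ndarray]:
    """Yield all basic solutions of ``A v = b`` with box bounds (duplicates possible).

    ``A`` must have full row rank r; each choice of r basic variables with a
    nonsingular submatrix, combined with each assignment of the n - r
    non-basic variables to one of their (finite) bounds, gives one candidate
    vertex. Feasibility of the bounds on the basic variables is checked by
    the caller. All bounds must be finite.
    """
    r, n = A.shape
    if r == 0:
        # no equalities: the vertices are the corners of the box
        for corner in product(*zip(lower_bounds, upper_bounds)):
            yield np.array(corner, dtype=float)
        return
    indices = np.arange(n)
    for basic in combinations(range(n), r):
        basic = np.array(basic)
        A_B = A[:, basic]
        if abs(np.linalg.det(A_B)) < tol:
            continue
        nonbasic = np.setdiff1d(indices, basic, assume_unique=True)
        k = nonbasic.size
        if k == 0:
            yield _scatter(n, basic, np.linalg.solve(A_B, b), nonbasic, np.empty(0))
            continue
        # all 2^k bound assignments of the non-basic variables at once
        choices = np.array(
            list(product(*[(lower_bounds[j], upper_bounds[j]) for j in nonbasic]))
        ).T  # k x 2^k
        rhs = b[:, None] - A[:, nonbasic] @ choices
        V_B = np.linalg.solve(A_B, rhs)  # r x 2^k
        for col in range(choices.shape[1]):
            yield _scatter(n, basic, V_B[:, col], nonbasic, choices[:, col])


def _scatter(n, basic, v_basic, nonbasic, v_nonbasic) -> np.ndarray:
    v = np.empty(n)
    v[basic] = v_basic
    v[nonbasic] = v_nonbasic
    return v


def fva_oracle_enumerate(
    model: MetabolicModel,
    mu: float = 1.0,
    max_reactions: int = _MAX_N,
    tol: Optional[float] = None,
) -> FVAResult:
    """Ground-truth FVA by exhaustive vertex enumeration (n <= 12, finite bounds).

    Computes Z0 as the objective maximum over phase-1 vertices, then takes
    coordinate-wise extents over all vertices of the phase-2 polytope
    (phase-1 vertices satisfying ``c^T v >= mu * Z0`` plus the vertices where
    that row itself is active). Entirely independent of any LP solver.
    """
    n = model.n
    if n > max_reactions:
        raise ValueError(
            f"enumeration oracle is limited to {max_reactions} reactions (got {n})"
        )
    lb, ub = model.lower_bounds, model.upper_bounds
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("enumeration oracle requires finite bounds")
    if tol is None:
        scale = max(1.0, float(np.max(np.abs(np.concatenate([lb, ub])))))
        tol = 1e-6 + 1e-9 * scale
    c = model.objective

    S = _independent_rows(model.S.toarray())
    b0 = np.zeros(S.shape[0])

    def feasible(v: np.ndarray) -> bool:
        return bool(np.all(v >= lb - tol) and np.all(v <= ub + tol))

    phase1 = [v for v in enumerate_vertices(S, b0, lb, ub) if feasible(v)]
    if not phase1:
        raise InfeasibleModelError("no feasible vertex: the flux polytope is empty")
    Z0 = max(float(np.dot(c, v)) for v in phase1)
    threshold = mu * Z0

    candidates = [v for v in phase1 if np.dot(c, v) >= threshold - tol]
    if np.any(c):
        # vertices where the optimality row itself is active
        A2 = np.vstack([S, c])
        b2 = np.append(b0, threshold)
        A2r = _independent_rows(A2)
        if A2r.shape[0] > S.shape[0]:  # c independent of the mass-balance rows
            candidates.extend(
                v for v in enumerate_vertices(A2r, b2, lb, ub)
                if feasible(v) and np.dot(c, v) >= threshold - tol
            )
    if not candidates:
        raise InfeasibleModelError(
            f"phase-2 polytope has no vertex (mu = {mu}, Z0 = {Z0})"
        )

    V = np.array(candidates)
    v_min = np.clip(V.min(axis=0), lb, ub)
    v_max = np.clip(V.max(axis=0), lb, ub)
    return FVAResult(
        reaction_ids=list(model.reaction_ids),
        v_min=v_min,
        v_max=v_max,
        method_min=["enumerated"] * n,
        method_max=["enumerated"] * n,
        Z0=Z0,
        mu=mu,
        lps_solved=0,
        lps_removed=conventional_lp_count(n),
        tasks=None,
    )
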