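"""Core in-memory representation of a constraint-based metabolic model.

A model is the tuple (S, lb, ub, c) together with metabolite and reaction
identifiers: the m x n stoichiometric matrix ``S`` encodes mass balance of
each metabolite (rows) across reactions (columns), ``lb``/``ub`` are box
bounds on reaction fluxes ``v`` and ``c`` is the objective vector of the
biological imperative (typically a single biomass or product reaction).
The steady-state assumption ``S v = 0`` plus the box ``lb <= v <= ub``
defines the flux polytope all analyses operate on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "MetabolicModel",
    "ModelValidationError",
    "ValidationReport",
    "validate_model",
]


class ModelValidationError(ValueError):
    """A model violates a structural requirement (shapes, duplicate ids, bounds)."""


@dataclass
class MetabolicModel:
    """A stoichiometric model: identifiers, S, flux bounds and objective.

    Parameters
    ----------
    metabolite_ids
        Ordered unique metabolite identifiers; defines the row order of ``S``.
    reaction_ids
        Ordered unique reaction identifiers; defines the column order of ``S``
        and the order of bounds, objective and all per-reaction results.
    S
        m x n sparse matrix. ``S[j, i]`` is the signed stoichiometric
        coefficient of metabolite ``j`` in reaction ``i``: consumption
        negative, production positive (COBRA convention).
    lower_bounds, upper_bounds
        Length-n flux bounds; ``-inf``/``+inf`` are allowed and preserved.
    objective
        Length-n objective coefficient vector ``c``. A zero vector is legal
        but makes FBA vacuous, so it triggers a warning.
    name
        Optional display name.
    flux_units
        Opaque unit label carried through to reports (default
        ``mmol/gDW/h``, the common genome-scale convention).
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    objective: np.ndarray
    name: str = ""
    flux_units: str = "mmol/gDW/h"

    def __post_init__(self) -> None:
        self.metabolite_ids = list(self.metabolite_ids)
        self.reaction_ids = list(self.reaction_ids)
        self.S = sp.csc_matrix(self.S, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float).ravel()
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float).ravel()
        self.objective = np.asarray(self.objective, dtype=float).ravel()

        m, n = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (m, n):
            raise ModelValidationError(
                f"S has shape {self.S.shape}, expected ({m}, {n}) from identifier lists"
            )
        for label, ids in (("metabolite", self.metabolite_ids), ("reaction", self.reaction_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise ModelValidationError(f"duplicate {label} id: {dup!r}")
        for label, vec in (
            ("lower_bounds", self.lower_bounds),
            ("upper_bounds", self.upper_bounds),
            ("objective", self.objective),
        ):
            if vec.shape != (n,):
                raise ModelValidationError(f"{label} has length {vec.shape[0]}, expected {n}")
        bad = np.nonzero(self.lower_bounds > self.upper_bounds)[0]
        if bad.size:
            i = int(bad[0])
            raise ModelValidationError(
                f"lower bound exceeds upper bound for reaction {self.reaction_ids[i]!r}: "
                f"[{self.lower_bounds[i]}, {self.upper_bounds[i]}]"
            )
        if np.isnan(self.objective).any():
            raise ModelValidationError("objective contains NaN")
        if n > 0 and not np.any(self.objective):
            warnings.warn(
                "objective vector is all-zero; FBA will trivially return Z0 = 0",
                stacklevel=3,
            )

    @property
    def m(self) -> int:
        """Number of metabolites (mass-balance rows)."""
        return len(self.metabolite_ids)

    @property
    def n(self) -> int:
        """Number of reactions (flux variables)."""
        return len(self.reaction_ids)

    def reaction_index(self, reaction_id: str) -> int:
        return self.reaction_ids.index(reaction_id)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            objective=self.objective.copy(),
            name=self.name,
            flux_units=self.flux_units,
        )

    def equals(self, other: "MetabolicModel", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Structural equality: identifiers, sparsity pattern, values, bounds, objective."""
        if (
            self.metabolite_ids != other.metabolite_ids
            or self.reaction_ids != other.reaction_ids
        ):
            return False
        if (self.S != other.S).nnz != 0 and not np.allclose(
            self.S.toarray(), other.S.toarray(), rtol=rtol, atol=atol
        ):
            return False
        return (
            np.array_equal(self.lower_bounds, other.lower_bounds)
            and np.array_equal(self.upper_bounds, other.upper_bounds)
            and np.array_equal(self.objective, other.objective)
        )


@dataclass
class ValidationReport:
    """Structural diagnostics for a model; purely informational, never mutates."""

    n_reactions: int
    n_metabolites: int
    more_reactions_than_metabolites: bool
    fixed_reactions: list[str] = field(default_factory=list)
    infinite_bound_reactions: list[str] = field(default_factory=list)
    empty_rows: list[str] = field(default_factory=list)
    decoupled_reactions: list[str] = field(default_factory=list)
    zero_objective: bool = False

    def summary(self) -> str:
        lines = [
            f"reactions: {self.n_reactions}, metabolites: {self.n_metabolites} "
            f"(n > m: {self.more_reactions_than_metabolites})",
            f"fixed reactions (lb == ub): {len(self.fixed_reactions)}",
            f"reactions with infinite bounds: {len(self.infinite_bound_reactions)}",
            f"empty mass-balance rows: {len(self.empty_rows)}",
            f"mass-balance-decoupled reactions (zero column): {len(self.decoupled_reactions)}",
        ]
        if self.zero_objective:
            lines.append("objective is all-zero")
        return "\n".join(lines)


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Report structural properties relevant to FVA.

    ``n > m`` matters because with more fluxes than mass-balance rows every
    basic feasible solution must have some fluxes pinned at their bounds,
    which is what makes solution inspection productive. Fixed reactions
    (lb == ub), infinite bounds, empty rows and zero columns are reported
    so callers can anticipate pruning behaviour and degenerate cases.
    """
    S = model.S.tocsc()
    col_nnz = np.diff(S.indptr)
    row_nnz = np.diff(S.tocsr().indptr)
    fixed = model.lower_bounds == model.upper_bounds
    infinite = ~np.isfinite(model.lower_bounds) | ~np.isfinite(model.upper_bounds)
    return ValidationReport(
        n_reactions=model.n,
        n_metabolites=model.m,
        more_reactions_than_metabolites=model.n > model.m,
        fixed_reactions=[r for r, f in zip(model.reaction_ids, fixed) if f],
        infinite_bound_reactions=[r for r, f in zip(model.reaction_ids, infinite) if f],
        empty_rows=[mid for mid, k in zip(model.metabolite_ids, row_nnz) if k == 0],
        decoupled_reactions=[r for r, k in zip(model.reaction_ids, col_nnz) if k == 0],
        zero_objective=not bool(np.any(model.objective)),
    )
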