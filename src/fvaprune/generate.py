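"""Built-in example network and a random mass-balanced model generator.

The example is a 7-reaction, 5-metabolite toy network proxying a small
bacterial metabolism with an extracellular and a cytosolic compartment; its
FVA is fully workable by hand, which makes it the canonical fixture for the
inspection algorithm (phase 1 gives Z0 = 0 at v* = 0, and complete FVA needs
only 7 of the conventional 15 LPs).

The random generator emulates the structural features the algorithm relies
on — more reactions than metabolites, every metabolite both produced and
consumed somewhere, integer stoichiometry, finite bounds, and v = 0 always
feasible — without attempting biological realism (no compartments, no
scale-free topology).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .model import MetabolicModel

__all__ = ["GeneratorSpec", "example_network", "generate_random_network"]

#: Default bound magnitude, matching the example network's box.
DEFAULT_BOUND = 1e5

_COEFS = np.array([-2, -1, 1, 2], dtype=float)


def example_network() -> MetabolicModel:
    """The built-in 5-metabolite, 7-reaction example model.

    Metabolites A..E; reaction 4 (1-based) carries the objective. Reactions
    2 and 6 are reversible (lower bound -1e5); all other fluxes are
    irreversible with bounds [0, 1e5].
    """
    S = np.array(
        [
            [-1, 0, 1, 0, 1, 0, 0],
            [1, -2, 0, -1, 0, 0, 0],
            [0, 0, 0, 2, 0, 0, 0],
            [-1, 0, 0, 0, 0, 1, 0],
            [0, 2, -1, -1, 0, 0, 1],
        ],
        dtype=float,
    )
    B = DEFAULT_BOUND
    lower = np.array([0.0, -B, 0.0, 0.0, 0.0, -B, 0.0])
    upper = np.full(7, B)
    objective = np.zeros(7)
    objective[3] = 1.0  # maximize v_4
    return MetabolicModel(
        metabolite_ids=["A", "B", "C", "D", "E"],
        reaction_ids=[f"v_{i}" for i in range(1, 8)],
        S=sp.csc_matrix(S),
        lower_bounds=lower,
        upper_bounds=upper,
        objective=objective,
        name="example_network",
    )


@dataclass
class GeneratorSpec:
    """Parameters of the random network generator.

    Attributes
    ----------
    m, n
        Metabolite and reaction counts; ``n > m >= 1`` is required so the
        generated LPs have more variables than equality rows (the regime in
        which inspection is guaranteed productive).
    density
        Target average number of nonzero stoichiometric coefficients per
        reaction column (the construction guarantees at least one producer
        and one consumer per metabolite regardless).
    irreversible_fraction
        Expected fraction of reactions with lower bound 0; the rest are
        reversible with lower bound ``-bound_magnitude``.
    bound_magnitude
        Common finite bound B > 0; uppers are B, reversible lowers are -B.
    objective_index
        Reaction carrying the indicator objective ``c = e_i``; ``None``
        draws it from the seed.
    seed
        Seed making generation fully reproducible.
    """

    m: int
    n: int
    density: float = 3.0
    irreversible_fraction: float = 0.5
    bound_magnitude: float = DEFAULT_BOUND
    objective_index: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n > self.m >= 1):
            raise ValueError(f"need n > m >= 1, got m={self.m}, n={self.n}")
        if not (np.isfinite(self.bound_magnitude) and self.bound_magnitude > 0):
            raise ValueError("bound_magnitude must be finite and positive")
        if self.objective_index is not None and not (0 <= self.objective_index < self.n):
            raise ValueError("objective_index out of range")


def generate_random_network(spec: GeneratorSpec) -> MetabolicModel:
    """Generate a random mass-balanced model satisfying the spec's invariants.

    Every metabolite row receives at least one positive (producing) and one
    negative (consuming) coefficient, extra entries are added to approach the
    target column density, all coefficients are drawn from {-2, -1, 1, 2},
    and 0 always lies inside every reaction's bounds, so ``v = 0`` is feasible
    and — the box being finite — every FVA extent LP is bounded.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.m, spec.n
    S = np.zeros((m, n))

    for j in range(m):
        prod_col, cons_col = rng.choice(n, size=2, replace=False)
        S[j, prod_col] = rng.choice([1.0, 2.0])
        S[j, cons_col] = -rng.choice([1.0, 2.0])

    target_nnz = int(round(spec.density * n))
    extra = target_nnz - np.count_nonzero(S)
    if extra > 0:
        zero_slots = np.argwhere(S == 0)
        take = min(extra, len(zero_slots))
        for j, i in zero_slots[rng.choice(len(zero_slots), size=take, replace=False)]:
            S[j, i] = rng.choice(_COEFS)

    B = spec.bound_magnitude
    irreversible = rng.random(n) < spec.irreversible_fraction
    lower = np.where(irreversible, 0.0, -B)
    upper = np.full(n, B)

    obj_index = (
        int(rng.integers(n)) if spec.objective_index is None else spec.objective_index
    )
    objective = np.zeros(n)
    objective[obj_index] = 1.0

    return MetabolicModel(
        metabolite_ids=[f"M{j + 1}" for j in range(m)],
        reaction_ids=[f"R{i + 1}" for i in range(n)],
        S=sp.csc_matrix(S),
        lower_bounds=lower,
        upper_bounds=upper,
        objective=objective,
        name=f"random_m{m}_n{n}_seed{spec.seed}",
    )
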