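"""Shared fixtures: the worked example and synthetic SBML serialization."""

from __future__ import annotations

import numpy as np
import pytest

from fvaprune import GeneratorSpec, example_network, generate_random_network
from fvaprune.model import MetabolicModel


@pytest.fixture
def example_model() -> MetabolicModel:
    return example_network()


def random_model(seed: int) -> MetabolicModel:
    """Deterministic small random model; sizes drawn from the seed."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(3, 9))
    n = int(rng.integers(m + 1, 13))
    return generate_random_network(GeneratorSpec(m=m, n=n, seed=seed))


def model_to_sbml(model: MetabolicModel, boundary_ids: frozenset[str] = frozenset()) -> str:
    """Serialize a model as SBML L3 + FBC v2 text (synthetic test fixture writer).

    Minimal but valid: bounds become shared parameters, the objective the
    active fbc objective. Species in ``boundary_ids`` are flagged as boundary
    conditions (they still appear in species references).
    """
    params: dict[float, str] = {}

    def param(value: float) -> str:
        if value not in params:
            params[value] = f"p_{len(params)}"
        return params[value]

    rxn_blocks = []
    S = model.S.tocsc()
    for i, rid in enumerate(model.reaction_ids):
        col = S.getcol(i).tocoo()
        reactants, products = [], []
        for j, coef in zip(col.row, col.data):
            ref = (
                f'<speciesReference species="{model.metabolite_ids[j]}" '
                f'stoichiometry="{abs(coef):g}" constant="true"/>'
            )
            (products if coef > 0 else reactants).append(ref)
        lo = param(model.lower_bounds[i])
        hi = param(model.upper_bounds[i])
        body = ""
        if reactants:
            body += "<listOfReactants>" + "".join(reactants) + "</listOfReactants>"
        if products:
            body += "<listOfProducts>" + "".join(products) + "</listOfProducts>"
        rxn_blocks.append(
            f'<reaction id="{rid}" reversible="{str(model.lower_bounds[i] < 0).lower()}" '
            f'fast="false" fbc:lowerFluxBound="{lo}" fbc:upperFluxBound="{hi}">{body}</reaction>'
        )

    species = "".join(
        f'<species id="{mid}" compartment="c" hasOnlySubstanceUnits="false" '
        f'boundaryCondition="{str(mid in boundary_ids).lower()}" constant="false"/>'
        for mid in model.metabolite_ids
    )
    parameters = "".join(
        f'<parameter id="{pid}" value="{value:g}" constant="true"/>'
        for value, pid in params.items()
    )
    nz = np.nonzero(model.objective)[0]
    flux_objs = "".join(
        f'<fbc:fluxObjective fbc:reaction="{model.reaction_ids[i]}" '
        f'fbc:coefficient="{model.objective[i]:g}"/>'
        for i in nz
    )
    objectives = (
        f'<fbc:listOfObjectives fbc:activeObjective="obj">'
        f'<fbc:objective fbc:id="obj" fbc:type="maximize">'
        f"<fbc:listOfFluxObjectives>{flux_objs}</fbc:listOfFluxObjectives>"
        f"</fbc:objective></fbc:listOfObjectives>"
    ) if nz.size else ""

    return (
        '<?xml version="1.0" encoding="UTF-8"?>'
        '<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" '
        'xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2" '
        'level="3" version="1" fbc:required="false">'
        f'<model id="{model.name or "model"}" fbc:strict="false">'
        '<listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>'
        f"<listOfSpecies>{species}</listOfSpecies>"
        f"<listOfParameters>{parameters}</listOfParameters>"
        f"<listOfReactions>{''.join(rxn_blocks)}</listOfReactions>"
        f"{objectives}"
        "</model></sbml>"
    )
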