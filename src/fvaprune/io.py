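"""Reading and writing metabolic models.

Two on-disk formats are supported: the COBRA-JSON dialect used by the BIGG
model repository, and SBML Level 3 with the Flux Balance Constraints (FBC)
package. Both map onto the same :class:`~fvaprune.model.MetabolicModel`;
row order follows the file's metabolite order and column order the file's
reaction order, so results keyed by reaction id line up with the source file.

Gene-protein-reaction rules, compartments and annotations are intentionally
ignored: they do not affect the flux polytope.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .model import MetabolicModel, ModelValidationError

__all__ = [
    "ModelFormatError",
    "load_model",
    "load_model_json",
    "load_model_sbml",
    "save_model_json",
]


class ModelFormatError(ValueError):
    """The file is not a well-formed model in the expected format."""


def load_model(path: str | Path) -> MetabolicModel:
    """Load a model, dispatching on file extension (.json vs .xml/.sbml)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".json":
        return load_model_json(path)
    if suffix in (".xml", ".sbml"):
        return load_model_sbml(path)
    raise ModelFormatError(
        f"cannot infer model format from extension {suffix!r} (expected .json, .xml or .sbml)"
    )


def load_model_json(path: str | Path) -> MetabolicModel:
    """Read a COBRA-JSON model (BIGG dialect).

    Expects top-level ``metabolites`` and ``reactions`` arrays; each reaction
    carries ``lower_bound``, ``upper_bound``, a ``metabolites`` coefficient
    map and an optional ``objective_coefficient`` (missing treated as 0).
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON: {exc}") from exc

    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise ModelFormatError(f"{path}: missing required key {key!r}")

    try:
        met_ids = [m["id"] for m in doc["metabolites"]]
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"{path}: metabolite entry missing key 'id'") from exc
    met_index = {mid: j for j, mid in enumerate(met_ids)}
    if len(met_index) != len(met_ids):
        raise ModelValidationError(f"{path}: duplicate metabolite ids")

    rxn_ids: list[str] = []
    lb, ub, obj = [], [], []
    rows, cols, vals = [], [], []
    for i, rxn in enumerate(doc["reactions"]):
        try:
            rid = rxn["id"]
            lo = rxn["lower_bound"]
            hi = rxn["upper_bound"]
        except (KeyError, TypeError) as exc:
            raise ModelFormatError(
                f"{path}: reaction #{i} missing key {exc.args[0]!r}"
            ) from exc
        rxn_ids.append(rid)
        lb.append(float(lo))
        ub.append(float(hi))
        obj.append(float(rxn.get("objective_coefficient", 0.0)))
        for mid, coef in rxn.get("metabolites", {}).items():
            if mid not in met_index:
                raise ModelValidationError(
                    f"{path}: reaction {rid!r} references undeclared metabolite {mid!r}"
                )
            rows.append(met_index[mid])
            cols.append(i)
            vals.append(float(coef))

    m, n = len(met_ids), len(rxn_ids)
    S = sp.csc_matrix((vals, (rows, cols)), shape=(m, n))
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lower_bounds=np.array(lb),
        upper_bounds=np.array(ub),
        objective=np.array(obj),
        name=str(doc.get("id", path.stem)),
    )


def save_model_json(model: MetabolicModel, path: str | Path) -> None:
    """Write a model as COBRA-JSON (the subset this package reads back)."""
    S = model.S.tocsc()
    reactions = []
    for i, rid in enumerate(model.reaction_ids):
        col = S.getcol(i).tocoo()
        entry = {
            "id": rid,
            "lower_bound": _json_num(model.lower_bounds[i]),
            "upper_bound": _json_num(model.upper_bounds[i]),
            "metabolites": {
                model.metabolite_ids[j]: v for j, v in zip(col.row, col.data)
            },
        }
        if model.objective[i] != 0.0:
            entry["objective_coefficient"] = model.objective[i]
        reactions.append(entry)
    doc = {
        "id": model.name or "model",
        "metabolites": [{"id": mid} for mid in model.metabolite_ids],
        "reactions": reactions,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _json_num(x: float) -> float | str:
    # JSON has no Infinity literal; BIGG files use large finite bounds, but
    # round-tripping our own models must preserve true infinities.
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return float(x)


def load_model_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML Level 3 model with the FBC package.

    Flux bounds come from the fbc lower/upper flux-bound parameters; the
    objective from the active fbc objective. Species flagged as boundary
    conditions are excluded from the mass-balance rows.
    """
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ModelFormatError(
            "reading SBML requires the python-libsbml package"
        ) from exc

    path = Path(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(f"{path}: SBML parse error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"{path}: file contains no SBML model element")

    params = {
        p.getId(): p.getValue() for p in sbml_model.getListOfParameters()
    }

    met_ids = []
    for sp_ in sbml_model.getListOfSpecies():
        if sp_.getBoundaryCondition():
            continue  # boundary species contribute no mass-balance row
        met_ids.append(sp_.getId())
    met_index = {mid: j for j, mid in enumerate(met_ids)}

    rxn_ids, lb, ub = [], [], []
    rows, cols, vals = [], [], []
    missing_bounds = []
    for i, rxn in enumerate(sbml_model.getListOfReactions()):
        rid = rxn.getId()
        rxn_ids.append(rid)
        fbc = rxn.getPlugin("fbc")
        lo = hi = None
        if fbc is not None:
            lo = params.get(fbc.getLowerFluxBound())
            hi = params.get(fbc.getUpperFluxBound())
        if lo is None or hi is None:
            missing_bounds.append(rid)
            lo, hi = 0.0, 0.0
        lb.append(float(lo))
        ub.append(float(hi))
        for ref in rxn.getListOfReactants():
            j = met_index.get(ref.getSpecies())
            if j is not None:
                rows.append(j); cols.append(i); vals.append(-float(ref.getStoichiometry()))
        for ref in rxn.getListOfProducts():
            j = met_index.get(ref.getSpecies())
            if j is not None:
                rows.append(j); cols.append(i); vals.append(float(ref.getStoichiometry()))
    if missing_bounds:
        raise ModelFormatError(
            f"{path}: reactions without FBC flux bounds: {', '.join(missing_bounds)}"
        )

    obj = np.zeros(len(rxn_ids))
    mplug = sbml_model.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        active = mplug.getActiveObjective() or mplug.getObjective(0)
        sense = -1.0 if active.getType() == "minimize" else 1.0
        rxn_pos = {rid: i for i, rid in enumerate(rxn_ids)}
        for fo in active.getListOfFluxObjectives():
            i = rxn_pos.get(fo.getReaction())
            if i is not None:
                obj[i] = sense * fo.getCoefficient()

    m, n = len(met_ids), len(rxn_ids)
    S = sp.csc_matrix((vals, (rows, cols)), shape=(m, n))
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lower_bounds=np.array(lb),
        upper_bounds=np.array(ub),
        objective=obj,
        name=sbml_model.getId() or path.stem,
    )
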