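"""Optional SBML Level 3 export of the assembled network.

Requires ``python-libsbml`` (install the ``hifdyn[sbml]`` extra); the rest
of the package has no SBML dependency.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from .errors import HifdynError
from .network import O2, ModelDefinition


def _kinetic_formula(rxn, params: Mapping[str, float]) -> str:
    keys = rxn.parameter_keys
    pid = lambda role: _sanitize(keys[role])
    if rxn.kind == "constant_inflow":
        return pid("k")
    if rxn.kind == "first_order":
        return f"{pid('k')} * {rxn.reactants[0][0]}"
    if rxn.kind == "catalytic_production":
        return f"{pid('k')} * {rxn.modifiers[0]}"
    if rxn.kind == "reversible_binding":
        (a, _), (b, _) = rxn.reactants
        (ab, _), = rxn.products
        return f"{pid('k')} * ({a} * {b} - {pid('kd')} * {ab})"
    sub = rxn.reactants[0][0]
    phd = next(m for m in rxn.modifiers if m != O2)
    return (
        f"{pid('kcat')} * {phd} * ({sub} / ({pid('km_hif')} + {sub}))"
        f" * ({O2} / ({pid('km_o2')} + {O2}))"
    )


def _sanitize(name: str) -> str:
    return name.replace(".", "__")


def export_sbml(
    model: ModelDefinition,
    params: Mapping[str, float],
    init: Mapping[str, float],
    path,
    o2_level: float = 1.0,
) -> Path:
    """Write the network as an SBML Level 3 Version 2 document."""
    try:
        import libsbml
    except ImportError as err:  # pragma: no cover - depends on extras
        raise HifdynError(
            "SBML export requires python-libsbml (pip install hifdyn[sbml])"
        ) from err

    doc = libsbml.SBMLDocument(3, 2)
    sbml_model = doc.createModel()
    sbml_model.setId("hif_hypoxia_activation")
    comp = sbml_model.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)

    for name in (*model.species, O2):
        sp = sbml_model.createSpecies()
        sp.setId(name)
        sp.setCompartment("cell")
        sp.setInitialConcentration(
            float(o2_level) if name == O2 else float(init.get(name, 0.0))
        )
        sp.setBoundaryCondition(name == O2)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)

    for name in model.parameter_names():
        par = sbml_model.createParameter()
        par.setId(_sanitize(name))
        par.setValue(float(params[name]))
        par.setConstant(True)

    for rxn in model.reactions:
        reaction = sbml_model.createReaction()
        reaction.setId(rxn.id)
        reaction.setReversible(rxn.kind == "reversible_binding")
        for name, stoich in rxn.reactants:
            ref = reaction.createReactant()
            ref.setSpecies(name)
            ref.setStoichiometry(float(stoich))
            ref.setConstant(True)
        for name, stoich in rxn.products:
            ref = reaction.createProduct()
            ref.setSpecies(name)
            ref.setStoichiometry(float(stoich))
            ref.setConstant(True)
        for name in rxn.modifiers:
            ref = reaction.createModifier()
            ref.setSpecies(name)
        if rxn.kind == "mm_hydroxylation" and O2 not in rxn.modifiers:
            ref = reaction.createModifier()
            ref.setSpecies(O2)
        law = reaction.createKineticLaw()
        law.setMath(libsbml.parseL3Formula(_kinetic_formula(rxn, params)))

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    libsbml.writeSBMLToFile(doc, str(path))
    return path
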