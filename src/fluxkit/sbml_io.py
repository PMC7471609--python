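"""SBML Level-3 + FBC v2 reading and writing via python-libsbml.

Identifiers follow the common convention of ``R_``/``M_``/``G_`` SId
prefixes (stripped on read), flux bounds as shared/per-reaction parameters,
gene associations as ``fbc:geneProductAssociation`` trees, formulas and
charges on the ``fbc`` species plugin.  Biomass variants and the NGAM
pseudo-reaction are recognised from the ``BIOMASS_*`` / ``ATPM`` id
convention after reading (see :func:`fluxkit.core.detect_pseudo_reactions`).
"""

from __future__ import annotations

import os
from typing import Optional, Union

import libsbml

from .balance import format_formula, parse_formula
from .core import Metabolite, Model, Reaction, detect_pseudo_reactions
from .errors import GPRParseError, ModelStructureError
from .gpr import BoolOp, GeneRef, GPRExpression

__all__ = ["read_model", "write_model", "read_model_string", "write_model_string"]

_SID_SAFE = str.maketrans({c: "_" for c in " -.,:;()[]"})


def _sid(prefix: str, raw: str) -> str:
    return prefix + raw.translate(_SID_SAFE)


def _strip(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


# ---------------------------------------------------------------- writing

def _association_from_gpr(node, fbc_parent, label_to_sid):
    if isinstance(node, GeneRef):
        ref = fbc_parent.createGeneProductRef()
        ref.setGeneProduct(label_to_sid[node.gene])
        return
    container = (
        fbc_parent.createAnd() if node.op == "and" else fbc_parent.createOr()
    )
    for child in node.children:
        _association_from_gpr(child, container, label_to_sid)


def write_model_string(model: Model) -> str:
    """Serialise a validated :class:`Model` to an SBML L3V1+FBCv2 string."""
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sid("", model.id) or "model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted(model.compartments):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(_sid("M_", met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(format_formula(met.formula))
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    label_to_sid = {}
    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gid = _sid("G_", gene)
        gp.setId(gid)
        gp.setLabel(gene)
        label_to_sid[gene] = gid

    # one parameter per distinct bound value
    bound_params = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(float(value))
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(_sid("R_", rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for mid, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(_sid("M_", mid))
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if not rxn.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            _association_from_gpr(rxn.gpr.root, gpa, label_to_sid)

    active = model.active_biomass
    if active is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sid("R_", active))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    return libsbml.writeSBMLToString(doc)


def write_model(model: Model, path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        fh.write(write_model_string(model))


# ---------------------------------------------------------------- reading

def _gpr_from_association(assoc, sid_to_label) -> GPRExpression:
    def walk(node):
        if node.isGeneProductRef():
            sid = node.getGeneProduct()
            if sid not in sid_to_label:
                raise ModelStructureError(
                    f"gene association references undeclared gene product {sid!r}"
                )
            return GeneRef(sid_to_label[sid])
        if node.isFbcAnd() or node.isFbcOr():
            op = "and" if node.isFbcAnd() else "or"
            children = tuple(
                walk(node.getAssociation(i)) for i in range(node.getNumAssociations())
            )
            if len(children) == 1:
                return children[0]
            return BoolOp(op, children)
        raise GPRParseError("unsupported gene-association node")

    return GPRExpression(walk(assoc.getAssociation()))


def _read_document(doc: libsbml.SBMLDocument, source: str) -> Model:
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelStructureError(
            f"SBML parse error in {source}: {err.getMessage().strip()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise ModelStructureError(f"no <model> element in {source}")
    model = Model(id=sm.getId() or "model")
    model.compartments = {
        sm.getCompartment(i).getId() for i in range(sm.getNumCompartments())
    } or {"c", "e"}

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = parse_formula(splug.getChemicalFormula())
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.add_metabolite(
            Metabolite(
                id=_strip("M_", sp.getId()),
                name=sp.getName(),
                formula=formula,
                charge=charge,
                compartment=sp.getCompartment(),
            )
        )

    mplug = sm.getPlugin("fbc")
    sid_to_label = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label = gp.getLabel() or _strip("G_", gp.getId())
            sid_to_label[gp.getId()] = label
            model.genes.add(label)

    declared = {sm.getSpecies(i).getId() for i in range(sm.getNumSpecies())}
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = _strip("R_", sr.getId())
        stoich = {}
        for refs, sign in ((sr.getListOfReactants(), -1), (sr.getListOfProducts(), 1)):
            for j in range(len(refs)):
                ref = refs.get(j)
                if ref.getSpecies() not in declared:
                    raise ModelStructureError(
                        f"reaction {rid!r} references undeclared species "
                        f"{ref.getSpecies()!r}"
                    )
                mid = _strip("M_", ref.getSpecies())
                stoich[mid] = stoich.get(mid, 0.0) + sign * ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0}
        lb, ub = -1000.0, 1000.0
        gpr = GPRExpression()
        rplug = sr.getPlugin("fbc")
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                par = sm.getParameter(rplug.getLowerFluxBound())
                if par is not None:
                    lb = par.getValue()
            if rplug.isSetUpperFluxBound():
                par = sm.getParameter(rplug.getUpperFluxBound())
                if par is not None:
                    ub = par.getValue()
            if rplug.isSetGeneProductAssociation():
                gpr = _gpr_from_association(
                    rplug.getGeneProductAssociation(), sid_to_label
                )
        mets = list(stoich)
        is_exchange = (
            len(mets) == 1
            and model.metabolites[mets[0]].compartment == "e"
            and (rid.startswith("EX_") or rid.startswith("DM_") or rid.startswith("SK_"))
        ) or (len(mets) == 1 and rid.startswith("EX_"))
        model.add_reaction(
            Reaction(
                id=rid,
                name=sr.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                is_exchange=is_exchange,
            )
        )

    detect_pseudo_reactions(model)
    model.validate()
    return model


def read_model(path: Union[str, os.PathLike]) -> Model:
    """Read an SBML L3+FBC file into a validated :class:`Model`."""
    doc = libsbml.readSBMLFromFile(os.fspath(path))
    return _read_document(doc, str(path))


def read_model_string(text: str) -> Model:
    doc = libsbml.readSBMLFromString(text)
    return _read_document(doc, "<string>")


def model_stats(model: Model) -> dict:
    """Gene/metabolite/reaction counts, as reported for model comparisons."""
    return {
        "genes": len(model.genes),
        "metabolites": len(model.metabolites),
        "reactions": len(model.reactions),
    }
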