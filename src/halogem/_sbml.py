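"""SBML Level 3 + fbc read/write for :mod:`halogem.network_core` models.

Species/gene identifiers are encoded into SBML SIds reversibly: any character
outside ``[A-Za-z0-9_]`` becomes ``__<ordinal>__`` (so ``glc-d[c]`` maps to
``M_glc__45__d__91__c__93__``).  Gene products additionally carry the original
id in their ``label``, reactions carry subsystem/kind in their notes body.
"""

from __future__ import annotations

import re
from pathlib import Path

import libsbml

from .network_core import (
    DEFAULT_BOUND,
    GPRRule,
    Metabolite,
    MetabolicModel,
    ModelParseError,
    Reaction,
)

_ENC = re.compile(r"[^A-Za-z0-9_]")
_DEC = re.compile(r"__(\d+)__")


def _encode(raw: str, prefix: str) -> str:
    return prefix + _ENC.sub(lambda m: f"__{ord(m.group(0))}__", raw)


def _decode(sid: str, prefix: str) -> str:
    if sid.startswith(prefix):
        sid = sid[len(prefix):]
    return _DEC.sub(lambda m: chr(int(m.group(1))), sid)


def _check(status, what: str) -> None:
    if status is None or (isinstance(status, int) and status != libsbml.LIBSBML_OPERATION_SUCCESS):
        raise RuntimeError(f"libsbml operation failed: {what} (status {status})")


_NOTE = re.compile(r"<p>\s*([a-z]+)\s*:\s*(.*?)\s*</p>", re.IGNORECASE | re.DOTALL)


def _notes_dict(sbase) -> dict[str, str]:
    if not sbase.isSetNotes():
        return {}
    return {k.lower(): v for k, v in _NOTE.findall(sbase.getNotesString())}


def _build_association(parent, node) -> None:
    """Recursively mirror a GPR tree into fbc association objects."""
    op = node[0]
    if op == "gene":
        ref = parent.createGeneProductRef()
        _check(ref.setGeneProduct(_encode(node[1], "G_")), f"gene ref {node[1]}")
        return
    container = parent.createAnd() if op == "and" else parent.createOr()
    for child in node[1]:
        _build_association(container, child)


def write_sbml(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    _check(sm, "createModel")
    sm.setId(_encode(model.id, ""))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    comps = sorted({m.compartment for m in model.metabolites}) or ["c"]
    for cid in comps:
        c = sm.createCompartment()
        c.setId(cid)
        c.setConstant(True)
        c.setSize(1.0)

    for met in model.metabolites:
        s = sm.createSpecies()
        s.setId(_encode(met.id, "M_"))
        s.setName(met.name)
        s.setCompartment(met.compartment)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        s.setInitialConcentration(0.0)
        splug = s.getPlugin("fbc")
        splug.setCharge(int(met.charge))
        if met.formula:
            splug.setChemicalFormula(met.formula)

    for gene in model.genes:
        gp = mplug.createGeneProduct()
        gp.setId(_encode(gene, "G_"))
        gp.setLabel(gene)

    # flux bounds live in global parameters, one pair per reaction
    def _bound_param(pid: str, value: float) -> str:
        p = sm.createParameter()
        p.setId(pid)
        p.setValue(float(value))
        p.setConstant(True)
        return pid

    for rxn in model.reactions:
        r = sm.createReaction()
        rid = _encode(rxn.id, "R_")
        r.setId(rid)
        r.setName(rxn.name)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        for mid, coeff in sorted(rxn.stoichiometry.items()):
            if coeff < 0:
                sr = r.createReactant()
                sr.setStoichiometry(-float(coeff))
            else:
                sr = r.createProduct()
                sr.setStoichiometry(float(coeff))
            sr.setSpecies(_encode(mid, "M_"))
            sr.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(f"{rid}_lb", rxn.lower_bound))
        rplug.setUpperFluxBound(_bound_param(f"{rid}_ub", rxn.upper_bound))
        if not rxn.gpr.is_empty:
            ga = rplug.createGeneProductAssociation()
            _build_association(ga, rxn.gpr.root)
        _check(
            r.setNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>subsystem: {rxn.subsystem}</p><p>kind: {rxn.kind}</p></body>"
            ),
            f"notes for {rxn.id}",
        )

    if model.objective_id:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_encode(model.objective_id, "R_"))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if not libsbml.writeSBMLToFile(doc, str(path)):
        raise IOError(f"could not write SBML to {path}")


def _association_to_gpr(assoc) -> tuple:
    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        gp = assoc.getSBMLDocument().getModel().getPlugin("fbc").getGeneProduct(
            assoc.getGeneProduct()
        )
        label = gp.getLabel() if gp is not None and gp.isSetLabel() else None
        return ("gene", label or _decode(assoc.getGeneProduct(), "G_"))
    if isinstance(assoc, libsbml.FbcAnd):
        return ("and", tuple(_association_to_gpr(assoc.getAssociation(i))
                             for i in range(assoc.getNumAssociations())))
    if isinstance(assoc, libsbml.FbcOr):
        return ("or", tuple(_association_to_gpr(assoc.getAssociation(i))
                            for i in range(assoc.getNumAssociations())))
    raise ModelParseError(f"unsupported GPR association node {type(assoc).__name__}")


def read_sbml(path: Path) -> MetabolicModel:
    path = Path(path)
    if not path.exists():
        raise ModelParseError(f"no such file: {path}")
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise ModelParseError(f"{path}: no <model> element")
    mplug = sm.getPlugin("fbc")

    mets = []
    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        splug = s.getPlugin("fbc")
        charge = 0
        formula = ""
        if splug is not None:
            if splug.isSetCharge():
                charge = splug.getCharge()
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
        raw = _decode(s.getId(), "M_")
        if not raw.endswith("]"):
            raw = f"{raw}[{s.getCompartment()}]"
        mets.append(
            Metabolite(
                id=raw,
                name=s.getName(),
                formula=formula,
                charge=charge,
                compartment=s.getCompartment(),
            )
        )

    genes = []
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            genes.append(gp.getLabel() if gp.isSetLabel() else _decode(gp.getId(), "G_"))

    objective_rid = ""
    if mplug is not None and mplug.getActiveObjective() is not None:
        obj = mplug.getActiveObjective()
        if obj.getNumFluxObjectives() > 0:
            objective_rid = _decode(obj.getFluxObjective(0).getReaction(), "R_")

    rxns = []
    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            sr = r.getReactant(j)
            mid = _decode(sr.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - sr.getStoichiometry()
        for j in range(r.getNumProducts()):
            sr = r.getProduct(j)
            mid = _decode(sr.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + sr.getStoichiometry()
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        gpr = GPRRule()
        rplug = r.getPlugin("fbc")
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                p = sm.getParameter(rplug.getLowerFluxBound())
                if p is not None:
                    lb = p.getValue()
            if rplug.isSetUpperFluxBound():
                p = sm.getParameter(rplug.getUpperFluxBound())
                if p is not None:
                    ub = p.getValue()
            if rplug.isSetGeneProductAssociation():
                gpr = GPRRule(
                    _association_to_gpr(rplug.getGeneProductAssociation().getAssociation())
                )
        if not r.getReversible():
            lb = max(lb, 0.0)
        notes = _notes_dict(r)
        kind = notes.get("kind", "")
        if not kind:
            kind = "exchange" if len(stoich) == 1 else "metabolic"
        rxns.append(
            Reaction(
                id=_decode(r.getId(), "R_"),
                name=r.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem=notes.get("subsystem", ""),
                gpr=gpr,
                kind=kind,
            )
        )

    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective_id=objective_rid,
        id=_decode(sm.getId(), "") or "model",
    )
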