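"""SBML import/export for metabolic models.

Reading accepts Level 2 and Level 3 documents, with GPRs taken from FBC
gene-product associations when present, else from legacy
``GENE_ASSOCIATION`` note strings; subsystems come from the groups
package when present, else from ``SUBSYSTEM`` notes.  Writing targets
Level 3 Version 1 with FBC v2 (GPRs, bounds) and groups (subsystems),
the de-facto standard for COBRA-style models.  Identifiers are
preserved verbatim.
"""

from __future__ import annotations

import os
import re
from typing import Optional

import libsbml

from .gpr import GprNode, parse_gpr_string
from .model import MetabolicModel, Metabolite, Reaction


class SBMLParseError(ValueError):
    """The document is not readable SBML."""


_NOTE_PATTERNS = {
    "gene_association": re.compile(
        r"GENE[ _]?ASSOCIATION\s*:\s*([^<\n]*)", re.IGNORECASE
    ),
    "subsystem": re.compile(r"SUBSYSTEM\s*:\s*([^<\n]*)", re.IGNORECASE),
}


def _note_field(sbase, which: str) -> Optional[str]:
    if not sbase.isSetNotes():
        return None
    notes = sbase.getNotesString()
    m = _NOTE_PATTERNS[which].search(notes)
    if m:
        value = m.group(1).strip()
        return value or None
    return None


def _association_to_gpr(assoc, gp_label: dict[str, str]) -> Optional[GprNode]:
    name = assoc.getElementName()
    if name == "geneProductRef":
        ref = assoc.getGeneProduct()
        return GprNode("GENE", gene_id=gp_label.get(ref, ref))
    children = [
        _association_to_gpr(assoc.getAssociation(i), gp_label)
        for i in range(assoc.getNumAssociations())
    ]
    children = [c for c in children if c is not None]
    if not children:
        return None
    if len(children) == 1:
        return children[0]
    kind = "AND" if name == "and" else "OR"
    return GprNode(kind, children=children)


def read_model(path: str) -> MetabolicModel:
    """Read an SBML file into a MetabolicModel.

    Reaction order equals document order and is the index space that
    flux-mode files address.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise SBMLParseError(
            f"malformed SBML in {path}: line {err.getLine()}: "
            f"{err.getMessage().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLParseError(f"no <model> element in {path}")

    model = MetabolicModel(id=sbml_model.getId() or "model")
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        model.metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "",
                is_boundary=bool(sp.getBoundaryCondition()),
            )
        )

    # FBC gene products: id -> label (the label carries the gene name)
    gp_label: dict[str, str] = {}
    mplugin = sbml_model.getPlugin("fbc")
    if mplugin is not None:
        for i in range(mplugin.getNumGeneProducts()):
            gp = mplugin.getGeneProduct(i)
            gp_label[gp.getIdAttribute()] = gp.getLabel() or gp.getIdAttribute()
    genes: list[str] = list(gp_label.values())
    gene_seen = set(genes)

    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - (
                ref.getStoichiometry() or 1.0
            )
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + (
                ref.getStoichiometry() or 1.0
            )
        stoich = {k: v for k, v in stoich.items() if v != 0.0}

        gpr: Optional[GprNode] = None
        rplugin = rxn.getPlugin("fbc")
        if rplugin is not None and rplugin.isSetGeneProductAssociation():
            gpa = rplugin.getGeneProductAssociation()
            if gpa.getAssociation() is not None:
                gpr = _association_to_gpr(gpa.getAssociation(), gp_label)
        if gpr is None:
            rule = _note_field(rxn, "gene_association")
            if rule:
                gpr = parse_gpr_string(rule)

        if gpr is not None:
            for g in gpr.genes():
                if g not in gene_seen:
                    gene_seen.add(g)
                    genes.append(g)

        model.reactions.append(
            Reaction(
                id=rxn.getId(),
                name=rxn.getName() or "",
                stoichiometry=stoich,
                reversible=bool(rxn.getReversible()),
                gpr=gpr,
                subsystem=_note_field(rxn, "subsystem"),
            )
        )

    # groups-package subsystems override / complement notes
    gplugin = sbml_model.getPlugin("groups")
    if gplugin is not None:
        labels: dict[str, list[str]] = {}
        for i in range(gplugin.getNumGroups()):
            grp = gplugin.getGroup(i)
            label = grp.getName() or grp.getId()
            for j in range(grp.getNumMembers()):
                ref = grp.getMember(j).getIdRef()
                labels.setdefault(ref, []).append(label)
        if labels:
            for rxn in model.reactions:
                if rxn.id in labels:
                    rxn.subsystem = "; ".join(labels[rxn.id])

    model.genes = genes
    model.validate()
    return model


def _gpr_to_association(node: GprNode, gp_id: dict[str, str], parent) -> None:
    if node.kind == "GENE":
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(gp_id[node.gene_id])
        return
    assoc = parent.createAnd() if node.kind == "AND" else parent.createOr()
    for child in node.children:
        _gpr_to_association(child, gp_id, assoc)


def _sanitize_sid(raw: str) -> str:
    sid = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "_" + sid
    return sid


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write a model as SBML L3V1 + FBC v2 + groups.

    Flux bounds are wide-open defaults (the document is an analysis /
    visualization artifact, not a curated simulation model).
    """
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    ns.addPackageNamespace("groups", 1)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    doc.setPackageRequired("groups", False)

    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    mplugin = sbml_model.getPlugin("fbc")
    mplugin.setStrict(False)

    compartments = dict(model.compartments)
    for m in model.metabolites:
        if m.compartment and m.compartment not in compartments:
            compartments[m.compartment] = m.compartment
    if any(not m.compartment for m in model.metabolites):
        compartments.setdefault("default", "default")
    for cid, cname in compartments.items():
        comp = sbml_model.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(m.id)
        if m.name:
            sp.setName(m.name)
        sp.setCompartment(m.compartment or "default")
        sp.setBoundaryCondition(m.is_boundary)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    gp_id: dict[str, str] = {}
    for gene in model.genes:
        gp = mplugin.createGeneProduct()
        sid = "G_" + _sanitize_sid(gene)
        gp.setId(sid)
        gp.setLabel(gene)
        gp_id[gene] = sid

    for pid, value in (
        ("fm_lower_bound", -1000.0),
        ("fm_zero_bound", 0.0),
        ("fm_upper_bound", 1000.0),
    ):
        param = sbml_model.createParameter()
        param.setId(pid)
        param.setValue(value)
        param.setConstant(True)

    subsystems: dict[str, list[str]] = {}
    for rxn in model.reactions:
        sr = sbml_model.createReaction()
        sr.setId(rxn.id)
        if rxn.name:
            sr.setName(rxn.name)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(met_id)
            ref.setConstant(True)
        rplugin = sr.getPlugin("fbc")
        rplugin.setLowerFluxBound(
            "fm_lower_bound" if rxn.reversible else "fm_zero_bound"
        )
        rplugin.setUpperFluxBound("fm_upper_bound")
        if rxn.gpr is not None:
            gpa = rplugin.createGeneProductAssociation()
            _gpr_to_association(rxn.gpr, gp_id, gpa)
        for label in rxn.subsystems:
            subsystems.setdefault(label, []).append(rxn.id)

    if subsystems:
        gplugin = sbml_model.getPlugin("groups")
        for k, (label, rxn_ids) in enumerate(sorted(subsystems.items())):
            grp = gplugin.createGroup()
            grp.setId(f"group{k + 1}")
            grp.setName(label)
            grp.setKind("partonomy")
            for rid in rxn_ids:
                member = grp.createMember()
                member.setIdRef(rid)

    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise IOError(f"could not write SBML to {path}")
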