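"""Submodel extraction: one flux mode as a standalone SBML model.

Given a selected EFM, all other reactions are removed from the model
along with any metabolites and genes left unconnected, and the result
is written as SBML for downstream network visualization.  Ubiquitous
currency metabolites (ATP, H+, H2O, ...) participate in so many
reactions that they obscure the pathway structure; they can optionally
be removed during extraction.  Removal deletes species and their edges
but never reactions, since reaction nodes carry the flux annotations
mapped later.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from . import sbml
from .efm_io import Efm
from .model import MetabolicModel, Metabolite, Reaction


@dataclass(frozen=True)
class UbiquitousList:
    """Compartment-qualified metabolite ids to drop from extraction.

    ``protected`` ids (typically the designated input/output species of
    the mode under study) may never be removed.
    """

    removable: frozenset[str] = field(default_factory=frozenset)
    protected: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        clash = self.removable & self.protected
        if clash:
            raise ValueError(
                f"metabolites marked both removable and protected: {sorted(clash)}"
            )


def default_ubiquitous_base_ids() -> list[str]:
    """Base ids of the shipped currency-metabolite list."""
    ref = resources.files("fluxmodes.data") / "ubiquitous_metabolites.tsv"
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    return [str(b) for b in table["base_id"]]


def default_ubiquitous_list(
    model: MetabolicModel, protected: frozenset[str] = frozenset()
) -> UbiquitousList:
    """Expand the shipped base ids per model compartment.

    A base id ``atp`` matches model metabolites named ``atp_<comp>`` (or
    exactly ``atp``) for every compartment of the model.  Fully
    overridable by constructing an UbiquitousList directly.
    """
    bases = set(default_ubiquitous_base_ids())
    hits = set()
    for met in model.metabolites:
        stem = met.id
        for comp in model.compartments:
            suffix = f"_{comp}"
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        if stem.lower() in bases:
            hits.add(met.id)
    return UbiquitousList(removable=frozenset(hits), protected=protected)


def read_ubiquitous_list(
    path: str, protected: frozenset[str] = frozenset()
) -> UbiquitousList:
    """Read a user list: one compartment-qualified metabolite id per line."""
    with open(path) as fh:
        ids = {line.strip() for line in fh if line.strip() and not line.startswith("#")}
    return UbiquitousList(removable=frozenset(ids), protected=protected)


def extract_submodel(
    model: MetabolicModel,
    efm: Efm,
    ubiquitous: UbiquitousList | None = None,
) -> MetabolicModel:
    """Build the standalone model containing exactly one EFM's reactions.

    Metabolites are restricted to those participating in a retained
    reaction (minus the ubiquitous list); genes to those appearing in a
    retained GPR.  GPR trees are kept whole.  A reaction emptied of all
    participants by ubiquitous removal stays in the submodel as a
    species-free placeholder.
    """
    if not efm.reaction_indices:
        raise ValueError("cannot extract a submodel from an empty EFM")
    bad = [i for i in efm.reaction_indices if not 1 <= i <= model.n_reactions]
    if bad:
        raise ValueError(f"EFM indices out of model range: {sorted(bad)}")
    removable = ubiquitous.removable if ubiquitous is not None else frozenset()

    sub = MetabolicModel(id=f"{model.id}_EFM{efm.efm_id}")
    kept_mets: set[str] = set()
    kept_genes: set[str] = set()
    for j in sorted(efm.reaction_indices):
        rxn = model.reactions[j - 1]
        stoich = {
            met_id: coeff
            for met_id, coeff in rxn.stoichiometry.items()
            if met_id not in removable
        }
        sub.reactions.append(
            Reaction(
                id=rxn.id,
                name=rxn.name,
                stoichiometry=stoich,
                reversible=rxn.reversible,
                gpr=rxn.gpr,
                subsystem=rxn.subsystem,
            )
        )
        kept_mets.update(stoich)
        if rxn.gpr is not None:
            kept_genes.update(rxn.gpr.genes())

    for met in model.metabolites:
        if met.id in kept_mets:
            sub.metabolites.append(
                Metabolite(
                    id=met.id,
                    name=met.name,
                    compartment=met.compartment,
                    is_boundary=met.is_boundary,
                )
            )
    used_comps = {m.compartment for m in sub.metabolites if m.compartment}
    sub.compartments = {
        cid: name for cid, name in model.compartments.items() if cid in used_comps
    }
    sub.genes = [g for g in model.genes if g in kept_genes]
    sub.validate()
    return sub


def write_submodel_sbml(sub: MetabolicModel, path: str) -> None:
    """Serialize a submodel as SBML L3V1 + FBC v2 + groups."""
    sbml.write_sbml(sub, path)
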