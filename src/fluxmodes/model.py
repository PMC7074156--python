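"""In-memory representation of a genome-scale metabolic model.

The model is the substrate of every downstream operation: reaction order
defines the index space addressed by flux-mode files, stoichiometry
defines the matrix S used for steady-state checks, and per-reaction GPR
trees and subsystem labels drive omics mapping and pathway profiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .gpr import GprNode


class ModelValidationError(ValueError):
    """A model (or model file) violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    is_boundary: bool = False


@dataclass
class Reaction:
    """A stoichiometric conversion.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed, positive = produced).  Exchange/demand
    placeholders may legitimately have a single participant, or none at
    all after ubiquitous-metabolite removal.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    reversible: bool = False
    gpr: Optional[GprNode] = None
    subsystem: Optional[str] = None

    @property
    def subsystems(self) -> list[str]:
        """Subsystem labels as a list (models may attach several)."""
        if not self.subsystem:
            return []
        return [s.strip() for s in self.subsystem.split(";") if s.strip()]


@dataclass
class MetabolicModel:
    id: str
    reactions: list[Reaction] = field(default_factory=list)
    metabolites: list[Metabolite] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    compartments: dict[str, str] = field(default_factory=dict)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def reaction_by_id(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def validate(self) -> None:
        """Raise ModelValidationError on any invariant violation."""
        seen_r: set[str] = set()
        for r in self.reactions:
            if not r.id:
                raise ModelValidationError("reaction with empty id")
            if r.id in seen_r:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
        seen_m: set[str] = set()
        for m in self.metabolites:
            if not m.id:
                raise ModelValidationError("metabolite with empty id")
            if m.id in seen_m:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            seen_m.add(m.id)
            if m.compartment and m.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {m.id!r} references undeclared compartment "
                    f"{m.compartment!r}"
                )
        gene_set = set(self.genes)
        for r in self.reactions:
            for met_id, coeff in r.stoichiometry.items():
                if met_id not in seen_m:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references unknown metabolite "
                        f"{met_id!r}"
                    )
                if not np.isfinite(coeff) or coeff == 0:
                    raise ModelValidationError(
                        f"reaction {r.id!r} has invalid coefficient for "
                        f"{met_id!r}: {coeff}"
                    )
            if r.gpr is not None:
                missing = set(r.gpr.genes()) - gene_set
                if missing:
                    raise ModelValidationError(
                        f"reaction {r.id!r} GPR references unknown genes: "
                        f"{sorted(missing)}"
                    )


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense stoichiometric matrix S (metabolites x reactions).

    Entry (i, j) is the signed coefficient of metabolite i in reaction j;
    row and column order follow model order.
    """
    S = np.zeros((model.n_metabolites, model.n_reactions))
    met_idx = model.metabolite_index()
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            S[met_idx[met_id], j] = coeff
    return S
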