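"""Cross-EFM analyses: subsystem occurrence, backbone, pairwise overlap.

*Subsystem occurrence* profiles each mode by the share of its reactions
falling in each pathway subsystem — the matrix behind heatmap-style
comparisons of enriched modes.  The *backbone* of a mode collection is
the set of reactions present in more than a chosen fraction of modes;
tracking the per-reaction occurrence fraction reveals the conserved
core and the alternative routes between metabolites.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .efm_io import Efm, EfmSet
from .model import MetabolicModel

UNASSIGNED = "(unassigned)"


@dataclass
class SubsystemOccurrence:
    """Fraction of each EFM's reactions per subsystem.

    Rows are EFMs, columns subsystem labels; each row sums to 1 when
    every reaction carries at least one label (multi-label reactions
    count 1/m per label; unlabeled ones pool under ``(unassigned)``).
    """

    matrix: pd.DataFrame
    reaction_counts: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        return self.matrix


def subsystem_occurrence(model: MetabolicModel, efms: EfmSet) -> SubsystemOccurrence:
    if len(efms) == 0:
        raise ValueError("cannot profile an empty EFM set")
    rows: dict[int, dict[str, float]] = {}
    counts: dict[int, int] = {}
    for efm in efms:
        shares: dict[str, float] = {}
        for j in efm.reaction_indices:
            labels = model.reactions[j - 1].subsystems or [UNASSIGNED]
            w = 1.0 / len(labels)
            for label in labels:
                shares[label] = shares.get(label, 0.0) + w
        n = len(efm.reaction_indices)
        rows[efm.efm_id] = {label: v / n for label, v in shares.items()}
        counts[efm.efm_id] = n
    columns = sorted({label for row in rows.values() for label in row})
    matrix = pd.DataFrame(
        [[rows[eid].get(c, 0.0) for c in columns] for eid in rows],
        index=pd.Index(list(rows), name="efm_id"),
        columns=columns,
    )
    return SubsystemOccurrence(matrix=matrix, reaction_counts=counts)


@dataclass
class BackboneResult:
    """Per-reaction occurrence fractions and the cutoff-selected core."""

    tau: float
    inclusive: bool
    fractions: dict[int, float] = field(default_factory=dict)
    selected: frozenset[int] = frozenset()
    histogram: list[tuple[float, float, int]] = field(default_factory=list)

    def occurrence_pct(self, index: int) -> float:
        return 100.0 * self.fractions[index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "reaction_index": j,
                    "occurrence_fraction": f,
                    "occurrence_pct": 100.0 * f,
                    "in_backbone": j in self.selected,
                }
                for j, f in sorted(self.fractions.items())
            ]
        )


def extract_backbone(
    efms: EfmSet, tau: float, inclusive: bool = False, n_bins: int = 10
) -> BackboneResult:
    """Reactions present in more than a fraction ``tau`` of the EFMs.

    The cutoff is strict (``f_r > tau``) by default — a reaction must be
    present in *more than* tau of the modes; ``inclusive`` switches to
    ``>=``.  The histogram bins the occurrence fractions of all
    reactions appearing in at least one mode over (0, 1].
    """
    if len(efms) == 0:
        raise ValueError("cannot extract a backbone from an empty EFM set")
    if not 0 <= tau < 1:
        if inclusive and tau == 1.0:
            pass
        else:
            raise ValueError(
                "tau must be in [0, 1) for the strict cutoff "
                "(no reaction can strictly exceed 100% occurrence)"
            )
    counts: Counter[int] = Counter()
    for efm in efms:
        counts.update(efm.reaction_indices)
    m = len(efms)
    fractions = {j: c / m for j, c in counts.items()}
    if inclusive:
        selected = frozenset(j for j, f in fractions.items() if f >= tau)
    else:
        selected = frozenset(j for j, f in fractions.items() if f > tau)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    values = np.array(list(fractions.values()))
    histogram = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        # right-closed bins so f_r = 1 lands in the last bin
        in_bin = int(np.sum((values > lo) & (values <= hi)))
        histogram.append((float(lo), float(hi), in_bin))
    return BackboneResult(
        tau=tau,
        inclusive=inclusive,
        fractions=fractions,
        selected=selected,
        histogram=histogram,
    )


def efm_overlap(a: Efm, b: Efm) -> tuple[frozenset[int], frozenset[int], frozenset[int]]:
    """Pairwise comparison: (common, only in a, only in b)."""
    common = a.reaction_indices & b.reaction_indices
    return (
        frozenset(common),
        frozenset(a.reaction_indices - common),
        frozenset(b.reaction_indices - common),
    )
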