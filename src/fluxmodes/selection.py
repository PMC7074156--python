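"""EFM selection: presence filtering, yield analysis, omics mapping and
per-EFM over-representation analysis.

Two selection strategies are offered.  *Yield analysis* scores each mode
by the ratio of a product-release flux to a substrate-uptake flux (e.g.
mol acetate released per mol glucose consumed) and picks the modes at
the extremes.  *Enrichment* maps gene-level differential-expression
statistics onto reactions through GPR rules (AND = complex, take the
gene with minimum expression; OR = isozymes, take the maximum) and then
asks, per mode, whether it contains more significantly up- (or down-)
regulated reactions than expected by chance, via a one-sided
hypergeometric test with Benjamini-Hochberg correction across modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import pandas as pd
from scipy import stats as sps

from .efm_io import EfmSet, EfmValidationError
from .gpr import GprNode
from .model import MetabolicModel

Direction = Literal["up", "down"]
RankKey = Literal["expression", "abs_log2_fc"]


@dataclass
class GeneRecord:
    gene_id: str
    p_value: float
    log2_fc: float
    expression: float


@dataclass
class GeneStats:
    """Per-gene differential statistics, keyed by unique gene id."""

    records: dict[str, GeneRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, gene_id: str) -> Optional[GeneRecord]:
        return self.records.get(gene_id)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneStats":
        required = {"gene_id", "p_value", "log2_fc", "expression"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"gene statistics table lacks columns {sorted(missing)}")
        if df["gene_id"].duplicated().any():
            dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids in statistics table: {dupes}")
        if ((df["p_value"] < 0) | (df["p_value"] > 1)).any():
            raise ValueError("p_value outside [0, 1] in gene statistics table")
        records = {
            str(row.gene_id): GeneRecord(
                gene_id=str(row.gene_id),
                p_value=float(row.p_value),
                log2_fc=float(row.log2_fc),
                expression=float(row.expression),
            )
            for row in df.itertuples()
        }
        return cls(records=records)


def read_gene_stats(path: str) -> GeneStats:
    """Read a TSV/CSV table with columns gene_id, p_value, log2_fc, expression."""
    sep = "," if str(path).endswith(".csv") else "\t"
    return GeneStats.from_frame(pd.read_csv(path, sep=sep))


@dataclass
class ReactionRecord:
    reaction_index: int
    p_value: float
    log2_fc: float
    source_gene: str


@dataclass
class ReactionStats:
    """Per-reaction statistics derived from gene data via GPR rules.

    Only reactions whose GPR resolves to at least one gene with data are
    present (covered); all others are implicitly "no data".
    """

    records: dict[int, ReactionRecord] = field(default_factory=dict)

    def covered(self) -> frozenset[int]:
        return frozenset(self.records)

    def get(self, index: int) -> Optional[ReactionRecord]:
        return self.records.get(index)


def _rank_value(record: GeneRecord, key: RankKey) -> float:
    return record.expression if key == "expression" else abs(record.log2_fc)


def _evaluate_gpr(
    node: GprNode, stats: GeneStats, key: RankKey
) -> Optional[GeneRecord]:
    """Resolve a GPR tree to a single gene record, or None if no data.

    AND keeps the child with minimum ranking value, OR the maximum;
    children without data are ignored at both node kinds; ties keep the
    first child in rule order.
    """
    if node.kind == "GENE":
        return stats.get(node.gene_id)
    best: Optional[GeneRecord] = None
    for child in node.children:
        cand = _evaluate_gpr(child, stats, key)
        if cand is None:
            continue
        if best is None:
            best = cand
        elif node.kind == "AND" and _rank_value(cand, key) < _rank_value(best, key):
            best = cand
        elif node.kind == "OR" and _rank_value(cand, key) > _rank_value(best, key):
            best = cand
    return best


def map_gene_stats_to_reactions(
    model: MetabolicModel, stats: GeneStats, key: RankKey = "expression"
) -> ReactionStats:
    """Assign gene statistics to reactions through their GPR rules.

    ``key`` selects the quantity ranked by AND/OR resolution: the
    ``expression`` column (default) or ``abs_log2_fc`` for tables
    lacking a meaningful expression value.
    """
    out = ReactionStats()
    for j, rxn in enumerate(model.reactions, start=1):
        if rxn.gpr is None:
            continue
        record = _evaluate_gpr(rxn.gpr, stats, key)
        if record is None:
            continue
        out.records[j] = ReactionRecord(
            reaction_index=j,
            p_value=record.p_value,
            log2_fc=record.log2_fc,
            source_gene=record.gene_id,
        )
    return out


def filter_efms_by_reaction(
    efms: EfmSet, reaction_index: int, mode: Literal["contains", "excludes"] = "contains"
) -> EfmSet:
    """Keep EFMs that contain (or exclude) one reaction of interest.

    Original efm_ids and order are preserved, so selections remain
    addressable by their row number in the source file.
    """
    if not 1 <= reaction_index <= efms.n_reactions:
        raise EfmValidationError(
            f"reaction index {reaction_index} out of range 1..{efms.n_reactions}"
        )
    if mode not in ("contains", "excludes"):
        raise ValueError(f"unknown filter mode {mode!r}")
    keep = [
        efm
        for efm in efms
        if (reaction_index in efm.reaction_indices) == (mode == "contains")
    ]
    return EfmSet(efms=keep, model_ref=efms.model_ref, n_reactions=efms.n_reactions)


@dataclass
class YieldRecord:
    efm_id: int
    input_flux: float
    output_flux: float
    yield_value: float


@dataclass
class YieldResult:
    input_rxn: int
    output_rxn: int
    records: list[YieldRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "efm_id": r.efm_id,
                    "input_flux": r.input_flux,
                    "output_flux": r.output_flux,
                    "yield": r.yield_value,
                }
                for r in self.records
            ]
        )


def compute_yields(efms: EfmSet, input_rxn: int, output_rxn: int) -> YieldResult:
    """Yield of each EFM: |output flux| / |input flux|.

    Magnitudes are used because exchange-reaction sign conventions
    (forward/backward split vs. signed net flux) differ between
    enumeration tools; the ratio is what carries meaning.
    """
    missing = [
        efm.efm_id
        for efm in efms
        if input_rxn not in efm.reaction_indices
        or output_rxn not in efm.reaction_indices
    ]
    if missing:
        raise EfmValidationError(
            f"EFMs {missing} do not contain both reactions "
            f"{input_rxn} and {output_rxn}; filter first"
        )
    no_flux = [efm.efm_id for efm in efms if efm.relative_fluxes is None]
    if no_flux:
        raise EfmValidationError(f"EFMs {no_flux} have no relative fluxes")
    result = YieldResult(input_rxn=input_rxn, output_rxn=output_rxn)
    for efm in efms:
        v_in = abs(efm.relative_fluxes[input_rxn])
        v_out = abs(efm.relative_fluxes[output_rxn])
        if v_in == 0:
            raise EfmValidationError(
                f"EFM {efm.efm_id}: zero input flux on reaction {input_rxn}"
            )
        result.records.append(
            YieldRecord(
                efm_id=efm.efm_id,
                input_flux=v_in,
                output_flux=v_out,
                yield_value=v_out / v_in,
            )
        )
    return result


def select_extreme_yield(
    yields: YieldResult,
    which: Literal["min", "max"],
    efms: EfmSet,
    rel_tol: float = 1e-9,
) -> list[int]:
    """All efm_ids attaining the extreme yield, shortest EFM first.

    Ties at the extreme (within ``rel_tol`` relative tolerance) are all
    returned, ordered by ascending reaction count then efm_id, so the
    first element is "the shortest EFM" at that extreme.
    """
    if not yields.records:
        raise ValueError("no yield records to select from")
    if which not in ("min", "max"):
        raise ValueError(f"which must be 'min' or 'max', got {which!r}")
    values = {r.efm_id: r.yield_value for r in yields.records}
    extreme = min(values.values()) if which == "min" else max(values.values())
    tol = rel_tol * max(abs(extreme), 1.0)
    hits = [eid for eid, v in values.items() if abs(v - extreme) <= tol]
    lengths = {efm.efm_id: len(efm) for efm in efms}
    hits.sort(key=lambda eid: (lengths.get(eid, 0), eid))
    return hits


@dataclass
class EfmEnrichment:
    efm_id: int
    direction: Direction
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_adjusted: float


@dataclass
class EnrichmentResult:
    direction: Direction
    sig_p: float
    records: list[EfmEnrichment] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "efm_id": r.efm_id,
                    "direction": r.direction,
                    "k": r.k,
                    "n": r.n,
                    "K": r.K,
                    "N": r.N,
                    "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                }
                for r in self.records
            ]
        )

    def significant(self, alpha: float = 0.05) -> list[int]:
        return [r.efm_id for r in self.records if r.p_adjusted < alpha]


def _significant_set(
    rstats: ReactionStats, direction: Direction, sig_p: float
) -> frozenset[int]:
    if direction == "up":
        return frozenset(
            i
            for i, r in rstats.records.items()
            if r.p_value < sig_p and r.log2_fc > 0
        )
    return frozenset(
        i for i, r in rstats.records.items() if r.p_value < sig_p and r.log2_fc < 0
    )


def enrich_efms(
    efms: EfmSet,
    rstats: ReactionStats,
    direction: Direction,
    sig_p: float = 0.05,
    background: Optional[frozenset[int]] = None,
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation test per EFM.

    A reaction is significant-``up`` when it has mapped data, raw
    p < ``sig_p`` and log2FC > 0 (``down``: < 0).  With N mapped
    reactions in the background, K of them significant, and an EFM
    containing n mapped reactions of which k are significant,
    p_raw = P(X >= k) for X hypergeometric(N, K, n); EFMs with n = 0 get
    p_raw = 1.  p_adjusted is Benjamini-Hochberg across all tested EFMs.
    """
    if len(efms) == 0:
        raise ValueError("cannot run enrichment on an empty EFM set")
    if not 0 < sig_p < 1:
        raise ValueError("sig_p must be in (0, 1)")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    mapped = rstats.covered()
    bg = mapped if background is None else frozenset(background) & mapped
    significant = _significant_set(rstats, direction, sig_p) & bg
    N, K = len(bg), len(significant)
    if K == 0:
        warnings.warn(
            f"no significant {direction}-regulated reactions in background; "
            "all enrichment p-values are 1",
            stacklevel=2,
        )
    result = EnrichmentResult(direction=direction, sig_p=sig_p)
    p_raws = []
    for efm in efms:
        inside = efm.reaction_indices & bg
        n, k = len(inside), len(inside & significant)
        if n == 0 or K == 0:
            p = 1.0
        else:
            p = float(sps.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        p_raws.append(p)
        result.records.append(
            EfmEnrichment(
                efm_id=efm.efm_id,
                direction=direction,
                k=k,
                n=n,
                K=K,
                N=N,
                p_raw=p,
                p_adjusted=p,
            )
        )
    adjusted = sps.false_discovery_control(p_raws, method="bh")
    for record, adj in zip(result.records, adjusted):
        record.p_adjusted = float(min(adj, 1.0))
    return result


def label_efm_directions(
    efms: EfmSet,
    rstats: ReactionStats,
    sig_p: float = 0.05,
    background: Optional[frozenset[int]] = None,
) -> dict[int, EfmEnrichment]:
    """Run both directions and label each EFM with the smaller-p one.

    Ties go to "up" (tested first).
    """
    both = {
        d: enrich_efms(efms, rstats, d, sig_p=sig_p, background=background)
        for d in ("up", "down")
    }
    labels: dict[int, EfmEnrichment] = {}
    for up_rec, down_rec in zip(both["up"].records, both["down"].records):
        labels[up_rec.efm_id] = (
            up_rec if up_rec.p_adjusted <= down_rec.p_adjusted else down_rec
        )
    return labels
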