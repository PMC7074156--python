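"""Deterministic synthetic data for every pipeline stage.

Real flux-mode studies need a genome-scale model, an enumeration run
and an omics dataset; none of that is required to exercise this
package.  The generator builds a small but complete overflow-metabolism
network — glucose uptake feeding lumped glycolysis, three alternative
pyruvate-dissipating routes (a dehydrogenase/acetyl-phosphate route, a
decarboxylase/aldehyde route and a formate-lyase route) and exchange
reactions for every released product — together with four hand-designed
flux modes that balance every internal metabolite exactly, a
planted differential-expression table, and a ground-truth record of the
yields, occurrence fractions and enrichment contingency counts those
inputs must reproduce.

The planted effects are route-specific: the dehydrogenase-route genes
are upregulated (so exactly one mode is the most enriched for
upregulation) and the decarboxylase-route genes downregulated.  Only
gene-level summary statistics are emulated, not the sampling noise of
real RNA-seq; one transporter gene is deliberately absent from the
table to exercise missing-data handling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .efm_io import Efm, EfmSet, write_efm_file, write_flux_file
from .gpr import parse_gpr_string
from .model import MetabolicModel, Metabolite, Reaction, stoichiometric_matrix
from .sbml import write_sbml
from .selection import GeneStats


def toy_model() -> MetabolicModel:
    """Minimal 7-reaction / 6-metabolite / 4-gene chain for I/O tests."""
    model = MetabolicModel(id="toynet", compartments={"e": "extracellular", "c": "cytosol"})
    model.metabolites = [
        Metabolite("glc_e", "D-Glucose", "e"),
        Metabolite("glc_c", "D-Glucose", "c"),
        Metabolite("pyr_c", "Pyruvate", "c"),
        Metabolite("ac_c", "Acetate", "c"),
        Metabolite("ac_e", "Acetate", "e"),
        Metabolite("co2_c", "CO2", "c"),
    ]
    model.genes = ["gT1", "gGLYA", "gGLYB", "gPOX"]
    specs = [
        ("EX_glc", {"glc_e": 1.0}, None, "Exchange"),
        ("GLCt", {"glc_e": -1.0, "glc_c": 1.0}, "gT1", "Transport"),
        ("GLY", {"glc_c": -1.0, "pyr_c": 2.0}, "gGLYA and gGLYB", "Glycolysis"),
        ("POX", {"pyr_c": -1.0, "ac_c": 1.0, "co2_c": 1.0}, "gPOX", "Pyruvate Metabolism"),
        ("ACt", {"ac_c": -1.0, "ac_e": 1.0}, None, "Transport"),
        ("EX_ac", {"ac_e": -1.0}, None, "Exchange"),
        ("EX_co2", {"co2_c": -1.0}, None, "Exchange"),
    ]
    for rid, stoich, rule, subsystem in specs:
        model.reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                gpr=parse_gpr_string(rule) if rule else None,
                subsystem=subsystem,
            )
        )
    model.validate()
    return model


@dataclass
class FixtureParams:
    """Knobs of the planted-effect structure.

    ``planted_p`` / ``effect_size`` set the significance and log2FC of
    route-specific genes; null genes draw p from ``null_p_range`` and
    log2FC from +-``null_lfc_scale``.  Fluxes of each mode are scaled by
    a dyadic factor in ``flux_scale_range`` so ratios stay exact.
    """

    planted_p: float = 0.001
    effect_size: float = 2.0
    null_p_range: tuple[float, float] = (0.2, 0.95)
    null_lfc_scale: float = 0.1
    expression_range: tuple[float, float] = (5.0, 100.0)
    flux_scale_range: tuple[float, float] = (0.5, 2.0)
    sig_p: float = 0.05

    def validate(self) -> None:
        if not 0 < self.planted_p < self.sig_p:
            raise ValueError("planted_p must lie below the significance cutoff")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        lo, hi = self.null_p_range
        if not self.sig_p <= lo < hi <= 1:
            raise ValueError("null_p_range must lie within [sig_p, 1]")
        lo, hi = self.flux_scale_range
        if not 0 < lo <= hi:
            raise ValueError("flux_scale_range must be positive")
        lo, hi = self.expression_range
        if not 0 <= lo < hi:
            raise ValueError("expression_range must be nondecreasing and nonnegative")


# reaction table of the overflow network: id, stoichiometry, GPR, subsystem
_REACTIONS = [
    ("EX_glc", {"glc_e": 1.0}, None, "Exchange"),
    ("GLCt", {"glc_e": -1.0, "glc_c": 1.0}, "gT1 or gT2", "Transport"),
    ("HEX1", {"glc_c": -1.0, "atp_c": -1.0, "g6p_c": 1.0, "adp_c": 1.0}, "gHEX", "Glycolysis"),
    ("PYK", {"g6p_c": -1.0, "adp_c": -2.0, "pyr_c": 2.0, "atp_c": 2.0}, "gGLYA and gGLYB", "Glycolysis"),
    ("PDH", {"pyr_c": -1.0, "accoa_c": 1.0, "co2_c": 1.0}, "gPDH1 and gPDH2", "Pyruvate Metabolism"),
    ("PFL", {"pyr_c": -1.0, "accoa_c": 1.0, "for_c": 1.0}, "gPFL", "Pyruvate Metabolism"),
    ("PDC", {"pyr_c": -1.0, "acald_c": 1.0, "co2_c": 1.0}, "gPDC", "Pyruvate Metabolism"),
    ("PTAr", {"accoa_c": -1.0, "actp_c": 1.0}, "gPTA", "Acetate Metabolism"),
    ("ACKr", {"actp_c": -1.0, "ac_c": 1.0}, "gACK", "Acetate Metabolism"),
    ("ALDD", {"acald_c": -1.0, "ac_c": 1.0}, "gALDD", "Acetate Metabolism"),
    ("ACt", {"ac_c": -1.0, "ac_e": 1.0}, "gT3", "Transport"),
    ("EX_ac", {"ac_e": -1.0}, None, "Exchange"),
    ("FORt", {"for_c": -1.0, "for_e": 1.0}, "gT4", "Transport"),
    ("EX_for", {"for_e": -1.0}, None, "Exchange"),
    ("PYRt", {"pyr_c": -1.0, "pyr_e": 1.0}, "gT5", "Transport"),
    ("EX_pyr", {"pyr_e": -1.0}, None, "Exchange"),
    ("CO2t", {"co2_c": -1.0, "co2_e": 1.0}, None, "Transport"),
    ("EX_co2", {"co2_e": -1.0}, None, "Exchange"),
    ("ATPM", {"atp_c": -1.0, "adp_c": 1.0}, "gATPM", "Energy Maintenance"),
]

_METABOLITES = [
    ("glc_e", "D-Glucose", "e"), ("glc_c", "D-Glucose", "c"),
    ("g6p_c", "Glucose 6-phosphate", "c"), ("pyr_c", "Pyruvate", "c"),
    ("pyr_e", "Pyruvate", "e"), ("accoa_c", "Acetyl-CoA", "c"),
    ("actp_c", "Acetyl phosphate", "c"), ("acald_c", "Acetaldehyde", "c"),
    ("ac_c", "Acetate", "c"), ("ac_e", "Acetate", "e"),
    ("for_c", "Formate", "c"), ("for_e", "Formate", "e"),
    ("co2_c", "CO2", "c"), ("co2_e", "CO2", "e"),
    ("atp_c", "ATP", "c"), ("adp_c", "ADP", "c"),
]

_GENES = [
    "gT1", "gT2", "gHEX", "gGLYA", "gGLYB", "gPDH1", "gPDH2", "gPFL",
    "gPDC", "gPTA", "gACK", "gALDD", "gT3", "gT4", "gT5", "gATPM",
]

_UP_GENES = ("gPDH1", "gPDH2", "gPTA", "gACK")      # dehydrogenase route
_DOWN_GENES = ("gPDC", "gALDD")                     # decarboxylase route
_MISSING_GENES = ("gT5",)                           # absent from the table

# planted flux modes: reaction index (1-based) -> base flux, glucose basis 1
_EFM_FLUXES: list[dict[int, float]] = [
    # dehydrogenase / acetyl-phosphate route: 2 acetate per glucose
    {1: 1, 2: 1, 3: 1, 4: 1, 5: 2, 8: 2, 9: 2, 11: 2, 12: 2, 17: 2, 18: 2, 19: 1},
    # decarboxylase / aldehyde route with pyruvate overflow: 1 acetate per glucose
    {1: 1, 2: 1, 3: 1, 4: 1, 7: 1, 10: 1, 11: 1, 12: 1, 15: 1, 16: 1, 17: 1, 18: 1, 19: 1},
    # formate-lyase route: 2 acetate per glucose, formate co-released
    {1: 1, 2: 1, 3: 1, 4: 1, 6: 2, 8: 2, 9: 2, 11: 2, 12: 2, 13: 2, 14: 2, 19: 1},
    # pure pyruvate overflow: no acetate release
    {1: 1, 2: 1, 3: 1, 4: 1, 15: 2, 16: 2, 19: 1},
]

GLUCOSE_UPTAKE = 1   # EX_glc
ACETATE_RELEASE = 12  # EX_ac


def build_model() -> MetabolicModel:
    """The fixed 19-reaction overflow-metabolism network."""
    model = MetabolicModel(
        id="synthnet", compartments={"e": "extracellular", "c": "cytosol"}
    )
    model.metabolites = [Metabolite(i, n, c) for i, n, c in _METABOLITES]
    model.genes = list(_GENES)
    for rid, stoich, rule, subsystem in _REACTIONS:
        model.reactions.append(
            Reaction(
                id=rid,
                stoichiometry=dict(stoich),
                gpr=parse_gpr_string(rule) if rule else None,
                subsystem=subsystem,
            )
        )
    model.validate()
    return model


@dataclass
class FixtureBundle:
    """A complete synthetic study: model, modes, omics and ground truth."""

    model: MetabolicModel
    efms: EfmSet
    gene_stats: GeneStats
    gene_table: "list[dict]"
    ground_truth: dict
    params: FixtureParams
    seed: int


def _ground_truth(params: FixtureParams) -> dict:
    """Planted expectations, derived by direct counting over the tables
    above (independent of the analysis modules)."""
    gpr_genes = {
        j: set(parse_gpr_string(rule).genes())
        for j, (_, _, rule, _) in enumerate(_REACTIONS, start=1)
        if rule
    }
    with_data = {
        j for j, genes in gpr_genes.items() if genes - set(_MISSING_GENES)
    }
    up = {j for j in with_data if gpr_genes[j] & set(_UP_GENES)}
    down = {j for j in with_data if gpr_genes[j] & set(_DOWN_GENES)}
    n_efms = len(_EFM_FLUXES)
    ac_ids = [
        i + 1 for i, fluxes in enumerate(_EFM_FLUXES) if ACETATE_RELEASE in fluxes
    ]
    yields = {
        i + 1: fluxes[ACETATE_RELEASE] / fluxes[GLUCOSE_UPTAKE]
        for i, fluxes in enumerate(_EFM_FLUXES)
        if ACETATE_RELEASE in fluxes
    }
    best = max(yields.values())
    worst = min(yields.values())
    occurrence = {}
    for j in range(1, len(_REACTIONS) + 1):
        c = sum(1 for fluxes in _EFM_FLUXES if j in fluxes)
        if c:
            occurrence[j] = c / n_efms
    contingency = {}
    for direction, sig in (("up", up), ("down", down)):
        per_efm = {}
        for eid in ac_ids:
            active = set(_EFM_FLUXES[eid - 1])
            inside = active & with_data
            per_efm[str(eid)] = {"n": len(inside), "k": len(inside & sig)}
        contingency[direction] = {
            "N": len(with_data),
            "K": len(sig),
            "per_efm": per_efm,
        }
    subsystem_rows = {}
    for eid in range(1, n_efms + 1):
        active = sorted(_EFM_FLUXES[eid - 1])
        tally: dict[str, int] = {}
        for j in active:
            label = _REACTIONS[j - 1][3]
            tally[label] = tally.get(label, 0) + 1
        subsystem_rows[eid] = {
            label: c / len(active) for label, c in sorted(tally.items())
        }
    return {
        "model": {
            "n_reactions": len(_REACTIONS),
            "n_metabolites": len(_METABOLITES),
            "n_genes": len(_GENES),
        },
        "n_efms": n_efms,
        "acetate_release_index": ACETATE_RELEASE,
        "glucose_uptake_index": GLUCOSE_UPTAKE,
        "acetate_efm_ids": ac_ids,
        "yields": {str(k): v for k, v in yields.items()},
        "max_yield": best,
        "min_yield": worst,
        "max_yield_efm_ids": sorted(
            (eid for eid, y in yields.items() if y == best),
            key=lambda e: (len(_EFM_FLUXES[e - 1]), e),
        ),
        "min_yield_efm_ids": sorted(
            (eid for eid, y in yields.items() if y == worst),
            key=lambda e: (len(_EFM_FLUXES[e - 1]), e),
        ),
        "backbone_fractions": {str(j): f for j, f in sorted(occurrence.items())},
        "enrichment": contingency,
        "most_enriched_up_efm": 1,
        "most_enriched_down_efm": 2,
        "subsystem_occurrence": {
            str(eid): row for eid, row in subsystem_rows.items()
        },
        "sig_p": params.sig_p,
    }


def generate_fixture(
    params: Optional[FixtureParams] = None, seed: int = 0
) -> FixtureBundle:
    """Deterministic bundle for a given (params, seed).

    The seed varies flux magnitudes (per-mode dyadic scale factors) and
    the null-gene statistics; the network topology, the planted modes
    and the planted effect directions are fixed by ``params``.
    """
    params = params or FixtureParams()
    params.validate()
    rng = np.random.default_rng(seed)
    model = build_model()

    efms = []
    lo, hi = params.flux_scale_range
    # dyadic grid inside [lo, hi]: exact in binary floating point
    grid = np.arange(np.ceil(lo * 8), np.floor(hi * 8) + 1) / 8.0
    for i, base in enumerate(_EFM_FLUXES):
        scale = float(rng.choice(grid))
        fluxes = {j: v * scale for j, v in base.items()}
        efms.append(
            Efm(
                efm_id=i + 1,
                reaction_indices=frozenset(base),
                relative_fluxes=fluxes,
            )
        )
    efm_set = EfmSet(efms=efms, model_ref=model.id, n_reactions=model.n_reactions)

    rows = []
    for gene in _GENES:
        if gene in _MISSING_GENES:
            continue
        expression = round(float(rng.uniform(*params.expression_range)), 4)
        if gene in _UP_GENES:
            p, lfc = params.planted_p, params.effect_size
        elif gene in _DOWN_GENES:
            p, lfc = params.planted_p, -params.effect_size
        else:
            p = round(float(rng.uniform(*params.null_p_range)), 6)
            lfc = round(float(rng.uniform(-1, 1)) * params.null_lfc_scale, 6)
        rows.append(
            {
                "gene_id": gene,
                "p_value": p,
                "log2_fc": lfc,
                "expression": expression,
            }
        )
    gene_stats = GeneStats.from_frame(pd.DataFrame(rows))

    return FixtureBundle(
        model=model,
        efms=efm_set,
        gene_stats=gene_stats,
        gene_table=rows,
        ground_truth=_ground_truth(params),
        params=params,
        seed=seed,
    )


def write_bundle(bundle: FixtureBundle, outdir: str) -> dict[str, str]:
    """Serialize the bundle; returns a name -> path mapping.

    Outputs: SBML model, EFM file, flux file, gene-statistics TSV and
    the ground-truth JSON.  Byte-identical for identical (params, seed).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "model": str(out / "model.xml"),
        "efms": str(out / "efms.txt"),
        "fluxes": str(out / "fluxes.txt"),
        "gene_stats": str(out / "gene_stats.tsv"),
        "ground_truth": str(out / "ground_truth.json"),
    }
    write_sbml(bundle.model, paths["model"])
    write_efm_file(bundle.efms, paths["efms"])
    write_flux_file(bundle.efms, paths["fluxes"])
    with open(paths["gene_stats"], "w") as fh:
        fh.write("gene_id\tp_value\tlog2_fc\texpression\n")
        for row in bundle.gene_table:
            fh.write(
                f"{row['gene_id']}\t{row['p_value']!r}\t{row['log2_fc']!r}\t"
                f"{row['expression']!r}\n"
            )
    payload = dict(bundle.ground_truth)
    payload["seed"] = bundle.seed
    payload["params"] = asdict(bundle.params)
    with open(paths["ground_truth"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def validate_efm_steady_state(
    model: MetabolicModel, efm: Efm, tol: float = 1e-9
) -> tuple[bool, float]:
    """Check |S v| <= tol on every non-boundary metabolite.

    The full-length flux vector is zero outside the mode.  Returns
    (valid, max residual).
    """
    if efm.relative_fluxes is None:
        raise ValueError(f"EFM {efm.efm_id} has no relative fluxes")
    v = np.zeros(model.n_reactions)
    for j, flux in efm.relative_fluxes.items():
        v[j - 1] = flux
    S = stoichiometric_matrix(model)
    residuals = np.abs(S @ v)
    internal = np.array([not m.is_boundary for m in model.metabolites])
    max_residual = float(residuals[internal].max()) if internal.any() else 0.0
    return max_residual <= tol, max_residual


def random_efms(
    model: MetabolicModel, n: int, seed: int = 0, min_size: int = 2
) -> EfmSet:
    """Random reaction-subset modes (no steady-state guarantee).

    Useful for structural property tests (extraction, backbone,
    overlap) that do not interpret fluxes.
    """
    rng = np.random.default_rng(seed)
    efms = []
    for i in range(n):
        size = int(rng.integers(min_size, model.n_reactions + 1))
        indices = rng.choice(model.n_reactions, size=size, replace=False) + 1
        efms.append(Efm(efm_id=i + 1, reaction_indices=frozenset(int(j) for j in indices)))
    return EfmSet(efms=efms, model_ref=model.id, n_reactions=model.n_reactions)
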