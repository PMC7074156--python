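"""Yield analysis, GPR-based omics mapping and per-EFM enrichment."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxmodes import (
    Efm,
    EfmSet,
    EfmValidationError,
    GeneStats,
    GprNode,
    MetabolicModel,
    Metabolite,
    Reaction,
    compute_yields,
    enrich_efms,
    filter_efms_by_reaction,
    label_efm_directions,
    map_gene_stats_to_reactions,
    select_extreme_yield,
)
from fluxmodes.selection import GeneRecord, _evaluate_gpr


def _efm_set(rows, n_reactions=10, fluxes=None):
    efms = [
        Efm(
            efm_id=i + 1,
            reaction_indices=frozenset(r),
            relative_fluxes=None if fluxes is None else fluxes[i],
        )
        for i, r in enumerate(rows)
    ]
    return EfmSet(efms=efms, n_reactions=n_reactions)


class TestFilter:
    def test_contains_keeps_matching_with_original_ids(self):
        efms = _efm_set([{1, 2}, {2, 3}, {1, 3}])
        kept = filter_efms_by_reaction(efms, 2, "contains")
        assert [e.efm_id for e in kept] == [1, 2]

    def test_excludes_is_complement(self):
        efms = _efm_set([{1, 2}, {2, 3}, {1, 3}])
        out = filter_efms_by_reaction(efms, 2, "excludes")
        assert [e.efm_id for e in out] == [3]

    def test_absent_reaction_gives_empty_set(self):
        assert len(filter_efms_by_reaction(_efm_set([{1, 2}]), 5)) == 0

    def test_ubiquitous_reaction_is_identity(self):
        efms = _efm_set([{1, 2}, {1, 3}])
        assert len(filter_efms_by_reaction(efms, 1)) == len(efms)

    def test_invalid_index_raises(self):
        with pytest.raises(EfmValidationError):
            filter_efms_by_reaction(_efm_set([{1}]), 99)


class TestYields:
    def test_reported_flux_extremes(self):
        """Substrate uptake 3.43 against release 10 gives the ~2.9
        maximum; uptake 20 against release 10 gives exactly 0.5."""
        efms = _efm_set(
            [{1, 2}, {1, 2}],
            fluxes=[{1: 3.43, 2: 10.0}, {1: 20.0, 2: 10.0}],
        )
        result = compute_yields(efms, input_rxn=1, output_rxn=2)
        high, low = result.records
        assert round(high.yield_value, 1) == 2.9
        assert low.yield_value == 0.5

    def test_same_input_output_reaction_yields_one(self):
        efms = _efm_set([{1, 2}], fluxes=[{1: 3.0, 2: 7.0}])
        result = compute_yields(efms, 2, 2)
        assert result.records[0].yield_value == 1.0

    def test_sign_conventions_ignored(self):
        efms = _efm_set([{1, 2}], fluxes=[{1: -4.0, 2: 2.0}])
        assert compute_yields(efms, 1, 2).records[0].yield_value == 0.5

    def test_missing_reaction_lists_offenders(self):
        efms = _efm_set([{1, 2}, {1, 3}])
        with pytest.raises(EfmValidationError, match=r"\[2\]"):
            compute_yields(efms, 1, 2)

    def test_missing_fluxes_rejected(self):
        with pytest.raises(EfmValidationError, match="no relative fluxes"):
            compute_yields(_efm_set([{1, 2}]), 1, 2)

    def test_zero_input_flux_rejected(self):
        efms = _efm_set([{1, 2}], fluxes=[{1: 1.0, 2: 1.0}])
        efms.efms[0].relative_fluxes[1] = 0.0
        with pytest.raises(EfmValidationError, match="zero input flux"):
            compute_yields(efms, 1, 2)

    @given(st.floats(min_value=1e-6, max_value=1e6), st.data())
    @settings(deadline=None, max_examples=50)
    def test_scale_invariance(self, scale, data):
        v_in = data.draw(st.floats(min_value=0.1, max_value=100.0))
        v_out = data.draw(st.floats(min_value=0.1, max_value=100.0))
        base = _efm_set([{1, 2}], fluxes=[{1: v_in, 2: v_out}])
        scaled = _efm_set([{1, 2}], fluxes=[{1: v_in * scale, 2: v_out * scale}])
        y0 = compute_yields(base, 1, 2).records[0].yield_value
        y1 = compute_yields(scaled, 1, 2).records[0].yield_value
        assert y1 == pytest.approx(y0, rel=1e-9)


class TestExtremeSelection:
    def test_ties_ordered_by_length_then_id(self):
        efms = _efm_set(
            [set(range(1, 36)), set(range(1, 41)), {1, 2}],
            n_reactions=50,
            fluxes=[
                {i: 1.0 for i in range(1, 36)},
                {i: 1.0 for i in range(1, 41)},
                {1: 1.0, 2: 1.0},
            ],
        )
        # plant yields 0.5, 0.5, 2.9 via explicit flux choice on rxn 1/2
        efms.efms[0].relative_fluxes.update({1: 2.0, 2: 1.0})
        efms.efms[1].relative_fluxes.update({1: 2.0, 2: 1.0})
        efms.efms[2].relative_fluxes.update({1: 1.0, 2: 2.9})
        yields = compute_yields(efms, 1, 2)
        assert select_extreme_yield(yields, "min", efms) == [1, 2]
        assert select_extreme_yield(yields, "max", efms) == [3]

    def test_single_efm_is_both_extremes(self):
        efms = _efm_set([{1, 2}], fluxes=[{1: 1.0, 2: 3.0}])
        yields = compute_yields(efms, 1, 2)
        assert select_extreme_yield(yields, "min", efms) == [1]
        assert select_extreme_yield(yields, "max", efms) == [1]

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        rows = [
            set(rng.choice(20, size=rng.integers(2, 10), replace=False) + 1) | {1, 2}
            for _ in range(15)
        ]
        fluxes = [
            {i: float(rng.uniform(0.5, 5.0)) for i in row} for row in rows
        ]
        efms = _efm_set(rows, n_reactions=20, fluxes=fluxes)
        yields = compute_yields(efms, 1, 2)
        values = {r.efm_id: r.yield_value for r in yields.records}
        lengths = {e.efm_id: len(e) for e in efms}
        for which, fn in (("min", min), ("max", max)):
            extreme = fn(values.values())
            expected = sorted(
                (eid for eid, v in values.items() if abs(v - extreme) <= 1e-9 * max(1, abs(extreme))),
                key=lambda eid: (lengths[eid], eid),
            )
            assert select_extreme_yield(yields, which, efms) == expected


def _stats(**expr):
    """GeneStats with per-gene expression and distinguishable p/fc."""
    return GeneStats(
        records={
            g: GeneRecord(
                gene_id=g, p_value=round(0.001 * (i + 1), 6),
                log2_fc=float(i + 1), expression=float(e),
            )
            for i, (g, e) in enumerate(expr.items())
        }
    )


def _single_reaction_model(rule, genes):
    return MetabolicModel(
        id="m",
        compartments={"c": "c"},
        metabolites=[Metabolite("A", compartment="c")],
        genes=list(genes),
        reactions=[
            Reaction(
                id="R",
                stoichiometry={"A": 1.0},
                gpr=GprNode("GENE", gene_id=rule) if isinstance(rule, str) else rule,
            )
        ],
    )


def _oracle_resolve(node, stats, key="expression"):
    """Bottom-up brute-force: resolve each subtree to its chosen gene by
    explicit candidate enumeration with sorted() selection."""
    if node.kind == "GENE":
        return stats.get(node.gene_id)
    candidates = [
        r for r in (_oracle_resolve(c, stats, key) for c in node.children)
        if r is not None
    ]
    if not candidates:
        return None
    keyed = [
        (r.expression if key == "expression" else abs(r.log2_fc), i, r)
        for i, r in enumerate(candidates)
    ]
    keyed.sort()
    return keyed[0][2] if node.kind == "AND" else keyed[-1][2]


def _random_tree(rng, genes, depth):
    if depth == 0 or rng.random() < 0.3:
        return GprNode("GENE", gene_id=str(rng.choice(genes)))
    kind = "AND" if rng.random() < 0.5 else "OR"
    n = int(rng.integers(2, 4))
    return GprNode(kind, children=[_random_tree(rng, genes, depth - 1) for _ in range(n)])


class TestGprMapping:
    def test_and_takes_minimum_expression(self):
        from fluxmodes import parse_gpr_string

        model = _single_reaction_model(parse_gpr_string("A and B"), ["A", "B"])
        stats = _stats(A=5, B=8)
        rs = map_gene_stats_to_reactions(model, stats)
        assert rs.records[1].source_gene == "A"
        assert rs.records[1].p_value == stats.get("A").p_value
        assert rs.records[1].log2_fc == stats.get("A").log2_fc

    def test_or_takes_maximum_expression(self):
        from fluxmodes import parse_gpr_string

        model = _single_reaction_model(parse_gpr_string("A or B"), ["A", "B"])
        rs = map_gene_stats_to_reactions(model, _stats(A=5, B=8))
        assert rs.records[1].source_gene == "B"

    def test_missing_children_ignored(self):
        from fluxmodes import parse_gpr_string

        model = _single_reaction_model(parse_gpr_string("A and B"), ["A", "B"])
        rs = map_gene_stats_to_reactions(model, _stats(B=8))
        assert rs.records[1].source_gene == "B"

    def test_all_missing_flags_no_data(self):
        model = _single_reaction_model(GprNode("GENE", gene_id="A"), ["A"])
        rs = map_gene_stats_to_reactions(model, _stats(B=8))
        assert 1 not in rs.records
        assert rs.covered() == frozenset()

    def test_abs_log2fc_rank_key(self):
        from fluxmodes import parse_gpr_string

        model = _single_reaction_model(parse_gpr_string("A or B"), ["A", "B"])
        stats = GeneStats(
            records={
                "A": GeneRecord("A", 0.1, -3.0, 1.0),
                "B": GeneRecord("B", 0.2, 2.0, 9.0),
            }
        )
        rs = map_gene_stats_to_reactions(model, stats, key="abs_log2_fc")
        assert rs.records[1].source_gene == "A"

    def test_flattening_oracle_on_pure_trees(self):
        """AND-only trees pick the argmin of expression over the flat
        gene set, OR-only the argmax, regardless of nesting."""
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(6)]
        stats = _stats(**{g: rng.uniform(1, 100) for g in genes})
        for kind, pick in (("AND", min), ("OR", max)):
            nested = GprNode(
                kind,
                children=[
                    GprNode(kind, children=[
                        GprNode("GENE", gene_id=genes[0]),
                        GprNode("GENE", gene_id=genes[1]),
                    ]),
                    GprNode("GENE", gene_id=genes[2]),
                    GprNode(kind, children=[
                        GprNode("GENE", gene_id=genes[3]),
                        GprNode("GENE", gene_id=genes[4]),
                        GprNode("GENE", gene_id=genes[5]),
                    ]),
                ],
            )
            expected = pick(genes, key=lambda g: stats.get(g).expression)
            assert _evaluate_gpr(nested, stats, "expression").gene_id == expected

    def test_random_trees_match_bruteforce(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(8)]
        # leave two genes without data to exercise missing handling
        stats = _stats(**{g: rng.uniform(1, 100) for g in genes[:6]})
        for _ in range(300):
            tree = _random_tree(rng, genes, depth=4)
            ours = _evaluate_gpr(tree, stats, "expression")
            oracle = _oracle_resolve(tree, stats)
            assert (ours is None) == (oracle is None)
            if ours is not None:
                assert ours.expression == oracle.expression


def hypergeom_tail_oracle(k, N, K, n):
    """Exact P(X >= k) by combinatorial counting with rational arithmetic."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(n, K) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return acc


def enumeration_tail_oracle(k, N, K, n):
    """Literal enumeration of all n-subsets of an N-set with K marked."""
    marked = set(range(K))
    hits = sum(
        1
        for subset in itertools.combinations(range(N), n)
        if len(marked.intersection(subset)) >= k
    )
    return Fraction(hits, math.comb(N, n))


class TestEnrichment:
    def _setup(self, n_reactions, sig, covered, rows):
        rstats_model = MetabolicModel(id="m")
        stats = {}
        for j in covered:
            stats[j] = GeneRecord(
                gene_id=f"g{j}",
                p_value=0.01 if j in sig else 0.5,
                log2_fc=1.0 if j in sig else 0.05,
                expression=1.0,
            )
        from fluxmodes.selection import ReactionRecord, ReactionStats

        rstats = ReactionStats(
            records={
                j: ReactionRecord(j, r.p_value, r.log2_fc, r.gene_id)
                for j, r in stats.items()
            }
        )
        return _efm_set(rows, n_reactions=n_reactions), rstats

    def test_frozen_contingency_example(self):
        """N=20 mapped, K=5 significant, EFM with n=4 mapped of which
        k=3 significant: tail probability 155/4845."""
        covered = set(range(1, 21))
        sig = {1, 2, 3, 4, 5}
        rows = [{1, 2, 3, 6}]
        efms, rstats = self._setup(25, sig, covered, rows)
        result = enrich_efms(efms, rstats, "up")
        expected = hypergeom_tail_oracle(3, 20, 5, 4)
        assert expected == Fraction(155, 4845)
        assert expected == enumeration_tail_oracle(3, 20, 5, 4)
        assert result.records[0].p_raw == pytest.approx(float(expected), abs=1e-12)

    def test_no_mapped_reactions_gives_p_one(self):
        efms, rstats = self._setup(25, {1}, {1, 2}, [{10, 11}])
        assert enrich_efms(efms, rstats, "up").records[0].p_raw == 1.0

    def test_k_zero_gives_p_one(self):
        efms, rstats = self._setup(25, {1}, {1, 2, 3}, [{2, 3}])
        assert enrich_efms(efms, rstats, "up").records[0].p_raw == 1.0

    def test_empty_background_warns_and_returns_ones(self):
        efms, rstats = self._setup(25, set(), {1, 2, 3}, [{1, 2}])
        with pytest.warns(UserWarning, match="no significant"):
            result = enrich_efms(efms, rstats, "up")
        assert all(r.p_raw == 1.0 for r in result.records)

    def test_empty_efmset_rejected(self):
        _, rstats = self._setup(25, {1}, {1, 2}, [{1}])
        with pytest.raises(ValueError, match="empty"):
            enrich_efms(EfmSet(efms=[], n_reactions=25), rstats, "up")

    def test_down_direction_uses_negative_fold_change(self):
        from fluxmodes.selection import ReactionRecord, ReactionStats

        rstats = ReactionStats(
            records={
                1: ReactionRecord(1, 0.01, -2.0, "g1"),
                2: ReactionRecord(2, 0.01, 2.0, "g2"),
                3: ReactionRecord(3, 0.5, -0.1, "g3"),
            }
        )
        efms = _efm_set([{1, 3}])
        down = enrich_efms(efms, rstats, "down")
        assert down.records[0].k == 1

    def test_p_raw_monotone_nonincreasing_in_k(self):
        from scipy import stats as sps

        N, K, n = 30, 8, 12
        tails = [float(sps.hypergeom.sf(k - 1, N, K, n)) for k in range(0, 9)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))
        assert tails[0] == 1.0

    def test_bh_adjustment_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(3)
        covered = set(range(1, 16))
        sig = {1, 2, 3, 4}
        rows = [
            set(rng.choice(15, size=rng.integers(1, 10), replace=False) + 1)
            for _ in range(12)
        ]
        efms, rstats = self._setup(20, sig, covered, rows)
        result = enrich_efms(efms, rstats, "up")
        raw = [r.p_raw for r in result.records]
        _, expected, _, _ = sm.multipletests(raw, method="fdr_bh")
        assert [r.p_adjusted for r in result.records] == pytest.approx(
            list(expected), abs=1e-12
        )
        assert all(r.p_adjusted >= r.p_raw - 1e-15 for r in result.records)

    def test_direction_labels_on_planted_fixture(self, bundle):
        from fluxmodes import (
            filter_efms_by_reaction,
            map_gene_stats_to_reactions,
        )

        ac = filter_efms_by_reaction(
            bundle.efms, bundle.ground_truth["acetate_release_index"]
        )
        rstats = map_gene_stats_to_reactions(bundle.model, bundle.gene_stats)
        labels = label_efm_directions(ac, rstats)
        by_raw_up = min(
            (rec for rec in labels.values() if rec.direction == "up"),
            key=lambda r: r.p_raw,
        )
        assert by_raw_up.efm_id == bundle.ground_truth["most_enriched_up_efm"]
        assert labels[2].direction == "down"


class TestGeneStatsTable:
    def test_duplicate_gene_ids_rejected(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "a"],
                "p_value": [0.1, 0.2],
                "log2_fc": [1.0, -1.0],
                "expression": [2.0, 3.0],
            }
        )
        with pytest.raises(ValueError, match="duplicate gene ids"):
            GeneStats.from_frame(df)

    def test_p_value_range_enforced(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a"],
                "p_value": [1.5],
                "log2_fc": [0.0],
                "expression": [1.0],
            }
        )
        with pytest.raises(ValueError, match="p_value"):
            GeneStats.from_frame(df)

    def test_missing_column_named(self):
        df = pd.DataFrame({"gene_id": ["a"], "p_value": [0.1]})
        with pytest.raises(ValueError, match="expression"):
            GeneStats.from_frame(df)
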