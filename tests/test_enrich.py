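"""Hypergeometric test, kappa, BH correction, ranking and the set graph."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossgsa.core import CrossGsaError
from crossgsa.enrich import (
    ContingencyTable,
    bh_adjust,
    filter_rank,
    hypergeom_pvalue,
    kappa,
    run_gsa,
    set_graph,
)
from crossgsa.synth import PlantedSignal, SynthSpec, gen_corpus, plant_signal

from .conftest import gset


def enumeration_pvalue(N, K, n, k):
    """Upper-tail probability by brute-force enumeration of all C(N,n) draws."""
    population = [1] * K + [0] * (N - K)
    total = 0
    hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return Fraction(hits, total)


class TestHypergeomPvalue:
    def test_zero_overlap_gives_exactly_one(self):
        assert hypergeom_pvalue(50, 10, 5, 0) == 1.0

    def test_worked_example_is_one_third(self):
        # N=10, K=4, n=3, k>=2: 40 of the 120 possible draws qualify
        assert hypergeom_pvalue(10, 4, 3, 2) == pytest.approx(1 / 3, rel=1e-12)

    def test_full_overlap_closed_form(self):
        expected = 1 / math.comb(100, 10)
        assert hypergeom_pvalue(100, 10, 10, 10) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize(
        "N,K,n", [(8, 3, 4), (9, 5, 5), (10, 4, 3), (11, 6, 4), (12, 5, 6)]
    )
    def test_matches_enumeration_oracle(self, N, K, n):
        for k in range(min(n, K) + 1):
            expected = float(enumeration_pvalue(N, K, n, k))
            assert hypergeom_pvalue(N, K, n, k) == pytest.approx(expected, rel=1e-10)

    def test_monotone_decreasing_in_k(self):
        ps = [hypergeom_pvalue(100, 20, 15, k) for k in range(11)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_monotone_decreasing_in_universe_size(self):
        # growing the universe with K, n, k fixed dilutes the draw, so a
        # given overlap becomes more surprising
        ps = [hypergeom_pvalue(N, 20, 15, 5) for N in (60, 120, 240, 480)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize(
        "N,K,n,k,msg",
        [
            (10, 11, 5, 1, "K <= N"),
            (10, 5, 11, 1, "n <= N"),
            (10, 5, 5, 6, "min"),
        ],
    )
    def test_violated_bounds_named(self, N, K, n, k, msg):
        with pytest.raises(CrossGsaError, match=msg):
            hypergeom_pvalue(N, K, n, k)


class TestKappa:
    def test_identical_sets_give_one(self):
        assert kappa(ContingencyTable(a=5, b=0, c=0, d=15)) == pytest.approx(1.0)

    def test_worked_two_by_two_example(self):
        # po=0.8, pe=0.68 -> kappa = 0.12/0.32
        assert kappa(ContingencyTable(10, 10, 10, 70)) == pytest.approx(
            0.375, abs=1e-12
        )

    def test_independence_gives_zero(self):
        # margins 50/100 and 40/100, a = 20 = n*K/N exactly
        assert kappa(ContingencyTable(20, 30, 20, 30)) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_under_set_swap(self):
        t = ContingencyTable(7, 3, 12, 40)
        swapped = ContingencyTable(7, 12, 3, 40)
        assert kappa(t) == pytest.approx(kappa(swapped), abs=1e-12)

    def test_degenerate_margins_are_nan(self):
        assert math.isnan(kappa(ContingencyTable(0, 0, 0, 10)))
        assert math.isnan(kappa(ContingencyTable(10, 0, 0, 0)))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_bounds(self, cells):
        t = ContingencyTable(*cells)
        if t.N == 0:
            return
        value = kappa(t)
        if not math.isnan(value):
            assert -1.0 - 1e-12 <= value <= 1.0 + 1e-12


class TestBHAdjust:
    def test_hand_computed_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.9], m=4) == pytest.approx(
            [0.04, 0.04, 0.04, 0.9]
        )

    def test_single_p_is_unchanged(self):
        assert bh_adjust([0.2], m=1) == [pytest.approx(0.2)]

    def test_equal_ps_are_unchanged(self):
        assert bh_adjust([0.3] * 5) == pytest.approx([0.3] * 5)

    def test_family_size_may_exceed_list_length(self):
        # zero-overlap family members carry p=1 and need not be listed
        explicit = bh_adjust([0.01, 0.02, 1.0, 1.0], m=4)[:2]
        implicit = bh_adjust([0.01, 0.02], m=4)
        assert implicit == pytest.approx(explicit)

    def test_matches_statsmodels_when_family_is_listed(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(1e-6, 1.0, size=40)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p.tolist()) == pytest.approx(expected.tolist(), rel=1e-12)

    def test_invalid_p_rejected(self):
        for bad in ([0.0], [1.5], [math.nan]):
            with pytest.raises(CrossGsaError):
                bh_adjust(bad)
        with pytest.raises(CrossGsaError):
            bh_adjust([0.1, 0.2], m=1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0, exclude_min=False), min_size=1, max_size=30))
    def test_q_dominates_p_and_is_permutation_invariant(self, ps):
        q = bh_adjust(ps)
        assert all(qi >= pi - 1e-15 for qi, pi in zip(q, ps))
        assert all(qi <= 1.0 for qi in q)
        order = sorted(range(len(ps)), key=lambda i: ps[i])
        q_sorted = [q[i] for i in order]
        assert all(a <= b + 1e-15 for a, b in zip(q_sorted, q_sorted[1:]))
        perm = list(reversed(range(len(ps))))
        q_perm = bh_adjust([ps[i] for i in perm])
        assert [q_perm[perm.index(i)] for i in range(len(ps))] == pytest.approx(q)


@pytest.fixture
def planted_run():
    spec = SynthSpec(seed=0, n_sets=80, inventory_sizes=(2000, 1000), n_edges=50)
    corpus = gen_corpus(spec)
    private = plant_signal(corpus, spec)
    return spec, corpus, private


class TestRunGsa:
    def test_planted_contingency_is_exact(self, planted_run):
        spec, corpus, private = planted_run
        result = run_gsa([private], corpus, "phenotype")
        row = next(
            r
            for r in result.blocks["planted_input"]
            if r.public_set == spec.planted.target_name
        )
        assert (row.input_size, row.set_size, row.overlap) == (
            spec.planted.input_size,
            spec.planted.target_size,
            spec.planted.overlap,
        )

    def test_planted_target_ranks_first(self, planted_run):
        spec, corpus, private = planted_run
        result = run_gsa([private], corpus, "phenotype")
        top = result.blocks["planted_input"][0]
        assert top.public_set == spec.planted.target_name
        assert top.rank == 1

    def test_family_size_counts_zero_overlap_sets(self, planted_run):
        spec, corpus, private = planted_run
        result = run_gsa([private], corpus, "phenotype")
        assert result.m["planted_input"] == spec.n_sets + 1
        assert len(result.blocks["planted_input"]) <= result.m["planted_input"]

    def test_ranks_contiguous_and_rows_ordered(self, planted_run):
        _, corpus, private = planted_run
        rows = run_gsa([private], corpus, "phenotype").blocks["planted_input"]
        assert [r.rank for r in rows] == list(range(1, len(rows) + 1))
        assert all(a.p_value <= b.p_value for a, b in zip(rows, rows[1:]))
        assert all(r.overlap > 0 for r in rows)

    def test_disjoint_private_set_yields_empty_block_and_intact_m(
        self, small_corpus
    ):
        private = gset("lonely", [10], category="private/test")
        result = run_gsa([private], small_corpus, "phenotype", "all-genes")
        assert result.blocks["lonely"] == []
        assert result.m["lonely"] == 3

    def test_identical_private_sets_give_identical_blocks(self, small_corpus):
        a = gset("a", [1, 2, 3], category="private/test")
        b = gset("b", [1, 2, 3], category="private/test")
        result = run_gsa([a, b], small_corpus, "phenotype")
        strip = lambda rows: [  # noqa: E731
            (r.rank, r.public_set, r.p_value, r.q_value) for r in rows
        ]
        assert strip(result.blocks["a"]) == strip(result.blocks["b"])

    def test_empty_after_restriction_is_an_error(self, small_corpus):
        private = gset("out", [10], category="private/test")  # 10 is unannotated
        with pytest.raises(CrossGsaError, match="no analyzable genes"):
            run_gsa([private], small_corpus, "phenotype", "annotated")

    def test_unknown_annotation_type_rejected(self, small_corpus):
        with pytest.raises(CrossGsaError, match="phenotype"):
            run_gsa([gset("a", [1])], small_corpus, "pathway")

    def test_universe_policy_changes_N(self, small_corpus):
        private = gset("a", [1, 2], category="private/test")
        ann = run_gsa([private], small_corpus, "phenotype", "annotated")
        allg = run_gsa([private], small_corpus, "phenotype", "all-genes")
        assert ann.blocks["a"][0].universe_size == 9
        assert allg.blocks["a"][0].universe_size == 10


class TestFilterRank:
    def test_threshold_zero_empties(self, planted_run):
        _, corpus, private = planted_run
        rows = run_gsa([private], corpus, "phenotype").blocks["planted_input"]
        assert filter_rank(rows, 0.0) == []

    def test_filter_preserves_original_ranks(self, planted_run):
        _, corpus, private = planted_run
        rows = run_gsa([private], corpus, "phenotype").blocks["planted_input"]
        kept = filter_rank(rows, 0.5)
        assert [r.rank for r in kept] == [r.rank for r in rows if r.q_value < 0.5]


class TestSetGraph:
    def test_no_passing_rows_gives_empty_graph(self, planted_run):
        _, corpus, private = planted_run
        result = run_gsa([private], corpus, "phenotype")
        sg = set_graph(result, q_threshold=0.0)
        assert sg.graph.number_of_edges() == 0

    def test_single_edge_weight_is_neglog10_q(self, planted_run):
        spec, corpus, private = planted_run
        result = run_gsa([private], corpus, "phenotype")
        top = result.blocks["planted_input"][0]
        sg = set_graph(result, q_threshold=top.q_value * 1.0001)
        edges = [e for e in sg.edges() if top.public_set in e[:2]]
        assert len(edges) == 1
        assert edges[0][2] == pytest.approx(-math.log10(top.q_value))

    def test_two_private_sets_sharing_a_hit_form_a_star(self, small_corpus):
        a = gset("a", [1, 2, 3], category="private/test")
        b = gset("b", [2, 3, 4], category="private/test")
        result = run_gsa([a, b], small_corpus, "phenotype")
        sg = set_graph(result, q_threshold=1.1)
        degrees = dict(sg.graph.degree)
        assert degrees.get("term_a", 0) == 2
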