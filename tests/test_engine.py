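import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigsearch import (
    ContingencyTable,
    GeneSet,
    GeneUniverse,
    SearchParams,
    bh_adjust,
    build_single_table,
    filter_results,
    fisher_one_sided,
    mimicker_reverser_overlaps,
    odds_ratio,
    results_to_frame,
    search_paired,
    search_single,
)
from sigsearch.engine import EmptyQueryError, intersect_count

from oracles import bh_step_up, hypergeom_upper_tail


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((0, 5, 5, 10), 1.0),
            ((1, 0, 0, 1), 0.5),
            ((5, 0, 0, 15), 1.0 / math.comb(20, 5)),
        ],
    )
    def test_known_tails(self, table, expected):
        assert fisher_one_sided(ContingencyTable(*table)) == pytest.approx(expected, abs=1e-14)

    def test_matches_exact_enumeration_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            if a + b + c + d == 0:
                continue
            p = fisher_one_sided(ContingencyTable(a, b, c, d))
            assert p == pytest.approx(hypergeom_upper_tail(a, b, c, d), abs=1e-13)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 1)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((2, 1, 1, 2), 4.0),
            ((0, 1, 1, 1), 0.0),
            ((3, 0, 2, 5), math.inf),
            ((0, 0, 2, 5), 0.0),
        ],
    )
    def test_conventions(self, table, expected):
        assert odds_ratio(ContingencyTable(*table)) == expected


class TestBuildTable:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((10, 20, 5, 100), (5, 5, 15, 75)),
            ((0, 20, 0, 100), (0, 0, 20, 80)),
        ],
    )
    def test_definition(self, args, expected):
        t = build_single_table(*args)
        assert (t.a, t.b, t.c, t.d) == expected

    def test_margin_violations_named(self):
        with pytest.raises(ValueError, match="overlap"):
            build_single_table(3, 5, 4, 100)
        with pytest.raises(ValueError, match="background"):
            build_single_table(50, 60, 0, 100)

    @given(
        q=st.integers(0, 200),
        s=st.integers(0, 200),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_margins_reconstruct_inputs(self, q, s, data):
        o = data.draw(st.integers(0, min(q, s)))
        bg = data.draw(st.integers(q + s - o, q + s - o + 500))
        if bg == 0:
            bg = 1
        t = build_single_table(q, s, o, bg)
        assert t.a + t.b == q
        assert t.a + t.c == s
        assert t.a == o
        assert t.n == bg


class TestMimickerReverser:
    def _masks(self, uni, *sets):
        return [uni.mask(s) for s in sets]

    def test_counting_by_definition(self):
        uni = GeneUniverse(["A", "B", "C", "D", "E", "X", "Y"])
        up_q, down_q = {"A", "B", "C"}, {"D", "E"}
        up_s, down_s = {"A", "B", "X"}, {"D", "Y"}
        m, mg, r, rg = mimicker_reverser_overlaps(*self._masks(uni, up_q, down_q, up_s, down_s), uni)
        assert (m, r) == (3, 0)
        assert mg == {"A", "B", "D"} and rg == frozenset()

    def test_swapping_stored_halves_exchanges_roles(self):
        uni = GeneUniverse(["A", "B", "C", "D", "E", "X", "Y"])
        up_q, down_q = {"A", "B", "C"}, {"D", "E"}
        up_s, down_s = {"A", "B", "X"}, {"D", "Y"}
        m1, mg1, r1, rg1 = mimicker_reverser_overlaps(*self._masks(uni, up_q, down_q, up_s, down_s), uni)
        m2, mg2, r2, rg2 = mimicker_reverser_overlaps(*self._masks(uni, up_q, down_q, down_s, up_s), uni)
        assert (m1, mg1) == (r2, rg2) and (r1, rg1) == (m2, mg2)

    def test_overlapping_query_halves_rejected(self):
        uni = GeneUniverse(["A", "B"])
        with pytest.raises(ValueError):
            mimicker_reverser_overlaps(*self._masks(uni, {"A"}, {"A"}, {"B"}, {"B"}), uni)

    def test_random_quadruples_match_set_arithmetic(self):
        rng = np.random.default_rng(17)
        symbols = [f"G{i:03d}" for i in range(120)]
        uni = GeneUniverse(symbols)
        for _ in range(300):
            pool = rng.permutation(120)
            up_q = {symbols[i] for i in pool[:20]}
            down_q = {symbols[i] for i in pool[20:40]}
            up_s = {symbols[i] for i in rng.choice(120, 25, replace=False)}
            down_s = {symbols[i] for i in rng.choice(120, 25, replace=False)} - up_s
            m, mg, r, rg = mimicker_reverser_overlaps(
                *[uni.mask(s) for s in (up_q, down_q, up_s, down_s)], uni
            )
            assert m == len(up_q & up_s) + len(down_q & down_s)
            assert r == len(up_q & down_s) + len(down_q & up_s)
            assert mg == (up_q & up_s) | (down_q & down_s)
            assert rg == (up_q & down_s) | (down_q & up_s)
            assert m + r <= len(up_q) + len(down_q)


class TestBH:
    def test_m1_identity(self):
        assert bh_adjust([0.04]).tolist() == [0.04]

    def test_worked_step_up_example(self):
        adj = bh_adjust([0.01, 0.04, 0.03, 0.05])
        assert np.allclose(adj, [0.04, 0.05, 0.05, 0.05])

    def test_constant_vector_unchanged(self):
        assert np.allclose(bh_adjust([0.2] * 7), [0.2] * 7)

    def test_matches_literal_definition_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 60))
            adj = bh_adjust(p)
            assert np.allclose(adj, bh_step_up(p), atol=1e-12)
            assert np.allclose(adj, multipletests(p, method="fdr_bh")[1], atol=1e-12)
            assert np.all(adj >= p - 1e-15)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSearchSingle:
    def test_self_retrieval_ranks_first(self, tiny_pairs, tiny_index):
        query = GeneSet("q", tiny_pairs[0].up.members)
        res = search_single(query, tiny_index, SearchParams(apply_threshold=False))
        assert res[0].rank == 1
        assert res[0].meta.signature_id == tiny_pairs[0].up.label
        assert res[0].overlap_count == len(query.members)
        assert res[0].overlap_genes == query.members

    def test_disjoint_query_returns_nothing_under_threshold(self, tiny_pairs):
        from sigsearch import build_bit_index, build_universe

        uni = build_universe(tiny_pairs, extra=["ZZZ1", "ZZZ2"])
        idx = build_bit_index(tiny_pairs, uni)
        res = search_single(GeneSet("q", frozenset({"ZZZ1", "ZZZ2"})), idx)
        assert res == []

    def test_zero_resolved_genes_raise(self, tiny_index):
        with pytest.raises(EmptyQueryError):
            search_single(GeneSet("q", frozenset({"NOT_A_GENE"})), tiny_index)

    def test_pvalues_match_per_row_oracle(self, small_index):
        uni = small_index.universe
        rng = np.random.default_rng(21)
        query = GeneSet("q", frozenset(str(s) for s in rng.choice(uni.symbols, 60, replace=False)))
        res = search_single(query, small_index, SearchParams(apply_threshold=False))
        assert len(res) == small_index.n_rows
        by_id = {r.meta.signature_id: r for r in res}
        for k in range(0, 50):  # 50-row spot check against the exact oracle
            meta, _ = small_index.row_meta[k]
            r = by_id[meta.signature_id]
            a = r.overlap_count
            t = build_single_table(len(query.members), r.set_size, a, uni.size)
            assert r.p_value == pytest.approx(
                hypergeom_upper_tail(t.a, t.b, t.c, t.d), abs=1e-12
            )

    def test_adj_p_at_least_raw_and_ranks_contiguous(self, small_index):
        uni = small_index.universe
        query = GeneSet("q", frozenset(uni.symbols[:80]))
        res = search_single(query, small_index, SearchParams(apply_threshold=False))
        assert [r.rank for r in res] == list(range(1, len(res) + 1))
        assert all(r.adj_p_value >= r.p_value - 1e-15 for r in res)
        ps = [r.p_value for r in res]
        assert ps == sorted(ps)


class TestSearchPaired:
    def test_identical_pair_is_rank1_mimicker(self, tiny_pairs, tiny_index):
        p = tiny_pairs[0]
        res = search_paired(p.up, p.down, tiny_index, SearchParams(apply_threshold=False))
        assert res[0].role == "mimicker"
        assert res[0].meta.signature_id == p.meta.signature_id
        swapped = search_paired(p.down, p.up, tiny_index, SearchParams(apply_threshold=False))
        assert swapped[0].role == "reverser"
        assert swapped[0].meta.signature_id == p.meta.signature_id

    def test_half_swap_exactly_exchanges_pvalues(self, tiny_pairs, tiny_index):
        p = tiny_pairs[0]
        fwd = search_paired(p.up, p.down, tiny_index, SearchParams(apply_threshold=False))
        rev = search_paired(p.down, p.up, tiny_index, SearchParams(apply_threshold=False))

        def table(results):
            return {(r.meta.signature_id, r.role): r.p_value for r in results}

        tf, tr = table(fwd), table(rev)
        for (sid, role), pv in tf.items():
            other = "reverser" if role == "mimicker" else "mimicker"
            assert tr[(sid, other)] == pv

    def test_empty_down_half_degenerates(self, tiny_pairs, tiny_index):
        p = tiny_pairs[0]
        res = search_paired(
            p.up, GeneSet("q down", frozenset()), tiny_index, SearchParams(apply_threshold=False)
        )
        for r in res:
            if r.meta.signature_id == p.meta.signature_id and r.role == "mimicker":
                assert r.overlap_count == len(p.up.members)

    def test_nondisjoint_halves_rejected(self, tiny_pairs, tiny_index):
        p = tiny_pairs[0]
        with pytest.raises(ValueError, match="share genes"):
            search_paired(p.up, p.up, tiny_index)

    def test_full_search_matches_brute_force(self, small_library, small_index):
        pairs, _ = small_library
        sub = pairs[:20]
        uni = small_index.universe
        rng = np.random.default_rng(33)
        picks = rng.choice(uni.symbols, 80, replace=False)
        up_q = frozenset(str(s) for s in picks[:40])
        down_q = frozenset(str(s) for s in picks[40:])
        res = search_paired(
            GeneSet("u", up_q), GeneSet("d", down_q), small_index, SearchParams(apply_threshold=False)
        )
        by_key = {(r.meta.signature_id, r.role): r for r in res}
        qsize = len(up_q) + len(down_q)
        for p in sub:
            mimic = len(up_q & p.up.members) + len(down_q & p.down.members)
            reverse = len(up_q & p.down.members) + len(down_q & p.up.members)
            ssize = len(p.up.members) + len(p.down.members)
            for role, overlap in (("mimicker", mimic), ("reverser", reverse)):
                r = by_key[(p.meta.signature_id, role)]
                assert r.overlap_count == overlap
                t = build_single_table(qsize, ssize, overlap, uni.size)
                assert r.p_value == pytest.approx(
                    hypergeom_upper_tail(t.a, t.b, t.c, t.d), rel=1e-10, abs=1e-12
                )


class TestFiltering:
    def _results(self, small_index):
        uni = small_index.universe
        q = GeneSet("q", frozenset(uni.symbols[:60]))
        return search_single(q, small_index, SearchParams(apply_threshold=False))

    def test_fda_only(self, small_library, small_index):
        _, truth = small_library
        res = self._results(small_index)
        kept = filter_results(res, fda_only=True)
        assert kept and all(r.meta.fda_approved for r in kept)
        assert all(r.meta.perturbation in truth.fda_compounds for r in kept)

    def test_term_filter(self, small_index):
        res = self._results(small_index)
        pert = res[0].meta.perturbation
        kept = filter_results(res, term=pert.lower())
        assert kept and all(pert.lower() in r.meta.perturbation.lower() for r in kept)

    def test_ko_and_fda_conjunction_is_empty(self, small_index):
        res = self._results(small_index)
        assert filter_results(res, fda_only=True, ko_only=True) == []

    def test_ranks_reassigned(self, small_index):
        res = self._results(small_index)
        kept = filter_results(res, direction="up")
        assert [r.rank for r in kept] == list(range(1, len(kept) + 1))
        assert all(r.meta.direction == "up" for r in kept)

    def test_frame_columns(self, small_index):
        df = results_to_frame(self._results(small_index)[:5])
        assert list(df.columns) == [
            "signature_id", "perturbation", "perturbation_kind", "cell_line",
            "time_point", "concentration", "role", "set_size", "overlap",
            "overlap_genes", "odds_ratio", "p_value", "adj_p_value", "rank",
        ]


def test_intersect_count_examples():
    r = np.packbits(np.array([1, 0, 1, 1], dtype=bool))
    m = np.packbits(np.array([0, 0, 1, 1], dtype=bool))
    assert intersect_count(r, m) == 2
    zero = np.zeros_like(r)
    assert intersect_count(r, zero) == 0
    with pytest.raises(ValueError):
        intersect_count(r, np.zeros(2, dtype=np.uint8))
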