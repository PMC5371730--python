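"""Hypergeometric tail, BH adjustment, term/category enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import step_up_bh
from mythpipe.enrich import (
    BackgroundSpec,
    bh_adjust,
    enrich_drug_categories,
    enrich_drug_targets,
    enrich_gene_sets,
    enrich_terms,
    hypergeom_upper_tail,
)
from mythpipe.errors import DomainError, InconsistencyError
from mythpipe.io import AnnotationTable, GeneSetCollection


def rational_tail(N, K, n, k):
    """Closed-form exact tail by rational arithmetic (independent of scipy)."""
    return Fraction(
        sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1)),
        comb(N, n),
    )


class TestHypergeomUpperTail:
    @pytest.mark.parametrize("N,K,n", [(10, 4, 5), (50, 10, 7), (7, 7, 3)])
    def test_k_zero_is_one(self, N, K, n):
        assert hypergeom_upper_tail(N, K, n, 0) == 1.0

    def test_small_exact_value(self):
        # 66 of the 252 size-5 samples of a 10-population with 4 successes
        # contain at least 3 successes
        assert hypergeom_upper_tail(10, 4, 5, 3) == pytest.approx(
            66 / 252, rel=1e-12
        )

    def test_drug_target_scale(self):
        # the 48-bait drug-target test: large population, tiny tail
        p = hypergeom_upper_tail(19008, 4333, 48, 28)
        assert p == pytest.approx(float(rational_tail(19008, 4333, 48, 28)),
                                  rel=1e-10)

    def test_large_population_stability(self):
        p = hypergeom_upper_tail(200000, 5000, 100, 30)
        assert 0 < p < 1e-20
        assert p == pytest.approx(
            float(rational_tail(200000, 5000, 100, 30)), rel=1e-9
        )

    @pytest.mark.parametrize(
        "N,K,n,k,arg",
        [(10, 11, 5, 1, "K"), (10, 4, 11, 1, "n"), (10, 4, 5, 5, "k"),
         (-1, 0, 0, 0, "N")],
    )
    def test_bounds_name_offender(self, N, K, n, k, arg):
        with pytest.raises(DomainError, match=arg):
            hypergeom_upper_tail(N, K, n, k)

    @given(
        st.integers(min_value=1, max_value=60).flatmap(
            lambda N: st.tuples(
                st.just(N),
                st.integers(0, N),
                st.integers(0, N),
            )
        )
    )
    @settings(max_examples=80, deadline=None)
    def test_monotone_decreasing_in_k_and_symmetric(self, NKn):
        N, K, n = NKn
        tails = [
            hypergeom_upper_tail(N, K, n, k) for k in range(min(n, K) + 1)
        ]
        assert all(a >= b for a, b in zip(tails, tails[1:]))
        # strictly decreasing above the lower support bound max(0, n+K-N),
        # where the pmf is positive
        lower = max(0, n + K - N)
        assert all(
            tails[k - 1] > tails[k]
            for k in range(lower + 1, min(n, K) + 1)
        )
        for k in range(min(n, K) + 1):
            assert hypergeom_upper_tail(N, n, K, k) == pytest.approx(
                tails[k], rel=1e-10
            )


class TestBHAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.037]) == [0.037]

    def test_hand_example(self):
        assert bh_adjust([0.01, 0.04, 0.03, 0.02]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                 min_size=1, max_size=40)
    )
    @settings(max_examples=100, deadline=None)
    def test_against_step_up_oracle(self, p_values):
        assert bh_adjust(p_values) == pytest.approx(
            step_up_bh(p_values), abs=1e-12
        )

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                 min_size=1, max_size=30)
    )
    @settings(max_examples=60, deadline=None)
    def test_elementwise_bounds(self, p_values):
        adjusted = bh_adjust(p_values)
        for p, a in zip(p_values, adjusted):
            assert p <= a + 1e-12
            assert a <= 1.0

    def test_all_null_false_discovery_control(self):
        """With independent uniform p-values the chance of any BH discovery
        at level alpha is ~alpha (here 2,000 seeded replicates)."""
        rng = np.random.default_rng(12345)
        alpha = 0.05
        hits = sum(
            bool(min(bh_adjust(rng.uniform(size=20))) < alpha)
            for _ in range(2000)
        )
        assert hits / 2000 <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 2000)


class TestEnrichTerms:
    @pytest.fixture
    def disease_table(self):
        table = AnnotationTable(namespace="disease")
        carriers = {"A": ["Q1", "Q2", "Q3", "Q4", "P5"],
                    "B": ["Q1", "P6", "P7"]}
        for term, proteins in carriers.items():
            for p in proteins:
                table.protein_to_terms.setdefault(p, set()).add(term)
        return table

    def test_exact_p_value(self, disease_table):
        background = BackgroundSpec(
            population_size=20,
            annotated_in_population={"A": 5, "B": 3},
        )
        results = enrich_terms(
            {"Q1", "Q2", "Q3", "Q4", "X1", "X2"}, disease_table, background
        )
        top = results[0]
        assert top.term_id == "A"
        assert (top.k, top.n_query, top.K, top.N) == (4, 6, 5, 20)
        assert top.p_raw == pytest.approx(540 / 38760, rel=1e-12)
        assert top.fraction == pytest.approx(4 / 6)

    def test_k_zero_not_reported(self, disease_table):
        background = BackgroundSpec(
            population_size=20, annotated_in_population={"A": 5, "B": 3}
        )
        results = enrich_terms({"Q2", "Q3"}, disease_table, background)
        assert [r.term_id for r in results] == ["A"]

    def test_min_K_restricts_family(self, disease_table):
        background = BackgroundSpec(
            population_size=20, annotated_in_population={"A": 5, "B": 3}
        )
        results = enrich_terms({"Q1"}, disease_table, background, min_K=4)
        assert [r.term_id for r in results] == ["A"]

    def test_background_mismatch_is_inconsistency(self, disease_table):
        background = BackgroundSpec(
            population_size=20, annotated_in_population={"A": 5}
        )
        with pytest.raises(InconsistencyError, match="'B'"):
            enrich_terms({"Q1"}, disease_table, background)

    def test_permutation_null_p_values(self):
        """Under random query draws the term's p-values follow the exact
        discrete null: the observed counts k match the hypergeometric pmf
        (chi-square) and the p-values are superuniform."""
        from scipy.stats import chisquare, hypergeom

        rng = np.random.default_rng(99)
        population = [f"P{i}" for i in range(60)]
        table = AnnotationTable(namespace="t")
        for p in population[:20]:
            table.protein_to_terms[p] = {"T"}
        background = BackgroundSpec(
            population_size=60, annotated_in_population={"T": 20}
        )
        n_rep = 400
        ks, p_values = [], []
        for _ in range(n_rep):
            query = rng.choice(population, size=15, replace=False)
            res = enrich_terms(set(query), table, background)
            # k=0 draws are unreported; they correspond to p_raw = 1
            ks.append(res[0].k if res else 0)
            p_values.append(res[0].p_raw if res else 1.0)
        support = np.arange(0, 16)
        expected = hypergeom.pmf(support, 60, 20, 15) * n_rep
        observed = np.bincount(ks, minlength=16).astype(float)
        # pool sparse tail bins for a valid chi-square
        keep = expected > 4
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        assert chisquare(obs, exp).pvalue > 0.01
        # superuniformity of the discrete p-value: P(p <= t) <= t (+3 se)
        for t in (0.05, 0.1, 0.25):
            frac = np.mean(np.asarray(p_values) <= t)
            assert frac <= t + 3 * np.sqrt(t * (1 - t) / n_rep)


class TestDrugEnrichment:
    def test_disjoint_targets(self):
        res = enrich_drug_targets({"B1", "B2"}, {"T1", "T2"}, genome_size=100)
        assert res.k == 0 and res.p_raw == 1.0

    def test_printed_parameterization(self):
        targets = {f"T{i}" for i in range(4333)}
        baits = {f"T{i}" for i in range(28)} | {f"B{i}" for i in range(20)}
        res = enrich_drug_targets(baits, targets, genome_size=19008)
        assert (res.N, res.K, res.n_query, res.k) == (19008, 4333, 48, 28)
        assert res.p_raw == pytest.approx(
            float(rational_tail(19008, 4333, 48, 28)), rel=1e-10
        )
        assert res.p_adj == res.p_raw

    def test_toy_against_rational_oracle(self):
        targets = {f"T{i}" for i in range(10)}
        baits = {f"T{i}" for i in range(5)} | {f"B{i}" for i in range(5)}
        res = enrich_drug_targets(baits, targets, genome_size=100)
        assert res.p_raw == pytest.approx(
            float(rational_tail(100, 10, 10, 5)), rel=1e-12
        )

    def test_categories_compose_from_single_tests(self):
        table = AnnotationTable(namespace="drug_category")
        members = {
            "antihistamine": ["P1", "P2", "P3"],
            "antiparkinson": ["P2", "P4", "P5", "P6"],
            "antipruritic": ["P7"],
        }
        for cat, proteins in members.items():
            for p in proteins:
                table.protein_to_terms.setdefault(p, set()).add(cat)
        query = {"P1", "P2", "P4", "X1"}
        results = enrich_drug_categories(query, table, genome_size=50)
        by_id = {r.term_id: r for r in results}
        for cat, proteins in members.items():
            k = len(query & set(proteins))
            if k == 0:
                assert cat not in by_id
                continue
            assert by_id[cat].p_raw == pytest.approx(
                float(rational_tail(50, len(proteins), 4, k)), rel=1e-12
            )
        assert bh_adjust([r.p_raw for r in results]) == pytest.approx(
            [r.p_adj for r in results]
        )

    def test_no_category_intersection_gives_empty(self):
        table = AnnotationTable(
            namespace="drug_category", protein_to_terms={"P1": {"C"}}
        )
        assert enrich_drug_categories({"X1"}, table, genome_size=50) == []


def test_gene_set_enrichment_matches_term_route(tmp_path):
    coll = GeneSetCollection(
        sets={"S1": {"A", "B", "C"}, "S2": {"C", "D"}},
        description={"S1": "first", "S2": "second"},
    )
    results = enrich_gene_sets({"A", "B", "X"}, coll, background_size=30)
    top = results[0]
    assert top.term_id == "S1"
    assert top.p_raw == pytest.approx(
        float(rational_tail(30, 3, 3, 2)), rel=1e-12
    )
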