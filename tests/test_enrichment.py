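"""Hypergeometric ORA, BH adjustment and top-k cross-source overlap."""

import math
import random
from fractions import Fraction
from itertools import combinations

import pytest
from scipy import stats

from phytoscreen.enrichment import (
    EnrichmentResult,
    GeneSetCollection,
    adjust_bh,
    hypergeom_upper_tail,
    normalize_set_name,
    ora,
    read_gmt,
    top_k_overlap,
    write_gmt,
)
from phytoscreen.errors import ParseError, ValidationError


def enumeration_p(N, K, n, k):
    """Independent oracle: exhaustively enumerate all C(N, n) draws and
    count those with at least k members inside the first K elements."""
    marked = set(range(K))
    hits = sum(1 for draw in combinations(range(N), n)
               if len(marked & set(draw)) >= k)
    return Fraction(hits, math.comb(N, n))


# --- GMT parsing ------------------------------------------------------------

def test_read_gmt_basic(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("S1\tdesc\tA\tB\tC\nS2\tdesc\tD\tE\tF\tG\n")
    collection = read_gmt(path)
    assert set(collection.sets) == {"S1", "S2"}
    assert len(collection.universe) == 7


def test_read_gmt_collapses_duplicate_members(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("S1\tdesc\tA\tB\tA\n")
    assert read_gmt(path).sets["S1"] == frozenset({"A", "B"})


def test_read_gmt_rejects_memberless_line(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("S1\tdesc\tA\nBARE_NAME\n")
    with pytest.raises(ParseError, match=":2"):
        read_gmt(path)


def test_gmt_write_read_round_trip(tmp_path, default_genesets):
    path = tmp_path / "a.gmt"
    write_gmt(default_genesets.source_a, path)
    back = read_gmt(path, source_label=default_genesets.source_a.source_label)
    assert back.sets == default_genesets.source_a.sets


# --- hypergeometric ORA -----------------------------------------------------

def test_zero_overlap_gives_p_exactly_one():
    assert hypergeom_upper_tail(10, 4, 3, 0) == 1


def test_full_overlap_closed_form():
    # drawing all 5 marked in 5 draws from 10: 1 / C(10,5) = 1/252
    assert hypergeom_upper_tail(10, 5, 5, 5) == Fraction(1, 252)
    assert enumeration_p(10, 5, 5, 5) == Fraction(1, 252)


def test_matches_enumeration_on_small_instances():
    """Exact rational agreement with the exhaustive-draw oracle, N <= 8."""
    for N in range(1, 9):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert hypergeom_upper_tail(N, K, n, k) == \
                        enumeration_p(N, K, n, k), (N, K, n, k)


def test_matches_scipy_survival_function():
    rng = random.Random(2)
    for _ in range(200):
        N = rng.randint(5, 500)
        K = rng.randint(0, N)
        n = rng.randint(0, N)
        k = rng.randint(0, min(K, n))
        ours = float(hypergeom_upper_tail(N, K, n, k))
        assert ours == pytest.approx(stats.hypergeom.sf(k - 1, N, K, n),
                                     rel=1e-9, abs=1e-12)


def test_p_monotone_in_overlap():
    for k in range(1, 6):
        assert hypergeom_upper_tail(12, 6, 6, k) <= hypergeom_upper_tail(12, 6, 6, k - 1)


def test_query_equal_to_universe_gives_p_one_everywhere():
    collection = GeneSetCollection("src", {
        "S1": frozenset({"A", "B"}), "S2": frozenset({"B", "C", "D"}),
    })
    results = ora(collection.universe, collection)
    for r in results:
        assert r.k == r.K
        assert r.p_exact == 1
        assert r.neg_log10_p == 0


def test_ora_drops_out_of_universe_symbols_and_requires_overlap():
    collection = GeneSetCollection("src", {"S1": frozenset({"A", "B"})})
    (result,) = ora({"A", "ZZZ"}, collection)
    assert result.n == 1  # ZZZ dropped
    with pytest.raises(ValidationError):
        ora({"ZZZ"}, collection)


def test_ora_ease_variant_is_more_conservative(default_target_set, default_genesets):
    query = default_target_set.retained_symbols
    plain = {r.set_name: r.p_exact for r in ora(query, default_genesets.source_a)}
    eased = {r.set_name: r.p_exact for r in ora(query, default_genesets.source_a, ease=True)}
    assert all(eased[name] >= plain[name] for name in plain)


def test_planted_set_ranks_first(default_target_set, default_genesets):
    query = default_target_set.retained_symbols
    for collection in (default_genesets.source_a, default_genesets.source_b):
        results = ora(query, collection)
        assert normalize_set_name(results[0].set_name) == default_genesets.planted_key
        assert results[0].q_value >= results[0].p_value


# --- BH adjustment ----------------------------------------------------------

def test_bh_worked_examples():
    assert adjust_bh([0.03]) == [pytest.approx(0.03)]
    assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert adjust_bh([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]


def test_bh_properties_on_random_inputs():
    rng = random.Random(7)
    for _ in range(20):
        p_values = [round(rng.random(), 4) for _ in range(rng.randint(1, 30))]
        q_values = adjust_bh(p_values)
        assert all(q >= p for p, q in zip(p_values, q_values))
        assert all(q <= 1 for q in q_values)
        # permutation invariance up to the inverse permutation
        order = list(range(len(p_values)))
        rng.shuffle(order)
        permuted_q = adjust_bh([p_values[i] for i in order])
        assert [permuted_q[order.index(i)] for i in range(len(p_values))] == \
            pytest.approx(q_values)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        adjust_bh([0.5, 1.2])


# --- top-k overlap ----------------------------------------------------------

def fake_results(names_with_p):
    out = []
    for name, p in names_with_p:
        out.append(EnrichmentResult(
            set_name=name, k=1, K=2, n=3, N=10,
            p_value=p, p_exact=Fraction(p).limit_denominator(),
            q_value=p, neg_log10_p=-math.log10(p), overlap_members=(),
        ))
    return out


def test_top_k_overlap_exact_mode():
    a = fake_results([(f"P{i}", 0.01 * i) for i in range(1, 10)])
    b = fake_results([(f"P{i}", 0.01 * (i - 4)) for i in range(5, 14)])
    assert top_k_overlap(a, b, k=5, name_matcher="exact") == {"P5"}
    assert top_k_overlap(a, a, k=5, name_matcher="exact") == {f"P{i}" for i in range(1, 6)}


def test_top_k_overlap_disjoint_namespaces_empty():
    a = fake_results([("X signaling", 0.01)])
    b = fake_results([("Y pathway", 0.01)])
    assert top_k_overlap(a, b, k=5, name_matcher="exact") == set()


def test_top_k_overlap_normalized_reconciles_label_styles():
    a = fake_results([("Hypoxia-Response Signaling", 0.001), ("Other A", 0.5)])
    b = fake_results([("hypoxia response signaling pathway", 0.002), ("Other B", 0.5)])
    assert top_k_overlap(a, b, k=1) == {"hypoxia response"}


@pytest.mark.parametrize("raw,expected", [
    ("HIF-1α Signaling", "hif 1a"),
    ("HIF-1 signaling pathway", "hif 1"),
    ("Osteoclast Differentiation", "osteoclast differentiation"),
])
def test_name_normalization(raw, expected):
    assert normalize_set_name(raw) == expected
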