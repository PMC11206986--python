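"""Similarity matrix, candidate scoring, thresholds and network exports."""

import random
from fractions import Fraction

import pandas as pd
import pytest

from phytoscreen.errors import ValidationError
from phytoscreen.library import CompoundLibrary, CompoundRecord, KNOWN_ACTIVE
from phytoscreen.network import (
    NEIGHBORS_ONLY,
    build_network,
    export_network,
    import_graphml,
    pairwise_similarity,
    score_candidates,
)


def matrix_from(values, index=None, columns=None):
    values = [[Fraction(v).limit_denominator() for v in row] for row in values]
    index = index or [f"K{i}" for i in range(len(values))]
    columns = columns or [f"C{j}" for j in range(len(values[0]))]
    return pd.DataFrame(values, index=index, columns=columns, dtype=object)


def toy_library():
    return CompoundLibrary([
        CompoundRecord("k1", "c1ccccc1O", activity_status=KNOWN_ACTIVE),
        CompoundRecord("k2", "c1ccccc1N", activity_status=KNOWN_ACTIVE),
        CompoundRecord("c1", "c1ccccc1O"),          # identical to k1
        CompoundRecord("c2", "CCCCCCCC"),
        CompoundRecord("c3", "c1ccccc1OC"),
    ])


def test_pairwise_matrix_shape_and_bounds():
    matrix = pairwise_similarity(toy_library())
    assert matrix.shape == (2, 3)
    assert all(0 <= Fraction(v) <= 1 for v in matrix.values.ravel())
    # candidate structurally identical to a known scores 1.0 on its row
    assert matrix.at["k1", "c1"] == 1


def test_pairwise_requires_both_partitions():
    library = CompoundLibrary([CompoundRecord("a", "CCO")])
    with pytest.raises(ValidationError):
        pairwise_similarity(library)


def test_average_at_threshold_is_not_selected():
    """avg_tc exactly 0.4 fails the strict greater-than selection rule."""
    matrix = matrix_from([["3/5"], ["1/5"]])  # mean = 2/5 exactly
    (score,) = score_candidates(matrix)
    assert score.avg_tc == Fraction(2, 5)
    assert not score.selected
    assert score.rank is None


def test_candidate_identical_to_every_known_ranks_first():
    matrix = matrix_from([[1, "1/2"], [1, "1/2"]])
    scores = {s.candidate_id: s for s in score_candidates(matrix)}
    assert scores["C0"].avg_tc == 1
    assert scores["C0"].selected and scores["C0"].rank == 1
    assert scores["C1"].avg_tc == Fraction(1, 2)
    assert scores["C1"].selected and scores["C1"].rank == 2


def test_rank_ties_break_by_candidate_id():
    matrix = matrix_from([["1/2", "1/2", "9/10"]])
    scores = {s.candidate_id: s for s in score_candidates(matrix)}
    assert scores["C2"].rank == 1
    assert scores["C0"].rank == 2 and scores["C1"].rank == 3


def test_neighbors_only_averaging():
    # C0: one neighbor at 0.6 -> avg 0.6; C1: no neighbors -> 0, not selected
    matrix = matrix_from([["3/5", "1/10"], ["1/5", "1/10"]])
    scores = {s.candidate_id: s
              for s in score_candidates(matrix, averaging_mode=NEIGHBORS_ONLY)}
    assert scores["C0"].avg_tc == Fraction(3, 5)
    assert scores["C0"].n_known_neighbors == 1
    assert scores["C1"].avg_tc == 0
    assert not scores["C1"].selected


def test_edge_threshold_is_inclusive():
    """tc values {0.5, 0.40, 0.39} -> exactly 2 edges (0.4 counts)."""
    matrix = matrix_from([["1/2", "2/5", "39/100"]])
    network = build_network(matrix)
    assert network.n_edges == 2
    assert {e.candidate_id for e in network.edges} == {"C0", "C1"}
    # every node participates in >= 1 edge
    assert set(network.nodes) == {"K0", "C0", "C1"}


def test_impossible_threshold_gives_empty_network():
    matrix = matrix_from([["1/2"]])
    network = build_network(matrix, edge_threshold=Fraction(101, 100))
    assert network.n_edges == 0 and network.nodes == {}


def test_edge_count_monotone_in_threshold():
    rng = random.Random(3)
    values = [[Fraction(rng.randint(0, 100), 100) for _ in range(8)] for _ in range(5)]
    matrix = matrix_from(values)
    counts = [build_network(matrix, edge_threshold=Fraction(t, 20)).n_edges
              for t in range(21)]
    assert counts == sorted(counts, reverse=True)


def test_selection_monotone_in_threshold():
    rng = random.Random(4)
    values = [[Fraction(rng.randint(0, 100), 100) for _ in range(10)] for _ in range(4)]
    matrix = matrix_from(values)
    selected = [sum(s.selected for s in
                    score_candidates(matrix, selection_threshold=Fraction(t, 20)))
                for t in range(21)]
    assert selected == sorted(selected, reverse=True)


def test_scores_agree_with_brute_force_mean():
    """all_knowns averaging equals a plain mean over the matrix column on
    50 random matrices."""
    rng = random.Random(5)
    for _ in range(50):
        n_known = rng.randint(1, 6)
        n_cand = rng.randint(1, 6)
        values = [[Fraction(rng.randint(0, 1000), 1000) for _ in range(n_cand)]
                  for _ in range(n_known)]
        matrix = matrix_from(values)
        for score in score_candidates(matrix):
            j = list(matrix.columns).index(score.candidate_id)
            expected = sum((row[j] for row in values), Fraction(0)) / n_known
            assert score.avg_tc == expected


def test_planted_library_recovery(default_library):
    library, truth = default_library
    matrix = pairwise_similarity(library)
    network = build_network(matrix, library=library)
    analog_ids = {t.candidate_id for t in truth if t.is_analog}
    decoy_ids = {t.candidate_id for t in truth if not t.is_analog}
    with_edges = {e.candidate_id for e in network.edges}
    assert analog_ids <= with_edges
    assert decoy_ids.isdisjoint(with_edges)


def test_graphml_round_trip(tmp_path, default_library):
    library, _ = default_library
    matrix = pairwise_similarity(library)
    scores = score_candidates(matrix)
    network = build_network(matrix, library=library)
    path = tmp_path / "net.graphml"
    export_network(network, scores, path, format="graphml")
    back = import_graphml(path)
    assert back.nodes == network.nodes
    assert sorted((e.known_id, e.candidate_id, e.tc) for e in back.edges) == \
        sorted((e.known_id, e.candidate_id, e.tc) for e in network.edges)
    assert back.threshold == network.threshold


def test_sif_format_contract(tmp_path):
    matrix = matrix_from([["1/2"]], index=["known1"], columns=["cand1"])
    network = build_network(matrix)
    path = tmp_path / "net.sif"
    export_network(network, None, path, format="sif")
    assert path.read_text() == "known1\ttc_sim\tcand1\n"


def test_export_node_roles_match_labels(tmp_path):
    matrix = matrix_from([["1/2", "3/5"], ["9/10", "1/5"]],
                         index=["k1", "k2"], columns=["c1", "c2"])
    network = build_network(matrix)
    path = tmp_path / "toy.graphml"
    export_network(network, None, path)
    back = import_graphml(path)
    assert {n: a["role"] for n, a in back.nodes.items()} == {
        "k1": KNOWN_ACTIVE, "k2": KNOWN_ACTIVE,
        "c1": "potential_active", "c2": "potential_active",
    }
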