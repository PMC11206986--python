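"""Activity-transfer similarity network and candidate scoring.

The screen connects known actives to candidates whose Tanimoto similarity
reaches the edge threshold (0.4 or higher), scores every candidate by its
average similarity to the known actives, and selects candidates whose
average strictly exceeds the selection threshold (greater than 0.4). The
two comparisons deliberately differ — inclusive for edges, strict for
selection — matching the screening rules this pipeline implements.

The similarity matrix is a pandas DataFrame of exact ``Fraction`` values:
rows are known-active ids, columns candidate ids (or a square all-pairs
grid in ``all_pairs`` mode).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd

from phytoscreen.errors import ValidationError
from phytoscreen.fingerprints import (
    DEFAULT_N_BITS,
    DEFAULT_RADIUS,
    compute_fingerprint,
    tanimoto,
)
from phytoscreen.library import KNOWN_ACTIVE, CompoundLibrary

DEFAULT_THRESHOLD = Fraction(2, 5)  # the screen's 0.4 cutoff, exact

ALL_KNOWNS = "all_knowns"
NEIGHBORS_ONLY = "neighbors_only"


@dataclass(frozen=True)
class SimilarityEdge:
    known_id: str
    candidate_id: str
    tc: Fraction


@dataclass(frozen=True)
class CandidateScore:
    candidate_id: str
    avg_tc: Fraction
    n_known_neighbors: int
    selected: bool
    rank: Optional[int] = None


@dataclass
class SimilarityNetwork:
    """Thresholded known↔candidate graph. Only compounds participating in
    at least one edge appear as nodes; isolated compounds stay in the score
    table but are dropped here, as a network viewer would show them."""

    nodes: dict[str, dict]  # id -> {"role": ..., "compound_class": ...}
    edges: list[SimilarityEdge]
    threshold: Fraction

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def pairwise_similarity(
    library: CompoundLibrary,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    use_chirality: bool = False,
    mode: str = "known_candidate",
) -> pd.DataFrame:
    """Tanimoto similarity grid between knowns (rows) and candidates
    (columns); ``mode="all_pairs"`` instead returns the square grid over
    every compound. Entries are exact Fractions."""
    fps = {
        r.compound_id: compute_fingerprint(
            r.smiles, radius=radius, n_bits=n_bits, use_chirality=use_chirality
        )
        for r in library
    }
    if mode == "all_pairs":
        ids = library.ids
        data = [[tanimoto(fps[a], fps[b]) for b in ids] for a in ids]
        return pd.DataFrame(data, index=ids, columns=ids, dtype=object)
    known_ids = [r.compound_id for r in library.known()]
    cand_ids = [r.compound_id for r in library.candidates()]
    if not known_ids or not cand_ids:
        raise ValidationError(
            f"library must contain at least one known active and one "
            f"candidate (got {len(known_ids)} known, {len(cand_ids)} candidate)"
        )
    data = [[tanimoto(fps[k], fps[c]) for c in cand_ids] for k in known_ids]
    return pd.DataFrame(data, index=known_ids, columns=cand_ids, dtype=object)


def score_candidates(
    matrix: pd.DataFrame,
    selection_threshold: Fraction = DEFAULT_THRESHOLD,
    averaging_mode: str = ALL_KNOWNS,
    neighbor_threshold: Fraction = DEFAULT_THRESHOLD,
) -> list[CandidateScore]:
    """Average-similarity score per candidate with strict selection.

    ``avg_tc`` is the arithmetic mean of the candidate's column, either
    over every known (default) or over its neighbors only — the knowns
    whose similarity reaches ``neighbor_threshold``. A candidate is
    selected iff ``avg_tc`` strictly exceeds ``selection_threshold``;
    selected candidates are ranked by ``avg_tc`` descending, ties broken
    by candidate id. A candidate with zero neighbors in ``neighbors_only``
    mode scores 0 and is never selected.
    """
    if matrix.empty:
        raise ValidationError("similarity matrix is empty")
    if averaging_mode not in (ALL_KNOWNS, NEIGHBORS_ONLY):
        raise ValidationError(f"unknown averaging_mode {averaging_mode!r}")
    selection_threshold = Fraction(selection_threshold)
    neighbor_threshold = Fraction(neighbor_threshold)
    scores = []
    for candidate_id in matrix.columns:
        column = [Fraction(v) for v in matrix[candidate_id]]
        neighbors = [v for v in column if v >= neighbor_threshold]
        pool = column if averaging_mode == ALL_KNOWNS else neighbors
        avg = sum(pool, Fraction(0)) / len(pool) if pool else Fraction(0)
        scores.append(CandidateScore(
            candidate_id=str(candidate_id),
            avg_tc=avg,
            n_known_neighbors=len(neighbors),
            selected=avg > selection_threshold,
        ))
    selected = sorted(
        (s for s in scores if s.selected),
        key=lambda s: (-s.avg_tc, s.candidate_id),
    )
    ranks = {s.candidate_id: i + 1 for i, s in enumerate(selected)}
    return [
        CandidateScore(s.candidate_id, s.avg_tc, s.n_known_neighbors,
                       s.selected, ranks.get(s.candidate_id))
        for s in scores
    ]


def build_network(
    matrix: pd.DataFrame,
    edge_threshold: Fraction = DEFAULT_THRESHOLD,
    library: Optional[CompoundLibrary] = None,
    scores: Optional[list[CandidateScore]] = None,
    restrict_to_selected: bool = False,
) -> SimilarityNetwork:
    """Build the thresholded network: an edge for every (known, candidate)
    pair whose similarity is at or above ``edge_threshold`` (inclusive).
    Nodes are the edge endpoints only. With ``restrict_to_selected`` the
    candidate columns are first limited to selected candidates."""
    if matrix.empty:
        raise ValidationError("similarity matrix is empty")
    edge_threshold = Fraction(edge_threshold)
    columns = list(matrix.columns)
    if restrict_to_selected:
        if scores is None:
            raise ValidationError("restrict_to_selected requires scores")
        keep = {s.candidate_id for s in scores if s.selected}
        columns = [c for c in columns if c in keep]
    classes = {}
    if library is not None:
        classes = {r.compound_id: r.compound_class for r in library}
    square = list(matrix.index) == list(matrix.columns)
    edges: list[SimilarityEdge] = []
    for known_id in matrix.index:
        for candidate_id in columns:
            if square and str(known_id) >= str(candidate_id):
                continue  # all-pairs grids are symmetric; keep one direction
            tc = Fraction(matrix.at[known_id, candidate_id])
            if tc >= edge_threshold:
                edges.append(SimilarityEdge(str(known_id), str(candidate_id), tc))
    def node_role(node_id: str) -> str:
        if square and library is not None:
            status = library.get(node_id).activity_status
            return KNOWN_ACTIVE if status == KNOWN_ACTIVE else "potential_active"
        known_set = set(map(str, matrix.index))
        return KNOWN_ACTIVE if node_id in known_set else "potential_active"

    nodes: dict[str, dict] = {}
    for edge in edges:
        for node_id in (edge.known_id, edge.candidate_id):
            nodes[node_id] = {
                "role": node_role(node_id),
                "compound_class": classes.get(node_id, "other"),
            }
    return SimilarityNetwork(nodes=nodes, edges=edges, threshold=edge_threshold)


def export_network(
    network: SimilarityNetwork,
    scores: Optional[list[CandidateScore]],
    path,
    format: str = "graphml",
) -> None:
    """Write the network as GraphML (node attributes ``role``, ``avg_tc``,
    ``compound_class``; edge attributes ``tc`` and exact ``tc_exact``) or
    as SIF lines ``knownId tc_sim candidateId``. GraphML files are
    re-importable by :func:`import_graphml`."""
    path = Path(path)
    avg = {s.candidate_id: s.avg_tc for s in scores} if scores else {}
    if format == "graphml":
        graph = nx.Graph(threshold=str(network.threshold))
        for node_id, attrs in sorted(network.nodes.items()):
            graph.add_node(
                node_id,
                role=attrs["role"],
                compound_class=attrs["compound_class"],
                avg_tc=float(avg.get(node_id, 0)),
                avg_tc_exact=str(avg.get(node_id, Fraction(0))),
            )
        for edge in network.edges:
            graph.add_edge(
                edge.known_id, edge.candidate_id,
                tc=float(edge.tc), tc_exact=str(edge.tc),
            )
        nx.write_graphml(graph, path)
    elif format == "sif":
        with open(path, "w") as handle:
            for edge in network.edges:
                handle.write(f"{edge.known_id}\ttc_sim\t{edge.candidate_id}\n")
    else:
        raise ValidationError(f"unknown export format {format!r}")


def import_graphml(path) -> SimilarityNetwork:
    """Read a network previously written by :func:`export_network`."""
    graph = nx.read_graphml(Path(path))
    nodes = {
        str(n): {"role": d.get("role", "potential_active"),
                 "compound_class": d.get("compound_class", "other")}
        for n, d in graph.nodes(data=True)
    }
    edges = []
    for u, v, d in graph.edges(data=True):
        tc = Fraction(d["tc_exact"]) if "tc_exact" in d else Fraction(d["tc"]).limit_denominator()
        known_id, candidate_id = (u, v)
        if nodes.get(v, {}).get("role") == KNOWN_ACTIVE and nodes.get(u, {}).get("role") != KNOWN_ACTIVE:
            known_id, candidate_id = v, u
        edges.append(SimilarityEdge(str(known_id), str(candidate_id), tc))
    threshold = Fraction(graph.graph.get("threshold", DEFAULT_THRESHOLD))
    return SimilarityNetwork(nodes=nodes, edges=edges, threshold=threshold)


def screening_summary(
    library: CompoundLibrary,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    use_chirality: bool = False,
    edge_threshold: Fraction = DEFAULT_THRESHOLD,
    selection_threshold: Fraction = DEFAULT_THRESHOLD,
    averaging_mode: str = ALL_KNOWNS,
) -> dict:
    """Headline screening quantities for one labelled library: the pair
    count at the edge threshold, the selected-candidate count and the
    top-ranked candidate's average similarity. Intended for comparing a
    run against externally reported screens; fingerprint-dialect choices
    (radius, length, chirality flags) shift these numbers, so they are
    reported rather than asserted anywhere."""
    matrix = pairwise_similarity(library, radius=radius, n_bits=n_bits,
                                 use_chirality=use_chirality)
    scores = score_candidates(matrix, selection_threshold=selection_threshold,
                              averaging_mode=averaging_mode,
                              neighbor_threshold=edge_threshold)
    net = build_network(matrix, edge_threshold=edge_threshold, library=library)
    top = min((s for s in scores if s.rank == 1), default=None,
              key=lambda s: s.rank or 0)
    return {
        "n_known": library.n_known,
        "n_candidate": library.n_candidate,
        "n_pairs_over_threshold": net.n_edges,
        "n_candidates_selected": sum(s.selected for s in scores),
        "top_candidate_id": top.candidate_id if top else None,
        "top_candidate_avg_tc": float(top.avg_tc) if top else None,
    }


def write_scores(
    scores: list[CandidateScore],
    path,
    available: Optional[dict[str, Optional[bool]]] = None,
) -> None:
    """Candidate-score TSV: id, avg_tc, neighbor count, selection, rank and
    the commercial-availability flag used as the screen's second criterion."""
    available = available or {}
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow([
            "candidate_id", "avg_tc", "avg_tc_exact",
            "n_known_neighbors", "selected", "rank", "available",
        ])
        for s in sorted(scores, key=lambda s: (s.rank is None, s.rank or 0, s.candidate_id)):
            flag = available.get(s.candidate_id)
            writer.writerow([
                s.candidate_id, f"{float(s.avg_tc):.6f}", str(s.avg_tc),
                s.n_known_neighbors, str(s.selected).lower(),
                s.rank if s.rank is not None else "",
                "" if flag is None else str(flag).lower(),
            ])
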