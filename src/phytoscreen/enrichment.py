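"""Hypergeometric over-representation analysis (ORA) with cross-source
top-k overlap.

Given a query gene list (the retained targets) and a named collection of
gene sets, each set is scored by the hypergeometric upper-tail probability

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

where N is the universe size, K the set size, n the effective query size
and k the observed overlap. p is computed in exact rational arithmetic
(``Fraction``); k = 0 gives p = 1 exactly. Results are ranked by -log10 p
and adjusted by the Benjamini–Hochberg step-up. Two differently labelled
collections (e.g. two pathway annotation sources) are compared by
intersecting their top-k set names after optional label normalization,
mirroring how screens reconcile the same pathway named differently by
different engines.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional, Sequence

from statsmodels.stats.multitest import multipletests

from phytoscreen.errors import ParseError, ValidationError

log = logging.getLogger(__name__)

_GREEK = {
    "α": "a", "β": "b", "γ": "g", "δ": "d", "ε": "e",
    "κ": "k", "λ": "l", "μ": "m", "σ": "s", "ω": "o",
}


@dataclass
class GeneSetCollection:
    """Named gene-symbol sets from one annotation source, plus the
    background universe (union of members unless supplied)."""

    source_label: str
    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        members = frozenset().union(*self.sets.values()) if self.sets else frozenset()
        if not self.universe:
            self.universe = members
        elif not members <= self.universe:
            raise ValidationError(
                f"{self.source_label}: set members outside the supplied universe: "
                f"{sorted(members - self.universe)[:5]}"
            )
        for name, mem in self.sets.items():
            if not mem:
                raise ValidationError(f"{self.source_label}: empty set {name!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int            # overlap size
    K: int            # gene-set size
    n: int            # effective query size (within the universe)
    N: int            # universe size
    p_value: float
    p_exact: Fraction
    q_value: float
    neg_log10_p: float
    overlap_members: tuple[str, ...]


def read_gmt(path, source_label: Optional[str] = None) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated as
    ``name<TAB>description<TAB>member...``. Duplicate members collapse;
    a line without at least one member is a parse error naming the line.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            members = [f.strip() for f in fields[2:] if f.strip()]
            if len(fields) < 3 or not members:
                raise ParseError(
                    f"{path.name}:{lineno}: gene set line needs name, "
                    f"description and at least one member"
                )
            name = fields[0].strip()
            if not name:
                raise ParseError(f"{path.name}:{lineno}: empty set name")
            sets[name] = frozenset(members)
    return GeneSetCollection(source_label or path.stem, sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            handle.write(f"{name}\t{collection.source_label}\t{members}\n")


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k):
        raise ValidationError(f"invalid hypergeometric instance N={N} K={K} n={n} k={k}")
    if k == 0:
        return Fraction(1)
    upper = min(K, n)
    numerator = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, upper + 1))
    return Fraction(numerator, math.comb(N, n))


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Over-representation of a query gene list in every set of a collection.

    Symbols outside the universe are dropped (with a logged count); an
    empty effective query is an error. ``ease`` applies the conservative
    EASE variant (score the overlap as k − 1). Results are sorted by
    p ascending, ties by set name; BH q-values are attached.
    """
    query_set = set(query)
    effective = query_set & collection.universe
    dropped = len(query_set) - len(effective)
    if dropped:
        log.info("%s: dropped %d query symbols outside the universe",
                 collection.source_label, dropped)
    if not effective:
        raise ValidationError(
            f"{collection.source_label}: no query symbols in the universe"
        )
    N = len(collection.universe)
    n = len(effective)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        overlap = effective & members
        k = len(overlap)
        k_scored = max(k - 1, 0) if ease else k
        p = hypergeom_upper_tail(N, len(members), n, k_scored)
        rows.append((name, k, len(members), overlap, p))
    rows.sort(key=lambda r: (r[4], r[0]))
    q_values = adjust_bh([float(r[4]) for r in rows])
    results = []
    for (name, k, K, overlap, p), q in zip(rows, q_values):
        p_float = float(p)
        results.append(EnrichmentResult(
            set_name=name, k=k, K=K, n=n, N=N,
            p_value=p_float, p_exact=p, q_value=q,
            neg_log10_p=-math.log10(p_float),
            overlap_members=tuple(sorted(overlap)),
        ))
    return results


def adjust_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values (monotone, q >= p, q <= 1)."""
    p_values = list(p_values)
    if not p_values:
        return []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"p-value {p} outside [0, 1]")
    return list(multipletests(p_values, method="fdr_bh")[1])


def normalize_set_name(name: str) -> str:
    """Normalize a pathway/disease label for cross-source matching:
    casefold, transliterate Greek letters, drop punctuation, and strip the
    trailing 'signaling pathway' / 'signaling' / 'pathway' qualifiers that
    annotation sources append inconsistently."""
    text = name.casefold()
    for greek, latin in _GREEK.items():
        text = text.replace(greek, latin)
    tokens = re.sub(r"[^a-z0-9]+", " ", text).split()
    while tokens and tokens[-1] in ("pathway", "signaling", "signalling"):
        tokens.pop()
    return " ".join(tokens)


def top_k_overlap(
    results_a: Sequence[EnrichmentResult],
    results_b: Sequence[EnrichmentResult],
    k: int = 5,
    name_matcher: str = "normalized",
) -> set[str]:
    """Intersect the top-k set names of two ranked result collections.

    Ranking is by ``neg_log10_p`` descending (ties by set name). In
    ``exact`` mode literal names are intersected; in ``normalized`` mode
    names are first passed through :func:`normalize_set_name` and the
    shared normalized keys are returned. A ``k`` beyond either collection
    falls back to the full collection with a logged warning.
    """
    if not results_a or not results_b:
        raise ValidationError("both result collections must be nonempty")
    if name_matcher not in ("exact", "normalized"):
        raise ValidationError(f"unknown name_matcher {name_matcher!r}")
    if k > len(results_a) or k > len(results_b):
        log.warning("top-k (k=%d) exceeds a collection size (%d, %d); using all",
                    k, len(results_a), len(results_b))

    def top_names(results: Sequence[EnrichmentResult]) -> list[str]:
        ranked = sorted(results, key=lambda r: (-r.neg_log10_p, r.set_name))
        return [r.set_name for r in ranked[:k]]

    names_a, names_b = top_names(results_a), top_names(results_b)
    if name_matcher == "exact":
        return set(names_a) & set(names_b)
    return {normalize_set_name(a) for a in names_a} & {normalize_set_name(b) for b in names_b}


def write_enrichment(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w") as handle:
        handle.write("set_name\tk\tK\tn\tN\tp\tp_exact\tq\tneg_log10_p\toverlap_members\n")
        for r in results:
            handle.write(
                f"{r.set_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p_value:.6g}\t{r.p_exact}\t{r.q_value:.6g}\t"
                f"{r.neg_log10_p:.6g}\t{','.join(r.overlap_members)}\n"
            )
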