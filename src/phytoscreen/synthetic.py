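"""Synthetic benchmark data with planted, generation-verified structure.

Every stage of the screen is testable offline against libraries whose
ground truth is known by construction:

* **Libraries** are built from a fragment grammar — flavonoid-like cores
  (chromen-4-one scaffolds with two substitution sites) for the active
  family, plain aliphatic chains/rings for the decoy family — rather than
  random SMILES, which rarely parse and have degenerate fingerprints.
  Known actives are decorated scaffolds; planted analogs reuse a parent
  known's scaffold with one substituent swapped; decoys come from the
  disjoint aliphatic family. The generator *proves* its planted design
  before returning: each analog's Tanimoto similarity to its parent must
  reach 0.4 and its average over all knowns must exceed 0.4, and each
  decoy's maximum similarity to any known must stay below 0.4 —
  structures failing verification are redrawn (bounded attempts).
* **Prediction tables** plant targets supported by ≥3 compounds with
  scores drawn above the 0.1 filter, against background targets that fail
  the support filter, the score filter, or both.
* **Gene-set collections** come in pairs emulating two annotation sources
  that label the same planted pathway differently; the planted set is
  verified to rank first in both sources' over-representation results.

All draws come from one seeded ``random.Random`` per spec: the same spec
yields byte-identical outputs on any platform.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import NamedTuple, Optional

from phytoscreen.errors import GenerationError, ValidationError
from phytoscreen.fingerprints import compute_fingerprint, tanimoto
from phytoscreen.library import (
    CANDIDATE,
    KNOWN_ACTIVE,
    CompoundLibrary,
    CompoundRecord,
    canonical_smiles,
)
from phytoscreen.targets import TargetPrediction, TargetSet
from phytoscreen.enrichment import GeneSetCollection, normalize_set_name, ora

SELECTION_TC = Fraction(2, 5)
_MAX_ATTEMPTS = 200

#: Chromen-4-one (flavone/isoflavone-like) cores with two substitution
#: sites — the active family all knowns and analogs are drawn from.
DEFAULT_SCAFFOLDS = (
    "O=c1cc(-c2ccc({R1})cc2)oc2cc({R2})ccc12",
    "O=c1c(-c2ccc({R1})cc2)coc2cc({R2})ccc12",
    "O=c1cc(-c2ccc({R1})cc2)oc2c({R2})cccc12",
)

#: Small substituents valid inside an aromatic-carbon branch.
DEFAULT_DECORATIONS = ("O", "OC", "C", "CC", "N", "Cl", "F", "OCC", "C(C)C")

#: A bulky deoxy-sugar substituent; swapping it in moves an analog far
#: from its parent — used by the decoration-distance sweep.
BULKY_DECORATION = "O[C@@H]9O[C@H](C)[C@@H](O)[C@H](O)[C@H]9O"  # ring digit 9: scaffold digits 1-2 are open at the insertion point

#: Aliphatic decoy family: no aromatic rings, no carbonyl-on-ring — a
#: fingerprint neighborhood disjoint from the flavonoid cores.
DEFAULT_DECOY_SCAFFOLDS = (
    "CCCCC{R}",
    "CC(C)CCC{R}",
    "C1CCCCC1{R}",
    "CCCSC{R}",
    "CCCCOC{R}",
    "CC(C)(C)CC{R}",
)
DEFAULT_DECOY_DECORATIONS = ("C", "CC", "CCC", "O", "N", "CCO", "C(C)C")


@dataclass(frozen=True)
class LibrarySpec:
    """Recipe for one synthetic library; a pure function of its fields."""

    n_known: int = 5
    n_analog: int = 10
    n_decoy: int = 10
    scaffold_pool: tuple[str, ...] = DEFAULT_SCAFFOLDS
    decoration_pool: tuple[str, ...] = DEFAULT_DECORATIONS
    decoy_scaffold_pool: tuple[str, ...] = DEFAULT_DECOY_SCAFFOLDS
    decoy_decoration_pool: tuple[str, ...] = DEFAULT_DECOY_DECORATIONS
    #: 1 = swap one substituent (the verified planted design); 2 = swap
    #: both substituents; 3 = bulky sugar at one site, random swap at the
    #: other; 4 = as 3 but on a different core from the scaffold pool.
    #: Larger distance -> lower similarity to the parent known.
    analog_distance: int = 1
    seed: int = 1


class TruthRecord(NamedTuple):
    candidate_id: str
    is_analog: bool
    parent_id: Optional[str]  # parent known for analogs, None for decoys


class LibraryTruth(NamedTuple):
    library: CompoundLibrary
    truth: list[TruthRecord]


def _decorate(scaffold: str, r1: str, r2: str) -> str:
    return scaffold.format(R1=r1, R2=r2)


def generate_library(spec: LibrarySpec) -> LibraryTruth:
    """Generate a known/analog/decoy library with verified planted truth."""
    if spec.n_known < 1 and (spec.n_analog or spec.n_decoy):
        raise ValidationError("analogs/decoys require at least one known")
    if not spec.scaffold_pool or not spec.decoration_pool:
        raise ValidationError("scaffold and decoration pools must be nonempty")
    if spec.analog_distance not in (1, 2, 3, 4):
        raise ValidationError("analog_distance must be 1..4")
    rng = random.Random(spec.seed)
    scaffold = rng.choice(spec.scaffold_pool)  # one chemotype per library
    combos = list(product(spec.decoration_pool, repeat=2))
    if spec.n_known > len(combos):
        raise ValidationError("decoration pool too small for n_known")
    known_combos = rng.sample(combos, spec.n_known)

    records: list[CompoundRecord] = []
    truth: list[TruthRecord] = []
    seen_structures: set[str] = set()
    known_fps = {}
    for i, (r1, r2) in enumerate(known_combos, start=1):
        cid = f"K{i:02d}"
        smiles = canonical_smiles(_decorate(scaffold, r1, r2))
        if smiles in seen_structures:
            raise GenerationError("duplicate known structure; enlarge pools")
        seen_structures.add(smiles)
        known_fps[cid] = compute_fingerprint(smiles)
        records.append(CompoundRecord(
            compound_id=cid, smiles=smiles, name=f"known active {i}",
            compound_class="flavonoid", activity_status=KNOWN_ACTIVE,
            commercially_available=rng.random() < 0.7,
            provenance="synthetic: decorated active-family scaffold",
        ))

    def avg_tc(fp) -> Fraction:
        values = [tanimoto(fp, kfp) for kfp in known_fps.values()]
        return sum(values, Fraction(0)) / len(values)

    for i in range(1, spec.n_analog + 1):
        cid = f"A{i:02d}"
        parent_idx = (i - 1) % spec.n_known
        parent_id = f"K{parent_idx + 1:02d}"
        pr1, pr2 = known_combos[parent_idx]
        for attempt in range(_MAX_ATTEMPTS):
            r1, r2 = pr1, pr2
            site = rng.randrange(2)
            distance = spec.analog_distance
            swap = BULKY_DECORATION if distance >= 3 else rng.choice(spec.decoration_pool)
            if site == 0:
                r1 = swap
            else:
                r2 = swap
            if distance >= 2:
                other = rng.choice(spec.decoration_pool)
                if site == 0:
                    r2 = other
                else:
                    r1 = other
            core = scaffold
            if distance == 4 and len(spec.scaffold_pool) > 1:
                core = rng.choice([s for s in spec.scaffold_pool if s != scaffold])
            if (core, r1, r2) == (scaffold, pr1, pr2):
                continue
            smiles = canonical_smiles(_decorate(core, r1, r2))
            if smiles in seen_structures:
                continue
            fp = compute_fingerprint(smiles)
            if spec.analog_distance == 1:
                # planted design: analog must be recoverable by the screen
                if tanimoto(fp, known_fps[parent_id]) < SELECTION_TC:
                    continue
                if avg_tc(fp) <= SELECTION_TC:
                    continue
            break
        else:
            raise GenerationError(
                f"could not generate analog {cid} satisfying the planted "
                f"design after {_MAX_ATTEMPTS} attempts (spec={spec})"
            )
        seen_structures.add(smiles)
        records.append(CompoundRecord(
            compound_id=cid, smiles=smiles, name=f"planted analog {i}",
            compound_class="flavonoid", activity_status=CANDIDATE,
            commercially_available=rng.random() < 0.7,
            provenance=f"synthetic: analog of {parent_id}",
        ))
        truth.append(TruthRecord(cid, True, parent_id))

    for i in range(1, spec.n_decoy + 1):
        cid = f"D{i:02d}"
        for attempt in range(_MAX_ATTEMPTS):
            template = rng.choice(spec.decoy_scaffold_pool)
            deco = rng.choice(spec.decoy_decoration_pool)
            smiles = canonical_smiles(template.format(R=deco))
            if smiles in seen_structures:
                continue
            fp = compute_fingerprint(smiles)
            if known_fps and max(tanimoto(fp, kfp) for kfp in known_fps.values()) >= SELECTION_TC:
                continue
            break
        else:
            raise GenerationError(
                f"could not generate decoy {cid} dissimilar to every known "
                f"after {_MAX_ATTEMPTS} attempts (spec={spec})"
            )
        seen_structures.add(smiles)
        records.append(CompoundRecord(
            compound_id=cid, smiles=smiles, name=f"decoy {i}",
            compound_class="hydrocarbon", activity_status=CANDIDATE,
            commercially_available=rng.random() < 0.7,
            provenance="synthetic: decoy-family structure",
        ))
        truth.append(TruthRecord(cid, False, None))

    return LibraryTruth(CompoundLibrary(records), truth)


@dataclass(frozen=True)
class PredictionSpec:
    """Recipe for synthetic target-prediction tables."""

    n_targets: int = 20
    n_planted: int = 3
    #: planted supports draw scores from this range (above the 0.1 filter)
    planted_score_range: tuple[float, float] = (0.15, 0.9)
    #: background targets draw from this low-score range
    background_score_range: tuple[float, float] = (0.0, 0.08)
    seed: int = 1


class PredictionTruth(NamedTuple):
    predictions: list[TargetPrediction]
    planted_symbols: tuple[str, ...]


def generate_predictions(library: CompoundLibrary, spec: PredictionSpec) -> PredictionTruth:
    """Prediction tables whose planted targets pass the retention filters
    by construction and whose background targets fail them.

    Background targets alternate between the two failure modes: broad
    support with sub-threshold scores (mean filter fails) and high scores
    from at most two compounds (support filter fails).
    """
    if len(library) == 0:
        raise ValidationError("library is empty")
    if spec.n_planted > spec.n_targets:
        raise ValidationError("n_planted exceeds n_targets")
    rng = random.Random(spec.seed)
    ids = library.ids
    predictions: list[TargetPrediction] = []
    planted: list[str] = []
    lo_p, hi_p = spec.planted_score_range
    lo_b, hi_b = spec.background_score_range
    for t in range(1, spec.n_targets + 1):
        symbol = f"G{t:03d}"
        if t <= spec.n_planted:
            planted.append(symbol)
            n_support = rng.randint(3, min(5, len(ids))) if len(ids) >= 3 else len(ids)
            supporters = rng.sample(ids, n_support)
            score_range = (max(lo_p, 0.11), hi_p)
        elif t % 2 == 0:
            supporters = rng.sample(ids, min(rng.randint(3, 5), len(ids)))
            score_range = (lo_b, min(hi_b, 0.099))
        else:
            supporters = rng.sample(ids, min(rng.randint(1, 2), len(ids)))
            score_range = (0.2, 0.9)
        for cid in sorted(supporters):
            predictions.append(TargetPrediction(
                compound_id=cid, gene_symbol=symbol,
                score=round(rng.uniform(*score_range), 4),
                target_name=f"synthetic target {symbol}",
                uniprot_id=f"P{10000 + t}",
            ))
    return PredictionTruth(predictions, tuple(planted))


@dataclass(frozen=True)
class GenesetSpec:
    """Recipe for a pair of gene-set collections with one planted set."""

    n_sets: int = 8
    set_size_range: tuple[int, int] = (5, 12)
    planted_name: str = "Hypoxia Response"
    seed: int = 1


class GenesetTruth(NamedTuple):
    source_a: GeneSetCollection
    source_b: GeneSetCollection
    planted_key: str  # normalized name shared by both sources


def generate_genesets(target_set: TargetSet, spec: GenesetSpec) -> GenesetTruth:
    """Two collections emulating independent annotation sources.

    Both contain the planted set — seeded with the retained target
    symbols but labelled in each source's house style ("<name> Signaling"
    vs "<name> signaling pathway") — plus background sets that share at
    most one retained symbol, so over-representation ranks the planted
    set first in both sources. Verified by running the test at
    generation time.
    """
    retained = target_set.retained_symbols
    if not retained:
        raise ValidationError("target set has no retained targets")
    rng = random.Random(spec.seed)
    lo, hi = spec.set_size_range
    background_pool = [f"BG{i:03d}" for i in range(1, 200)]

    def make_collection(label: str, planted_label: str, style) -> GeneSetCollection:
        sets: dict[str, frozenset[str]] = {}
        size = max(lo, min(hi, len(retained) + rng.randint(0, 3)))
        filler = rng.sample(background_pool, max(0, size - len(retained)))
        sets[planted_label] = frozenset(retained[:size] + filler)
        for i in range(1, spec.n_sets):
            members = set(rng.sample(background_pool, rng.randint(lo, hi)))
            if rng.random() < 0.5:  # background sets touch the query barely
                members.add(rng.choice(retained))
            sets[style(i)] = frozenset(members)
        return GeneSetCollection(label, sets)

    for attempt in range(_MAX_ATTEMPTS):
        name_a = f"{spec.planted_name} Signaling"
        name_b = f"{spec.planted_name.lower()} signaling pathway"
        source_a = make_collection("source-A", name_a,
                                   lambda i: f"Alpha Process {i:02d} Signaling")
        source_b = make_collection("source-B", name_b,
                                   lambda i: f"beta process {i:02d} pathway")
        ranked_a = ora(retained, source_a)
        ranked_b = ora(retained, source_b)
        if ranked_a[0].set_name == name_a and ranked_b[0].set_name == name_b:
            return GenesetTruth(source_a, source_b, normalize_set_name(name_a))
    raise GenerationError(
        f"planted set failed to rank first after {_MAX_ATTEMPTS} attempts "
        f"(spec={spec})"
    )


def write_benchmark(
    out_dir,
    library_spec: Optional[LibrarySpec] = None,
    prediction_spec: Optional[PredictionSpec] = None,
    geneset_spec: Optional[GenesetSpec] = None,
) -> dict:
    """Generate the full benchmark and write it in the formats the
    pipeline reads; returns the paths plus the planted truth."""
    from pathlib import Path

    from phytoscreen.library import write_compound_table
    from phytoscreen.enrichment import write_gmt
    from phytoscreen.targets import aggregate_and_filter

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    library_spec = library_spec or LibrarySpec()
    prediction_spec = prediction_spec or PredictionSpec(seed=library_spec.seed)
    geneset_spec = geneset_spec or GenesetSpec(seed=library_spec.seed)

    library, truth = generate_library(library_spec)
    write_compound_table(library, out / "library.csv")
    with open(out / "truth.tsv", "w") as handle:
        handle.write("candidate_id\tis_analog\tparent_id\n")
        for rec in truth:
            handle.write(f"{rec.candidate_id}\t{str(rec.is_analog).lower()}\t"
                         f"{rec.parent_id or ''}\n")
    with open(out / "known_ids.txt", "w") as handle:
        for record in library.known():
            handle.write(record.compound_id + "\n")

    predictions, planted = generate_predictions(library, prediction_spec)
    with open(out / "predictions.csv", "w") as handle:
        handle.write("compound_id,target_name,gene_symbol,uniprot_id,score\n")
        for p in predictions:
            handle.write(f"{p.compound_id},{p.target_name},{p.gene_symbol},"
                         f"{p.uniprot_id},{p.score}\n")

    target_set = aggregate_and_filter(predictions)
    genesets = generate_genesets(target_set, geneset_spec)
    write_gmt(genesets.source_a, out / "source_a.gmt")
    write_gmt(genesets.source_b, out / "source_b.gmt")
    return {
        "library": str(out / "library.csv"),
        "known_ids": str(out / "known_ids.txt"),
        "predictions": str(out / "predictions.csv"),
        "gmt_a": str(out / "source_a.gmt"),
        "gmt_b": str(out / "source_b.gmt"),
        "truth": truth,
        "planted_targets": planted,
        "planted_key": genesets.planted_key,
    }
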