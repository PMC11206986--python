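# Methods

## Screening model

The screen is a guilt-by-association argument made quantitative: if an
untested compound shares enough substructure with compounds of
demonstrated activity, it inherits a testable activity hypothesis. The
chain is

1. **library curation** — parse SMILES, canonicalize (isomeric canonical
   SMILES; stereochemistry is kept because sugar configuration
   distinguishes many natural-product glycosides), optionally strip to
   the largest organic fragment (salts/solvates), merge structural
   duplicates (first-seen id wins), and partition into known actives vs
   candidates from a supplied id list;
2. **similarity scoring** — ECFP4 fingerprints (Morgan radius 2, 2048
   bits, binary, chirality flags off by default), Tanimoto coefficient
   between every known–candidate pair;
3. **selection** — a candidate is selected when its mean similarity over
   the knowns strictly exceeds 0.4; known–candidate pairs at Tc ≥ 0.4
   form the interaction network (isolated compounds are dropped from
   network exports but kept in the score table);
4. **target filtering** — per gene symbol, mean prediction score over
   the supporting compounds > 0.1 (strict) and supporting-compound count
   > 2 (strict, i.e. ≥ 3);
5. **enrichment** — hypergeometric upper tail per gene set, BH q-values,
   ranking by −log10 p, and intersection of two sources' top-5 names
   after label normalization.

### Threshold semantics

The two 0.4 comparisons intentionally differ: edge membership is
inclusive (≥ 0.4), selection is strict (> 0.4). The target filters are
both strict. These boundaries are enforced in exact arithmetic:
similarities are integer-count `Fraction`s, and the target-score mean is
computed over decimal (string-parsed) fractions, so a mean of exactly
0.1 — unrepresentable in binary floating point — is excluded rather
than passing on round-off. p-values are exact rationals converted to
float only for display and BH adjustment.

### Averaging modes

The default candidate score averages over *all* knowns. A
`neighbors_only` mode (mean over knowns at Tc ≥ the edge threshold;
zero neighbors ⇒ score 0, never selected) is provided because a
published per-candidate similarity could plausibly be either average;
both are reported side by side in the score table via the neighbor
count column.

### Name normalization

Cross-source overlap casefolds labels, transliterates Greek letters,
strips punctuation, and removes trailing "pathway"/"signaling"
qualifiers greedily. Stripping only the literal two-word suffix
"signaling pathway" would leave "X signaling" vs "X signaling pathway"
unmatched, which is precisely the case the normalization exists for; an
`exact` mode is available when both sources share a namespace.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `radius` / `n_bits` | 2 / 2048 | Morgan radius (ECFP4 = diameter 4) and fold length; 2048 is the dominant convention, configurable because published screens rarely state it |
| `use_chirality` | off | chirality flags in atom invariants; conventions differ between toolchains |
| `edge_tc` | 0.4 (inclusive) | network edge threshold |
| `selection_avg_tc` | 0.4 (strict) | candidate selection threshold |
| `target_score` | 0.1 (strict) | minimum mean prediction score |
| `target_support` | 2 (strict) | supporting compounds must exceed this |
| `top_k` | 5 | per-source list depth for the overlap rule |
| `ease` | off | EASE variant (score overlap as k−1), the more conservative Fisher-style reading some engines use |
| universe | union of collection members | background for the hypergeometric test; user-suppliable |

## Synthetic benchmark

The generator emulates the statistical structure the screen assumes,
not real phytochemistry:

- **Actives** are chromen-4-one (flavone/isoflavone-like) cores with two
  substitution sites decorated from a small fragment pool; one core per
  library, mirroring a chemotaxonomically coherent herb library and
  keeping cross-known similarities high enough that the all-knowns
  average is meaningful.
- **Planted analogs** reuse a parent known's core with one substituent
  swapped. The generator verifies, before returning, that each analog's
  Tc to its parent is ≥ 0.4 *and* its average over all knowns is > 0.4,
  redrawing up to a bounded attempt count — the planted property is
  proven at generation time, not assumed by tests.
- **Decoys** are aliphatic chains/rings with no aromatic system;
  verified max Tc to any known < 0.4.
- **Decoration distance** (1–4) moves analogs away from their parents:
  one swap, two swaps, a bulky deoxy-sugar swap, and the sugar swap on a
  different core. Selection sensitivity is monotone non-increasing along
  this sweep and collapses at distance 4.
- **Prediction tables** plant targets supported by ≥ 3 compounds with
  scores in (0.15, 0.9); background targets fail either the mean filter
  (broad support, scores < 0.1) or the support filter (≤ 2 compounds,
  high scores), exercising both rejection paths.
- **Gene-set pairs** plant one set seeded with the retained targets in
  both collections under different label styles; background sets share
  at most one query symbol. The generator verifies the planted set ranks
  first in both sources' ORA before returning.

Default sizes — 5 knowns, 10 analogs, 10 decoys, 20 targets (3 planted),
8 sets per source, seed 1 — are the benchmark's study conditions; they
are deliberately desk-scale and are what the analysis scripts, tests and
acceptance script all run.

What passing on this benchmark does **not** show: recovery rates on real
herbal libraries, where activity annotations are noisy, chemotypes are
mixed, salt/tautomer states vary, and prediction scores correlate across
structurally similar compounds. The benchmark demonstrates mechanical
correctness and threshold behavior of the screen, not field performance.
Headline numbers from a published screen (pair counts, selected-compound
counts) additionally depend on the exact input structure list and the
fingerprint dialect; the `screening_summary` helper reports those
quantities for comparison without asserting them.

## Numerical and design choices

- Tanimoto of two empty fingerprints is defined as 0 (the formula is
  0/0); featureless structures are never "similar".
- Ranking ties (equal average Tc, equal p) break lexicographically by
  id/name for determinism.
- All generator randomness flows from one `random.Random(seed)` per
  spec; no global state, no float accumulation in structural choices, so
  outputs are byte-identical across platforms.
- GraphML exports carry both a float `tc` and an exact `tc_exact`
  fraction string so re-imports reproduce the exact edge weights.
- Records that fail SMILES parsing are excluded with a per-row rejection
  report rather than aborting — unresolved entries are routine in herbal
  libraries.
- BH adjustment delegates to the standard step-up implementation in
  statsmodels; the hypergeometric tail is computed in-package because
  the exactness contract (rational equality with enumeration) is part of
  the design, with scipy's survival function as an independent
  cross-check in the tests.
- The pipeline writes a timestamped report and a timestamp-free
  `report_body.json`; determinism checks compare the latter.

## Known limitations

- Counted fingerprints, 3D/pharmacophore descriptors and alternative
  similarity coefficients are out of scope.
- The hypergeometric ORA is a generic stand-in for proprietary
  enrichment engines; with identical gene sets and universe it gives the
  standard Fisher one-sided result, but it cannot reproduce
  engine-specific pathway definitions or counts.
- Commercial availability is an input flag filtered after ranking, never
  inferred.
- No online structure resolution (CAS or otherwise); all structures
  must arrive as SMILES/SDF.
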