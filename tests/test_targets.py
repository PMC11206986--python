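"""Target-prediction parsing, aggregation and the two retention filters."""

import random
from fractions import Fraction

import pytest

from phytoscreen.errors import ConfigurationError, ValidationError
from phytoscreen.targets import (
    TargetPrediction,
    aggregate_and_filter,
    read_target_predictions,
)


def write_predictions(path, rows, header="compound_id,gene_symbol,score"):
    path.write_text("\n".join([header] + [",".join(map(str, r)) for r in rows]) + "\n")
    return path


def test_reads_valid_rows(tmp_path):
    path = write_predictions(tmp_path / "p.csv", [
        ("c1", "EGFR", 0.5), ("c1", "ESR1", 0.3), ("c2", "EGFR", 0.2),
    ])
    predictions, rejected = read_target_predictions(path)
    assert len(predictions) == 3
    assert rejected == []


def test_duplicate_pair_collapses_to_max_score(tmp_path):
    path = write_predictions(tmp_path / "p.csv", [
        ("cX", "EGFR", 0.2), ("cX", "EGFR", 0.6),
    ])
    predictions, _ = read_target_predictions(path)
    assert len(predictions) == 1
    assert predictions[0].score == 0.6


def test_out_of_range_score_rejected(tmp_path):
    path = write_predictions(tmp_path / "p.csv", [
        ("c1", "EGFR", 1.7), ("c1", "ESR1", 0.3),
    ])
    predictions, rejected = read_target_predictions(path)
    assert [p.gene_symbol for p in predictions] == ["ESR1"]
    assert "outside [0, 1]" in rejected[0][2]


def test_missing_column_is_configuration_error(tmp_path):
    path = tmp_path / "p.csv"
    path.write_text("compound_id,foo\nc1,x\n")
    with pytest.raises(ConfigurationError):
        read_target_predictions(path)


def test_service_export_dialect_recognized(tmp_path):
    """The common prediction-service export headers work out of the box."""
    path = tmp_path / "c9.csv"
    path.write_text('Target,Common name,Uniprot ID,Probability*\n'
                    'Estrogen receptor,ESR1,P03372,0.71\n')
    predictions, _ = read_target_predictions(path, compound_id="c9")
    (pred,) = predictions
    assert (pred.compound_id, pred.gene_symbol, pred.uniprot_id, pred.score) == \
        ("c9", "ESR1", "P03372", 0.71)


def predictions_of(mapping):
    return [TargetPrediction(cid, gene, score)
            for gene, pairs in mapping.items() for cid, score in pairs]


def test_retention_filter_analytic_cases():
    preds = predictions_of({
        # mean 0.1333 from 3 compounds -> retained
        "T_IN": [("a", 0.2), ("b", 0.05), ("c", 0.15)],
        # high scores but only 2 compounds -> excluded ("more than two")
        "T_SUPPORT": [("a", 0.5), ("b", 0.5)],
        # mean exactly 0.1 -> excluded (strict "greater than")
        "T_MEAN": [("a", 0.1), ("b", 0.1), ("c", 0.1)],
    })
    records = {r.gene_symbol: r for r in aggregate_and_filter(preds).records}
    assert records["T_IN"].retained
    assert records["T_IN"].mean_score == pytest.approx(0.4 / 3)
    assert not records["T_SUPPORT"].retained
    assert not records["T_MEAN"].retained
    assert records["T_MEAN"].n_supporting_compounds == 3


def test_aggregation_is_order_independent():
    preds = predictions_of({
        "A": [("x", 0.4), ("y", 0.2), ("z", 0.9)],
        "B": [("x", 0.05), ("y", 0.02)],
    })
    base = aggregate_and_filter(preds)
    for seed in range(5):
        shuffled = list(preds)
        random.Random(seed).shuffle(shuffled)
        assert aggregate_and_filter(shuffled) == base


def test_empty_input_is_error():
    with pytest.raises(ValidationError):
        aggregate_and_filter([])


def test_retained_set_monotone_in_both_thresholds():
    rng = random.Random(11)
    preds = []
    for t in range(30):
        for c in rng.sample(range(12), rng.randint(1, 6)):
            preds.append(TargetPrediction(f"c{c}", f"T{t}", round(rng.random(), 3)))
    base_kwargs = dict(score_threshold=0.1, support_threshold=2)
    n_base = len(aggregate_and_filter(preds, **base_kwargs).retained_symbols)
    for score_thr in (0.2, 0.4, 0.8):
        n = len(aggregate_and_filter(preds, score_threshold=score_thr,
                                     support_threshold=2).retained_symbols)
        assert n <= n_base
    for support_thr in (3, 4, 6):
        n = len(aggregate_and_filter(preds, score_threshold=0.1,
                                     support_threshold=support_thr).retained_symbols)
        assert n <= n_base


def test_matches_brute_force_group_and_average():
    """Equivalence with an independent group-by/mean computation on 50
    random prediction tables (max-collapse applied first in both)."""
    for seed in range(50):
        rng = random.Random(seed)
        preds = [TargetPrediction(f"c{rng.randint(0, 5)}", f"T{rng.randint(0, 8)}",
                                  round(rng.random(), 3))
                 for _ in range(rng.randint(1, 40))]
        # brute force: dict of gene -> {compound: max score}
        table: dict[str, dict[str, float]] = {}
        for p in preds:
            row = table.setdefault(p.gene_symbol, {})
            row[p.compound_id] = max(row.get(p.compound_id, 0.0), p.score)
        result = aggregate_and_filter(preds)
        assert len(result.records) == len(table)
        for record in result.records:
            row = table[record.gene_symbol]
            exact_mean = sum(Fraction(str(v)) for v in row.values()) / len(row)
            assert record.n_supporting_compounds == len(row)
            assert record.mean_score == pytest.approx(float(exact_mean))
            assert record.retained == (
                exact_mean > Fraction(1, 10) and len(row) > 2
            )


def test_filter_order_does_not_matter():
    """Applying the support filter before or after averaging is the same,
    because the mean is over supporting compounds only."""
    rng = random.Random(21)
    preds = [TargetPrediction(f"c{rng.randint(0, 6)}", f"T{rng.randint(0, 5)}",
                              round(rng.random(), 3)) for _ in range(60)]
    full = aggregate_and_filter(preds)
    # support-first: drop genes with <=2 compounds, then aggregate the rest
    survivors = {r.gene_symbol for r in full.records if r.n_supporting_compounds > 2}
    refiltered = aggregate_and_filter(
        [p for p in preds if p.gene_symbol in survivors])
    assert refiltered.retained_symbols == full.retained_symbols
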