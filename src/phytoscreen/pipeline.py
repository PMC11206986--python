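"""End-to-end orchestration: curate -> fingerprint/network -> targets -> enrich.

Each stage writes its outputs under the configured output directory, so
any stage can be re-run from the previous stage's files; the run report
records every filter's in/out counts, making the screening funnel
(library size -> pairs over threshold -> selected candidates -> retained
targets -> top-k overlap) auditable. Identical config and inputs yield
byte-identical outputs (the single timestamp line in the report is the
only exception).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from fractions import Fraction
from pathlib import Path
from typing import Optional

from phytoscreen.config import RunConfig
from phytoscreen.enrichment import ora, read_gmt, top_k_overlap, write_enrichment
from phytoscreen.errors import ValidationError
from phytoscreen.library import (
    CompoundLibrary,
    canonicalize_and_dedup,
    label_activity,
    read_compound_table,
    write_compound_table,
    write_rejection_report,
)
from phytoscreen.network import (
    build_network,
    export_network,
    pairwise_similarity,
    score_candidates,
    write_scores,
)
from phytoscreen.targets import (
    aggregate_and_filter,
    read_prediction_directory,
    read_target_predictions,
    write_target_set,
)

log = logging.getLogger(__name__)

_version = "0.1.0"


@dataclass
class RunReport:
    """Per-stage record counts plus the config echo."""

    config: dict
    version: str = _version
    counts: dict = field(default_factory=dict)
    top_overlap: list = field(default_factory=list)

    def validate(self) -> None:
        c = self.counts
        if c.get("candidates_selected", 0) > c.get("candidates", 0):
            raise ValidationError("selected candidates exceed candidate count")
        if c.get("targets_retained", 0) > c.get("targets_distinct", 0):
            raise ValidationError("retained targets exceed distinct targets")

    def to_json(self, timestamp: bool = True) -> str:
        body = {
            "version": self.version,
            "config": self.config,
            "counts": self.counts,
            "top_overlap": self.top_overlap,
        }
        if timestamp:
            body["generated_at"] = datetime.now(timezone.utc).isoformat()
        return json.dumps(body, indent=2, sort_keys=True) + "\n"


def _read_known_ids(path) -> set[str]:
    with open(path) as handle:
        return {line.strip() for line in handle if line.strip()}


def run_pipeline(config: RunConfig, library: Optional[CompoundLibrary] = None) -> RunReport:
    """Execute all stages in order; returns the run report.

    ``library`` may be passed in memory (e.g. fresh from the synthetic
    generator); otherwise it is read from ``config.library``. Stage
    outputs land under ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())

    # --- stage 1: curate -------------------------------------------------
    if library is None:
        if not config.library:
            raise ValidationError("no library path configured and none supplied")
        ingest = read_compound_table(config.library)
        library = ingest.library
        write_rejection_report(ingest.rejected, out / "rejected_compounds.tsv")
        report.counts["compounds_rejected"] = len(ingest.rejected)
    else:
        report.counts["compounds_rejected"] = 0
    report.counts["compounds_read"] = len(library)
    curated, merged = canonicalize_and_dedup(
        library, strip_salts=config.strip_salts, dedup=config.dedup
    )
    report.counts["compounds_merged"] = sum(len(v) for v in merged.values())
    if config.known_ids:
        curated = label_activity(curated, _read_known_ids(config.known_ids))
    report.counts["compounds_curated"] = len(curated)
    report.counts["known_actives"] = curated.n_known
    report.counts["candidates"] = curated.n_candidate
    write_compound_table(curated, out / "curated_library.csv")
    log.info("curate: %d read, %d curated (%d known, %d candidate)",
             report.counts["compounds_read"], len(curated),
             curated.n_known, curated.n_candidate)

    # --- stage 2: similarity network ------------------------------------
    matrix = pairwise_similarity(
        curated, radius=config.radius, n_bits=config.n_bits,
        use_chirality=config.use_chirality,
    )
    scores = score_candidates(
        matrix,
        selection_threshold=Fraction(config.selection_avg_tc).limit_denominator(10**6),
        averaging_mode=config.averaging_mode,
        neighbor_threshold=Fraction(config.edge_tc).limit_denominator(10**6),
    )
    network = build_network(
        matrix,
        edge_threshold=Fraction(config.edge_tc).limit_denominator(10**6),
        library=curated,
    )
    available = {r.compound_id: r.commercially_available for r in curated}
    write_scores(scores, out / "candidate_scores.tsv", available=available)
    if network.edges:
        export_network(network, scores, out / "network.graphml", format="graphml")
        export_network(network, scores, out / "network.sif", format="sif")
    else:
        log.warning("no pair reached the edge threshold; network not exported")
    report.counts["pairs_over_threshold"] = network.n_edges
    report.counts["network_nodes"] = len(network.nodes)
    report.counts["candidates_selected"] = sum(s.selected for s in scores)
    log.info("network: %d edges, %d/%d candidates selected",
             network.n_edges, report.counts["candidates_selected"], len(scores))

    # --- stage 3: target aggregation and filtering ----------------------
    target_set = None
    if config.predictions or config.predictions_glob:
        if config.predictions:
            ingest = read_target_predictions(config.predictions)
        else:
            ingest = read_prediction_directory(config.predictions_glob)
        report.counts["predictions_read"] = len(ingest.predictions)
        report.counts["predictions_rejected"] = len(ingest.rejected)
        target_set = aggregate_and_filter(
            ingest.predictions,
            score_threshold=config.target_score,
            support_threshold=config.target_support,
        )
        report.counts["targets_distinct"] = len(target_set.records)
        report.counts["targets_retained"] = len(target_set.retained_symbols)
        write_target_set(target_set, out / "target_set.tsv")
        log.info("targets: %d distinct, %d retained",
                 len(target_set.records), len(target_set.retained_symbols))

    # --- stage 4: enrichment and cross-source overlap -------------------
    if target_set is not None and config.gene_sets:
        query = target_set.retained_symbols
        all_results = {}
        for label, gmt_path in sorted(config.gene_sets.items()):
            collection = read_gmt(gmt_path, source_label=label)
            results = ora(query, collection)
            all_results[label] = results
            write_enrichment(results, out / f"enrichment_{label}.tsv")
            report.counts[f"sets_tested_{label}"] = len(results)
        if len(all_results) >= 2:
            labels = sorted(all_results)[:2]
            shared = top_k_overlap(
                all_results[labels[0]], all_results[labels[1]],
                k=config.top_k, name_matcher=config.name_matcher,
            )
            report.top_overlap = sorted(shared)
            with open(out / "top_overlap.txt", "w") as handle:
                for name in report.top_overlap:
                    handle.write(name + "\n")
            log.info("enrich: top-%d overlap between %s and %s: %s",
                     config.top_k, labels[0], labels[1], report.top_overlap)

    report.validate()
    (out / "report.json").write_text(report.to_json(timestamp=True))
    (out / "report_body.json").write_text(report.to_json(timestamp=False))
    return report
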