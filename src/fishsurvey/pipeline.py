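"""End-to-end pipeline: discover -> validate -> normalize -> summarize ->
compare, with per-stage JSON logs and deterministic tabular artifacts.

Reruns on identical inputs produce byte-identical outputs; every run writes
its fully-resolved configuration beside the artifacts for provenance.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from pydantic import BaseModel

from . import compare as compare_mod
from . import discovery, validation
from .dwc import SpecimenRecord, read_occurrences, read_recordset_catalog, write_occurrences
from .normalize import (
    CountPolicy,
    CountResolution,
    CountSource,
    NormalizedRecord,
    PreparationParse,
    normalize_records,
)
from .lexicons import load_grammar
from .summarize import (
    CollectionSummary,
    INT_METRICS,
    summarize_aggregate,
    summarize_collection,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


class PipelineConfig(BaseModel):
    occurrences: Path
    catalog: Path
    registry: Path
    out_dir: Path
    merge_rules: Path | None = None
    baseline: Path | None = None
    media_table: Path | None = None
    fish_lexicon: Path | None = None
    nonfish_lexicon: Path | None = None
    grammar: Path | None = None
    keywords: tuple[str, ...] = discovery.DEFAULT_KEYWORDS
    indicator_family: str = "Centrarchidae"
    percentile: float = 80.0
    max_edit_distance: int = 2
    count_default_one: bool = True
    placeholders: tuple[int, ...] = (0, 9999, 99999)
    top_k: int = 5


@dataclass
class PipelineResult:
    identities: list
    kept_records: list[SpecimenRecord]
    normalized: list[NormalizedRecord]
    summaries: list[CollectionSummary]
    aggregate: object
    coverage: list[dict]
    comparison: object | None
    validation_report: object
    stage_logs: list[dict] = field(default_factory=list)


def _require_paths(config: PipelineConfig) -> None:
    required = {"occurrences": config.occurrences, "catalog": config.catalog,
                "registry": config.registry}
    optional = {"merge_rules": config.merge_rules, "baseline": config.baseline,
                "media_table": config.media_table, "grammar": config.grammar,
                "fish_lexicon": config.fish_lexicon,
                "nonfish_lexicon": config.nonfish_lexicon}
    for name, path in {**required, **{k: v for k, v in optional.items() if v is not None}}.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"pipeline input '{name}' not found: {path}")


def _identity_row(ident) -> dict:
    return {
        "identity_id": ident.identity_id,
        "registry_code": ident.registry_code or "",
        "institution_code": ident.institution_code or "",
        "collection_code": ident.collection_code or "",
        "member_recordset_ids": "|".join(sorted(ident.member_recordset_ids)),
        "discovered_by": "|".join(sorted(ident.discovered_by)),
        "merged_from": "|".join(ident.merged_from),
    }


def write_checklist(identities, dest: Path) -> None:
    cols = ["identity_id", "registry_code", "institution_code", "collection_code",
            "member_recordset_ids", "discovered_by", "merged_from"]
    with open(dest, "w", newline="", encoding="utf-8") as handle:
        w = csv.DictWriter(handle, fieldnames=cols, lineterminator="\n")
        w.writeheader()
        for ident in sorted(identities, key=lambda i: i.identity_id):
            w.writerow(_identity_row(ident))


def read_checklist(source: Path) -> list[discovery.CollectionIdentity]:
    identities = []
    with open(source, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            identities.append(
                discovery.CollectionIdentity(
                    identity_id=row["identity_id"],
                    registry_code=row["registry_code"] or None,
                    institution_code=row["institution_code"] or None,
                    collection_code=row["collection_code"] or None,
                    member_recordset_ids=set(
                        x for x in row["member_recordset_ids"].split("|") if x
                    ),
                    discovered_by=set(x for x in row["discovered_by"].split("|") if x),
                    merged_from=[x for x in row["merged_from"].split("|") if x],
                )
            )
    return identities


def write_normalized(normalized: list[NormalizedRecord], dest: Path) -> None:
    """Canonical occurrence columns plus the normalization outcome."""
    cols = ["record_id", "resolved_count", "count_source", "category_counts",
            "media_mentioned", "unrecognized_tokens"]
    with open(dest, "w", newline="", encoding="utf-8") as handle:
        w = csv.writer(handle, lineterminator="\n")
        w.writerow(cols)
        for nr in normalized:
            cats = ";".join(
                f"{cat}:{'' if n is None else n}"
                for cat, n in sorted(nr.parse.category_counts.items())
            )
            w.writerow([
                nr.record.record_id,
                "" if nr.resolution.resolved_count is None else nr.resolution.resolved_count,
                nr.resolution.source.value,
                cats,
                "true" if nr.parse.media_mentioned else "false",
                "|".join(nr.parse.unrecognized_tokens),
            ])


def read_normalized(occurrences: Path, norm_table: Path) -> list[NormalizedRecord]:
    records = {r.record_id: r for r in read_occurrences(occurrences)}
    out: list[NormalizedRecord] = []
    with open(norm_table, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            rec = records[row["record_id"]]
            counts: dict[str, int | None] = {}
            for part in row["category_counts"].split(";"):
                if not part:
                    continue
                cat, _, n = part.partition(":")
                counts[cat] = int(n) if n else None
            parse = PreparationParse(
                category_counts=counts,
                media_mentioned=row["media_mentioned"] == "true",
                unrecognized_tokens=[t for t in row["unrecognized_tokens"].split("|") if t],
            )
            resolved = int(row["resolved_count"]) if row["resolved_count"] else None
            out.append(
                NormalizedRecord(
                    rec, parse, CountResolution(resolved, CountSource(row["count_source"]))
                )
            )
    return out


def write_summaries(summaries: list[CollectionSummary], dest: Path) -> None:
    cols = ["identity_id", *INT_METRICS, "pct_geopoint", "n_geopoint", "n_with_country",
            "country_pcts"]
    with open(dest, "w", newline="", encoding="utf-8") as handle:
        w = csv.writer(handle, lineterminator="\n")
        w.writerow(cols)
        for s in sorted(summaries, key=lambda s: s.identity_id):
            w.writerow(
                [s.identity_id]
                + [getattr(s, m) for m in INT_METRICS]
                + [
                    s.pct_geopoint,
                    s.n_geopoint,
                    s.n_with_country,
                    ";".join(f"{c}:{p}" for c, p in sorted(s.country_pcts.items())),
                ]
            )


def _json_dump(obj, dest: Path) -> None:
    dest.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str), encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full survey pipeline, writing artifacts and stage logs
    under ``config.out_dir``. Any stage error aborts with a stage-named
    message before later artifacts are written."""
    _require_paths(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _json_dump(json.loads(config.model_dump_json()), out / "resolved_config.json")
    stage_logs: list[dict] = []

    def log_stage(stage: str, n_in: int, n_out: int, t0: float, **params) -> None:
        entry = {
            "stage": stage, "n_in": n_in, "n_out": n_out,
            "n_dropped": n_in - n_out, "params": params,
            "seconds": round(time.perf_counter() - t0, 3),
        }
        stage_logs.append(entry)
        _json_dump(entry, out / f"stage_{len(stage_logs):02d}_{stage}.json")
        log.info("stage %s: %d -> %d", stage, n_in, n_out)

    # -- load ---------------------------------------------------------------
    t0 = time.perf_counter()
    catalog = read_recordset_catalog(config.catalog)
    records = read_occurrences(config.occurrences, media_table=config.media_table)
    registry = discovery.read_registry(config.registry)
    merge_rules = discovery.load_merge_rules(config.merge_rules)
    fish_lex = None
    if config.fish_lexicon is not None:
        from .lexicons import load_name_list

        fish_lex = load_name_list(config.fish_lexicon)
    block_lex = None
    if config.nonfish_lexicon is not None:
        from .lexicons import load_name_list

        block_lex = load_name_list(config.nonfish_lexicon)
    log_stage("load", len(records), len(records), t0,
              occurrences=str(config.occurrences), recordsets=len(catalog))

    # -- discover -----------------------------------------------------------
    t0 = time.perf_counter()
    flagged = {
        "metadata_keyword": discovery.flag_by_metadata(catalog, config.keywords),
        "indicator_taxon": {
            row["recordset_id"]
            for row in discovery.flag_by_indicator_taxon(records, config.indicator_family)
        },
    }
    identities = discovery.reconcile(flagged, records, registry, merge_rules)
    identities = discovery.apply_fish_collection_definition(
        identities, records, fish_lexicon=fish_lex, blocklist=block_lex
    )
    write_checklist(identities, out / "checklist.csv")
    member_of: dict[str, str] = {}
    for ident in identities:
        for rsid in ident.member_recordset_ids:
            member_of[rsid] = ident.identity_id
    in_scope = [r for r in records if r.recordset_id in member_of]
    in_scope = discovery.drop_excluded_records(in_scope)
    log_stage("discover", len(records), len(in_scope), t0,
              n_identities=len(identities),
              flagged_metadata=len(flagged["metadata_keyword"]),
              flagged_indicator=len(flagged["indicator_taxon"]))

    coverage = discovery.classify_registry_coverage(registry, identities)
    with open(out / "registry_coverage.csv", "w", newline="", encoding="utf-8") as handle:
        w = csv.DictWriter(handle, fieldnames=["mobilization_status", "count", "percent"],
                           lineterminator="\n")
        w.writeheader()
        w.writerows(coverage)

    # -- validate -----------------------------------------------------------
    t0 = time.perf_counter()
    by_identity: dict[str, list[SpecimenRecord]] = {i.identity_id: [] for i in identities}
    for rec in in_scope:
        by_identity[member_of[rec.recordset_id]].append(rec)
    reference_ids = validation.select_reference_collections(by_identity, config.percentile)
    reference_records = [r for i in reference_ids for r in by_identity[i]]
    dictionary = validation.build_dictionary(
        reference_records, source_collections=reference_ids,
        percentile_threshold=config.percentile, blocklist=block_lex,
    )
    kept, report = validation.filter_records(
        in_scope, dictionary, config.max_edit_distance, blocklist=block_lex
    )
    write_occurrences(kept, out / "validated.csv")
    _json_dump(
        {
            "kept_count": report.kept_count,
            "dropped_count": report.dropped_count,
            "fuzzy_matched_count": report.fuzzy_matched_count,
            "family_absent_count": report.family_absent_count,
            "dropped_examples": report.dropped_examples,
            "reference_collections": reference_ids,
            "dictionary_size": len(dictionary.entries),
        },
        out / "validation_report.json",
    )
    log_stage("validate", len(in_scope), len(kept), t0,
              percentile=config.percentile, max_edit_distance=config.max_edit_distance,
              reference_collections=reference_ids)

    # -- normalize ----------------------------------------------------------
    t0 = time.perf_counter()
    grammar = load_grammar(config.grammar) if config.grammar else None
    policy = CountPolicy(
        placeholders=frozenset(config.placeholders), default_one=config.count_default_one
    )
    normalized = normalize_records(kept, grammar=grammar, policy=policy)
    write_normalized(normalized, out / "normalized.csv")
    log_stage("normalize", len(kept), len(normalized), t0,
              default_one=config.count_default_one)

    # -- summarize ----------------------------------------------------------
    t0 = time.perf_counter()
    norm_by_identity: dict[str, list[NormalizedRecord]] = {
        i.identity_id: [] for i in identities
    }
    for nr in normalized:
        norm_by_identity[member_of[nr.record.recordset_id]].append(nr)
    summaries = [
        summarize_collection(identity_id, norm_by_identity[identity_id])
        for identity_id in sorted(norm_by_identity)
    ]
    aggregate = summarize_aggregate(summaries, top_k=config.top_k)
    write_summaries(summaries, out / "collection_summaries.csv")
    _json_dump(
        {
            "totals": aggregate.totals,
            "mean_specimens_per_record": aggregate.mean_specimens_per_record,
            "pct_geopoint": aggregate.pct_geopoint,
            "country_ranking": aggregate.country_ranking,
            "top": aggregate.top,
            "n_collections": aggregate.n_collections,
        },
        out / "aggregate_summary.json",
    )
    log_stage("summarize", len(normalized), len(summaries), t0, top_k=config.top_k)

    # -- compare ------------------------------------------------------------
    comparison = None
    if config.baseline is not None:
        t0 = time.perf_counter()
        baseline = compare_mod.read_baseline(config.baseline)
        comparison = compare_mod.compare_surveys(summaries, baseline)
        _json_dump(
            {
                "deltas": comparison.deltas,
                "growth": comparison.growth,
                "added_totals": comparison.added_totals,
                "pct_growth": comparison.pct_growth,
                "rankings": comparison.rankings,
                "matched": comparison.matched,
                "unmatched_current": comparison.unmatched_current,
                "unmatched_baseline": comparison.unmatched_baseline,
                "negative_deltas": comparison.negative_deltas,
            },
            out / "comparison.json",
        )
        log_stage("compare", len(summaries), len(comparison.matched), t0,
                  baseline=str(config.baseline))

    return PipelineResult(
        identities=identities,
        kept_records=kept,
        normalized=normalized,
        summaries=summaries,
        aggregate=aggregate,
        coverage=coverage,
        comparison=comparison,
        validation_report=report,
        stage_logs=stage_logs,
    )
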