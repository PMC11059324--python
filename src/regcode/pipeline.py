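"""End-to-end glue: reports → sentences → mentions → facts → codes.

Bundles the lexical resources (section lexicon, dictionary, patterns, rule
base) and drives extraction and inference over whole cohorts; this is what
the command-line interface and the evaluation workflows call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import lung
from .concept_extraction import (
    ConceptMention,
    DictionaryEntry,
    DictionaryIndex,
    concepts_to_facts,
    extract_numeric,
    recognize,
)
from .evaluation import GoldRecord
from .journey_model import PatientJourney, Report, segment_report
from .rule_engine import CodingResult, Fact, FactDatabase, Rule, infer_codes
from .weight_learning import TrainingRecord


@dataclass
class Resources:
    """Lexical resources needed to turn report text into facts."""

    section_lexicon: list[str] = field(default_factory=lambda: list(lung.SECTION_LEXICON))
    dictionary: list[DictionaryEntry] = field(default_factory=lung.default_dictionary)
    patterns: dict[str, list[dict]] = field(default_factory=lung.default_patterns)

    def __post_init__(self) -> None:
        self.index = DictionaryIndex(self.dictionary)


def extract_report_facts(report: Report, resources: Resources) -> list[Fact]:
    """All facts recognized in one report (dictionary + pattern mentions)."""
    mentions: list[ConceptMention] = []
    for sentence in segment_report(report, resources.section_lexicon):
        mentions.extend(
            recognize(
                sentence,
                resources.index,
                report_type=report.report_type,
                report_date=report.date,
            )
        )
        mentions.extend(
            extract_numeric(
                sentence,
                resources.patterns,
                report_type=report.report_type,
                report_date=report.date,
            )
        )
    return concepts_to_facts(mentions)


def journey_fact_db(journey: PatientJourney, resources: Resources) -> FactDatabase:
    facts: list[Fact] = []
    for report in journey.reports:
        facts.extend(extract_report_facts(report, resources))
    return FactDatabase(facts)


def extract_cohort_facts(
    journeys: Sequence[PatientJourney], resources: Resources
) -> dict[str, FactDatabase]:
    return {j.patient_id: journey_fact_db(j, resources) for j in journeys}


def infer_cohort(
    journey_facts: Mapping[str, FactDatabase],
    rules: Sequence[Rule],
    *,
    items: Sequence[str] | None = None,
    aggregate: str = "max",
) -> list[CodingResult]:
    results: list[CodingResult] = []
    for pid in sorted(journey_facts):
        results.extend(
            infer_codes(
                journey_facts[pid],
                rules,
                patient_id=pid,
                items=items,
                aggregate=aggregate,
            )
        )
    return results


def training_records(
    journey_facts: Mapping[str, FactDatabase],
    gold: Iterable[GoldRecord],
    *,
    scope: str = "journey",
) -> list[TrainingRecord]:
    """Pair journey facts with gold codes for weight learning.

    ``scope="journey"`` (default) yields one record per patient;
    ``scope="report"`` splits each journey's facts by report so
    co-occurrence is counted within single reports.
    """
    if scope not in ("journey", "report"):
        raise ValueError(f"unknown co-occurrence scope {scope!r}")
    gold_by_pid = {g.patient_id: g for g in gold}
    records: list[TrainingRecord] = []
    for pid in sorted(journey_facts):
        record = gold_by_pid.get(pid)
        if record is None:
            continue
        db = journey_facts[pid]
        if scope == "journey":
            records.append((db, record.codes))
        else:
            by_report: dict[str, list[Fact]] = {}
            for fact in db:
                by_report.setdefault(str(fact.get("reportId", "")), []).append(fact)
            for rid in sorted(by_report):
                records.append((FactDatabase(by_report[rid]), record.codes))
    return records
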