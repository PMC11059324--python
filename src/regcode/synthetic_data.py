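"""Seeded synthetic patient-journey generator.

No public corpus of hospital reports with registry gold exists for this
task, so every module is exercised on generated cohorts that reproduce the
statistical structure the coding system assumes: journeys mixing pathology
and imaging reports (≈4.8 pathology + ≈9.8 imaging per patient over an
18-month window), per-item skewed label distributions, evidence planted in
the report type that characteristically carries each item, and — for the
multi-report items — occasional *distractor* mentions: a conflicting code
planted in a report of the other type, so that candidate codes disagree
across the journey and rule weighting has something to decide.

The generator emits the gold registry record and a truth log (which sentence
carries the true evidence, which the distractor) alongside the journeys; the
gold is produced by the generator's own bookkeeping, never re-derived
through the engine, so round-trip tests have an independent oracle.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import lung
from .errors import ConfigError
from .evaluation import GoldRecord, save_gold_csv
from .journey_model import PatientJourney, Report, save_journeys_jsonl

_FILLERS = {
    lung.PATHOLOGY: (
        "The specimen was received in formalin.",
        "Routine processing was performed.",
    ),
    lung.IMAGE: (
        "The examination was technically adequate.",
        "Comparison was made with prior studies.",
    ),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Report volumes default to a mean of 4.8 pathology and 9.8 imaging
    reports per patient (14.6 in total); both are configurable.  The
    distractor rate applies to every multi-report item independently;
    single-report items (the site-specific factors and other
    one-characteristic-report fields) never receive distractors.
    """

    n_patients: int = 100
    mean_pathology_reports: float = 4.8
    mean_image_reports: float = 9.8
    distractor_rate: float = 0.3
    start_date: _dt.date = _dt.date(2018, 1, 1)
    window_days: int = 540
    seed: int = 0
    skew_overrides: Mapping[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be ≥ 1")
        if not 0 <= self.distractor_rate < 1:
            raise ConfigError("distractor_rate must be in [0, 1)")
        for item, probs in self.skew_overrides.items():
            spec = lung.spec_for(item)
            if spec is None or spec.kind != "valueset":
                raise ConfigError(f"skew override for non-valueset item {item!r}")
            if len(probs) != len(spec.codes):
                raise ConfigError(f"skew override for {item!r}: wrong arity")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"skew override for {item!r}: probs must sum to 1")


@dataclass
class SyntheticCohort:
    journeys: list[PatientJourney]
    gold: list[GoldRecord]
    truth_log: dict[str, dict[str, dict]]
    config: GeneratorConfig


def _probs_for(spec: lung.ItemSpec, config: GeneratorConfig) -> tuple[float, ...]:
    probs = config.skew_overrides.get(spec.item, spec.probs)
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ConfigError(f"item {spec.item!r}: label probabilities must sum to 1")
    return tuple(probs)


class _ReportDraft:
    def __init__(self, report_id: str, report_type: str, date: _dt.date, rng):
        self.report_id = report_id
        self.report_type = report_type
        self.date = date
        sections = (
            lung.PATHOLOGY_SECTIONS if report_type == lung.PATHOLOGY else lung.IMAGE_SECTIONS
        )
        self.sections: dict[str, list[str]] = {s: [] for s in sections}
        filler = _FILLERS[report_type]
        self.sections[sections[0]].append(filler[int(rng.integers(len(filler)))])

    def add(self, section: str, sentence: str) -> None:
        self.sections[section].append(sentence)

    def render(self, patient_id: str) -> Report:
        lines: list[str] = []
        for section, sentences in self.sections.items():
            if sentences:
                lines.append(f"{section}:")
                lines.extend(sentences)
        return Report(
            report_id=self.report_id,
            patient_id=patient_id,
            report_type=self.report_type,
            date=self.date,
            text="\n".join(lines),
        )


def _distractor_code(rng, codes: Sequence[str], gold: str) -> str:
    others = [c for c in codes if c != gold]
    return others[int(rng.integers(len(others)))]


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a seeded cohort; identical config ⇒ byte-identical output."""
    rng = np.random.default_rng(config.seed)
    journeys: list[PatientJourney] = []
    gold_records: list[GoldRecord] = []
    truth_log: dict[str, dict[str, dict]] = {}

    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        n_path = max(1, int(rng.poisson(config.mean_pathology_reports)))
        n_img = max(1, int(rng.poisson(config.mean_image_reports)))
        drafts: list[_ReportDraft] = []
        for k in range(n_path):
            date = config.start_date + _dt.timedelta(
                days=int(rng.integers(config.window_days))
            )
            drafts.append(_ReportDraft(f"{pid}-p{k:02d}", lung.PATHOLOGY, date, rng))
        for k in range(n_img):
            date = config.start_date + _dt.timedelta(
                days=int(rng.integers(config.window_days))
            )
            drafts.append(_ReportDraft(f"{pid}-i{k:02d}", lung.IMAGE, date, rng))
        by_type = {
            lung.PATHOLOGY: [d for d in drafts if d.report_type == lung.PATHOLOGY],
            lung.IMAGE: [d for d in drafts if d.report_type == lung.IMAGE],
        }

        codes: dict[str, str] = {}
        log: dict[str, dict] = {}

        def plant(item: str, spec_rt: str, section: str, sentence: str,
                  gold_code: str, *, distract: tuple[str, str] | None) -> None:
            """Append the evidence sentence to a random report of the
            characteristic type; optionally a distractor to the other type."""
            host = by_type[spec_rt][int(rng.integers(len(by_type[spec_rt])))]
            host.add(section, sentence)
            entry = {
                "gold": gold_code,
                "evidence_report": host.report_id,
                "evidence_text": sentence,
                "distractor_report": None,
                "distractor_text": None,
                "distractor_value": None,
            }
            if distract is not None:
                d_value, d_sentence = distract
                other_rt = lung.IMAGE if spec_rt == lung.PATHOLOGY else lung.PATHOLOGY
                d_host = by_type[other_rt][int(rng.integers(len(by_type[other_rt])))]
                d_host.add(lung.DEFAULT_SECTION[other_rt], d_sentence)
                entry.update(
                    distractor_report=d_host.report_id,
                    distractor_text=d_sentence,
                    distractor_value=d_value,
                )
            codes[item] = gold_code
            log[item] = entry

        # value-set items
        for spec in lung.VALUESET_ITEMS:
            probs = _probs_for(spec, config)
            gold_code = spec.codes[int(rng.choice(len(spec.codes), p=probs))]
            surface = spec.surfaces[spec.codes.index(gold_code)]
            sentence = spec.template.format(surface=surface)
            distract = None
            if spec.multi_report and len(spec.codes) > 1 and rng.random() < config.distractor_rate:
                d_code = _distractor_code(rng, spec.codes, gold_code)
                d_surface = spec.surfaces[spec.codes.index(d_code)]
                distract = (d_code, spec.template.format(surface=d_surface))
            plant(spec.item, spec.report_type, spec.section, sentence, gold_code,
                  distract=distract)

        # primary site + laterality (one mention fixes both items)
        combo_probs = [c[4] for c in lung.SITE_LATERALITY_COMBOS]
        ci = int(rng.choice(len(lung.SITE_LATERALITY_COMBOS), p=combo_probs))
        cuid, surface, site, lat, _ = lung.SITE_LATERALITY_COMBOS[ci]
        sentence = lung.SITE_TEMPLATE.format(surface=surface)
        distract_site = None
        if rng.random() < config.distractor_rate:
            others = [k for k in range(len(lung.SITE_LATERALITY_COMBOS)) if k != ci]
            di = others[int(rng.integers(len(others)))]
            d_cuid, d_surface, d_site, d_lat, _ = lung.SITE_LATERALITY_COMBOS[di]
            distract_site = (
                f"{d_site}/{d_lat}",
                lung.SITE_TEMPLATE.format(surface=d_surface),
            )
        plant(lung.PRIMARY_SITE_ITEM, lung.IMAGE, lung.SITE_SECTION, sentence, site,
              distract=distract_site)
        # laterality shares the mention: log it without re-planting
        codes[lung.LATERALITY_ITEM] = lat
        log[lung.LATERALITY_ITEM] = dict(
            log[lung.PRIMARY_SITE_ITEM], gold=lat
        )

        # nodal counts (one joint sentence)
        examined = int(rng.integers(5, 41))
        positive = int(rng.binomial(examined, 0.25))
        nodes_spec = lung.spec_for("Nodes Examined")
        sentence = nodes_spec.template.format(positive=positive, examined=examined)
        distract_nodes = None
        if rng.random() < config.distractor_rate:
            d_examined = int(rng.integers(5, 41))
            d_positive = int(rng.binomial(d_examined, 0.25))
            if (d_positive, d_examined) == (positive, examined):
                d_examined += 1
            distract_nodes = (
                f"{d_positive}/{d_examined}",
                nodes_spec.template.format(positive=d_positive, examined=d_examined),
            )
        plant("Nodes Examined", nodes_spec.report_type, nodes_spec.section,
              sentence, str(examined), distract=distract_nodes)
        codes["Nodes Positive"] = str(positive)
        log["Nodes Positive"] = dict(log["Nodes Examined"], gold=str(positive))

        # margin distance
        dist_spec = lung.spec_for("Surgical Margins Distance")
        value = round(float(rng.integers(1, 21)) / 10.0, 1)
        sentence = dist_spec.template.format(value=value)
        distract_dist = None
        if rng.random() < config.distractor_rate:
            d_value = round(float(rng.integers(1, 21)) / 10.0, 1)
            if d_value == value:
                d_value = round(d_value + 0.1, 1)
            distract_dist = (str(d_value), dist_spec.template.format(value=d_value))
        plant(dist_spec.item, dist_spec.report_type, dist_spec.section, sentence,
              str(value), distract=distract_dist)

        # date items: the gold date is the earliest report of the item's type
        for spec in lung.DATE_ITEMS:
            earliest = min(d.date for d in by_type[spec.report_type])
            gold_date = earliest.isoformat()
            sentence = spec.template.format(value=gold_date)
            distract_date = None
            if rng.random() < config.distractor_rate:
                shifted = earliest + _dt.timedelta(days=int(rng.integers(1, 60)))
                distract_date = (
                    shifted.isoformat(),
                    spec.template.format(value=shifted.isoformat()),
                )
            plant(spec.item, spec.report_type, spec.section, sentence, gold_date,
                  distract=distract_date)

        journeys.append(
            PatientJourney(
                patient_id=pid,
                reports=tuple(d.render(pid) for d in drafts),
            )
        )
        gold_records.append(GoldRecord(patient_id=pid, codes=codes))
        truth_log[pid] = log

    return SyntheticCohort(
        journeys=journeys, gold=gold_records, truth_log=truth_log, config=config
    )


def _perturb(sentence: str, rng) -> str:
    """Introduce a typo into the longest token of the sentence."""
    words = sentence.split()
    target = max(range(len(words)), key=lambda i: len(words[i]))
    w = words[target]
    pos = 1 + int(rng.integers(max(len(w) - 1, 1)))
    words[target] = w[:pos] + "x" + w[pos:]
    return " ".join(words)


def corrupt_cohort(
    cohort: SyntheticCohort, missing_rate: float, typo_rate: float, seed: int
) -> SyntheticCohort:
    """Drop or misspell evidence sentences at the given rates.

    Items sharing one evidence sentence (the nodal-count pair, primary
    site/laterality) are corrupted together.  Rates of zero return an
    equivalent cohort.
    """
    if not 0 <= missing_rate < 1 or not 0 <= typo_rate < 1:
        raise ConfigError("corruption rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    edits: dict[str, list[tuple[str, str | None]]] = {}
    new_log = {pid: {i: dict(e) for i, e in items.items()} for pid, items in cohort.truth_log.items()}

    for pid in sorted(cohort.truth_log):
        handled: set[tuple[str, str]] = set()
        for item in sorted(cohort.truth_log[pid]):
            entry = cohort.truth_log[pid][item]
            key = (entry["evidence_report"], entry["evidence_text"])
            if key in handled:
                # shared sentence: mirror the edit outcome recorded by its owner
                continue
            handled.add(key)
            if rng.random() < missing_rate:
                edits.setdefault(entry["evidence_report"], []).append(
                    (entry["evidence_text"], None)
                )
                for other, oe in cohort.truth_log[pid].items():
                    if (oe["evidence_report"], oe["evidence_text"]) == key:
                        new_log[pid][other]["evidence_text"] = None
                        new_log[pid][other]["dropped"] = True
            elif rng.random() < typo_rate:
                mutated = _perturb(entry["evidence_text"], rng)
                edits.setdefault(entry["evidence_report"], []).append(
                    (entry["evidence_text"], mutated)
                )
                for other, oe in cohort.truth_log[pid].items():
                    if (oe["evidence_report"], oe["evidence_text"]) == key:
                        new_log[pid][other]["evidence_text"] = mutated
                        new_log[pid][other]["typo"] = True

    new_journeys: list[PatientJourney] = []
    for journey in cohort.journeys:
        reports = []
        for report in journey.reports:
            if report.report_id in edits:
                lines = report.text.splitlines()
                for original, replacement in edits[report.report_id]:
                    if replacement is None:
                        lines = [ln for ln in lines if ln != original]
                    else:
                        lines = [replacement if ln == original else ln for ln in lines]
                reports.append(replace(report, text="\n".join(lines)))
            else:
                reports.append(report)
        new_journeys.append(PatientJourney(journey.patient_id, tuple(reports)))
    return SyntheticCohort(
        journeys=new_journeys, gold=list(cohort.gold), truth_log=new_log,
        config=cohort.config,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reports": outdir / "reports.jsonl",
        "gold": outdir / "gold.csv",
        "truth_log": outdir / "truth_log.json",
    }
    save_journeys_jsonl(cohort.journeys, paths["reports"])
    save_gold_csv(cohort.gold, paths["gold"])
    paths["truth_log"].write_text(
        json.dumps(cohort.truth_log, indent=1, sort_keys=True), encoding="utf-8"
    )
    return paths
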