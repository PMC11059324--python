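"""Reports, patient journeys, and report preprocessing.

A *patient journey* is the date-ordered collection of all free-text reports
(pathology and imaging) produced during one patient's cancer treatment,
typically spanning about 1.5 years.  The coding engine always operates on the
whole journey, never on a single report.

Preprocessing turns a report into :class:`Sentence` objects: the text is split
into sentences, tokenized, and each sentence is labelled with the most recent
section heading above it (e.g. ``"Microscopic Examination"``), or the sentinel
``"UNSECTIONED"`` when no heading has been seen yet.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import EmptyInputError, ValidationError

REPORT_TYPES = ("pathology", "image")
UNSECTIONED = "UNSECTIONED"

#: Abbreviations that may end with a period without terminating a sentence.
ABBREVIATIONS = frozenset({
    "cm.", "mm.", "no.", "dr.", "vs.", "e.g.", "i.e.", "approx.", "fig.",
    "st.", "pt.",
})

_PUNCT = ".,;:()[]{}\"'!?"


@dataclass(frozen=True, order=True)
class Report:
    """One free-text clinical report belonging to a patient journey."""

    date: _dt.date
    report_id: str
    patient_id: str = field(compare=False)
    report_type: str = field(compare=False)
    text: str = field(compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.report_type not in REPORT_TYPES:
            raise ValidationError(
                f"report {self.report_id!r}: unknown report_type "
                f"{self.report_type!r} (expected one of {REPORT_TYPES})"
            )
        if not self.text.strip():
            raise ValidationError(f"report {self.report_id!r}: empty text")


@dataclass(frozen=True)
class Sentence:
    """A preprocessed sentence with its section label and tokens."""

    report_id: str
    section_label: str
    index: int
    text: str
    tokens: tuple[str, ...]


@dataclass(frozen=True)
class PatientJourney:
    """Date-ordered reports of one patient (ties broken by report id)."""

    patient_id: str
    reports: tuple[Report, ...]

    def __post_init__(self) -> None:
        for r in self.reports:
            if r.patient_id != self.patient_id:
                raise ValidationError(
                    f"journey {self.patient_id!r}: report {r.report_id!r} "
                    f"belongs to patient {r.patient_id!r}"
                )
        object.__setattr__(self, "reports", tuple(sorted(self.reports)))

    def report_types(self) -> set[str]:
        return {r.report_type for r in self.reports}


def tokenize(text: str) -> tuple[str, ...]:
    """Whitespace split, then strip leading/trailing punctuation per token.

    Interior punctuation is preserved so values like ``0.3``, ``pT2a`` and
    ISO dates survive intact.
    """
    tokens = []
    for raw in text.split():
        tok = raw.strip(_PUNCT)
        if tok:
            tokens.append(tok)
    return tuple(tokens)


def normalize_heading(line: str) -> str:
    """Canonical form used for heading comparison."""
    return line.strip().rstrip(":").rstrip().casefold()


_SENT_BOUNDARY = re.compile(r"\.\s+(?=[A-Z])")


def split_sentences(line: str) -> list[str]:
    """Split one line into sentences on ``". "`` followed by an uppercase
    letter, keeping clinical abbreviations (``cm.``, ``No.`` ...) intact."""
    pieces: list[str] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(line):
        candidate = line[start : m.start() + 1]
        last_word = candidate.rsplit(None, 1)[-1].casefold() if candidate.split() else ""
        if last_word in ABBREVIATIONS:
            continue
        pieces.append(candidate)
        start = m.end()
    tail = line[start:]
    if tail.strip():
        pieces.append(tail.strip())
    return [p.strip() for p in pieces if p.strip()]


def segment_report(report: Report, section_lexicon: Sequence[str]) -> list[Sentence]:
    """Segment a report into section-labelled, tokenized sentences.

    A line is a heading iff, after stripping a trailing colon and whitespace
    and case-folding, it equals a lexicon entry.  Every other non-blank line
    is split into sentences; each sentence carries the most recent heading
    above it (last-heading-wins), else ``UNSECTIONED``.
    """
    if not report.text.strip():
        raise EmptyInputError(f"report {report.report_id!r} has empty text")
    if not section_lexicon:
        raise ValidationError("section lexicon must be non-empty")
    headings = {normalize_heading(h): h.strip().rstrip(":") for h in section_lexicon}

    sentences: list[Sentence] = []
    current = UNSECTIONED
    index = 0
    for line in report.text.splitlines():
        if not line.strip():
            continue
        key = normalize_heading(line)
        if key in headings:
            current = headings[key]
            continue
        for sent in split_sentences(line):
            sentences.append(
                Sentence(
                    report_id=report.report_id,
                    section_label=current,
                    index=index,
                    text=sent,
                    tokens=tokenize(sent),
                )
            )
            index += 1
    return sentences


def load_section_lexicon(path: str | Path) -> list[str]:
    """One heading per line; blank lines ignored."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def _parse_date(value: str, context: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{context}: bad ISO-8601 date {value!r}") from exc


def journeys_from_records(records: Iterable[dict]) -> list[PatientJourney]:
    """Group validated report records into date-ordered journeys."""
    by_patient: dict[str, list[Report]] = {}
    seen: set[tuple[str, str]] = set()
    for i, rec in enumerate(records):
        ctx = f"record {i} (report_id={rec.get('report_id')!r})"
        for key in ("report_id", "patient_id", "report_type", "date", "text"):
            if key not in rec:
                raise ValidationError(f"{ctx}: missing key {key!r}")
        report = Report(
            report_id=str(rec["report_id"]),
            patient_id=str(rec["patient_id"]),
            report_type=rec["report_type"],
            date=_parse_date(rec["date"], ctx),
            text=rec["text"],
        )
        pair = (report.patient_id, report.report_id)
        if pair in seen:
            raise ValidationError(
                f"{ctx}: duplicate report_id {report.report_id!r} "
                f"for patient {report.patient_id!r}"
            )
        seen.add(pair)
        by_patient.setdefault(report.patient_id, []).append(report)
    return [
        PatientJourney(patient_id=pid, reports=tuple(reps))
        for pid, reps in sorted(by_patient.items())
    ]


def load_journeys(path: str | Path) -> list[PatientJourney]:
    """Load journeys from a JSON-Lines report file or a directory of ``.txt``
    files named ``<patient_id>__<report_id>__<type>__<date>.txt``."""
    path = Path(path)
    records: list[dict] = []
    if path.is_dir():
        for f in sorted(path.glob("*.txt")):
            parts = f.stem.split("__")
            if len(parts) != 4:
                raise ValidationError(
                    f"file {f.name!r}: expected name "
                    "<patient_id>__<report_id>__<type>__<date>.txt"
                )
            pid, rid, rtype, date = parts
            records.append(
                {
                    "patient_id": pid,
                    "report_id": rid,
                    "report_type": rtype,
                    "date": date,
                    "text": f.read_text(encoding="utf-8"),
                }
            )
    else:
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise ValidationError(
                        f"{path}:{lineno}: malformed JSON ({exc})"
                    ) from exc
    return journeys_from_records(records)


def save_journeys_jsonl(journeys: Iterable[PatientJourney], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for j in journeys:
            for r in j.reports:
                fh.write(
                    json.dumps(
                        {
                            "report_id": r.report_id,
                            "patient_id": r.patient_id,
                            "report_type": r.report_type,
                            "date": r.date.isoformat(),
                            "text": r.text,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
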