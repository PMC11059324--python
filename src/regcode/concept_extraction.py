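"""Dictionary and pattern based concept recognition and fact conversion.

Registry concept mentions (histology, primary site/laterality, staging
categories, site-specific factors ...) are recognized in preprocessed
sentences by case-insensitive, punctuation-insensitive dictionary lookup and
normalized to canonical codes — UMLS concept identifiers (e.g. the surface
"lung, left upper lobe" normalizes to CUID ``C1261076``), registry value-set
codes (``pT2a``), or literal numbers for count/size/date concepts captured by
regular-expression patterns.

Mentions are then converted into :class:`~regcode.rule_engine.Fact` records
enriched with the sentence's section label and with same-sentence
co-occurrence flags (``cooccurHistology=True`` on a primary-site fact whose
sentence also contains a histology mention), which downstream rules condition
on.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .journey_model import Sentence, tokenize
from .rule_engine import Fact

_CUID_RE = re.compile(r"^C\d{7}$")

#: Number words accepted by the numeric patterns (clinical reports often
#: spell small counts out, e.g. "Six of 21 lymph nodes").
NUMBER_WORDS = {
    w: i
    for i, w in enumerate(
        "zero one two three four five six seven eight nine ten eleven twelve "
        "thirteen fourteen fifteen sixteen seventeen eighteen nineteen "
        "twenty".split()
    )
}


@dataclass(frozen=True)
class DictionaryEntry:
    """Maps a surface form to a concept type and a normalized code."""

    surface: str
    concept_type: str
    normalized: str
    allow_gap: bool = False  # tolerate one intervening token inside the match

    def __post_init__(self) -> None:
        if not self.surface.strip():
            raise ValidationError("dictionary entry with empty surface")
        if not self.normalized:
            raise ValidationError(
                f"dictionary entry {self.surface!r}: empty normalized code"
            )


@dataclass(frozen=True)
class ConceptMention:
    """One recognized concept occurrence inside a sentence."""

    concept_type: str
    normalized: str
    sentence: Sentence
    start: int  # token index, inclusive
    end: int  # token index, exclusive
    section_label: str
    report_type: str | None = None
    report_date: _dt.date | None = None


class DictionaryIndex:
    """First-token index over dictionary entries for fast longest-match scans."""

    def __init__(self, entries: Iterable[DictionaryEntry]):
        seen: set[tuple[str, str]] = set()
        self._by_first: dict[str, list[tuple[tuple[str, ...], DictionaryEntry]]] = {}
        for entry in entries:
            key = (entry.surface.casefold(), entry.concept_type)
            if key in seen:
                raise ValidationError(
                    f"duplicate dictionary entry {entry.surface!r} / "
                    f"{entry.concept_type!r}"
                )
            seen.add(key)
            toks = tokenize(entry.surface.casefold())
            if not toks:
                raise ValidationError(
                    f"dictionary surface {entry.surface!r} has no tokens"
                )
            self._by_first.setdefault(toks[0], []).append((toks, entry))
        # longest surface first; ties resolved deterministically by
        # (concept_type, normalized) so input order never matters
        for cands in self._by_first.values():
            cands.sort(key=lambda te: (-len(te[0]), te[1].concept_type, te[1].normalized))

    def candidates(self, first_token: str):
        return self._by_first.get(first_token, ())


def _match_at(tokens: Sequence[str], i: int, surface: tuple[str, ...], allow_gap: bool) -> int:
    """Return the token span length matched at position ``i``, or 0."""
    if not allow_gap:
        n = len(surface)
        if tokens[i : i + n] == list(surface) or tuple(tokens[i : i + n]) == surface:
            return n
        return 0
    # gapped variant: surface tokens in order, at most one extra token inside
    j = i
    gaps = 0
    for k, s in enumerate(surface):
        if j >= len(tokens):
            return 0
        if tokens[j] == s:
            j += 1
            continue
        if k > 0 and gaps == 0 and j + 1 < len(tokens) and tokens[j + 1] == s:
            gaps += 1
            j += 2
            continue
        return 0
    return j - i


def recognize(
    sentence: Sentence,
    dictionary: Iterable[DictionaryEntry] | DictionaryIndex,
    *,
    report_type: str | None = None,
    report_date: _dt.date | None = None,
) -> list[ConceptMention]:
    """Leftmost-longest, case-insensitive dictionary scan over token spans.

    Overlapping matches are resolved leftmost-longest, so the emitted spans
    are pairwise non-overlapping; the result is independent of dictionary
    order.
    """
    index = dictionary if isinstance(dictionary, DictionaryIndex) else DictionaryIndex(dictionary)
    tokens = [t.casefold() for t in sentence.tokens]
    mentions: list[ConceptMention] = []
    i = 0
    while i < len(tokens):
        best_len = 0
        best_entry: DictionaryEntry | None = None
        for surface, entry in index.candidates(tokens[i]):
            span = _match_at(tokens, i, surface, entry.allow_gap)
            if span > best_len:
                best_len, best_entry = span, entry
        if best_entry is not None:
            mentions.append(
                ConceptMention(
                    concept_type=best_entry.concept_type,
                    normalized=best_entry.normalized,
                    sentence=sentence,
                    start=i,
                    end=i + best_len,
                    section_label=sentence.section_label,
                    report_type=report_type,
                    report_date=report_date,
                )
            )
            i += best_len
        else:
            i += 1
    return mentions


def _canonical_number(raw: str) -> str:
    word = raw.casefold()
    if word in NUMBER_WORDS:
        return str(NUMBER_WORDS[word])
    if re.fullmatch(r"\d+", raw):
        return str(int(raw))
    if re.fullmatch(r"\d+\.\d+", raw):
        return repr(float(raw))
    return raw


def extract_numeric(
    sentence: Sentence,
    pattern_set: Mapping[str, Sequence[Mapping]],
    *,
    report_type: str | None = None,
    report_date: _dt.date | None = None,
) -> list[ConceptMention]:
    """Pattern-based extraction of literal values (counts, sizes, dates).

    ``pattern_set`` maps a concept type to a list of pattern specs
    ``{"pattern": <regex>, "group": <capture group>}``.  The captured value is
    normalized to a canonical literal string (number words become digits,
    ``"0.30"`` becomes ``"0.3"``, ISO dates pass through).  If a sentence
    matches a pattern twice, both captures are emitted; disambiguation is left
    to the rules.
    """
    mentions: list[ConceptMention] = []
    text = sentence.text
    for concept_type in sorted(pattern_set):
        for spec in pattern_set[concept_type]:
            regex = re.compile(spec["pattern"], re.IGNORECASE)
            group = spec.get("group", 1)
            for m in regex.finditer(text):
                raw = m.group(group)
                if raw is None:
                    continue
                start_tok, end_tok = _char_to_token_span(
                    sentence, m.start(group), m.end(group)
                )
                mentions.append(
                    ConceptMention(
                        concept_type=concept_type,
                        normalized=_canonical_number(raw),
                        sentence=sentence,
                        start=start_tok,
                        end=end_tok,
                        section_label=sentence.section_label,
                        report_type=report_type,
                        report_date=report_date,
                    )
                )
    return mentions


def _char_to_token_span(sentence: Sentence, start: int, end: int) -> tuple[int, int]:
    """Map a character span of ``sentence.text`` to covering token indices."""
    spans: list[tuple[int, int]] = []
    cursor = 0
    for raw in sentence.text.split():
        begin = sentence.text.index(raw, cursor)
        spans.append((begin, begin + len(raw)))
        cursor = begin + len(raw)
    lo, hi = 0, len(spans)
    for i, (b, e) in enumerate(spans):
        if e > start:
            lo = i
            break
    for i, (b, e) in enumerate(spans):
        if b < end:
            hi = i + 1
    # tokenization may drop punctuation-only tokens; clamp into token range
    n_tok = max(len(sentence.tokens), 1)
    lo = min(lo, n_tok - 1)
    hi = max(lo + 1, min(hi, n_tok))
    return lo, hi


def concepts_to_facts(mentions: Sequence[ConceptMention]) -> list[Fact]:
    """Convert mentions into facts with section and co-occurrence context.

    One fact per mention; for every pair of mentions within one sentence each
    fact receives a per-concept-type boolean flag ``cooccur<OtherType>=True``.
    """
    by_sentence: dict[tuple[str, int], list[ConceptMention]] = {}
    for m in mentions:
        by_sentence.setdefault((m.sentence.report_id, m.sentence.index), []).append(m)

    facts: list[Fact] = []
    for m in mentions:
        attrs: dict = {"type": m.concept_type, "value": m.normalized}
        if _CUID_RE.match(m.normalized):
            attrs["UMLS"] = m.normalized
        attrs["section"] = m.section_label
        if m.report_type is not None:
            attrs["reportType"] = m.report_type
        if m.report_date is not None:
            attrs["date"] = m.report_date
        attrs["reportId"] = m.sentence.report_id
        for other in by_sentence[(m.sentence.report_id, m.sentence.index)]:
            if other is m:
                continue
            if other.concept_type != m.concept_type:
                attrs[f"cooccur{other.concept_type}"] = True
        facts.append(Fact(attrs))
    return facts


def load_dictionary(path: str | Path) -> list[DictionaryEntry]:
    """TSV with columns surface, concept_type, normalized[, gap]."""
    entries: list[DictionaryEntry] = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 3:
            raise ValidationError(f"{path}:{lineno}: expected ≥3 tab-separated columns")
        gap = len(cols) > 3 and cols[3].strip() == "gap"
        entries.append(DictionaryEntry(cols[0], cols[1], cols[2], allow_gap=gap))
    return entries


def save_dictionary(entries: Iterable[DictionaryEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            gap = "\tgap" if e.allow_gap else ""
            fh.write(f"{e.surface}\t{e.concept_type}\t{e.normalized}{gap}\n")


def load_patterns(path: str | Path) -> dict[str, list[dict]]:
    """JSON pattern file keyed by concept type."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: pattern file must be a JSON object")
    return data


def save_patterns(patterns: Mapping[str, Sequence[Mapping]], path: str | Path) -> None:
    Path(path).write_text(json.dumps(patterns, indent=2), encoding="utf-8")
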