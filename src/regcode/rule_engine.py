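"""Fact database, weighted production rules, and forward-chaining inference.

The engine is a classic forward-chaining expert system specialised for
registry coding.  Observed facts (extracted concept mentions with their
section / report context) populate a working memory with set semantics; rules
whose AND-joined antecedents are satisfied fire and assert new facts,
including ``*_CODING`` facts carrying candidate codes for registry items;
sweeps repeat until a fixpoint.  Each rule carries a non-negative weight
(default 1.0, replaced by learned weights); the final code per item is the
candidate whose asserting rules have the highest weight.

Rule syntax
-----------
An antecedent is a condition ``(attribute, operator, value)`` over one fact,
e.g. ``C.type = 'PrimarySiteLaterality' AND C.UMLS = 'C1261076'``.  Conditions
sharing a fact variable (``var``) must be satisfied by the *same* fact;
conditions with distinct variables may each bind a different fact in the
database.  Consequents are fact templates; a template value of the form
``"{C.value}"`` copies the attribute from the fact bound to variable ``C``
(needed for literal-valued items such as Nodes Examined or date items).
"""

from __future__ import annotations

import datetime as _dt
import itertools
import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping, Sequence

from .errors import ValidationError

NOT_CODED = "NOT_CODED"
INTERMEDIATE = "intermediate"

OPERATORS = ("eq", "ne", "ge", "le", "present")

_PLACEHOLDER = re.compile(r"^\{(\w+)\.(\w+)\}$")
_FAR_FUTURE = _dt.date.max


def coding_fact_type(item: str) -> str:
    """Registry item name → the fact type its rules assert
    (``"Primary Site"`` → ``"PRIMARY_SITE_CODING"``)."""
    return item.upper().replace(" ", "_") + "_CODING"


class Fact(Mapping[str, Any]):
    """An immutable attribute-value record; the unit of working memory.

    Facts compare (and hash) by their full attribute map, giving the fact
    database set semantics: re-asserting an existing fact is a no-op.
    The ``type`` attribute is mandatory.
    """

    __slots__ = ("_attrs", "_key")

    def __init__(self, attrs: Mapping[str, Any] | None = None, **kwargs: Any):
        merged = dict(attrs or {})
        merged.update(kwargs)
        if "type" not in merged:
            raise ValidationError(f"fact without 'type' attribute: {merged!r}")
        self._attrs = merged
        self._key = frozenset(merged.items())

    def __getitem__(self, name: str) -> Any:
        return self._attrs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._attrs)

    def __len__(self) -> int:
        return len(self._attrs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Fact) and self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}={v!r}" for k, v in sorted(self._attrs.items(), key=lambda kv: kv[0]))
        return f"Fact({inner})"

    def to_dict(self) -> dict[str, Any]:
        return dict(self._attrs)

    def sort_key(self) -> tuple:
        return tuple(sorted((k, repr(v)) for k, v in self._attrs.items()))


@dataclass(frozen=True)
class Antecedent:
    """One condition of a rule: ``<var>.<attribute> <op> <value>``."""

    attribute: str
    op: str
    value: Any = None
    var: str = "C"

    def __post_init__(self) -> None:
        if self.op not in OPERATORS:
            raise ValidationError(f"unknown operator {self.op!r}")


def _comparable(a: Any, b: Any) -> tuple[Any, Any]:
    if isinstance(a, _dt.date) or isinstance(b, _dt.date):
        conv = lambda x: _dt.date.fromisoformat(x) if isinstance(x, str) else x
        a, b = conv(a), conv(b)
        if isinstance(a, _dt.date) and isinstance(b, _dt.date):
            return a, b
        raise TypeError(f"cannot order {a!r} and {b!r}")
    if isinstance(a, (int, float)) or isinstance(b, (int, float)):
        try:
            return float(a), float(b)
        except (TypeError, ValueError) as exc:
            raise TypeError(f"cannot order {a!r} and {b!r}") from exc
    if isinstance(a, str) and isinstance(b, str):
        return a, b
    raise TypeError(f"cannot order {a!r} and {b!r}")


def matches(antecedent: Antecedent, fact: Fact) -> bool:
    """True iff the fact has the attribute and the operator holds.

    A fact lacking the attribute never matches, for any operator (including
    ``present``, which is satisfied by mere attribute presence otherwise).
    ``ge``/``le`` on values with no common order raise :class:`TypeError`.
    """
    if antecedent.attribute not in fact:
        return False
    actual = fact[antecedent.attribute]
    op = antecedent.op
    if op == "present":
        return True
    if op == "eq":
        return actual == antecedent.value
    if op == "ne":
        return actual != antecedent.value
    a, b = _comparable(actual, antecedent.value)
    return a >= b if op == "ge" else a <= b


@dataclass(frozen=True)
class Consequent:
    """The action part of a rule: one or more fact templates to assert."""

    assertions: tuple[Mapping[str, Any], ...]

    def __post_init__(self) -> None:
        if not self.assertions:
            raise ValidationError("consequent with no assertions")
        for tmpl in self.assertions:
            if "type" not in tmpl:
                raise ValidationError(f"assertion template without type: {tmpl!r}")
        object.__setattr__(
            self, "assertions", tuple(dict(t) for t in self.assertions)
        )

    def referenced_vars(self) -> tuple[str, ...]:
        out: list[str] = []
        for tmpl in self.assertions:
            for v in tmpl.values():
                if isinstance(v, str):
                    m = _PLACEHOLDER.match(v)
                    if m and m.group(1) not in out:
                        out.append(m.group(1))
        return tuple(out)


@dataclass(frozen=True)
class Rule:
    """A weighted production rule for one coding item (or an intermediate)."""

    rule_id: str
    coding_item: str
    antecedents: tuple[Antecedent, ...]
    consequent: Consequent
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.antecedents:
            raise ValidationError(f"rule {self.rule_id!r} has no antecedents")
        if self.weight < 0:
            raise ValidationError(f"rule {self.rule_id!r} has negative weight")
        object.__setattr__(self, "antecedents", tuple(self.antecedents))

    def conditions_by_var(self) -> dict[str, list[Antecedent]]:
        """Conditions grouped by fact variable, in first-appearance order."""
        groups: dict[str, list[Antecedent]] = {}
        for a in self.antecedents:
            groups.setdefault(a.var, []).append(a)
        return groups


class FactDatabase:
    """Working memory: a set of facts with provenance and support dates."""

    OBSERVED = "observed"

    def __init__(self, facts: Iterable[Fact] = ()):
        self.facts: set[Fact] = set()
        self.provenance: dict[Fact, set[str]] = {}
        self.support: dict[Fact, _dt.date | None] = {}
        for f in facts:
            self.add(f, self.OBSERVED, f.get("date"))

    def add(self, fact: Fact, source: str, support: _dt.date | None = None) -> bool:
        """Insert a fact; returns True iff it was new.  Re-assertion merges
        provenance and keeps the earliest support date."""
        new = fact not in self.facts
        self.facts.add(fact)
        self.provenance.setdefault(fact, set()).add(source)
        prev = self.support.get(fact)
        if support is not None and (prev is None or support < prev):
            self.support[fact] = support
        elif fact not in self.support:
            self.support[fact] = support
        return new

    def copy(self) -> "FactDatabase":
        db = FactDatabase()
        db.facts = set(self.facts)
        db.provenance = {f: set(s) for f, s in self.provenance.items()}
        db.support = dict(self.support)
        return db

    def satisfying(self, conditions: Sequence[Antecedent]) -> list[Fact]:
        out = [f for f in self.facts if all(matches(c, f) for c in conditions)]
        out.sort(key=Fact.sort_key)
        return out

    def __contains__(self, fact: Fact) -> bool:
        return fact in self.facts

    def __len__(self) -> int:
        return len(self.facts)

    def __iter__(self) -> Iterator[Fact]:
        return iter(self.facts)


def _instantiate(template: Mapping[str, Any], binding: Mapping[str, Fact]) -> Fact | None:
    """Fill a fact template from bound variables; None if a placeholder
    refers to an attribute the bound fact lacks."""
    attrs: dict[str, Any] = {}
    for k, v in template.items():
        if isinstance(v, str):
            m = _PLACEHOLDER.match(v)
            if m:
                var, attr = m.groups()
                bound = binding.get(var)
                if bound is None or attr not in bound:
                    return None
                attrs[k] = bound[attr]
                continue
        attrs[k] = v
    return Fact(attrs)


def _min_date(*dates: _dt.date | None) -> _dt.date | None:
    present = [d for d in dates if d is not None]
    return min(present) if present else None


def fire_detailed(
    rule: Rule, db: FactDatabase
) -> list[tuple[Fact, _dt.date | None]]:
    """All facts the rule asserts against ``db``, with support dates.

    The rule fires iff every fact variable has at least one satisfying fact.
    Variables referenced by consequent placeholders are enumerated over all
    their satisfying facts (one assertion set per binding); purely
    existential variables are not enumerated.  The support date of an
    asserted fact is the earliest report date among the facts backing the
    firing.
    """
    groups = rule.conditions_by_var()
    candidates: dict[str, list[Fact]] = {}
    for var, conds in groups.items():
        sat = db.satisfying(conds)
        if not sat:
            return []
        candidates[var] = sat

    existential_support = _min_date(
        *(f.get("date") for sat in candidates.values() for f in sat)
    )
    referenced = [v for v in rule.consequent.referenced_vars() if v in candidates]
    results: list[tuple[Fact, _dt.date | None]] = []
    if not referenced:
        for tmpl in rule.consequent.assertions:
            inst = _instantiate(tmpl, {})
            if inst is not None:
                results.append((inst, existential_support))
        return results

    for combo in itertools.product(*(candidates[v] for v in referenced)):
        binding = dict(zip(referenced, combo))
        support = _min_date(
            existential_support, *(f.get("date") for f in combo)
        )
        for tmpl in rule.consequent.assertions:
            inst = _instantiate(tmpl, binding)
            if inst is not None:
                results.append((inst, support))
    return results


def fire(rule: Rule, db: FactDatabase) -> set[Fact]:
    """Facts asserted by the rule against ``db`` (empty set if it does not
    fire)."""
    return {f for f, _ in fire_detailed(rule, db)}


def forward_chain(
    db: FactDatabase, rules: Sequence[Rule], *, max_sweeps: int = 100_000
) -> FactDatabase:
    """Least fixpoint of the rule set over the database (input unchanged).

    Repeated sweeps over all rules add asserted facts until a sweep adds
    nothing.  Under set semantics the fixpoint is reached in at most
    (number of distinct derivable facts + 1) sweeps and is independent of
    rule order.
    """
    out = db.copy()
    for _ in range(max_sweeps):
        added = False
        for rule in rules:
            for fact, support in fire_detailed(rule, out):
                if out.add(fact, rule.rule_id, support):
                    added = True
        if not added:
            return out
    raise RuntimeError("forward chaining exceeded the sweep guard")  # pragma: no cover


@dataclass(frozen=True)
class CodingResult:
    """Ranked candidate codes and the selected code for one patient/item."""

    patient_id: str
    item: str
    candidates: tuple[tuple[str, float, tuple[str, ...]], ...]  # (code, weight, rule_ids)
    selected: str


def infer_codes(
    journey_facts: FactDatabase,
    rules: Sequence[Rule],
    *,
    patient_id: str = "",
    items: Sequence[str] | None = None,
    aggregate: str = "max",
) -> list[CodingResult]:
    """Forward-chain, then select one code per coding item by weight.

    Candidate codes are the distinct ``value`` attributes of the asserted
    ``*_CODING`` facts for the item; each candidate is scored by the maximum
    (or, with ``aggregate="sum"``, the sum of the) weight of the rules that
    asserted it.  Ties are broken by earlier supporting report date, then
    lexicographically smaller code.  Items with no asserted code yield the
    ``NOT_CODED`` sentinel.
    """
    if aggregate not in ("max", "sum"):
        raise ValidationError(f"unknown aggregation {aggregate!r}")
    if items is None:
        items = sorted(
            {r.coding_item for r in rules if r.coding_item != INTERMEDIATE}
        )
    weight_of = {r.rule_id: r.weight for r in rules}
    closure = forward_chain(journey_facts, rules)

    results: list[CodingResult] = []
    for item in items:
        ftype = coding_fact_type(item)
        per_value: dict[str, dict] = {}
        for fact in closure:
            if fact["type"] != ftype:
                continue
            value = str(fact.get("value", ""))
            rule_ids = sorted(
                p for p in closure.provenance[fact] if p in weight_of
            )
            if not rule_ids:
                continue
            slot = per_value.setdefault(
                value, {"rules": set(), "support": None}
            )
            slot["rules"].update(rule_ids)
            slot["support"] = _min_date(slot["support"], closure.support.get(fact))
        candidates = []
        for value, slot in per_value.items():
            weights = [weight_of[r] for r in slot["rules"]]
            score = max(weights) if aggregate == "max" else sum(weights)
            candidates.append((value, score, slot["support"], tuple(sorted(slot["rules"]))))
        candidates.sort(key=lambda c: (-c[1], c[2] or _FAR_FUTURE, c[0]))
        packed = tuple((v, s, rids) for v, s, _sup, rids in candidates)
        selected = packed[0][0] if packed else NOT_CODED
        results.append(
            CodingResult(patient_id=patient_id, item=item, candidates=packed, selected=selected)
        )
    return results


# ---------------------------------------------------------------------------
# rule file (JSON) serialization


def _antecedent_from_json(obj: Mapping, ctx: str) -> Antecedent:
    for key in ("attribute", "op"):
        if key not in obj:
            raise ValidationError(f"{ctx}: antecedent missing {key!r}")
    return Antecedent(
        attribute=obj["attribute"],
        op=obj["op"],
        value=obj.get("value"),
        var=obj.get("var", "C"),
    )


def rule_from_json(obj: Mapping) -> Rule:
    ctx = f"rule {obj.get('rule_id')!r}"
    for key in ("rule_id", "coding_item", "antecedents", "consequent"):
        if key not in obj:
            raise ValidationError(f"{ctx}: missing {key!r}")
    return Rule(
        rule_id=obj["rule_id"],
        coding_item=obj["coding_item"],
        antecedents=tuple(
            _antecedent_from_json(a, ctx) for a in obj["antecedents"]
        ),
        consequent=Consequent(tuple(obj["consequent"])),
        weight=float(obj.get("weight", 1.0)),
    )


def rule_to_json(rule: Rule) -> dict:
    return {
        "rule_id": rule.rule_id,
        "coding_item": rule.coding_item,
        "antecedents": [
            {"attribute": a.attribute, "op": a.op, "value": a.value, "var": a.var}
            for a in rule.antecedents
        ],
        "consequent": [dict(t) for t in rule.consequent.assertions],
        "weight": rule.weight,
    }


def load_rules(path: str | Path) -> list[Rule]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, list):
        raise ValidationError(f"{path}: rule file must be a JSON array")
    return [rule_from_json(obj) for obj in data]


def save_rules(rules: Iterable[Rule], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([rule_to_json(r) for r in rules], indent=1), encoding="utf-8"
    )


def with_unit_weights(rules: Sequence[Rule]) -> list[Rule]:
    """The same rule base with every weight forced to 1.0 (ablation arm)."""
    return [replace(r, weight=1.0) for r in rules]
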