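"""Cohort filtering, patient-level splitting, and micro P/R/Fβ scoring.

Scores follow the usual micro-averaged definitions per registry item:
P = TP/(TP+FP), R = TP/(TP+FN), Fβ = (1+β²)·P·R/(β²·P+R) with β = 1 by
default.  The engine emits exactly one code per patient and item, so for an
item where every test patient has a gold value and a real (non-abstaining)
prediction, micro precision, recall and F all equal plain accuracy; an
abstention (``NOT_CODED``) against a present gold value counts as a false
negative only, which breaks that equality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .journey_model import PatientJourney
from .rule_engine import NOT_CODED, CodingResult

PRIMARY_SITE_ITEM = "Primary Site"
LUNG_SITE_PREFIXES = ("C33", "C34")


@dataclass(frozen=True)
class GoldRecord:
    """Registrar-assigned codes for one patient (items may be omitted)."""

    patient_id: str
    codes: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "codes",
            {k: v for k, v in dict(self.codes).items() if v not in (None, "")},
        )


@dataclass
class ContingencyCounts:
    item: str
    TP: int = 0
    FP: int = 0
    FN: int = 0


def load_gold_csv(path: str | Path) -> list[GoldRecord]:
    """One row per patient, one column per item; empty cells mean the item
    was not abstracted for that patient."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "patient_id" not in frame.columns:
        raise ValidationError(f"{path}: gold CSV needs a patient_id column")
    records = []
    for _, row in frame.iterrows():
        codes = {c: row[c] for c in frame.columns if c != "patient_id" and row[c] != ""}
        records.append(GoldRecord(patient_id=row["patient_id"], codes=codes))
    return records


def save_gold_csv(gold: Sequence[GoldRecord], path: str | Path) -> None:
    items = sorted({i for g in gold for i in g.codes})
    rows = [
        {"patient_id": g.patient_id, **{i: g.codes.get(i, "") for i in items}}
        for g in gold
    ]
    pd.DataFrame(rows, columns=["patient_id", *items]).to_csv(path, index=False)


def filter_cohort(
    journeys: Sequence[PatientJourney],
    gold: Sequence[GoldRecord],
    *,
    site_item: str = PRIMARY_SITE_ITEM,
    site_prefixes: Sequence[str] = LUNG_SITE_PREFIXES,
) -> tuple[list[PatientJourney], list[GoldRecord], list[tuple[str, str]]]:
    """Drop non-lung patients and patients with too few or one-sided reports.

    Removes: patients whose gold primary site is missing or outside the lung
    value set; patients with fewer than two reports; patients whose reports
    are all of one type.  Returns the surviving pairs and a removal log of
    ``(patient_id, reason)``.
    """
    gold_by_pid = {g.patient_id: g for g in gold}
    kept_j: list[PatientJourney] = []
    kept_g: list[GoldRecord] = []
    log: list[tuple[str, str]] = []
    for journey in journeys:
        pid = journey.patient_id
        record = gold_by_pid.get(pid)
        site = record.codes.get(site_item) if record else None
        if site is None or not any(site.startswith(p) for p in site_prefixes):
            log.append((pid, f"primary site {site!r} not in lung value set"))
            continue
        if len(journey.reports) < 2:
            log.append((pid, "fewer than 2 reports"))
            continue
        if len(journey.report_types()) < 2:
            log.append((pid, "only one report type"))
            continue
        kept_j.append(journey)
        kept_g.append(record)
    return kept_j, kept_g, log


def split_patients(
    patients: Sequence[str], ratio: float, seed: int
) -> tuple[list[str], list[str]]:
    """Deterministic patient-granular split; train size = ⌊n·ratio⌋ (kept in
    [1, n-1] so both sides are non-empty)."""
    if not 0 < ratio < 1:
        raise ValidationError(f"split ratio must be in (0, 1), got {ratio}")
    ids = list(patients)
    if len(ids) < 2:
        raise ValidationError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = min(max(int(math.floor(len(ids) * ratio)), 1), len(ids) - 1)
    train = [ids[i] for i in order[:n_train]]
    test = [ids[i] for i in order[n_train:]]
    return train, test


def _f_beta(p: float, r: float, beta: float) -> float:
    if p == 0 and r == 0:
        return 0.0
    b2 = beta * beta
    denom = b2 * p + r
    return (1 + b2) * p * r / denom if denom > 0 else 0.0


def score(
    predictions: Iterable[CodingResult],
    gold: Sequence[GoldRecord],
    beta: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, ContingencyCounts]]:
    """Per-item micro precision/recall/Fβ against the gold records.

    Pairing rule per patient and item: prediction equal to gold → TP;
    a real prediction different from a present gold code → FP and FN;
    ``NOT_CODED`` against a present gold code → FN; patients without a gold
    value for the item are excluded for that item.  Items with no gold
    anywhere (TP+FN = 0) are dropped; TP+FP = 0 yields P = 0 with a flag.
    """
    gold_by_pid = {g.patient_id: g for g in gold}
    counts: dict[str, ContingencyCounts] = {}
    for pred in predictions:
        record = gold_by_pid.get(pred.patient_id)
        if record is None:
            continue
        gold_code = record.codes.get(pred.item)
        if gold_code is None:
            continue
        c = counts.setdefault(pred.item, ContingencyCounts(pred.item))
        if pred.selected == gold_code:
            c.TP += 1
        elif pred.selected == NOT_CODED:
            c.FN += 1
        else:
            c.FP += 1
            c.FN += 1

    rows = []
    for item in sorted(counts):
        c = counts[item]
        if c.TP + c.FN == 0:
            continue  # no gold for the item after pairing
        undefined_p = (c.TP + c.FP) == 0
        p = 0.0 if undefined_p else c.TP / (c.TP + c.FP)
        r = c.TP / (c.TP + c.FN)
        rows.append(
            {
                "item": item,
                "TP": c.TP,
                "FP": c.FP,
                "FN": c.FN,
                "precision": p,
                "recall": r,
                "f": _f_beta(p, r, beta),
                "precision_undefined": undefined_p,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["item", "TP", "FP", "FN", "precision", "recall", "f", "precision_undefined"],
    ).set_index("item")
    return frame, counts


@dataclass
class ModeBaseline:
    """Constant predictor: always the most frequent training label per item
    (ties broken lexicographically; missing items abstain)."""

    modal_codes: dict[str, str]
    tie_log: list[str] = field(default_factory=list)

    def predict(self, patient_ids: Sequence[str], items: Sequence[str]) -> list[CodingResult]:
        out = []
        for pid in patient_ids:
            for item in items:
                code = self.modal_codes.get(item, NOT_CODED)
                out.append(
                    CodingResult(
                        patient_id=pid,
                        item=item,
                        candidates=((code, 1.0, ()),) if code != NOT_CODED else (),
                        selected=code,
                    )
                )
        return out


def mode_baseline(train_gold: Sequence[GoldRecord]) -> ModeBaseline:
    if not train_gold:
        raise ValidationError("mode baseline needs non-empty training gold")
    tallies: dict[str, dict[str, int]] = {}
    for g in train_gold:
        for item, code in g.codes.items():
            tallies.setdefault(item, {}).setdefault(code, 0)
            tallies[item][code] += 1
    modal: dict[str, str] = {}
    ties: list[str] = []
    for item, counter in tallies.items():
        best = max(counter.values())
        winners = sorted(c for c, n in counter.items() if n == best)
        if len(winners) > 1:
            ties.append(f"{item}: tie among {winners}, chose {winners[0]!r}")
        modal[item] = winners[0]
    return ModeBaseline(modal_codes=modal, tie_log=ties)


def ablation_report(
    predictions_unweighted: Iterable[CodingResult],
    predictions_weighted: Iterable[CodingResult],
    gold: Sequence[GoldRecord],
    beta: float = 1.0,
) -> pd.DataFrame:
    """Side-by-side per-item P/R/F for unit-weight vs learned-weight runs."""
    unw, _ = score(predictions_unweighted, gold, beta)
    wtd, _ = score(predictions_weighted, gold, beta)
    cols = ["precision", "recall", "f"]
    table = unw[cols].join(wtd[cols], lsuffix="_unweighted", rsuffix="_weighted", how="outer")
    table["f_gain"] = table["f_weighted"] - table["f_unweighted"]
    return table
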