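"""Shipped lung-cancer registry configuration: the 30 coding items, their
value sets, the concept dictionary, numeric/date patterns, section lexicon,
sentence templates, and the starter rule base.

The 30 items cover tumour identity (Primary Site, Laterality, Histology,
Behavior Code), grading, pathologic TNM staging and stage descriptors, nodal
counts, surgical margins, site-specific factors (visceral pleural invasion,
mediastinal node sampling, EGFR mutation, ALK translocation), diagnostic
confirmation and key dates.  Each item is associated with the report type
that characteristically carries its evidence — most are abstracted from
pathology reports, while primary site/laterality, the clinical stage
descriptor and diagnosis/surgery dates come from imaging reports.

Value sets and surface forms are a compact, synthetic-but-plausible subset
of the registry coding manual's controlled vocabularies (UMLS identifiers
other than C1261076, "lung, left upper lobe", are illustrative); they are the
single source of truth shared by the rule base and the synthetic cohort
generator, which keeps the two mutually consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .concept_extraction import DictionaryEntry
from .rule_engine import Antecedent, Consequent, Rule, coding_fact_type

PATHOLOGY = "pathology"
IMAGE = "image"

#: Canonical section headings per report type, in rendering order.
PATHOLOGY_SECTIONS = ("Diagnosis", "Microscopic Examination", "Gross Description")
IMAGE_SECTIONS = ("Findings", "Impression")
SECTION_LEXICON = list(PATHOLOGY_SECTIONS + IMAGE_SECTIONS)

#: Section used when a distracting mention is planted in the other report type.
DEFAULT_SECTION = {PATHOLOGY: "Diagnosis", IMAGE: "Findings"}


@dataclass(frozen=True)
class ItemSpec:
    """Static profile of one registry coding item.

    ``kind`` is one of ``valueset`` (dictionary-normalized codes),
    ``numeric``/``decimal`` (pattern-captured literals), or ``date``
    (pattern-captured ISO dates).  ``multi_report`` marks items whose
    evidence can be contradicted from another report of the journey (the
    distractor-eligible items); single-report items keep their evidence in
    exactly one characteristic report.
    """

    item: str
    kind: str
    concept_type: str
    report_type: str
    section: str
    template: str
    codes: tuple[str, ...] = ()
    probs: tuple[float, ...] = ()
    surfaces: tuple[str, ...] = ()
    multi_report: bool = True


#: (CUID, surface, primary-site code, laterality code, probability)
SITE_LATERALITY_COMBOS: tuple[tuple[str, str, str, str, float], ...] = (
    ("C1261076", "lung, left upper lobe", "C341", "2", 0.35),
    ("C0225754", "lung, right upper lobe", "C341", "1", 0.30),
    ("C0225758", "lung, right lower lobe", "C343", "1", 0.20),
    ("C0225757", "lung, left lower lobe", "C343", "2", 0.15),
)

PRIMARY_SITE_ITEM = "Primary Site"
LATERALITY_ITEM = "Laterality"
SITE_CONCEPT = "PrimarySiteLaterality"
SITE_TEMPLATE = "Mass in the {surface}."
SITE_SECTION = "Impression"

VALUESET_ITEMS: tuple[ItemSpec, ...] = (
    ItemSpec(
        "AJCC Edition", "valueset", "AjccEdition", PATHOLOGY, "Diagnosis",
        "Staging performed per {surface}.",
        codes=("7", "8"), probs=(0.94, 0.06),
        surfaces=("AJCC 7th edition", "AJCC 8th edition"),
        multi_report=False,
    ),
    ItemSpec(
        "Behavior Code", "valueset", "BehaviorCode", PATHOLOGY, "Microscopic Examination",
        "Morphology consistent with {surface}.",
        codes=("3", "2"), probs=(0.97, 0.03),
        surfaces=("behavior code 3", "behavior code 2"),
        multi_report=False,
    ),
    ItemSpec(
        "Clinical Other Staging Group", "valueset", "ClinicalOtherStagingGroup",
        PATHOLOGY, "Diagnosis", "Assessment: {surface}.",
        codes=("888", "999"), probs=(0.93, 0.07),
        surfaces=("other staging group not applicable", "other staging group unknown"),
        multi_report=False,
    ),
    ItemSpec(
        "Clinical Stage Descriptor", "valueset", "ClinicalStageDescriptor",
        IMAGE, "Impression", "Staging annotation: {surface}.",
        codes=("0", "1"), probs=(0.70, 0.30),
        surfaces=("clinical descriptor none", "clinical descriptor y"),
    ),
    ItemSpec(
        "Diagnostic Confirmation", "valueset", "DiagnosticConfirmation",
        PATHOLOGY, "Diagnosis", "Diagnosis {surface}.",
        codes=("1", "2"), probs=(0.97, 0.03),
        surfaces=("confirmed by positive histology", "confirmed by positive cytology"),
        multi_report=False,
    ),
    ItemSpec(
        "Grade Clinical", "valueset", "GradeClinical", PATHOLOGY,
        "Microscopic Examination", "Pre-treatment assessment: {surface}.",
        codes=("1", "2", "3"), probs=(0.25, 0.58, 0.17),
        surfaces=("clinical grade I", "clinical grade II", "clinical grade III"),
    ),
    ItemSpec(
        "Grade Pathological", "valueset", "GradePathological", PATHOLOGY,
        "Microscopic Examination", "Tumor shows {surface}.",
        codes=("1", "2", "3"), probs=(0.20, 0.57, 0.23),
        surfaces=("histologic grade I", "histologic grade II", "histologic grade III"),
    ),
    ItemSpec(
        "Histology", "valueset", "Histology", PATHOLOGY, "Microscopic Examination",
        "Sections show {surface}.",
        codes=("8140", "8070", "8041"), probs=(0.40, 0.35, 0.25),
        surfaces=("adenocarcinoma", "squamous cell carcinoma", "small cell carcinoma"),
    ),
    ItemSpec(
        "Lymph vessels or Vascular Invasion", "valueset", "LymphVascularInvasion",
        PATHOLOGY, "Microscopic Examination", "Vessels: {surface}.",
        codes=("0", "1"), probs=(0.60, 0.40),
        surfaces=("no lymphovascular invasion", "lymphovascular invasion present"),
    ),
    ItemSpec(
        "Other Staging System", "valueset", "OtherStagingSystem", PATHOLOGY,
        "Diagnosis", "Classification note: {surface}.",
        codes=("88", "99"), probs=(0.93, 0.07),
        surfaces=("no other staging system used", "other staging system unknown"),
        multi_report=False,
    ),
    ItemSpec(
        "Pathologic M", "valueset", "PathologicM", PATHOLOGY, "Diagnosis",
        "Distant spread category {surface}.",
        codes=("pM0", "pM1a"), probs=(0.80, 0.20),
        surfaces=("pM0", "pM1a"),
    ),
    ItemSpec(
        "Pathologic N", "valueset", "PathologicN", PATHOLOGY, "Diagnosis",
        "Nodal category {surface}.",
        codes=("pN0", "pN1", "pN2"), probs=(0.53, 0.30, 0.17),
        surfaces=("pN0", "pN1", "pN2"),
    ),
    ItemSpec(
        "Pathologic T", "valueset", "PathologicT", PATHOLOGY, "Diagnosis",
        "Primary tumor category {surface}.",
        codes=("pT1b", "pT2a", "pT3"), probs=(0.52, 0.30, 0.18),
        surfaces=("pT1b", "pT2a", "pT3"),
    ),
    ItemSpec(
        "Pathologic Stage Descriptor", "valueset", "PathologicStageDescriptor",
        PATHOLOGY, "Diagnosis", "Stage annotation: {surface}.",
        codes=("0", "4"), probs=(0.94, 0.06),
        surfaces=("pathologic descriptor none", "pathologic descriptor y"),
        multi_report=False,
    ),
    ItemSpec(
        "Perineural Invasion", "valueset", "PerineuralInvasion", PATHOLOGY,
        "Microscopic Examination", "Nerves: {surface}.",
        codes=("0", "1"), probs=(0.58, 0.42),
        surfaces=("no perineural invasion", "perineural invasion identified"),
    ),
    ItemSpec(
        "Scope of Regional Lymph Node Surgery", "valueset", "NodeSurgeryScope",
        PATHOLOGY, "Gross Description", "Procedure: {surface}.",
        codes=("0", "4", "5"), probs=(0.52, 0.30, 0.18),
        surfaces=(
            "no regional node surgery",
            "regional lymphadenectomy performed",
            "sentinel node biopsy performed",
        ),
    ),
    ItemSpec(
        "SSF 2", "valueset", "SSF2", PATHOLOGY, "Microscopic Examination",
        "Pleura: {surface}.",
        codes=("000", "010"), probs=(0.55, 0.45),
        surfaces=("visceral pleural invasion absent", "visceral pleural invasion present"),
        multi_report=False,
    ),
    ItemSpec(
        "SSF 5", "valueset", "SSF5", PATHOLOGY, "Gross Description",
        "Mediastinum: {surface}.",
        codes=("000", "010"), probs=(0.55, 0.45),
        surfaces=("mediastinal nodes not sampled", "mediastinal nodes sampled"),
        multi_report=False,
    ),
    ItemSpec(
        "SSF 6", "valueset", "SSF6", PATHOLOGY, "Diagnosis",
        "Molecular testing: {surface}.",
        codes=("010", "020"), probs=(0.53, 0.47),
        surfaces=("EGFR mutation detected", "EGFR wild type"),
        multi_report=False,
    ),
    ItemSpec(
        "SSF 7", "valueset", "SSF7", PATHOLOGY, "Diagnosis",
        "Molecular testing: {surface}.",
        codes=("010", "020"), probs=(0.45, 0.55),
        surfaces=("ALK translocation detected", "ALK translocation not detected"),
        multi_report=False,
    ),
    ItemSpec(
        "Surgical Margins", "valueset", "SurgicalMargins", PATHOLOGY,
        "Gross Description", "Margins: {surface}.",
        codes=("0", "1"), probs=(0.52, 0.48),
        surfaces=("surgical margins uninvolved", "surgical margins involved"),
    ),
)

NUMERIC_ITEMS: tuple[ItemSpec, ...] = (
    ItemSpec(
        "Nodes Positive", "numeric", "NodesPositive", PATHOLOGY,
        "Microscopic Examination", "{positive} of {examined} lymph nodes are positive.",
    ),
    ItemSpec(
        "Nodes Examined", "numeric", "NodesExamined", PATHOLOGY,
        "Microscopic Examination", "{positive} of {examined} lymph nodes are positive.",
    ),
    ItemSpec(
        "Surgical Margins Distance", "decimal", "SurgicalMarginsDistance",
        PATHOLOGY, "Gross Description", "Closest margin distance {value} cm.",
    ),
)

DATE_ITEMS: tuple[ItemSpec, ...] = (
    ItemSpec(
        "Date of First Microscopic Confirmation", "date", "DateFirstMicroConfirm",
        PATHOLOGY, "Diagnosis", "Microscopic confirmation obtained on {value}.",
    ),
    ItemSpec(
        "Date of Surgical Diagnostic and Staging Procedure", "date",
        "DateSurgStaging", PATHOLOGY, "Gross Description",
        "Surgical staging procedure performed on {value}.",
    ),
    ItemSpec(
        "Date of Initial Diagnosis", "date", "DateInitialDiagnosis",
        IMAGE, "Impression", "Initial diagnosis established on {value}.",
    ),
    ItemSpec(
        "Date of First Surgical Procedure", "date", "DateFirstSurgery",
        IMAGE, "Impression", "First surgical procedure performed on {value}.",
    ),
)

ITEM_SPECS: tuple[ItemSpec, ...] = VALUESET_ITEMS + NUMERIC_ITEMS + DATE_ITEMS

#: All 30 coding items handled by the shipped configuration.
ITEMS: tuple[str, ...] = tuple(
    sorted([s.item for s in ITEM_SPECS] + [PRIMARY_SITE_ITEM, LATERALITY_ITEM])
)

_DATE_RE = r"(\d{4}-\d{2}-\d{2})"

#: Numeric / date capture patterns, keyed by concept type.  Tumor Size is
#: captured as a concept even though no shipped rule consumes it.
PATTERNS: dict[str, list[dict]] = {
    "NodesPositive": [
        {"pattern": r"\b([A-Za-z]+|\d+)\s+of\s+\d+\s+lymph nodes", "group": 1}
    ],
    "NodesExamined": [
        {"pattern": r"\bof\s+(\d+)\s+lymph nodes", "group": 1}
    ],
    "SurgicalMarginsDistance": [
        {"pattern": r"margin distance\s+(\d+(?:\.\d+)?)\s*cm", "group": 1}
    ],
    "TumorSize": [
        {"pattern": r"tumor size\s+(\d+(?:\.\d+)?)\s*cm", "group": 1}
    ],
    "DateFirstMicroConfirm": [
        {"pattern": r"microscopic confirmation obtained on\s+" + _DATE_RE, "group": 1}
    ],
    "DateSurgStaging": [
        {"pattern": r"surgical staging procedure performed on\s+" + _DATE_RE, "group": 1}
    ],
    "DateInitialDiagnosis": [
        {"pattern": r"initial diagnosis established on\s+" + _DATE_RE, "group": 1}
    ],
    "DateFirstSurgery": [
        {"pattern": r"first surgical procedure performed on\s+" + _DATE_RE, "group": 1}
    ],
}


def default_dictionary() -> list[DictionaryEntry]:
    """The shipped concept dictionary (surface → concept type + code)."""
    entries: list[DictionaryEntry] = []
    for spec in VALUESET_ITEMS:
        for code, surface in zip(spec.codes, spec.surfaces):
            entries.append(DictionaryEntry(surface, spec.concept_type, code))
    for cuid, surface, _site, _lat, _p in SITE_LATERALITY_COMBOS:
        entries.append(DictionaryEntry(surface, SITE_CONCEPT, cuid))
    return entries


def default_patterns() -> dict[str, list[dict]]:
    return {k: [dict(p) for p in v] for k, v in PATTERNS.items()}


def _slug(item: str) -> str:
    return item.lower().replace(" ", "-")


def _other(report_type: str) -> str:
    return IMAGE if report_type == PATHOLOGY else PATHOLOGY


def default_rules() -> list[Rule]:
    """The starter lung rule base covering all 30 items.

    Multi-report items get one rule per code per report type; the consequent
    carries a ``source`` attribute naming the report type, so the
    characteristic-type route and the cross-type route have distinct
    consequence vertices and can learn different weights (report-type
    priority is exactly what the weight learner is expected to discover).
    Single-report items get one type-agnostic rule per code.
    """
    rules: list[Rule] = []

    for spec in VALUESET_ITEMS:
        ftype = coding_fact_type(spec.item)
        for code in spec.codes:
            base = (
                Antecedent("type", "eq", spec.concept_type),
                Antecedent("value", "eq", code),
            )
            if spec.multi_report:
                for rt in (spec.report_type, _other(spec.report_type)):
                    rules.append(
                        Rule(
                            rule_id=f"{_slug(spec.item)}-{code}-{rt}",
                            coding_item=spec.item,
                            antecedents=base
                            + (Antecedent("reportType", "eq", rt),),
                            consequent=Consequent(
                                ({"type": ftype, "value": code, "source": rt},)
                            ),
                        )
                    )
            else:
                rules.append(
                    Rule(
                        rule_id=f"{_slug(spec.item)}-{code}",
                        coding_item=spec.item,
                        antecedents=base,
                        consequent=Consequent(({"type": ftype, "value": code},)),
                    )
                )

    for cuid, _surface, site, lat, _p in SITE_LATERALITY_COMBOS:
        base = (
            Antecedent("type", "eq", SITE_CONCEPT),
            Antecedent("UMLS", "eq", cuid),
        )
        for rt in (IMAGE, PATHOLOGY):
            rules.append(
                Rule(
                    rule_id=f"primary-site-{cuid}-{rt}",
                    coding_item=PRIMARY_SITE_ITEM,
                    antecedents=base + (Antecedent("reportType", "eq", rt),),
                    consequent=Consequent(
                        (
                            {
                                "type": coding_fact_type(PRIMARY_SITE_ITEM),
                                "value": site,
                                "source": rt,
                            },
                        )
                    ),
                )
            )
            rules.append(
                Rule(
                    rule_id=f"laterality-{cuid}-{rt}",
                    coding_item=LATERALITY_ITEM,
                    antecedents=base + (Antecedent("reportType", "eq", rt),),
                    consequent=Consequent(
                        (
                            {
                                "type": coding_fact_type(LATERALITY_ITEM),
                                "value": lat,
                                "source": rt,
                            },
                        )
                    ),
                )
            )

    for spec in NUMERIC_ITEMS + DATE_ITEMS:
        ftype = coding_fact_type(spec.item)
        for rt in (spec.report_type, _other(spec.report_type)):
            rules.append(
                Rule(
                    rule_id=f"{_slug(spec.item)}-{rt}",
                    coding_item=spec.item,
                    antecedents=(
                        Antecedent("type", "eq", spec.concept_type),
                        Antecedent("reportType", "eq", rt),
                    ),
                    consequent=Consequent(
                        ({"type": ftype, "value": "{C.value}", "source": rt},)
                    ),
                )
            )
    return rules


def spec_for(item: str) -> ItemSpec | None:
    for spec in ITEM_SPECS:
        if spec.item == item:
            return spec
    return None
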