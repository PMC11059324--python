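import datetime as dt

import numpy as np
import pytest

from regcode.journey_model import Report, Sentence
from regcode.rule_engine import Antecedent, Consequent, Fact, Rule


@pytest.fixture
def path_report():
    return Report(
        report_id="R1",
        patient_id="P1",
        report_type="pathology",
        date=dt.date(2018, 3, 2),
        text=(
            "Diagnosis:\n"
            "Adenocarcinoma of the lung, left upper lobe.\n"
            "Microscopic Examination:\n"
            "Tumor cells are seen. Six of 21 lymph nodes are positive.\n"
            "Gross Description:\n"
            "Closest margin distance 0.3 cm."
        ),
    )


@pytest.fixture
def lexicon():
    return ["Diagnosis", "Microscopic Examination", "Gross Description",
            "Findings", "Impression"]


def sentence(text, section="UNSECTIONED", report_id="R1", index=0):
    from regcode.journey_model import tokenize

    return Sentence(report_id=report_id, section_label=section, index=index,
                    text=text, tokens=tokenize(text))


@pytest.fixture
def make_sentence():
    return sentence


def prop_fact(letter):
    """Propositional fact used by the closure and graph oracles."""
    return Fact({"type": letter})


def prop_rule(rule_id, antecedent_letters, consequence, coding_item="intermediate",
              value=None):
    """A∧B→C style rule over propositional facts.  With ``value`` set, the
    consequent is a coding assertion ``{type: <consequence>, value: <value>}``."""
    ants = tuple(
        Antecedent("type", "eq", letter, var=f"v{i}")
        for i, letter in enumerate(antecedent_letters)
    )
    template = {"type": consequence}
    if value is not None:
        template["value"] = value
    return Rule(rule_id=rule_id, coding_item=coding_item, antecedents=ants,
                consequent=Consequent((template,)))


def naive_closure(observed_letters, propositional_rules):
    """Independent fixpoint oracle: repeated scans over (antecedents → head)
    letter rules until no new head letter is derived."""
    known = set(observed_letters)
    heads = [
        (
            {a.value for a in r.antecedents},
            r.consequent.assertions[0]["type"],
        )
        for r in propositional_rules
    ]
    changed = True
    while changed:
        changed = False
        for body, head in heads:
            if body <= known and head not in known:
                known.add(head)
                changed = True
    return known


@pytest.fixture
def rng():
    return np.random.default_rng(20240407)
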