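# Methods

## The coding task

A hospital cancer registry abstracts each patient's free-text reports into a
structured registry record: one controlled-vocabulary code per *coding item*
(Primary Site, Histology, Pathologic T, Nodes Examined, ...).  `regcode`
models this as a function from a **patient journey** — the date-ordered set
of all pathology and imaging reports accumulated over roughly 1.5 years of
treatment — to a vector of 30 lung-cancer item codes.  The unit of inference
is always the whole journey: the evidence for one item may sit in any
report, and different reports may disagree.

The system is symbolic end to end: concept extraction feeds a fact database,
weighted production rules forward-chain over it, and the highest-weight
candidate wins per item.  Every stage is deterministic given its inputs and
a seed.

## Preprocessing

Reports are split into lines; a line equal (case-insensitively, modulo a
trailing colon) to a section-lexicon entry becomes the active heading, and
every following sentence carries that heading until the next one
(last-heading-wins, flat — no nesting).  Sentences are split on newline and
on `". "` followed by an uppercase letter, with a small clinical
abbreviation list (`cm.`, `No.`, ...) exempted.  Tokens are whitespace-split
words with leading/trailing punctuation stripped, which keeps composite
values (`pT2a`, `0.3`, ISO dates) intact.  These choices are deliberately
bit-stable rather than linguistically sophisticated: the downstream matcher
is a dictionary, not a parser.

## Concept extraction

Recognition is case-insensitive leftmost-longest dictionary lookup over
token spans (with an optional per-entry one-token gap), normalising each
surface to a UMLS CUID, a registry value-set code, or — via regex patterns —
a literal number or date.  Count/size/date items cannot be enumerated in a
dictionary, so they are pattern-captured (`"Six of 21 lymph nodes"` →
NodesPositive = 6, NodesExamined = 21; number words up to twenty are
mapped to digits).

Mentions become facts: attribute maps carrying `type`, `value`, `UMLS`
(when the code is a CUID), `section`, `reportType`, `date`, `reportId`, and
one boolean `cooccur<Type>` flag per *other* concept type present in the
same sentence.  Co-occurrence is per concept type, not per mention, matching
the antecedent form rules actually use (`C.cooccurHistology = True`).

A learned neural recogniser could replace the dictionary behind the same
mention/fact schema; nothing downstream depends on how mentions were found.

## The rule engine

A rule is `AND`-joined antecedents plus a consequent of fact templates.
Antecedent conditions are `(attribute, operator, value)` with operators
`eq/ne/ge/le/present`; conditions sharing a fact variable must be satisfied
by a single fact, while distinct variables bind independently — the printed
registry rules are per-concept conditions, but cross-fact conjunctions
(e.g. a report-type guard) need independent binding.  Consequent template
values of the form `{C.value}` copy an attribute from the bound fact; this
is how literal-valued items (counts, distances, dates) get coded.  For a
static consequent the engine asserts once per satisfied rule; templated
consequents assert once per distinct binding of the referenced variables.

The fact database has set semantics (re-assertion is a no-op) and records
provenance (which rule asserted a fact) plus the earliest supporting report
date.  Forward chaining sweeps all rules until a sweep adds nothing; under
set semantics this least fixpoint exists, is reached in at most
(#derivable facts + 1) sweeps, and is independent of rule order (property-
tested against a naive closure oracle).

Per item, the candidate codes are the distinct values of the asserted
`*_CODING` facts.  Each candidate scores the **maximum** weight of the rules
that asserted it (a `sum` aggregation is available as a switch but is not
the default, since selection is specified as "highest weight").  Ties break
by earlier supporting report date, then lexicographically smaller code —
arbitrary but deterministic.  An item with no fired rule yields the
`NOT_CODED` sentinel, which evaluation counts as a false negative only.

## Weight learning

Weights are estimated per coding type from training journeys and their
registrar-assigned gold codes, via a directed co-occurrence graph:

* one vertex per distinct antecedent (a variable's canonicalised condition
  set) and per distinct consequence assertion, deduplicated across rules;
  an intermediate consequence that reappears as an antecedent is a single
  shared vertex;
* within a rule, every antecedent pair is joined by edges both ways; every
  antecedent points at each consequence and at its paired *non-match* twin
  (`-`-prefixed), which has no outgoing edges and exists purely as a count
  sink.

For each training journey (skipped when the patient has no gold value for
the type), counting runs against the forward-chained closure of the
journey's facts: an antecedent pair with both sides matched increments the
two symmetric cells of the integer matrix Β (a full rule firing is *not*
required for pair counts); a fired rule increments antecedent→consequence
cells when some asserted code equals gold, else antecedent→non-match cells;
intermediate consequences count as matched whenever their rule fires, since
no gold exists to contradict them.  Β is square over antecedent +
consequence + non-match vertices; the non-match columns are the reason the
matrix must be wider than antecedents-and-consequences alone.

The adjacency matrix is the row normalisation
`Α_ij = Β_ij / q_i` (with `Α_ii = 0` when row `i` has mass, `1` when it is
empty, `q_i` the row sum), so each occupied row is a probability vector.
One message-passing phase assigns every vertex the sum of adjacency mass
flowing *into* it from its in-neighbourhood, `w_i = Σ_{j∈N(v_i)} Α_ji`, and
each rule inherits the weight of its consequence vertex.  The update is
one-hop by design; `phases > 1` iterates it with the previous weights
normalised to unit mass, exposed for experimentation but not default.

Interpretation: an antecedent's row mass is split between the consequences
it supported and their non-match twins, so `Α_{ant→cons}` is the empirical
precision of that antecedent asserting that consequence, and a consequence
vertex's weight is the summed precision of its feeding antecedents.  Raw
sums are used; weights are not re-normalised per coding type before
ranking.

Co-occurrence scope defaults to the journey (codes and gold are per
patient); a per-report scope is available.

## The shipped lung rule base

One rule per (item, code) pair for single-report items; for multi-report
items, one rule per code per report type, whose consequents carry a
`source` attribute naming the report type.  The `source` attribute gives
the characteristic-type route and the cross-type route distinct consequence
vertices, hence independently learnable weights — encoding report-type
priority in rule weights is precisely the behaviour the weight learner is
meant to recover, and with unit weights the two routes are
indistinguishable.  Literal-valued items use `{C.value}` consequents, one
per report type.  Primary Site and Laterality are coded by separate rules
sharing the per-CUID site/laterality antecedent.

## Synthetic cohorts

No public corpus pairs free-text journeys with registry gold, so the
generator manufactures cohorts with the structure the method assumes:

* report volumes: Poisson means of 4.8 pathology and 9.8 imaging reports
  per patient (14.6 total; the literature reports both a 14.6-average and a
  larger imaging-heavy figure, so both means are configurable), dated
  uniformly over an 18-month window;
* per item: a gold code drawn from a skewed label distribution (strongly
  modal for the items registries observe to be near-constant, flatter
  elsewhere; overridable per item), and one supporting sentence rendered
  from a fixed template into the item's characteristic report type and
  section;
* distractors: for each multi-report item independently, with probability
  `distractor_rate` (default 0.3) a conflicting code is rendered into a
  report of the *other* type.  Single-report items (the SSFs, Behavior
  Code, stage descriptors, and similar) never receive distractors;
* date items take the date of the earliest report of their characteristic
  type; nodal counts share one sentence (`positive ≤ examined`); primary
  site and laterality share one site/laterality mention;
* gold and a truth log (which sentence is evidence, which distractor) are
  emitted by the generator's own bookkeeping, never re-derived through the
  engine, so round-trip tests have an independent oracle;
* `corrupt_cohort` drops or misspells evidence sentences at given rates for
  robustness fixtures.

What the generator does **not** emulate: realistic clinical prose, negation
and hedging, recogniser errors, inter-item correlations (TNM consistency),
Chinese/Taiwanese reporting conventions, or report-type-specific
vocabulary drift.  A clean round trip therefore demonstrates internal
consistency of extraction, rules and scoring — not clinical-grade accuracy;
the distractor experiments demonstrate the *direction* of the weighted-rule
effect, not its magnitude on hospital data.

## Evaluation

Patient-level cohort filters mirror registry practice: drop patients whose
gold primary site is outside the lung value set (C33x/C34x), with fewer
than two reports, or with a single report type.  Splits are
patient-granular with train size `⌊n·ratio⌋`, deterministic under a seed.
Scoring is micro-averaged P/R/Fβ per item (β = 1): equal codes → TP;
a real wrong code → FP + FN; `NOT_CODED` against present gold → FN only;
patients lacking gold for an item are excluded for that item.  Because the
engine emits exactly one code per patient and item, P = R = accuracy
whenever nothing abstains, and the mode baseline's F equals its modal-label
frequency.  The ablation report runs inference twice — unit weights vs
learned weights — on identical facts.

## Problem sizes and numerics

Default verification runs use cohorts of 40–1000 patients; the
weighted-vs-unweighted direction check uses 20 seeds × 1000 patients with
an 80:20 split, and the graph arithmetic is verified against a literal
counting oracle to 1e-12 on 100 random bases of ≤ 8 vertices.  All
randomness flows through `numpy.random.default_rng` seeds; generated
cohorts are byte-identical across runs of the same seed.  Division guards:
an empty Β row yields a unit diagonal in Α; P with TP+FP = 0 is reported
as 0 and flagged; items with no gold are dropped rather than scored.

## Known limitations

* The concept recogniser is a dictionary/pattern matcher; paraphrases and
  typos outside the gap tolerance are missed (the typo-corruption tests
  quantify this degradation).
* Rule weights are per consequence vertex, so two rules asserting an
  identical consequence are indistinguishable by weight; route-specific
  consequence attributes (as in the shipped base) are the supported way to
  separate them.
* Negation is not modelled as scope; "absent" readings must be explicit
  value-set surfaces.
* Backward chaining is not implemented as a query language; the provenance
  trace (rule ids per asserted fact) serves the explanation use case.
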