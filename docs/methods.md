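# Methods

## Data model

Patient data is an *archetype-lite* reconstruction of openEHR-style
records. A schema registry declares, per archetype, the element paths
(`/data[at0001]/items[at0002.1]`), value kinds (count, quantity,
boolean, text, coded text, date-time, duration), the fixed unit of each
quantity and the allowed local codes of each coded element. Sixteen
schemas ship with the package: fourteen reconstructions of reused
archetype identifiers plus two purpose-built ones (the NIHSS observation
and the thrombolysis-contraindications evaluation, one boolean element
per audited criterion). Element paths and at-codes are faithful
reconstructions, not copies of any published ADL source, since those
sources do not print them.

ITEM_TREE archetypes (imaging, medication, gas administration) are never
instantiated on their own; hosts declare a slot and the tree's elements
are flattened into the host under a `/description[<item-tree-id>]`
prefix (gas administration is hosted by the procedure ACTION, imaging by
the imaging INSTRUCTION, medication by the medication INSTRUCTION). This
mirrors how templates resolve slots while keeping the registry flat.

Units are fixed per element (mmol/l, mmHg, %, °C); a value in any other
unit is a validation error, never converted. Timestamps are ISO 8601 and
must be uniformly aware or uniformly naive within one case; durations
are fixed-span ISO periods (no calendar years/months), compared at
second resolution.

## Rule dialect and engine semantics

Rules are written as `when`/`then` strings over `$gt`-code bindings; the
grammar (documented in `strokeaudit/expr.py`) has strict and non-strict
comparisons, `&&`/`||`/`!` with Kleene three-valued semantics, datetime
± duration arithmetic against a fixed `currentDateTime`, `is_a`
membership tests against per-guideline term groups, `exists`, and
assignments whose right-hand side may be a literal, a coded term, or a
± chain over references (needed to total the NIHSS contributions).
Operator precedence is `!` > `&&` > `||`; a bare `=` is only legal as a
whole `then` expression.

Evaluation semantics, in order of importance:

* **Retrospective clock.** `currentDateTime` is fixed for the whole run
  and defaults to the case's `reference_time` — the thrombolysis
  decision instant set by the generator — so "more than 4.5 hours ago"
  is anchored to the decision, not to wall-clock now.
* **Existential instance joins.** Candidate tuples are the cartesian
  product of the case's entries over the rule's input archetypes; a rule
  fires when some tuple satisfies every condition. Screening asks "does
  any recorded event qualify", so one qualifying entry suffices. An
  input archetype without entries contributes an unknown-valued slot;
  rules none of whose inputs have entries get no tuples.
* **Three-valued logic.** Absent values make conditions unknown, and a
  rule fires only on definite truth. Every audited flag has a set-false
  rule (priority 20) and a set-true rule (priority 10); higher priority
  runs first and the last assignment in a pass wins, so a definite
  positive always dominates a definite negative, and a flag with
  neither is reported *indeterminate*. An audit must never conclude
  compliance from missing data.
* **Fixpoint.** Passes repeat until working memory is unchanged at a
  pass boundary (re-assigning an identical value is not a change), with
  a guard of `len(rules) + 1` passes. Comparing at pass boundaries makes
  the set-true/set-false pairs stable by construction. The shipped
  content is stratified — NIHSS item scores → total → flags — and
  settles in at most three passes.

Chaining across guidelines is explicit: the scoring guideline's outputs
are materialised back into the case (`apply_outputs`) before the
contraindication guideline reads the total. Outputs are written into
every existing entry of the output archetype, or into one new entry
stamped at the reference time when none exists.

## Temporal conventions

* Look-back windows are fixed spans: last week = 168 h, last month =
  30 d, last three months = 90 d, inclusive at both ends. Calendar-month
  arithmetic is deliberately avoided as untestable.
* Diagnosis-history windows additionally require the onset to predate
  the decision instant by more than 24 h. Without this guard the index
  stroke itself (onset a few hours before the decision) would satisfy
  "stroke in the last three months" for every patient; the guard
  separates pre-admission history from the current episode. Procedure
  windows are not guarded — a lumbar puncture during the admission
  still contraindicates.
* Temperature monitoring is satisfied by ≥ 1 reading inside
  [onset, onset + 72 h]; a pyrexia alert needs an in-window reading
  above 37.5 °C. No sampling-frequency requirement is imposed. With no
  in-window reading the pyrexia flag is indeterminate; with no
  temperature data at all both flags are indeterminate.
* Every numeric threshold is strict exactly as phrased: "higher than
  25", "lower than 3", "more than 4.5 hours", "below 95 %", "exceed
  37.5 °C".

## Terminology

Code systems are DAGs with explicit parent links; `is_a` is the
reflexive-transitive closure, and ICD-10 code nesting (G83.8 under G83)
is encoded as parent links rather than string-prefix logic so
subsumption is uniform across SNOMED CT, ICD-10 and ATC.
Anticoagulation is detected as the ATC `B01A` subtree on medication
entries, bleeding disorder as a diagnosis group. Group matching is
tolerant: a system the group does not bind, or a code the store does not
know, counts as a non-match (logged) instead of an error, so one oddly
coded entry cannot abort an audit.

Only a handful of concept identifiers in the shipped tables are
normative for this content; the remainder are curated placeholders
(marked as such in the table headers) sufficient to express and test the
criteria. The tables are deliberately small, human-editable TSVs.

## Rule decomposition

The thrombolysis guideline ships as 28 rules (a set-true/set-false pair
for each of the 14 represented criteria), the NIHSS guideline as 58 (one
per item level — the 15-element instrument has 57 levels — plus the
summation rule), and the European-criteria guideline as 10. The
decomposition is this package's own; only the criterion-level behaviour,
not any particular rule count, is asserted by tests.

## Synthetic cohort

The generator emulates a mock acute-stroke cohort: every case is a
perturbation of a clean scaffold (index stroke diagnosis with onset
0.5–12 h before the decision, unremarkable glucose 4–7 mmol/l, SpO2
96–99 %, temperature 36.2–37.2 °C in-window, low NIHSS, normal CT,
distant benign history, a benign procedure and medication so that group
criteria can evaluate to a definitive false). Thirty scenario profiles
exercise each criterion in both directions — including
missing-data profiles that land on *indeterminate* and a
deliberately non-compliant case (thrombolysis despite a late onset).
The default cohort of 49 cycles through the catalogue; all values are
drawn from `Random(f"{profile}|{seed}")` with per-case seeds derived
from the master seed, so cohorts are byte-identical across runs and any
case is independently reproducible.

What the generator does *not* emulate: realistic marginal distributions
or correlations (values are uniform within plausible ranges),
free-text notes, coding errors, duplicate or conflicting NIHSS
observations (exactly one per case), or longitudinal records. Passing
tests therefore demonstrate semantic correctness of the rule machinery
on plausible structured data, not robustness to real-world EHR noise.

## Verification strategy

The headline check is dual-route: the engine path (dialect files →
parser → bindings → forward chaining) versus a straight-line oracle that
re-derives every verdict directly from the entries with plain
per-criterion predicates, sharing only the terminology closure — which
is itself property-tested against brute-force graph reachability on
random DAGs. Engine and oracle must produce identical verdict vectors on
the default cohort and on fuzzed cases across all profiles and seeds.
Thresholds are additionally recovered black-box by scanning/bisection
over single-feature probe cases, so a mistyped constant in the content
cannot hide behind an agreeing oracle.

Problem sizes used by the default test run and the acceptance script:
the 49-case default cohort, ~360 fuzzed engine-vs-oracle cases, 1000
random NIHSS vectors, 25 random subsumption DAGs of ≤ 50 nodes, and
about 20 bisection probes per threshold. The whole suite runs in well
under a minute.

## Known limitations

* The onset-window criterion flags *any* stroke diagnosis whose onset
  exceeds 4.5 h — with both an old and an acute stroke diagnosis on
  file, the old one triggers it. The generator records the index stroke
  once; resolving "which onset is the index event" in general would need
  an episode model.
* "Suspected septic shock" matches the diagnosis group regardless of the
  recorded Confidence (Suspicion/Certainty); the confidence element is
  modelled and populated but not yet discriminating.
* The NIHSS scoring chain assumes one NIHSS observation per case;
  contributions from several observations would be pooled existentially.
* Indeterminate is deliberately sticky: a patient with no temperature
  observations is indeterminate for monitoring compliance rather than
  non-compliant, which understates violations when data capture itself
  is the failure.
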