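# strokeaudit

Retrospective auditing of acute-stroke care against clinical practice
guidelines, built as a small computer-interpretable-guideline stack:
an archetype-based clinical data model, a declarative rule dialect with
terminology bindings, a three-valued forward-chaining engine, and shipped
rule content for thrombolysis contraindications, NIHSS scoring and a
sample of the European ischaemic-stroke management recommendations.

It is aimed at clinical-informatics researchers who want to study
guideline-compliance checking over structured EHR-style data without a
full openEHR platform: patient cases are bags of typed, path-addressed
entries (`OBSERVATION` / `EVALUATION` / `INSTRUCTION` / `ACTION`), rules
bind `gt`-codes to archetype elements and set output flags, and coded
values are tested for set membership through SNOMED CT / ICD-10 / ATC
`is_a` subsumption.

## The model in brief

A guideline is a triple *(bindings, rules, term groups)*. Each rule is a
conjunction of conditions over bound elements — comparisons with strict
thresholds exactly as the clinical text phrases them ("higher than 25" ⇒
`$gt0008 > 25`), timestamp arithmetic against the fixed evaluation
instant ("more than 4.5 hours ago" ⇒ `$gt0004 + PT4H30M <
currentDateTime`), and subsumption tests (`$gt0003 is_a
local::gt0102|stroke|`). Evaluation is forward chaining to a fixpoint
under Kleene three-valued logic: a rule fires when *some* combination of
entries definitely satisfies it; flags whose rules never fire are
reported **indeterminate** rather than silently assumed compliant.
Each audited criterion carries a set-true/set-false rule pair, so every
verdict is `triggered`, `not_triggered`, or `indeterminate`.

The shipped content covers 14 of the 19 listed thrombolysis
contraindications (the five that hinge on vague wording are catalogued
but never evaluated), the 15-element NIHSS instrument (one rule per item
level plus a summation rule, totals 0–42), and five European-guideline
criteria (MRI justification, thrombolysis indication, 72 h temperature
monitoring with a 37.5 °C pyrexia alert, oxygen below 95 % SpO2).

An engine-independent oracle re-derives every verdict straight from the
entries with plain Python predicates, formalising a manual chart review;
`compare` counts the cases whose whole verdict vectors agree.

## Worked example

```
$ strokeaudit generate --n 8 --seed 7 --out cohort/
wrote 8 cases to cohort

$ strokeaudit check --cases cohort/ --self-test
criterion_id  title                                              triggered  not_triggered  indeterminate
c01           Stroke onset more than 4.5 hours ago                       1              7              0
c04           National Institutes of Health Stroke Scale ...             1              7              0
c05           CT scan shows haemorrhage                                  1              7              0
c07           Blood glucose is lower than 3 mmol/litre or ...            2              6              0
...
non-compliant cases (thrombolysis despite contraindication): 0
concordance: 8/8
```

Each row counts, over the cohort, how many cases triggered, cleared, or
could not decide that criterion; `concordance: 8/8` means the rule
engine and the brute-force oracle produced identical verdict vectors for
every case. The same pipeline is available as a library:

```python
from strokeaudit import generate_cohort, engine_check, oracle_check, compare

cases = generate_cohort(49)
engine = {c.case_id: engine_check(c) for c in cases}
oracle = {c.case_id: oracle_check(c) for c in cases}
print(compare(engine, oracle).matches)   # -> 49
```

Case files use either a human-readable `key = <value>` dADL-style
dialect (`.case.dadl`) or plain JSON (`.case.json`); guideline files are
plain text under `src/strokeaudit/knowledge/data/guidelines/`.

## Layout

- `src/strokeaudit/values.py`, `model.py`, `caseio.py`, `odin.py` — data
  values, schemas, cases, file formats
- `terminology.py` — code systems, subsumption, term groups
- `expr.py`, `guideline.py` — rule dialect, parser, validation
- `engine.py` — three-valued forward chaining
- `knowledge/` — shipped schemas, terminology tables, guideline files
- `cohort.py` — seeded synthetic case generator and probe cases
- `compliance.py` — audit, oracle, concordance
- `cli.py` — `strokeaudit generate | validate | check`

See `docs/methods.md` for the modelling conventions (look-back windows,
missing-data semantics, rule decomposition) and known limitations.
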