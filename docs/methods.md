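# Methods

## Domain and learner model

The knowledge base instantiates a small eLearning ontology. *Medical
concepts* carry a preferred name and code from a controlled vocabulary (codes
are opaque strings; no terminology server is consulted) and fall into three
categories — condition, observation, treatment option (the latter subtyped
medication / service / nutrition order / care plan, with `may_treat` /
`may_prevent` links to conditions). Concepts form acyclic generality
hierarchies through `parent_id`; a *lineage* is the parent chain read from
the most general ancestor down to the concept itself. *Condition facts* hold
free-text statements outside any terminology. A *condition profile* fixes the
skeleton of a course as six ordered lists (condition facts, findings,
complications, risk factors, treatment options, prevention options); the list
order is fixed, the order within each list is the author's.

A *basic unit of knowledge* (BUK) is either content or Q&A and is annotated
with the concept (or fact) it teaches, a theme, a two-level Bloom objective
(`lower` = remembering, `higher` = understanding/applying), and the
comprehension level it requires. Themes subdivide treatment material (dosage,
monitoring tests, direct effects, side effects, risky events, diet
restrictions); `general` is the wildcard theme used for everything that is
not a treatment option. Explanations are maps from VARK style to a rendering
(text and/or an asset reference for non-textual media); question renderings
are restricted to the A and R styles, because a multiple-choice question must
be read or heard. A single BUK may carry renderings for several styles at
once: the same unit is then available in multiple modalities and the learner
may switch among them. Unit text may contain `{treatment}`, `{dose}` and
`{timing}` placeholders bound from the patient's treatment request at
presentation time; unknown placeholders are left intact and reported as
warnings rather than failing a session.

The learner model is the patient record: comprehension level (`low < medium <
high`), an ordered duplicate-free list of preferred VARK styles, the
diagnosed condition, the treatment request (treatment option, dose, rate,
timing), and an append-only performance log of (Q&A unit, correct?, tick)
entries. Ticks are integer session counters rather than wall-clock times so
that logs and traces are exactly reproducible.

`validate_kb` checks every invariant (referential integrity, hierarchy
acyclicity, Q&A completeness and A/R question styles, sequence-index
uniqueness per (concept, theme, Bloom) group, monotone log ticks, ...) and
returns violations as report items instead of raising; a prescription absent
from the condition's profile is a warning, not an error, since profiles may
legitimately lag prescribing practice.

## Course generation

Control flow lives in four levels of precompiled plans executed by a
procedural-reasoning interpreter. A plan has a goal name, an optional
precondition (absent means always satisfied) and a procedural body; bodies
are Python generators that perform effects between `yield`s and yield
sub-goals. Yielding suspends the body exactly where it stands; the sub-goal's
plan runs to completion depth-first and the body resumes at its next step.
Plan selection takes the first registered plan whose goal name matches and
whose precondition holds (declaration order is the tie-break); an unknown
goal name is an error, and if plans exist but every precondition fails the
run stops with a precondition error. The comprehension-update goal is the one
place where "nothing applies" is legitimate — the log may still be shorter
than the window — so the default library registers an explicit no-op guard
plan after the real update plan rather than special-casing the interpreter.

* **Level 1** iterates the profile properties in their fixed order, restricts
  the treatment- and prevention-option lists to the prescribed treatment, and
  emits one lesson goal per non-empty property.
* **Level 2** expands each scope item along its concept lineage so general
  principles precede specific ones. A concept reached more than once in a
  session (through several profile properties or shared ancestry) is taught
  only the first time; re-asking a just-answered question would invite
  answer-by-elimination. Treatment-option concepts iterate all themes in the
  configured order; other scope items use the wildcard theme. Within a
  (concept, theme) cell the Bloom levels run lower → higher, and for every
  cell the plan retrieves a Q&A unit if one exists, else a content unit, at
  the patient's **current** comprehension level with strictly downward
  fallback (high → medium → low). If nothing exists at or below the
  patient's level the cell is skipped with a warning record; upward fallback
  is never attempted, since presenting material above the assessed
  comprehension level is exactly what the personalization is meant to avoid.
  Because the lesson body suspends at every delivery, a promotion earned by
  the inner plans changes what the next retrieval sees — this is what moves a
  just-promoted learner onto medium-level material mid-lesson.
* **Level 3** has two plans. The content plan binds placeholders, resolves
  the presentation style and logs `present_content`. The Q&A plan presents
  the question (A/R style), captures and evaluates the answer, appends the
  performance-log entry, logs `evaluate_response`, and immediately pushes the
  comprehension-update goal — the update therefore completes before the
  correctness branch continues, so the follow-up retrievals already see any
  level change. On a correct answer the explanation is shown (folded into the
  evaluation record as `explanation_shown`). On a wrong answer the plan
  delivers remedial content on the same concept and theme at the patient's
  level (same Bloom order preferred, the other accepted), then the next
  question in the cell's sequence.
* **Level 4** recomputes the level from the last `window_n` log entries:
  `accuracy` is the fraction correct; the trend is *increasing* when the most
  recent ⌈n/2⌉ entries are strictly more accurate than the preceding ⌊n/2⌋.
  Accuracy ≥ `satisfactory_accuracy` with an increasing trend promotes one
  step; accuracy below the bound with a non-increasing trend demotes one
  step; anything else leaves the level unchanged. Changes are clamped to the
  three-level scale and logged.

### Bloom gating

Higher-order material in a (concept, theme) cell unlocks after
`bloom_advance_threshold` consecutive correct answers on the cell's
lower-order questions. When a cell has no lower-order questions at all the
gate is vacuously open — there is nothing to master first, and authored
content frequently starts at the higher order (both study fixtures do).
Lower-order *content* without questions does not gate either: mastery cannot
be demonstrated on material that never asks anything.

### Question sequences and the retry cap

Alternative questions sharing (concept, theme, Bloom level) form a cyclic
sequence ordered by `sequence_index` (then id; unindexed units sort after
indexed ones). After a wrong answer the next sequence member is asked, so a
question never immediately repeats when an alternative exists. Authored plans
would otherwise loop forever against a learner who never answers correctly,
so each cell has a presentation budget: `max_qa_cycles` full passes through
the sequence when it has at least two members, and one retry (two
presentations) for a lone question. Exhausting the budget logs a warning and
moves on. A global step budget (`step_budget`) additionally guards authored
goal cycles in custom plan libraries.

### Style resolution

For every rendering the first of the patient's preferred styles that is
available wins; otherwise the configured fallback order (default K → V → R →
A) is scanned against availability. Questions only ever offer A/R, so V/K
learners receive them in R under the default fallback. After each
presentation (question, explanation, or content) the learner may request
another style: an available style is honoured and logged as a `style_change`
record (the re-presentation rides on that record); an unavailable one logs a
warning and changes nothing.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window_n` | 4 | answers in the comprehension window |
| `satisfactory_accuracy` | 0.75 | accuracy bound for promotion/demotion |
| `bloom_advance_threshold` | 1 | consecutive correct lower-order answers to unlock higher order |
| `theme_order` | dosage … diet restrictions | traversal order of treatment themes |
| `style_fallback` | K, V, R, A | style order when no preference is available |
| `max_qa_cycles` | 3 | sequence passes tolerated without a correct answer |
| `step_budget` | 10 000 | hard interpreter step cap |

`window_n = 4` and `satisfactory_accuracy = 0.75` are the smallest values
consistent with both study traces: one failure after three correct answers
sits exactly at the bound (blocking demotion for the anticoagulation
learner), and a single correct answer on top of an improving window promotes
the back-pain learner. `bloom_advance_threshold = 1` likewise matches that
trace, where one correct lower-order answer unlocks the higher-order
question. All are exposed in `EngineConfig` because the underlying rules
leave them symbolic ("at least n entries", "several correct answers").

## Persistence and export

The working store is JSON/YAML with a canonical serialization (sorted keys,
sorted sets, omitted defaults), so save∘load is byte-stable and fixture
snapshots can be diffed. The loader performs its own structural checks with
JSON-pointer-style error locations and then runs the validator: dangling
references raise, other violations surface as Python warnings. OWL/Turtle is
an *export* (classes for the ontology, one individual per entity, object and
data properties for the annotations), deterministic for identical KBs;
control flow and within-list ordering deliberately stay in the native store
and the plans, where sequencing is natural to express.

## Fixtures and the synthetic generators

The two authored fixtures cover exactly the printed fragments of the study
use cases, not clinically complete curricula. The anticoagulation KB places
the diet-restriction question pair and remedial content on the anticoagulant
class concept and the generic dosing question on warfarin, so the
general-before-specific traversal yields the published presentation order
under the default theme order. Both patients carry a three-entry pre-seeded
performance log attributed to an "earlier lesson" question on a concept
deliberately unreachable from the condition profile: the comprehension window
is full at the first answer without perturbing the replayed fragment.
Fixture unit texts are plain prose written for this package; where the
original wording was not available they are paraphrases, and they are data,
not code.

`generate_random_kb` emulates structural variety — acyclic concept forests,
mixed unit annotations, cyclic question sequences, a profile and a patient —
for property tests; it does not emulate clinical plausibility, textual
content, or learner behaviour beyond scripted correctness rates, so passing
randomized suites demonstrates the engine's control-flow and retrieval
contracts, not pedagogical effectiveness on real patients.
`generate_scripted_learners` draws i.i.d. correctness directives at a fixed
rate; real learners are neither stationary nor independent across items.

Problem sizes in the shipped suites — 500 random KBs for retrieval oracle
equivalence, 200 random plan trees for interpreter oracle equivalence, 1 000
scripted learners across answer rates {0, 0.5, 1} for batch invariants — keep
the whole suite in the low seconds while exercising every branch; the checks
are oracle-vs-implementation equalities and hold identically at larger sizes.

## Numerical and degenerate-input choices

Retrieval tie-breaks (sequence index, then id) make every query total and
reproducible. The trend comparison uses strict inequality, so a flat window
is "non-increasing" (a perfect streak therefore stops promoting once the
earlier half is also perfect). With `window_n = 1` the trend is defined as
non-increasing (there is no earlier half). An empty learner script aborts the
session cleanly with an `abort` record and a preserved partial log. All
randomness is confined to the synthetic generators and seeded; the engine
itself is deterministic, and identical inputs produce byte-identical JSONL
logs and Turtle exports.

## Known limitations

Course structure is fixed and progression linear; there is no spaced
repetition, no item-response-theory difficulty estimation, and no learning of
style preferences from behaviour. The comprehension proxy (three ordinal
levels) and the two-level Bloom split are deliberate simplifications of the
underlying constructs. Non-textual renderings are represented as asset
references only — no media is rendered. EHR integration is out of scope; the
`intake` command creates patient records from a minimal JSON document
instead. The OWL export is one-way: arbitrary third-party OWL is not
imported, and no description-logic reasoning is performed.
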