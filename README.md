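# tutorplan

Personalized patient-education courses, generated from an eLearning knowledge
base by a procedural-reasoning plan interpreter.

Patients who understand their condition and prescribed treatment adhere to
therapy better, but printed leaflets are one-size-fits-all. `tutorplan` is for
builders of patient-education tools: it assembles an interactive course —
intelligent-tutoring-system style — that is personalized along four axes:

* **condition and treatment** — the course skeleton is the condition's
  profile (condition facts, findings, complications, risk factors, treatment
  options, prevention options), with treatment material restricted to the
  actual prescription;
* **comprehension level** — an ordinal learner attribute (`low < medium <
  high`, initially proxied by educational attainment) that selects the
  difficulty of each unit and is re-estimated from quiz performance;
* **VARK presentation style** — every unit carries renderings per modality
  (Visual, Aural, Read/write, Kinesthetic); the learner's ordered preferences
  are matched against availability, with a K→V→R→A fallback;
* **Bloom objective** — a simplified two-level taxonomy; lower-order
  (remembering) units precede higher-order (understanding/applying) ones,
  which unlock only after correct lower-order answers.

## The model

The knowledge base holds coded **medical concepts** (SNOMED-CT-style codes)
in generality hierarchies via `has_parent`, and **basic units of knowledge**
(BUKs): *content* units (an explanation) and *Q&A* units (a multiple-choice
question; questions exist only in A/R modalities, the explanation is shown
after a correct answer). Each BUK is annotated with a concept, a theme (for
treatments: dosage, monitoring tests, direct effects, side effects, risky
events, diet restrictions), a Bloom level, and a required comprehension level.
Unit text may contain `{treatment}` / `{dose}` / `{timing}` placeholders bound
to the prescription at presentation time, so one generic unit serves a whole
medication class.

Course control flow is not encoded in the ontology (sequencing is awkward to
express there) but in four levels of **precompiled plans** run by a small
procedural-reasoning interpreter (goal stack; a plan body that adds a
sub-goal suspends until the sub-goal's plan completes):

1. **Course plan** — iterate the condition profile's properties in fixed
   order, emitting one lesson goal per non-empty property.
2. **Lesson plan** — expand each scope item along its concept lineage
   (general → specific), iterate themes and Bloom levels, and retrieve one
   unit per cell at the learner's *current* comprehension level, falling back
   to lower levels when needed.
3. **Delivery plans** — present content, or ask a question, capture and
   evaluate the answer; on failure, deliver remedial content and the next
   question in the cell's authored sequence (cyclic, so the same question is
   not immediately repeated).
4. **Update plan** — over the last *n* answers compute accuracy and trend;
   satisfactory and improving ⇒ promote one level, unsatisfactory and not
   improving ⇒ demote one level (clamped to the scale).

Because retrieval happens when the lesson plan *resumes*, a promotion earned
mid-lesson immediately changes which unit is selected next.

## Worked example

```sh
python examples/replay_backpain_course.py
```

prints the lower-back-pain session of a low-comprehension learner who
prefers K then V and answers both questions correctly:

```
  present_question   bp_qa_1 (lower-order, low level)
  evaluate_response  bp_qa_1 (lower-order, low level)
  comprehension      low -> medium  (accuracy 0.75 over last 4 answers, trend increasing)
  style re-request   bp_qa_1: K -> R
  present_question   bp_qa_2 (higher-order, medium level)
  evaluate_response  bp_qa_2 (higher-order, medium level)

comprehension trajectory: low -> medium
```

The first correct answer completes a satisfactory, improving window, so the
learner is promoted; the lesson plan, resuming afterwards, retrieves the
higher-order *medium*-level question rather than another low-level one. The
learner's re-request of the explanation in the Read/write style is honoured
and logged. `examples/replay_anticoagulation_course.py` shows the companion
anticoagulation session (failed question → remedial content → alternative
question → warfarin-customized dosing question), and the other examples cover
KB authoring/validation/OWL export and batch learner populations.

A thin CLI wraps the same API: `tutorplan demo-af`, `tutorplan simulate`,
`tutorplan summarize`, `tutorplan validate`, `tutorplan export-owl`,
`tutorplan intake`.

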