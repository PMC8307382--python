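"""Replay the anticoagulation course for a high-comprehension V/R learner.

Builds the atrial-fibrillation knowledge base, runs the scripted session
(answers: incorrect, correct, correct) through the plan interpreter, and
prints the interaction trace.  The failed diet-restrictions question triggers
a remedial content unit and an alternative question on the same concept and
theme; the final dosing question is authored once against the anticoagulant
class and customized to warfarin at presentation time.
"""

from tutorplan import build_af_fixture, simulate_session, summarize_log
from tutorplan.session import count_interactions

kb, patient_id, learner = build_af_fixture()
patient = kb.patients[patient_id]
log = simulate_session(
    kb, patient_id, patient.condition_id,
    patient.treatment_request.treatment_option_id, learner,
)

print(f"course for {patient_id!r}: {patient.condition_id} treated with "
      f"{patient.treatment_request.treatment_option_id}\n")
for record in log.of_kind("present_question", "evaluate_response", "present_content"):
    detail = ""
    if record["kind"] == "evaluate_response":
        detail = "correct" if record["correct"] else "incorrect"
        if record["explanation_shown"]:
            detail += ", explanation shown"
    else:
        detail = f"style {record['style']}"
    print(f"  {record['kind']:18s} {record.get('buk_id', ''):14s} {detail}")

summary = summarize_log(log)
print(f"\n{count_interactions(log)} interactions, "
      f"{summary.n_correct}/{summary.n_questions} questions correct; "
      f"comprehension stayed {summary.comprehension_trajectory[-1].value} "
      "(the one failure is outweighed by the majority-correct recent window).")
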