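"""Replay the lower-back-pain course for a low-comprehension K/V learner.

The first correct lower-order answer lifts the learner's comprehension from
low to medium mid-lesson; because unit retrieval happens only when the lesson
plan resumes, the very next question on the same concept is the higher-order,
medium-level one.  The learner also re-requests the first explanation in the
read/write style, which is logged as a style change.
"""

from tutorplan import build_backpain_fixture, simulate_session, summarize_log

kb, patient_id, learner = build_backpain_fixture()
patient = kb.patients[patient_id]
log = simulate_session(
    kb, patient_id, patient.condition_id,
    patient.treatment_request.treatment_option_id, learner,
)

for record in log.of_kind(
    "present_question", "evaluate_response", "comprehension_change", "style_change"
):
    if record["kind"] == "comprehension_change":
        print(f"  comprehension      {record['from_level']} -> {record['to_level']}"
              f"  ({record['reason']})")
    elif record["kind"] == "style_change":
        print(f"  style re-request   {record['buk_id']}: "
              f"{record['from_style']} -> {record['to_style']}")
    else:
        level = kb.buks[record["buk_id"]].comprehension.value
        bloom = kb.buks[record["buk_id"]].bloom.value
        print(f"  {record['kind']:18s} {record['buk_id']} ({bloom}-order, {level} level)")

trajectory = " -> ".join(l.value for l in summarize_log(log).comprehension_trajectory)
print(f"\ncomprehension trajectory: {trajectory}")
print("the second question is higher-order and medium-level: the promotion was "
      "visible to the lesson plan before it retrieved the next unit.")
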