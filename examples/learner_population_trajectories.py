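"""Simulate learner populations at different answer-accuracy rates.

Runs the back-pain course for seeded populations of scripted learners whose
answers are correct with probability p, and tabulates how often the course
promotes or demotes the comprehension level.  Promotions require a
satisfactory, improving window of recent answers, so they vanish at p = 0 and
dominate at p = 1.
"""

from tutorplan import build_backpain_fixture, generate_scripted_learners, simulate_session
from tutorplan.session import summarize_log

kb, patient_id, _ = build_backpain_fixture()
patient = kb.patients[patient_id]

print("p_correct   promoted   demoted   unchanged   (100 learners each)")
for p in (0.0, 0.5, 0.9, 1.0):
    promoted = demoted = unchanged = 0
    for learner in generate_scripted_learners(seed=42, n=100, p_correct=p):
        log = simulate_session(
            kb, patient_id, patient.condition_id,
            patient.treatment_request.treatment_option_id, learner,
        )
        trajectory = summarize_log(log).comprehension_trajectory
        if trajectory[-1].rank > trajectory[0].rank:
            promoted += 1
        elif trajectory[-1].rank < trajectory[0].rank:
            demoted += 1
        else:
            unchanged += 1
    print(f"   {p:4.1f}     {promoted:6d}    {demoted:6d}     {unchanged:6d}")

print("\neach row is a population of scripted learners; a promotion means the "
      "final comprehension level exceeds the initial one.")
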