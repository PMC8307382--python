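"""Deterministic study fixtures and seeded random generators.

Two authored knowledge bases reproduce the framework's worked use cases:

* ``build_af_fixture`` — atrial fibrillation managed with warfarin, learner
  "mario" (high comprehension, prefers V then R).  The diet-restriction cell
  carries a two-question sequence plus a remedial content unit; the dosing
  cell carries one generic question whose text binds ``{treatment}`` at
  presentation time.
* ``build_backpain_fixture`` — lumbar degenerative disc condition managed
  with daily ibuprofen plus a back-exercise care plan, learner "anne" (low
  comprehension, prefers K then V).  The symptoms cell carries a lower-order
  question at the low level and a higher-order question at the medium level,
  so a mid-lesson comprehension promotion changes what is retrieved next.

Both builders are pure: repeated calls produce identical knowledge bases.
``generate_random_kb`` / ``generate_scripted_learners`` provide seeded random
inputs for property tests and batch simulations.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from tutorplan.model import (
    BUK,
    BUKKind,
    BloomLevel,
    ComprehensionLevel,
    ConceptCategory,
    ConceptCode,
    ConditionFact,
    ConditionProfile,
    MedicalConcept,
    Patient,
    PerformanceEntry,
    PerformanceLog,
    RenderableText,
    Theme,
    TreatmentRequest,
    TreatmentSubtype,
    VARKStyle,
)
from tutorplan.session import ScriptedLearner
from tutorplan.store import KnowledgeBase

V, A, R, K = VARKStyle.V, VARKStyle.A, VARKStyle.R, VARKStyle.K
LOW, MEDIUM, HIGH = ComprehensionLevel.LOW, ComprehensionLevel.MEDIUM, ComprehensionLevel.HIGH


def _rt(style: VARKStyle, text: str, asset_ref: str | None = None) -> RenderableText:
    return RenderableText(style=style, text=text, asset_ref=asset_ref)


def _concept(
    cid: str,
    name: str,
    category: ConceptCategory,
    code: str,
    subtype: TreatmentSubtype | None = None,
    parent: str | None = None,
    may_treat: set[str] | None = None,
    may_prevent: set[str] | None = None,
) -> MedicalConcept:
    return MedicalConcept(
        id=cid,
        code=ConceptCode(system="SNOMED-CT", code=code, preferred_name=name),
        category=category,
        treatment_subtype=subtype,
        parent_id=parent,
        may_treat=may_treat or set(),
        may_prevent=may_prevent or set(),
    )


# ---------------------------------------------------------------------------
# Atrial fibrillation / warfarin


def build_af_fixture() -> tuple[KnowledgeBase, str, ScriptedLearner]:
    """Knowledge base, patient id and answer script for the AF use case.

    The scripted replay (incorrect, correct, correct) exercises: an alternative
    question after a failure, a remedial content unit, the unchanged
    comprehension level despite one failure (majority of recent answers
    correct), and treatment-name templating of the generic dosing question.
    """
    kb = KnowledgeBase()
    cond, obs, tx = (
        ConceptCategory.CONDITION,
        ConceptCategory.OBSERVATION,
        ConceptCategory.TREATMENT_OPTION,
    )
    for c in [
        _concept("af", "Atrial fibrillation", cond, "49436004"),
        _concept("stroke", "Stroke", cond, "230690007"),
        _concept("hypertension", "Hypertension", cond, "38341003"),
        _concept("palpitations", "Palpitations", obs, "80313002"),
        _concept("fatigue", "Fatigue", obs, "84229001"),
        _concept(
            "blood_clotting", "Blood clotting", obs, "50960005"
        ),  # earlier-lesson topic; not part of the AF profile
        _concept(
            "anticoagulant",
            "anticoagulation medication",
            tx,
            "372862008",
            subtype=TreatmentSubtype.MEDICATION,
            may_prevent={"stroke"},
        ),
        _concept(
            "warfarin",
            "warfarin",
            tx,
            "372756006",
            subtype=TreatmentSubtype.MEDICATION,
            parent="anticoagulant",
            may_prevent={"stroke"},
        ),
        _concept(
            "rate_control",
            "rate control medication",
            tx,
            "372913009",
            subtype=TreatmentSubtype.MEDICATION,
            may_treat={"af"},
        ),
    ]:
        kb.concepts[c.id] = c

    kb.facts["af_fact_rhythm"] = ConditionFact(
        id="af_fact_rhythm",
        text="Atrial fibrillation is an irregular and often very rapid heart rhythm.",
        about_condition="af",
    )
    kb.facts["af_fact_age"] = ConditionFact(
        id="af_fact_age",
        text="The chance of developing atrial fibrillation increases with age.",
        about_condition="af",
    )
    kb.profiles["af"] = ConditionProfile(
        condition_id="af",
        condition_facts=["af_fact_rhythm"],
        findings=["palpitations", "fatigue"],
        complications=["stroke"],
        risk_factors=["hypertension", "af_fact_age"],
        treatment_options=["warfarin", "rate_control"],
        prevention_options=["anticoagulant"],
    )

    kb.buks["af_qa_1"] = BUK(
        id="af_qa_1",
        kind=BUKKind.QA,
        refers_to="anticoagulant",
        theme=Theme.DIET_RESTRICTIONS,
        bloom=BloomLevel.HIGHER,
        comprehension=HIGH,
        sequence_index=1,
        question={
            R: _rt(R, "You are taking {treatment}. Which food on your plate deserves the most attention tonight?"),
            A: _rt(A, "Which food deserves the most attention while you take {treatment}?", asset_ref="audio/af_qa_1.ogg"),
        },
        choices=[
            "A large spinach and kale salad",
            "A bowl of plain rice",
            "A glass of apple juice",
        ],
        correct_choice_index=0,
        explanation_renderings={
            R: _rt(R, "Leafy greens are rich in vitamin K, which counteracts anticoagulation medication; keep your intake steady rather than avoiding them entirely."),
            V: _rt(V, "Chart of vitamin K content across common foods.", asset_ref="img/vitamin_k_chart.png"),
        },
    )
    kb.buks["af_content_2"] = BUK(
        id="af_content_2",
        kind=BUKKind.CONTENT,
        refers_to="anticoagulant",
        theme=Theme.DIET_RESTRICTIONS,
        bloom=BloomLevel.HIGHER,
        comprehension=HIGH,
        explanation_renderings={
            R: _rt(R, "Anticoagulation medication slows the clotting cascade that vitamin K supports. Sudden changes in vitamin K intake — leafy greens, liver, some vegetable oils — shift the medication's effect, so a consistent diet matters more than strict avoidance."),
        },
    )
    kb.buks["af_qa_3"] = BUK(
        id="af_qa_3",
        kind=BUKKind.QA,
        refers_to="anticoagulant",
        theme=Theme.DIET_RESTRICTIONS,
        bloom=BloomLevel.HIGHER,
        comprehension=HIGH,
        sequence_index=2,
        question={
            R: _rt(R, "Your vegetable garden produced a bumper crop of kale. While on {treatment}, what is the safest way to enjoy it?"),
            A: _rt(A, "What is the safest way to enjoy a bumper kale crop while on {treatment}?", asset_ref="audio/af_qa_3.ogg"),
        },
        choices=[
            "Eat as much as you like, vegetables are always safe",
            "Keep portions similar from week to week",
            "Stop the medication on days you eat kale",
        ],
        correct_choice_index=1,
        explanation_renderings={
            R: _rt(R, "A steady weekly amount of vitamin K keeps the anticoagulation effect stable; never pause the medication on your own."),
            V: _rt(V, "Weekly meal-planning graphic for stable vitamin K intake.", asset_ref="img/weekly_planner.png"),
        },
    )
    kb.buks["af_qa_4"] = BUK(
        id="af_qa_4",
        kind=BUKKind.QA,
        refers_to="warfarin",
        theme=Theme.DOSAGE,
        bloom=BloomLevel.HIGHER,
        comprehension=HIGH,
        question={
            R: _rt(R, "You realize at dinner that you forgot this morning's dose of {treatment} ({dose}, {timing}). What should you do?"),
            A: _rt(A, "What should you do about a missed morning dose of {treatment}?", asset_ref="audio/af_qa_4.ogg"),
        },
        choices=[
            "Take the missed dose as soon as you remember, on the same day",
            "Take a double dose tomorrow morning",
            "Skip doses for the rest of the week",
        ],
        correct_choice_index=0,
        explanation_renderings={
            R: _rt(R, "A missed dose of {treatment} can be taken the same day, but never double the next dose: doubling raises bleeding risk sharply."),
            V: _rt(V, "Decision diagram for a missed anticoagulant dose.", asset_ref="img/missed_dose.png"),
        },
    )
    # Earlier-lesson question: keeps the performance window seedable without
    # being reachable from the AF profile (blood_clotting is not a scope item).
    kb.buks["clot_qa_1"] = BUK(
        id="clot_qa_1",
        kind=BUKKind.QA,
        refers_to="blood_clotting",
        theme=Theme.GENERAL,
        bloom=BloomLevel.LOWER,
        comprehension=HIGH,
        question={R: _rt(R, "What does blood clotting normally do?")},
        choices=["Stops bleeding after an injury", "Lowers blood pressure"],
        correct_choice_index=0,
        explanation_renderings={R: _rt(R, "Clotting seals injured vessels to stop bleeding.")},
    )

    kb.patients["mario"] = Patient(
        id="mario",
        comprehension=HIGH,
        preferred_styles=[V, R],
        condition_id="af",
        treatment_request=TreatmentRequest(
            treatment_option_id="warfarin", dose="5 mg", timing="1 tablet/day"
        ),
        demographics={"given_name": "Mario"},
        # majority of recent responses correct: one failure in the replay
        # leaves windowed accuracy at the satisfactory bound, so no demotion
        performance_log=PerformanceLog(
            entries=[
                PerformanceEntry("clot_qa_1", True, 1),
                PerformanceEntry("clot_qa_1", True, 2),
                PerformanceEntry("clot_qa_1", True, 3),
            ]
        ),
    )
    script = ScriptedLearner(answer_script=["incorrect", "correct", "correct"])
    return kb, "mario", script


# ---------------------------------------------------------------------------
# Lower back pain / ibuprofen + exercises


def build_backpain_fixture() -> tuple[KnowledgeBase, str, ScriptedLearner]:
    """Knowledge base, patient id and answer script for the back-pain use case.

    The scripted replay (correct with an R-style explanation re-request,
    correct) exercises the mid-lesson comprehension promotion: the first
    correct answer lifts the learner from low to medium, and the next
    retrieval on the same concept finds the higher-order, medium-level
    question.
    """
    kb = KnowledgeBase()
    cond, obs, tx = (
        ConceptCategory.CONDITION,
        ConceptCategory.OBSERVATION,
        ConceptCategory.TREATMENT_OPTION,
    )
    for c in [
        _concept("ldd", "Lumbar degenerative disc condition", cond, "240221008"),
        _concept("sciatica", "Sciatica", cond, "23056005"),
        _concept("obesity", "Obesity", cond, "414916001"),
        _concept("back_pain", "Low back pain", obs, "279039007"),
        _concept("stiffness", "Morning stiffness of the spine", obs, "161874005"),
        _concept("spine_anatomy", "Structure of the spine", obs, "421060004"),
        _concept(
            "nsaid",
            "non-steroidal anti-inflammatory medication",
            tx,
            "372665008",
            subtype=TreatmentSubtype.MEDICATION,
            may_treat={"ldd"},
        ),
        _concept(
            "ibuprofen",
            "ibuprofen",
            tx,
            "387207008",
            subtype=TreatmentSubtype.MEDICATION,
            parent="nsaid",
            may_treat={"ldd"},
        ),
        _concept(
            "back_exercise",
            "back strengthening exercise programme",
            tx,
            "229065009",
            subtype=TreatmentSubtype.CARE_PLAN,
            may_treat={"ldd"},
            may_prevent={"ldd"},
        ),
    ]:
        kb.concepts[c.id] = c

    kb.facts["ldd_fact_wear"] = ConditionFact(
        id="ldd_fact_wear",
        text="The discs between the vertebrae lose water and cushioning with age, which can cause low-grade, continuous back pain.",
        about_condition="ldd",
    )
    kb.profiles["ldd"] = ConditionProfile(
        condition_id="ldd",
        condition_facts=["ldd_fact_wear"],
        findings=["back_pain"],
        complications=["sciatica"],
        risk_factors=["obesity"],
        treatment_options=["ibuprofen", "back_exercise"],
        prevention_options=["back_exercise"],
    )

    kb.buks["bp_qa_1"] = BUK(
        id="bp_qa_1",
        kind=BUKKind.QA,
        refers_to="back_pain",
        theme=Theme.GENERAL,
        bloom=BloomLevel.LOWER,
        comprehension=LOW,
        sequence_index=1,
        question={
            R: _rt(R, "Which kind of pain is most typical of a worn lumbar disc?"),
            A: _rt(A, "Which kind of pain is most typical of a worn lumbar disc?", asset_ref="audio/bp_qa_1.ogg"),
        },
        choices=[
            "Low-grade pain that is there most of the time and sometimes flares up",
            "Sharp pain only when sneezing",
            "Pain only at night",
        ],
        correct_choice_index=0,
        explanation_renderings={
            K: _rt(K, "Gently arch and flatten your lower back while seated: the dull ache you may feel at the end of the range is the kind of continuous, low-grade pain a worn disc causes.", asset_ref="exercise/seated_pelvic_tilt"),
            R: _rt(R, "A degenerated disc typically causes continuous, low-grade pain that occasionally flares into more severe pain."),
        },
    )
    kb.buks["bp_qa_2"] = BUK(
        id="bp_qa_2",
        kind=BUKKind.QA,
        refers_to="back_pain",
        theme=Theme.GENERAL,
        bloom=BloomLevel.HIGHER,
        comprehension=MEDIUM,
        sequence_index=1,
        question={
            R: _rt(R, "Your back pain flares after a long car ride. Which response applies what you have learned?"),
            A: _rt(A, "Which response to a flare after a long car ride applies what you have learned?", asset_ref="audio/bp_qa_2.ogg"),
        },
        choices=[
            "Stay in bed until the pain is completely gone",
            "Keep gently active and return to normal movement as the flare settles",
            "Stop all exercise for a month",
        ],
        correct_choice_index=1,
        explanation_renderings={
            V: _rt(V, "Illustrated flare-up plan: gentle movement, gradual return to activity.", asset_ref="img/flare_plan.png"),
            R: _rt(R, "Flares of disc-related pain settle fastest with gentle activity; prolonged bed rest weakens the muscles that protect the spine."),
        },
    )
    kb.buks["bp_content_exercises"] = BUK(
        id="bp_content_exercises",
        kind=BUKKind.CONTENT,
        refers_to="back_exercise",
        theme=Theme.RISKY_EVENTS,
        bloom=BloomLevel.LOWER,
        comprehension=LOW,
        explanation_renderings={
            R: _rt(R, "Avoid exercises that jolt or twist the lower back while it hurts: sit-ups with straight legs, toe touches, and heavy lifting above the waist are not recommended for people with back problems."),
            V: _rt(V, "Poster of exercises to avoid with back problems.", asset_ref="img/avoid_exercises.png"),
        },
    )
    # Earlier-lesson question, unreachable from the profile (see AF fixture).
    kb.buks["spine_qa_1"] = BUK(
        id="spine_qa_1",
        kind=BUKKind.QA,
        refers_to="spine_anatomy",
        theme=Theme.GENERAL,
        bloom=BloomLevel.LOWER,
        comprehension=LOW,
        question={R: _rt(R, "What sits between the bones of your spine?")},
        choices=["Cushioning discs", "Small muscles only"],
        correct_choice_index=0,
        explanation_renderings={R: _rt(R, "Soft discs cushion the vertebrae.")},
    )

    kb.patients["anne"] = Patient(
        id="anne",
        comprehension=LOW,
        preferred_styles=[K, V],
        condition_id="ldd",
        treatment_request=TreatmentRequest(
            treatment_option_id="ibuprofen", dose="400 mg", timing="1 tablet/day"
        ),
        demographics={"given_name": "Anne"},
        # recent performance trending upward: the next correct answer promotes
        performance_log=PerformanceLog(
            entries=[
                PerformanceEntry("spine_qa_1", False, 1),
                PerformanceEntry("spine_qa_1", True, 2),
                PerformanceEntry("spine_qa_1", True, 3),
            ]
        ),
    )
    # ordinal 1 is the first explanation (after question ordinal 0)
    script = ScriptedLearner(answer_script=["correct", "correct"], style_requests={1: R})
    return kb, "anne", script


# ---------------------------------------------------------------------------
# Randomized inputs


@dataclass(frozen=True)
class RandomKBSpec:
    """Parameters for seeded random KB generation (a pure function of this spec)."""

    seed: int
    n_concepts: int = 10
    max_depth: int = 3
    n_buks: int = 20
    p_qa: float = 0.5
    with_patient: bool = True


_CATEGORIES = [
    ConceptCategory.CONDITION,
    ConceptCategory.OBSERVATION,
    ConceptCategory.TREATMENT_OPTION,
]


def generate_random_kb(spec: RandomKBSpec) -> KnowledgeBase:
    """A random valid KB: acyclic concept forest, BUKs with A/R questions.

    Output always passes :func:`tutorplan.model.validate_kb` cleanly and is
    identical for identical specs.
    """
    if spec.n_concepts < 2:
        raise ValueError("need at least 2 concepts (one condition, one treatment)")
    rng = random.Random(spec.seed)
    kb = KnowledgeBase()
    depths: dict[str, int] = {}
    ids: list[str] = []
    for i in range(spec.n_concepts):
        cid = f"c{i}"
        if i == 0:
            category = ConceptCategory.CONDITION  # guarantee one condition
        elif i == 1:
            category = ConceptCategory.TREATMENT_OPTION  # and one treatment
        else:
            category = rng.choice(_CATEGORIES)
        parent = None
        same_cat = [p for p in ids if kb.concepts[p].category is category and depths[p] < spec.max_depth - 1]
        if same_cat and rng.random() < 0.6:
            parent = rng.choice(same_cat)
        depths[cid] = 0 if parent is None else depths[parent] + 1
        kb.concepts[cid] = _concept(
            cid,
            f"concept {i}",
            category,
            code=str(100000 + i),
            subtype=(
                rng.choice(list(TreatmentSubtype))
                if category is ConceptCategory.TREATMENT_OPTION
                else None
            ),
            parent=parent,
        )
        ids.append(cid)
    conditions = [c.id for c in kb.concepts.values() if c.category is ConceptCategory.CONDITION]
    treatments = [c.id for c in kb.concepts.values() if c.category is ConceptCategory.TREATMENT_OPTION]
    for c in kb.concepts.values():
        if c.category is ConceptCategory.TREATMENT_OPTION and rng.random() < 0.5:
            c.may_treat = {rng.choice(conditions)}

    n_facts = rng.randint(0, 3)
    for i in range(n_facts):
        fid = f"f{i}"
        kb.facts[fid] = ConditionFact(
            id=fid, text=f"fact {i} text", about_condition=rng.choice(conditions)
        )

    seq_counters: dict[tuple, int] = {}
    for i in range(spec.n_buks):
        bid = f"b{i}"
        ref_pool = ids + list(kb.facts)
        ref = rng.choice(ref_pool)
        concept = kb.concepts.get(ref)
        if concept is not None and concept.category is ConceptCategory.TREATMENT_OPTION:
            theme = rng.choice([t for t in Theme if t is not Theme.GENERAL])
        else:
            theme = Theme.GENERAL
        bloom = rng.choice(list(BloomLevel))
        comp = rng.choice(list(ComprehensionLevel))
        is_qa = rng.random() < spec.p_qa
        styles = rng.sample(list(VARKStyle), rng.randint(1, 4))
        explanation = {s: _rt(s, f"explanation of {bid} in {s.value}") for s in styles}
        if is_qa:
            key = (ref, theme, bloom)
            seq = seq_counters.get(key, 0)
            seq_counters[key] = seq + 1
            n_choices = rng.randint(2, 4)
            kb.buks[bid] = BUK(
                id=bid,
                kind=BUKKind.QA,
                refers_to=ref,
                theme=theme,
                bloom=bloom,
                comprehension=comp,
                sequence_index=seq,
                question={
                    R: _rt(R, f"question {bid}?"),
                    A: _rt(A, f"question {bid}?", asset_ref=f"audio/{bid}.ogg"),
                },
                choices=[f"choice {j}" for j in range(n_choices)],
                correct_choice_index=rng.randrange(n_choices),
                explanation_renderings=explanation,
            )
        else:
            kb.buks[bid] = BUK(
                id=bid,
                kind=BUKKind.CONTENT,
                refers_to=ref,
                theme=theme,
                bloom=bloom,
                comprehension=comp,
                explanation_renderings=explanation,
            )

    # one profile over a random condition, drawing from every pool
    cond_id = rng.choice(conditions)
    observations = [c.id for c in kb.concepts.values() if c.category is ConceptCategory.OBSERVATION]
    other_conditions = [c for c in conditions if c != cond_id]
    profile = ConditionProfile(
        condition_id=cond_id,
        condition_facts=rng.sample(list(kb.facts), min(len(kb.facts), rng.randint(0, 2))),
        findings=rng.sample(observations, min(len(observations), rng.randint(0, 3))),
        complications=rng.sample(other_conditions, min(len(other_conditions), rng.randint(0, 2))),
        risk_factors=rng.sample(observations, min(len(observations), rng.randint(0, 2))),
        treatment_options=rng.sample(treatments, rng.randint(1, min(3, len(treatments)))),
        prevention_options=rng.sample(treatments, min(len(treatments), rng.randint(0, 2))),
    )
    kb.profiles[cond_id] = profile

    if spec.with_patient and profile.treatment_options:
        tid = profile.treatment_options[0]
        styles_pref = rng.sample(list(VARKStyle), rng.randint(1, 3))
        kb.patients["p0"] = Patient(
            id="p0",
            comprehension=rng.choice(list(ComprehensionLevel)),
            preferred_styles=styles_pref,
            condition_id=cond_id,
            treatment_request=TreatmentRequest(
                treatment_option_id=tid, dose="1 unit", timing="daily"
            ),
        )
    return kb


def generate_scripted_learners(
    seed: int, n: int, p_correct: float, script_length: int = 20
) -> list[ScriptedLearner]:
    """``n`` learners with i.i.d. correctness directives at rate ``p_correct``."""
    if not 0 <= p_correct <= 1:
        raise ValueError("p_correct must lie in [0, 1]")
    rng = random.Random(seed)
    return [
        ScriptedLearner(
            answer_script=[
                "correct" if rng.random() < p_correct else "incorrect"
                for _ in range(script_length)
            ]
        )
        for _ in range(n)
    ]
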