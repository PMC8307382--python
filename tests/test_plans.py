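"""Course-plan tests: lesson scoping, ordering, delivery branches, mastery updates."""

import pytest

from tutorplan.engine import EngineConfig, ExecutionState, Goal
from tutorplan.model import (
    ComprehensionLevel,
    PROFILE_PROPERTIES,
    Theme,
    VARKStyle,
)
from tutorplan.fixtures import RandomKBSpec, generate_random_kb
from tutorplan.plans import (
    GOAL_COURSE,
    bloom_gate_open,
    default_plan_library,
    level1_course_plan,
    resolve_style,
)
from tutorplan.session import ScriptedLearner, simulate_session

V, A, R, K = VARKStyle.V, VARKStyle.A, VARKStyle.R, VARKStyle.K


def lesson_goals_for(kb, patient_id, condition_id, treatment_id):
    """Expand only the Level 1 plan and collect its lesson goals."""
    plan = level1_course_plan()
    state = ExecutionState(kb=kb)
    goal = Goal.of(GOAL_COURSE, patient=patient_id, condition=condition_id, treatment=treatment_id)

    class _Ctx:
        def __init__(self, state):
            self.state = state
            self.kb = state.kb
            self.config = state.config

        def emit(self, *a, **k):
            pass

    return list(plan.body(goal, _Ctx(state)))


class TestLevel1Scoping:
    def test_af_lessons_follow_profile_order_with_treatment_restricted(self, af):
        kb, _, _ = af
        goals = lesson_goals_for(kb, "mario", "af", "warfarin")
        topics = [g["topic"] for g in goals]
        scopes = [g["scope"] for g in goals]
        # prevention options (anticoagulant class only) vanish once restricted
        assert topics == ["condition_facts", "findings", "complications",
                          "risk_factors", "treatment_options"]
        assert scopes[-1] == ("warfarin",)  # restricted to the prescription
        assert scopes[0] == ("af_fact_rhythm",)

    def test_profile_with_all_empty_lists_yields_no_lessons(self, af):
        kb, _, _ = af
        for prop in PROFILE_PROPERTIES:
            setattr(kb.profiles["af"], prop, [])
        assert lesson_goals_for(kb, "mario", "af", "warfarin") == []

    @pytest.mark.parametrize("seed", range(10))
    def test_lesson_count_equals_nonempty_properties(self, seed):
        kb = generate_random_kb(RandomKBSpec(seed=seed))
        patient = kb.patients["p0"]
        tid = patient.treatment_request.treatment_option_id
        profile = kb.profiles[patient.condition_id]
        expected = 0
        for prop in PROFILE_PROPERTIES:
            items = list(getattr(profile, prop))
            if prop in ("treatment_options", "prevention_options"):
                items = [i for i in items if i == tid]
            expected += bool(items)
        assert len(lesson_goals_for(kb, "p0", patient.condition_id, tid)) == expected


class TestLevel2Ordering:
    def test_general_concepts_delivered_before_specific(self, af):
        """Anticoagulant-class units precede warfarin-specific units."""
        kb, pid, learner = af
        log = simulate_session(kb, pid, "af", "warfarin", learner)
        order = [r["buk_id"] for r in log.of_kind("present_question", "present_content")]
        anticoagulant_level = [i for i, b in enumerate(order) if b.startswith(("af_qa_1", "af_qa_3", "af_content_2"))]
        warfarin_level = [i for i, b in enumerate(order) if b == "af_qa_4"]
        assert anticoagulant_level and warfarin_level
        assert max(anticoagulant_level) < min(warfarin_level)

    def test_theme_traversal_follows_configured_order(self, af):
        """With units on two themes of one concept, dosage-first order applies."""
        kb, pid, learner = af
        # move the dosing question onto the anticoagulant concept: now both
        # themes live on the same concept and the configured order decides
        kb.buks["af_qa_4"].refers_to = "anticoagulant"
        learner = ScriptedLearner(answer_script=["correct", "correct", "correct"])
        log = simulate_session(kb, pid, "af", "warfarin", learner)
        presented = [r["buk_id"] for r in log.of_kind("present_question")]
        assert presented.index("af_qa_4") < presented.index("af_qa_1")
        themes = [kb.buks[b].theme for b in presented]
        order = list(EngineConfig().theme_order)
        assert [order.index(t) for t in themes] == sorted(order.index(t) for t in themes)

    def test_promotion_mid_lesson_changes_next_retrieval(self, backpain):
        """A correct lower-order answer promotes the learner, so the next unit
        on the same concept is the higher-order, medium-level question."""
        kb, pid, learner = backpain
        log = simulate_session(kb, pid, "ldd", "ibuprofen", learner)
        records = [r for r in log if r["kind"] in ("present_question", "comprehension_change")]
        assert [r["kind"] for r in records] == [
            "present_question", "comprehension_change", "present_question",
        ]
        assert records[0]["buk_id"] == "bp_qa_1"
        assert records[1]["to_level"] == "medium"
        assert records[2]["buk_id"] == "bp_qa_2"

    def test_higher_order_blocked_without_lower_order_mastery(self, backpain):
        kb, pid, _ = backpain
        learner = ScriptedLearner(answer_script=["incorrect"] * 10)
        log = simulate_session(kb, pid, "ldd", "ibuprofen", learner)
        assert all(r["buk_id"] != "bp_qa_2" for r in log.of_kind("present_question"))

    def test_gate_vacuously_open_without_lower_order_questions(self, af):
        kb, _, _ = af
        patient = kb.patients["mario"]
        assert bloom_gate_open(kb, EngineConfig(), patient, "anticoagulant", Theme.DIET_RESTRICTIONS)


class TestLevel3Content:
    def test_content_presented_in_first_available_preferred_style(self, af):
        kb, pid, learner = af
        log = simulate_session(kb, pid, "af", "warfarin", learner)
        record = log.of_kind("present_content")[0]
        # the remedial unit exists only in R; the V-preferring patient falls back
        assert record["buk_id"] == "af_content_2" and record["style"] == "R"

    def test_fallback_walks_kvra_intersected_with_availability(self):
        config = EngineConfig()
        assert resolve_style([K, V], {R}, "explanation", config) is R
        assert resolve_style([V, R], {R, V}, "explanation", config) is V
        assert resolve_style([A], {A}, "question", config) is A
        # no preference available: K -> V -> R -> A order decides
        assert resolve_style([V], {A, R}, "question", config) is R

    def test_unavailable_style_request_is_a_warning_noop(self, backpain):
        kb, pid, _ = backpain
        learner = ScriptedLearner(
            answer_script=["correct", "correct"], style_requests={1: VARKStyle.A}
        )  # bp_qa_1 explanation has no A rendering
        log = simulate_session(kb, pid, "ldd", "ibuprofen", learner)
        assert not log.of_kind("style_change")
        assert any("not available" in r["text"] for r in log.of_kind("warning"))

    def test_available_style_request_logs_a_change(self, backpain):
        kb, pid, learner = backpain
        log = simulate_session(kb, pid, "ldd", "ibuprofen", learner)
        change = log.of_kind("style_change")[0]
        assert (change["from_style"], change["to_style"]) == ("K", "R")


class TestLevel3QA:
    def test_incorrect_answer_triggers_content_then_alternative_question(self, af):
        kb, pid, learner = af
        log = simulate_session(kb, pid, "af", "warfarin", learner)
        order = [
            (r["kind"], r["buk_id"])
            for r in log.of_kind("present_question", "present_content")
        ]
        assert order[:3] == [
            ("present_question", "af_qa_1"),
            ("present_content", "af_content_2"),
            ("present_question", "af_qa_3"),
        ]

    def test_correct_answer_shows_reinforcing_explanation(self, af):
        kb, pid, learner = af
        log = simulate_session(kb, pid, "af", "warfarin", learner)
        evaluations = {r["buk_id"]: r for r in log.of_kind("evaluate_response")}
        assert evaluations["af_qa_3"]["correct"] and evaluations["af_qa_3"]["explanation_shown"]
        assert not evaluations["af_qa_1"]["explanation_shown"]

    def test_singleton_sequence_represented_once_then_capped(self, backpain):
        kb, pid, _ = backpain
        learner = ScriptedLearner(answer_script=["incorrect"] * 10)
        log = simulate_session(kb, pid, "ldd", "ibuprofen", learner)
        presented = [r["buk_id"] for r in log.of_kind("present_question")]
        assert presented.count("bp_qa_1") == 2  # initial + one retry
        assert any("retry cap" in r["text"] for r in log.of_kind("warning"))


class TestLevel4Update:
    def _run_update(self, af_kb, flags, level=ComprehensionLevel.HIGH, config=None):
        from tutorplan.model import PerformanceEntry
        from tutorplan.engine import run
        from tutorplan.plans import GOAL_UPDATE

        kb = af_kb
        patient = kb.patients["mario"]
        patient.comprehension = level
        patient.performance_log.entries = [
            PerformanceEntry("clot_qa_1", f, i + 1) for i, f in enumerate(flags)
        ]
        state = ExecutionState(kb=kb, config=config or EngineConfig(), tick=len(flags))
        run(default_plan_library(), Goal.of(GOAL_UPDATE, patient="mario"), state)
        return patient.comprehension, state.log

    def test_satisfactory_and_increasing_promotes(self, af):
        kb, _, _ = af
        level, log = self._run_update(kb, [False, True, True, True], ComprehensionLevel.LOW)
        assert level is ComprehensionLevel.MEDIUM
        assert log.of_kind("comprehension_change")

    def test_majority_correct_blocks_demotion_after_one_failure(self, af):
        kb, _, _ = af
        level, log = self._run_update(kb, [True, True, True, False], ComprehensionLevel.HIGH)
        assert level is ComprehensionLevel.HIGH
        assert not log.of_kind("comprehension_change")

    def test_all_incorrect_clamps_at_low(self, af):
        kb, _, _ = af
        level, _ = self._run_update(kb, [False] * 4, ComprehensionLevel.LOW)
        assert level is ComprehensionLevel.LOW

    def test_half_accuracy_non_increasing_demotes_one_step(self, af):
        # n=4, (correct, correct, incorrect, incorrect), satisfactory 0.8:
        # accuracy 0.5, recent half worse than earlier half -> one step down
        kb, _, _ = af
        config = EngineConfig(satisfactory_accuracy=0.8)
        level, log = self._run_update(
            kb, [True, True, False, False], ComprehensionLevel.HIGH, config
        )
        assert level is ComprehensionLevel.MEDIUM
        change = log.of_kind("comprehension_change")[0]
        assert (change["from_level"], change["to_level"]) == ("high", "medium")

    def test_short_log_leaves_level_unchanged(self, af):
        kb, _, _ = af
        level, log = self._run_update(kb, [False], ComprehensionLevel.MEDIUM)
        assert level is ComprehensionLevel.MEDIUM
        assert not log.of_kind("comprehension_change")
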