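"""Drive a full personalized course end-to-end against a learner.

A learner is anything implementing :class:`LearnerInterface`; the shipped
:class:`ScriptedLearner` replays a deterministic answer script (explicit
choice indexes or ``correct``/``incorrect`` directives resolved against the
presented question) and optional per-presentation style re-requests, which is
how the two in-study interaction traces are reproduced.

``simulate_session`` never mutates the caller's knowledge base: it runs
against a deep copy, so the same KB object can drive many simulated learners.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence, Union

from tutorplan.engine import (
    EngineConfig,
    ExecutionState,
    Goal,
    LearnerAbort,
    SessionLog,
    run,
)
from tutorplan.model import ComprehensionLevel, UnknownEntityError, VARKStyle
from tutorplan.plans import GOAL_COURSE, default_plan_library
from tutorplan.store import KnowledgeBase

#: Record kinds that correspond to one numbered exchange in an interaction
#: trace: a question shown, a response evaluated (explanation folded in), or
#: a content unit shown.  Style changes, comprehension changes and warnings
#: are bookkeeping within an exchange.
INTERACTION_KINDS = ("present_question", "evaluate_response", "present_content")


class LearnerInterface(ABC):
    """Contract for answer capture and style re-requests.

    Implementations must be deterministic given their script/seed; answers
    must lie within the presented choice range.
    """

    @abstractmethod
    def answer(self, presentation: dict[str, Any]) -> int:
        """Chosen 0-based index for a presented question."""

    def style_request(self, presentation: dict[str, Any]) -> Optional[VARKStyle]:
        """Optionally re-request the presentation in another VARK style."""
        return None


ScriptEntry = Union[int, str]  # explicit index, or "correct" / "incorrect"


@dataclass
class ScriptedLearner(LearnerInterface):
    """Deterministic test-double learner driven by a prerecorded script.

    ``style_requests`` maps a presentation ordinal (0-based, counted over all
    questions, explanations and content shown) to the requested style.
    """

    answer_script: Sequence[ScriptEntry]
    style_requests: dict[int, VARKStyle] = field(default_factory=dict)
    _cursor: int = field(default=0, init=False, repr=False)

    def answer(self, presentation: dict[str, Any]) -> int:
        if self._cursor >= len(self.answer_script):
            raise LearnerAbort("answer script exhausted")
        entry = self.answer_script[self._cursor]
        self._cursor += 1
        correct_index = presentation["correct_choice_index"]
        n_choices = len(presentation["choices"])
        if entry == "correct":
            return correct_index
        if entry == "incorrect":
            return next(i for i in range(n_choices) if i != correct_index)
        if isinstance(entry, int) and 0 <= entry < n_choices:
            return entry
        raise ValueError(f"bad script entry {entry!r}")

    def style_request(self, presentation: dict[str, Any]) -> Optional[VARKStyle]:
        return self.style_requests.get(presentation["ordinal"])


def simulate_session(
    kb: KnowledgeBase,
    patient_id: str,
    condition_id: str,
    treatment_id: str,
    learner: LearnerInterface,
    config: Optional[EngineConfig] = None,
    seed: int = 0,
) -> SessionLog:
    """Develop and deliver the personalized course for one patient.

    Pushes the course goal (patient, condition, treatment) and runs the
    default plan library.  The input KB is deep-copied; the patient's
    persistent state (comprehension level, performance log) changes only in
    the copy.  The run is deterministic given (kb, patient, script, config,
    seed); the seed is reserved for stochastic learners.
    """
    for entity, pool in (
        (patient_id, kb.patients),
        (condition_id, kb.concepts),
        (treatment_id, kb.concepts),
    ):
        if entity not in pool:
            raise UnknownEntityError(f"unknown id {entity!r}")
    work = kb.copy()
    patient = work.patients[patient_id]
    start_tick = max((e.tick for e in patient.performance_log.entries), default=0)
    state = ExecutionState(kb=work, config=config or EngineConfig(), rng_seed=seed, tick=start_tick)
    state.log.append(
        {
            "tick": state.take_tick(),
            "kind": "session_start",
            "patient_id": patient_id,
            "condition_id": condition_id,
            "treatment_id": treatment_id,
            "comprehension": patient.comprehension.value,
            "preferred_styles": [s.value for s in patient.preferred_styles],
        }
    )
    goal = Goal.of(GOAL_COURSE, patient=patient_id, condition=condition_id, treatment=treatment_id)
    return run(default_plan_library(), goal, state, learner)


@dataclass
class SessionSummary:
    n_presentations: int
    n_questions: int
    n_correct: int
    accuracy: float
    comprehension_trajectory: list[ComprehensionLevel]
    styles_used: dict[str, int]


def summarize_log(log: SessionLog) -> SessionSummary:
    """Aggregate counts and the comprehension trajectory from a session log."""
    records = list(log)
    if not all(isinstance(r, dict) and "kind" in r and "tick" in r for r in records):
        raise ValueError("malformed log: records need 'kind' and 'tick'")
    presentations = [r for r in records if r["kind"] in ("present_question", "present_content")]
    evaluations = [r for r in records if r["kind"] == "evaluate_response"]
    n_questions = sum(1 for r in records if r["kind"] == "present_question")
    n_correct = sum(1 for r in evaluations if r["correct"])
    styles: dict[str, int] = {}
    for r in presentations:
        styles[r["style"]] = styles.get(r["style"], 0) + 1
    trajectory: list[ComprehensionLevel] = []
    for r in records:
        if r["kind"] == "session_start":
            trajectory.append(ComprehensionLevel(r["comprehension"]))
        elif r["kind"] == "comprehension_change":
            if not trajectory:
                trajectory.append(ComprehensionLevel(r["from_level"]))
            trajectory.append(ComprehensionLevel(r["to_level"]))
    return SessionSummary(
        n_presentations=len(presentations),
        n_questions=n_questions,
        n_correct=n_correct,
        accuracy=n_correct / n_questions if n_questions else 0.0,
        comprehension_trajectory=trajectory,
        styles_used=styles,
    )


def count_interactions(log: SessionLog) -> int:
    """Number of records at the one-record-per-numbered-exchange granularity."""
    return len(log.of_kind(*INTERACTION_KINDS))


def audit_log(log: SessionLog, kb: KnowledgeBase) -> list[str]:
    """Independent well-formedness pass over a finished log.

    Checks record ordering (an evaluation only after its question, monotone
    ticks) and re-derives every correctness flag from the authored answer key.
    Returns a list of problems; empty means the log is sound.
    """
    problems: list[str] = []
    asked: set[str] = set()
    prev_tick = 0
    for r in log:
        if r["tick"] <= prev_tick:
            problems.append(f"tick {r['tick']} not strictly increasing")
        prev_tick = r["tick"]
        kind = r["kind"]
        if kind == "present_question":
            asked.add(r["buk_id"])
            if r["style"] not in ("A", "R"):
                problems.append(f"question {r['buk_id']} presented in style {r['style']}")
        elif kind == "evaluate_response":
            if r["buk_id"] not in asked:
                problems.append(f"evaluation of {r['buk_id']} before its question")
            buk = kb.buks.get(r["buk_id"])
            if buk is None:
                problems.append(f"evaluation references unknown buk {r['buk_id']}")
            elif r["correct"] != (r["chosen_index"] == buk.correct_choice_index):
                problems.append(f"correctness flag of {r['buk_id']} contradicts the answer key")
    return problems
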