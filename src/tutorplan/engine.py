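"""A small procedural-reasoning interpreter: goal stack + precompiled plans.

A precompiled plan names the goal it achieves, an optional precondition, and a
procedural body.  Bodies are written as Python generators: they perform their
effects (retrieve, present, capture, log, mutate the learner model) between
``yield`` statements and yield :class:`Goal` objects for sub-goals.  Yielding
suspends the current plan exactly where it stands; the sub-goal's plan runs to
completion (depth-first) and the suspended body then resumes at the next step.
This suspend/resume discipline is what lets an outer lesson loop observe
learner-model changes (e.g. a comprehension promotion) made by inner plans
before it retrieves the next unit.

The interpreter itself is deterministic: all interaction passes through the
learner interface and the session log, and no internal randomness exists.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Iterator, Optional

from tutorplan.model import DEFAULT_THEME_ORDER, Theme, VARKStyle
from tutorplan.store import KnowledgeBase


class EngineError(Exception):
    """Base class for interpreter errors."""


class UnhandledGoalError(EngineError):
    """No plan is registered for a goal's name."""


class PlanPreconditionError(EngineError):
    """Plans exist for the goal but none has a satisfied precondition."""


class StepBudgetExceeded(EngineError):
    """Safety valve against authored plan cycles."""


class DuplicatePlanError(EngineError):
    """Two registered plans share (goal_name, precondition label)."""


class LearnerAbort(Exception):
    """Raised by a learner implementation to end the session early."""


@dataclass(frozen=True)
class Goal:
    """A parametrized goal; ``params`` keys are plan-specific (patient id, ...)."""

    name: str
    params: tuple[tuple[str, Any], ...] = ()

    @staticmethod
    def of(name: str, **params: Any) -> "Goal":
        return Goal(name, tuple(sorted(params.items())))

    def __getitem__(self, key: str) -> Any:
        for k, v in self.params:
            if k == key:
                return v
        raise KeyError(key)

    def get(self, key: str, default: Any = None) -> Any:
        try:
            return self[key]
        except KeyError:
            return default


Precondition = Callable[[Goal, "ExecutionState"], bool]
PlanBody = Callable[[Goal, "PlanContext"], Iterator[Optional[Goal]]]


@dataclass(frozen=True)
class Plan:
    """A precompiled plan.

    An absent precondition is automatically satisfied.  ``precondition_label``
    identifies the precondition for duplicate detection and error messages.
    """

    name: str
    goal_name: str
    body: PlanBody
    precondition: Optional[Precondition] = None
    precondition_label: Optional[str] = None


class PlanLibrary:
    """Registered plans grouped by goal name, preserving declaration order."""

    def __init__(self) -> None:
        self._by_goal: dict[str, list[Plan]] = {}

    def plans_for(self, goal_name: str) -> list[Plan]:
        return list(self._by_goal.get(goal_name, []))

    def goal_names(self) -> list[str]:
        return list(self._by_goal)

    def add(self, plan: Plan) -> None:
        existing = self._by_goal.setdefault(plan.goal_name, [])
        for other in existing:
            if other.precondition_label == plan.precondition_label:
                raise DuplicatePlanError(
                    f"plan {plan.name!r} duplicates (goal {plan.goal_name!r}, "
                    f"precondition {plan.precondition_label!r}) of {other.name!r}"
                )
        existing.append(plan)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_goal.values())


def register_plans(plans: list[Plan]) -> PlanLibrary:
    lib = PlanLibrary()
    for p in plans:
        lib.add(p)
    return lib


@dataclass
class EngineConfig:
    """Tunable course-generation parameters.

    window_n
        Size of the sliding performance window for comprehension updates.
    satisfactory_accuracy
        Fraction of correct answers in the window deemed satisfactory.
    bloom_advance_threshold
        Consecutive correct lower-order answers on a (concept, theme) cell
        required before higher-order material is offered there.
    theme_order
        Traversal order of themes for treatment-option lessons.
    style_fallback
        Style order tried when no preferred style is available (K, V, R, A).
    qa_question_style_default
        Last-resort question style; questions exist only in A/R.
    max_qa_cycles
        Full passes through a Q&A sequence tolerated without a correct answer
        before the cell is abandoned with a warning.
    step_budget
        Hard cap on interpreter steps (guards authored goal cycles).
    """

    window_n: int = 4
    satisfactory_accuracy: float = 0.75
    bloom_advance_threshold: int = 1
    theme_order: tuple[Theme, ...] = DEFAULT_THEME_ORDER
    style_fallback: tuple[VARKStyle, ...] = (
        VARKStyle.K,
        VARKStyle.V,
        VARKStyle.R,
        VARKStyle.A,
    )
    qa_question_style_default: VARKStyle = VARKStyle.R
    max_qa_cycles: int = 3
    step_budget: int = 10_000

    def __post_init__(self) -> None:
        if set(self.style_fallback) != set(VARKStyle) or len(self.style_fallback) != 4:
            raise ValueError("style_fallback must be a permutation of {V, A, R, K}")
        if not 0 < self.satisfactory_accuracy <= 1:
            raise ValueError("satisfactory_accuracy must be in (0, 1]")
        if self.window_n < 1 or self.bloom_advance_threshold < 1:
            raise ValueError("window_n and bloom_advance_threshold must be positive")

    @staticmethod
    def from_dict(raw: dict[str, Any]) -> "EngineConfig":
        kwargs: dict[str, Any] = {}
        for key in ("window_n", "satisfactory_accuracy", "bloom_advance_threshold",
                    "max_qa_cycles", "step_budget"):
            if key in raw:
                kwargs[key] = raw[key]
        if "theme_order" in raw:
            kwargs["theme_order"] = tuple(Theme(t) for t in raw["theme_order"])
        if "style_fallback" in raw:
            kwargs["style_fallback"] = tuple(VARKStyle(s) for s in raw["style_fallback"])
        if "qa_question_style_default" in raw:
            kwargs["qa_question_style_default"] = VARKStyle(raw["qa_question_style_default"])
        return EngineConfig(**kwargs)


class SessionLog:
    """Ordered session records with monotone ticks; serialized as JSON Lines."""

    def __init__(self, records: Optional[list[dict[str, Any]]] = None) -> None:
        self.records: list[dict[str, Any]] = records if records is not None else []

    def append(self, record: dict[str, Any]) -> None:
        self.records.append(record)

    def of_kind(self, *kinds: str) -> list[dict[str, Any]]:
        return [r for r in self.records if r["kind"] in kinds]

    def to_jsonl(self) -> str:
        return "".join(
            json.dumps(r, sort_keys=True, ensure_ascii=False) + "\n" for r in self.records
        )

    @staticmethod
    def from_jsonl(text: str) -> "SessionLog":
        return SessionLog([json.loads(line) for line in text.splitlines() if line.strip()])

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ExecutionState:
    """Mutable interpreter state: KB, log, config, and per-session scratch."""

    kb: Optional[KnowledgeBase] = None
    config: EngineConfig = field(default_factory=EngineConfig)
    log: SessionLog = field(default_factory=SessionLog)
    rng_seed: int = 0
    tick: int = 0
    presentation_ordinal: int = 0
    qa_presentations: dict[tuple, int] = field(default_factory=dict)
    covered_nodes: set[str] = field(default_factory=set)

    def take_tick(self) -> int:
        self.tick += 1
        return self.tick


class PlanContext:
    """What a plan body may touch: state, learner, and logging helpers."""

    def __init__(self, state: ExecutionState, learner: Any) -> None:
        self.state = state
        self.learner = learner

    @property
    def kb(self) -> KnowledgeBase:
        assert self.state.kb is not None
        return self.state.kb

    @property
    def config(self) -> EngineConfig:
        return self.state.config

    def emit(self, kind: str, **fields: Any) -> dict[str, Any]:
        record = {"tick": self.state.take_tick(), "kind": kind, **fields}
        self.state.log.append(record)
        return record

    def next_presentation_ordinal(self) -> int:
        ordinal = self.state.presentation_ordinal
        self.state.presentation_ordinal += 1
        return ordinal


def select_plan(lib: PlanLibrary, goal: Goal, state: ExecutionState) -> Plan:
    """First registered plan matching the goal name with a satisfied precondition."""
    candidates = lib.plans_for(goal.name)
    if not candidates:
        raise UnhandledGoalError(f"no plan registered for goal {goal.name!r}")
    for plan in candidates:
        if plan.precondition is None or plan.precondition(goal, state):
            return plan
    raise PlanPreconditionError(
        f"no plan for goal {goal.name!r} has a satisfied precondition"
    )


def run(
    lib: PlanLibrary,
    initial_goal: Goal,
    state: ExecutionState,
    learner: Any = None,
) -> SessionLog:
    """Execute the goal depth-first until the stack empties.

    When a body yields a sub-goal the current frame suspends immediately; the
    sub-goal's plan runs to completion, then the frame resumes at its next
    step.  A learner abort appends an ``abort`` record and returns the partial
    log; a step-budget overrun raises :class:`StepBudgetExceeded`.
    """
    ctx = PlanContext(state, learner)
    stack: list[Iterator[Optional[Goal]]] = []

    def activate(goal: Goal) -> None:
        plan = select_plan(lib, goal, state)
        stack.append(plan.body(goal, ctx))

    steps = 0
    try:
        activate(initial_goal)
        while stack:
            steps += 1
            if steps > state.config.step_budget:
                raise StepBudgetExceeded(
                    f"exceeded step budget of {state.config.step_budget}"
                )
            try:
                sub = next(stack[-1])
            except StopIteration:
                stack.pop()
                continue
            if sub is not None:
                activate(sub)
    except LearnerAbort as exc:
        ctx.emit("abort", reason=str(exc) or "learner aborted the session")
    finally:
        for frame in stack:
            close = getattr(frame, "close", None)
            if close is not None:
                close()
    return state.log


def window_accuracy(flags: list[bool]) -> float:
    return sum(flags) / len(flags) if flags else 0.0


def window_trend_increasing(flags: list[bool]) -> bool:
    """Accuracy of the most recent ceil(n/2) answers strictly exceeds the rest."""
    if len(flags) < 2:
        return False
    k = math.ceil(len(flags) / 2)
    recent, earlier = flags[-k:], flags[:-k]
    return window_accuracy(recent) > window_accuracy(earlier)
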