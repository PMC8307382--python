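"""The four course-generation plan levels and VARK style resolution.

Level 1 turns a condition profile into a sequence of lesson goals (one per
non-empty profile property, with treatment/prevention options restricted to
the prescribed treatment).  Level 2 expands each lesson scope item along its
concept lineage (general before specific), iterates themes (for treatment
options) and Bloom levels (lower before higher, gated by recent lower-order
mastery), and retrieves one unit per cell at the patient's *current*
comprehension level with downward fallback.  Level 3 delivers a single unit —
content, or a multiple-choice question with remediation and alternative
questions on failure.  Level 4 re-estimates the comprehension level from the
sliding window of recent answers.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional, Sequence

from tutorplan.engine import (
    EngineConfig,
    Goal,
    Plan,
    PlanContext,
    PlanLibrary,
    register_plans,
    window_accuracy,
    window_trend_increasing,
)
from tutorplan.model import (
    BUK,
    BUKKind,
    BloomLevel,
    PROFILE_PROPERTIES,
    Patient,
    PerformanceEntry,
    Theme,
    VARKStyle,
    concept_lineage,
    instantiate_text,
)
from tutorplan.store import (
    BUKQuery,
    KnowledgeBase,
    next_qa_in_sequence,
    retrieve_buk_with_fallback,
    sequence_group,
)

GOAL_COURSE = "develop_course"
GOAL_LESSON = "develop_lesson"
GOAL_DELIVER = "deliver_buk"
GOAL_UPDATE = "update_comprehension"


def resolve_style(
    preferred: Sequence[VARKStyle],
    available: Iterable[VARKStyle],
    kind: str,
    config: EngineConfig,
) -> VARKStyle:
    """First preferred style that is available, else first available fallback style.

    ``kind`` is "question" or "explanation"; question renderings only exist in
    A/R, so a V/K-preferring patient receives questions via the K->V->R->A
    fallback (normally R).
    """
    avail = set(available)
    if not avail:
        raise ValueError("no styles available")
    for style in preferred:
        if style in avail:
            return style
    for style in config.style_fallback:
        if style in avail:
            return style
    return config.qa_question_style_default  # unreachable: fallback is a permutation


# ---------------------------------------------------------------------------
# Level 1: course -> lessons


def _has_profile(goal: Goal, state) -> bool:
    return goal["condition"] in state.kb.profiles


def _level1_body(goal: Goal, ctx: PlanContext) -> Iterator[Optional[Goal]]:
    pid, cid, tid = goal["patient"], goal["condition"], goal["treatment"]
    profile = ctx.kb.profiles[cid]
    for prop in PROFILE_PROPERTIES:
        items = list(getattr(profile, prop))
        if prop in ("treatment_options", "prevention_options"):
            items = [i for i in items if i == tid]
        if not items:
            continue
        yield Goal.of(GOAL_LESSON, patient=pid, scope=tuple(items), treatment=tid, topic=prop)


def level1_course_plan() -> Plan:
    return Plan(
        name="course-from-profile",
        goal_name=GOAL_COURSE,
        body=_level1_body,
        precondition=_has_profile,
        precondition_label="condition-has-profile",
    )


# ---------------------------------------------------------------------------
# Level 2: lesson -> unit deliveries


def _theme_matches(buk_theme: Theme, theme: Theme) -> bool:
    return theme is Theme.GENERAL or buk_theme is theme


def _lower_order_qas(kb: KnowledgeBase, node: str, theme: Theme) -> list[BUK]:
    return [
        b
        for b in kb.buks.values()
        if b.kind is BUKKind.QA
        and b.refers_to == node
        and b.bloom is BloomLevel.LOWER
        and _theme_matches(b.theme, theme)
    ]


def bloom_gate_open(
    kb: KnowledgeBase, config: EngineConfig, patient: Patient, node: str, theme: Theme
) -> bool:
    """Whether higher-order material may be offered for (node, theme).

    The gate requires ``bloom_advance_threshold`` consecutive correct answers
    on lower-order questions of the cell.  When the cell has no lower-order
    questions at all there is nothing to master first and the gate is open.
    """
    lower = _lower_order_qas(kb, node, theme)
    if not lower:
        return True
    ids = {b.id for b in lower}
    streak = 0
    for entry in reversed(patient.performance_log.entries):
        if entry.buk_id not in ids:
            continue
        if not entry.correct:
            break
        streak += 1
        if streak >= config.bloom_advance_threshold:
            return True
    return streak >= config.bloom_advance_threshold


def _retrieve_for_delivery(
    kb: KnowledgeBase, patient: Patient, node: str, theme: Theme, bloom: BloomLevel
) -> Optional[BUK]:
    """A question if one exists, else a content unit, at the patient's level."""
    for kind in (BUKKind.QA, BUKKind.CONTENT):
        buk = retrieve_buk_with_fallback(
            kb, BUKQuery(node, theme, bloom, kind, patient.comprehension)
        )
        if buk is not None:
            return buk
    return None


def _level2_body(goal: Goal, ctx: PlanContext) -> Iterator[Optional[Goal]]:
    pid, scope, tid = goal["patient"], goal["scope"], goal["treatment"]
    kb, config = ctx.kb, ctx.config
    # session-global: a concept reached through several profile properties or
    # shared ancestry is taught once, never re-asked in a later lesson
    seen = ctx.state.covered_nodes
    for item in scope:
        nodes = concept_lineage(kb, item) if item in kb.concepts else [item]
        for node in nodes:
            if node in seen:
                continue
            seen.add(node)
            concept = kb.concepts.get(node)
            is_treatment = concept is not None and concept.category.value == "treatment_option"
            themes = config.theme_order if is_treatment else (Theme.GENERAL,)
            for theme in themes:
                for bloom in (BloomLevel.LOWER, BloomLevel.HIGHER):
                    # re-read the patient each step: inner deliveries may have
                    # changed the comprehension level before we resume here
                    patient = kb.patients[pid]
                    if bloom is BloomLevel.HIGHER and not bloom_gate_open(
                        kb, config, patient, node, theme
                    ):
                        continue
                    buk = _retrieve_for_delivery(kb, patient, node, theme, bloom)
                    if buk is None:
                        ctx.emit(
                            "warning",
                            text=(
                                f"no unit for {node}/{theme.value}/{bloom.value} "
                                f"at or below level {patient.comprehension.value}"
                            ),
                        )
                        continue
                    yield Goal.of(GOAL_DELIVER, patient=pid, buk=buk.id, treatment=tid)


def level2_lesson_plan() -> Plan:
    return Plan(name="lesson-from-scope", goal_name=GOAL_LESSON, body=_level2_body)


# ---------------------------------------------------------------------------
# Level 3: unit delivery


def _render(ctx: PlanContext, rt_text: str, patient: Patient) -> str:
    text, warned = instantiate_text(rt_text, patient.treatment_request, ctx.kb)
    for w in warned:
        ctx.emit("warning", text=w)
    return text


def _present(
    ctx: PlanContext,
    record_kind: Optional[str],
    buk: BUK,
    style: VARKStyle,
    text: str,
    role: str,
    choices: Optional[list[str]] = None,
    asset_ref: Optional[str] = None,
) -> dict:
    """Show one rendering; returns the learner-facing payload.

    ``record_kind`` is None for explanations after correct answers: the
    evaluation record already notes ``explanation_shown`` and the numbered
    trace granularity folds the explanation into it.
    """
    if record_kind is not None:
        ctx.emit(record_kind, buk_id=buk.id, style=style.value)
    payload = {
        "ordinal": ctx.next_presentation_ordinal(),
        "buk_id": buk.id,
        "role": role,
        "style": style.value,
        "text": text,
        "asset_ref": asset_ref,
    }
    if choices is not None:
        payload["choices"] = list(choices)
        payload["correct_choice_index"] = buk.correct_choice_index
    return payload


def _offer_style_change(
    ctx: PlanContext,
    buk: BUK,
    current: VARKStyle,
    available: set[VARKStyle],
    payload: dict,
) -> VARKStyle:
    """Let the learner re-request the rendering in another style."""
    if ctx.learner is None:
        return current
    requested = ctx.learner.style_request(payload)
    if requested is None or requested is current:
        return current
    if requested not in available:
        ctx.emit(
            "warning",
            text=f"style {requested.value} not available for {buk.id}; keeping {current.value}",
        )
        return current
    ctx.emit("style_change", buk_id=buk.id, from_style=current.value, to_style=requested.value)
    return requested


def _is_content(goal: Goal, state) -> bool:
    return state.kb.buks[goal["buk"]].kind is BUKKind.CONTENT


def _is_qa(goal: Goal, state) -> bool:
    return state.kb.buks[goal["buk"]].kind is BUKKind.QA


def _content_body(goal: Goal, ctx: PlanContext) -> Iterator[Optional[Goal]]:
    kb = ctx.kb
    buk = kb.buks[goal["buk"]]
    patient = kb.patients[goal["patient"]]
    available = set(buk.explanation_renderings)
    style = resolve_style(patient.preferred_styles, available, "explanation", ctx.config)
    rt = buk.explanation_renderings[style]
    payload = _present(
        ctx, "present_content", buk, style, _render(ctx, rt.text, patient),
        role="content", asset_ref=rt.asset_ref,
    )
    _offer_style_change(ctx, buk, style, available, payload)
    return
    yield  # pragma: no cover - makes the body a generator


def level3_content_plan() -> Plan:
    return Plan(
        name="deliver-content",
        goal_name=GOAL_DELIVER,
        body=_content_body,
        precondition=_is_content,
        precondition_label="buk-is-content",
    )


def _remedial_content(kb: KnowledgeBase, patient: Patient, buk: BUK) -> Optional[BUK]:
    """Content on the same concept/theme at the patient's level (any Bloom order)."""
    for bloom in (buk.bloom, BloomLevel.LOWER if buk.bloom is BloomLevel.HIGHER else BloomLevel.HIGHER):
        hit = retrieve_buk_with_fallback(
            kb, BUKQuery(buk.refers_to, buk.theme, bloom, BUKKind.CONTENT, patient.comprehension)
        )
        if hit is not None:
            return hit
    return None


def _qa_budget(config: EngineConfig, group_size: int) -> int:
    # one retry for a lone question; full cycles when alternatives exist
    return config.max_qa_cycles * group_size if group_size >= 2 else 2


def _qa_body(goal: Goal, ctx: PlanContext) -> Iterator[Optional[Goal]]:
    kb, config = ctx.kb, ctx.config
    buk = kb.buks[goal["buk"]]
    pid = goal["patient"]
    patient = kb.patients[pid]
    group = sequence_group(kb, buk)
    key = (buk.refers_to, buk.theme.value, buk.bloom.value)
    presented = ctx.state.qa_presentations.get(key, 0)
    if presented >= _qa_budget(config, len(group)):
        ctx.emit(
            "warning",
            text=f"retry cap reached for {buk.refers_to}/{buk.theme.value}/{buk.bloom.value}; moving on",
        )
        return
    ctx.state.qa_presentations[key] = presented + 1

    assert buk.question and buk.choices is not None
    style = resolve_style(patient.preferred_styles, set(buk.question), "question", config)
    rt = buk.question[style]
    choices = [_render(ctx, c, patient) for c in buk.choices]
    payload = _present(
        ctx, "present_question", buk, style, _render(ctx, rt.text, patient),
        role="question", choices=choices, asset_ref=rt.asset_ref,
    )
    _offer_style_change(ctx, buk, style, set(buk.question), payload)

    chosen = ctx.learner.answer(payload)  # may raise LearnerAbort
    if not isinstance(chosen, int) or not 0 <= chosen < len(choices):
        raise ValueError(f"learner answer {chosen!r} outside choice range for {buk.id}")
    correct = chosen == buk.correct_choice_index
    patient.performance_log.append(
        PerformanceEntry(buk_id=buk.id, correct=correct, tick=ctx.state.take_tick())
    )
    ctx.emit(
        "evaluate_response",
        buk_id=buk.id,
        chosen_index=chosen,
        correct=correct,
        explanation_shown=correct,
    )
    # the comprehension update runs now, before any follow-up retrieval,
    # so promotions are visible to the very next unit selection
    yield Goal.of(GOAL_UPDATE, patient=pid)

    if correct:
        available = set(buk.explanation_renderings)
        estyle = resolve_style(patient.preferred_styles, available, "explanation", config)
        ert = buk.explanation_renderings[estyle]
        epayload = _present(
            ctx, None, buk, estyle, _render(ctx, ert.text, patient),
            role="explanation", asset_ref=ert.asset_ref,
        )
        _offer_style_change(ctx, buk, estyle, available, epayload)
        return

    remedial = _remedial_content(kb, kb.patients[pid], buk)
    if remedial is not None:
        yield Goal.of(GOAL_DELIVER, patient=pid, buk=remedial.id, treatment=goal.get("treatment"))
    if len(group) >= 2:
        nxt = next_qa_in_sequence(kb, buk)
        yield Goal.of(GOAL_DELIVER, patient=pid, buk=nxt.id, treatment=goal.get("treatment"))
    else:
        # no alternatives authored: restart with the same question (budget-capped)
        yield Goal.of(GOAL_DELIVER, patient=pid, buk=buk.id, treatment=goal.get("treatment"))


def level3_qa_plan() -> Plan:
    return Plan(
        name="deliver-qa",
        goal_name=GOAL_DELIVER,
        body=_qa_body,
        precondition=_is_qa,
        precondition_label="buk-is-qa",
    )


# ---------------------------------------------------------------------------
# Level 4: comprehension update


def _log_window_full(goal: Goal, state) -> bool:
    patient = state.kb.patients[goal["patient"]]
    return len(patient.performance_log.entries) >= state.config.window_n


def _update_body(goal: Goal, ctx: PlanContext) -> Iterator[Optional[Goal]]:
    config = ctx.config
    patient = ctx.kb.patients[goal["patient"]]
    flags = [e.correct for e in patient.performance_log.entries[-config.window_n:]]
    accuracy = window_accuracy(flags)
    increasing = window_trend_increasing(flags)
    old = patient.comprehension
    if accuracy >= config.satisfactory_accuracy and increasing:
        new = old.step(+1)
    elif accuracy < config.satisfactory_accuracy and not increasing:
        new = old.step(-1)
    else:
        new = old
    if new is not old:
        patient.comprehension = new
        ctx.emit(
            "comprehension_change",
            from_level=old.value,
            to_level=new.value,
            reason=(
                f"accuracy {accuracy:.2f} over last {len(flags)} answers, "
                f"trend {'increasing' if increasing else 'non-increasing'}"
            ),
        )
    return
    yield  # pragma: no cover


def _noop_body(goal: Goal, ctx: PlanContext) -> Iterator[Optional[Goal]]:
    return
    yield  # pragma: no cover


def level4_update_plan() -> Plan:
    return Plan(
        name="comprehension-from-window",
        goal_name=GOAL_UPDATE,
        body=_update_body,
        precondition=_log_window_full,
        precondition_label="log-window-full",
    )


def level4_short_log_guard() -> Plan:
    """Satisfies the update goal with no change while the log is still short."""
    return Plan(name="comprehension-window-pending", goal_name=GOAL_UPDATE, body=_noop_body)


def course_plans() -> list[Plan]:
    """The five substantive plans of the framework (Table-of-plans order)."""
    return [
        level1_course_plan(),
        level2_lesson_plan(),
        level3_content_plan(),
        level3_qa_plan(),
        level4_update_plan(),
    ]


def default_plan_library() -> PlanLibrary:
    return register_plans(course_plans() + [level4_short_log_guard()])
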