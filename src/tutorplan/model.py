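"""Typed domain and learner model for personalized patient education.

The model mirrors an eLearning ontology: coded medical concepts (conditions,
observations, treatment options) arranged into generality hierarchies via
``parent_id``, condition profiles that fix the skeleton of a course, and basic
units of knowledge (BUKs) — atomic content or multiple-choice Q&A items —
annotated with a theme, a two-level Bloom objective, a required comprehension
level, and per-VARK-style renderings.  Patients carry the learner model: a
comprehension level (low/medium/high, initially proxied by educational
attainment), an ordered list of preferred VARK presentation styles, the
diagnosed condition, the prescribed treatment request, and an append-only
performance log of Q&A correctness that drives comprehension updates.

Everything here is a plain in-memory value object; loading, saving, querying
and OWL export live in :mod:`tutorplan.store`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Callable, Optional

if TYPE_CHECKING:  # pragma: no cover
    from tutorplan.store import KnowledgeBase


class KBError(Exception):
    """Base class for knowledge-base errors."""


class UnknownEntityError(KBError):
    """An identifier does not resolve in the knowledge base."""


class SchemaError(KBError):
    """A KB document is structurally malformed.

    ``path`` is a JSON-pointer-style location of the offending element.
    """

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


class VARKStyle(str, Enum):
    """VARK presentation modality."""

    V = "V"  # visual
    A = "A"  # aural
    R = "R"  # read/write
    K = "K"  # kinesthetic


class ComprehensionLevel(str, Enum):
    """Ordinal learner comprehension level, low < medium < high."""

    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"

    @property
    def rank(self) -> int:
        return _COMPREHENSION_ORDER.index(self)

    def step(self, delta: int) -> "ComprehensionLevel":
        """Move ``delta`` steps along the ordering, clamped at the ends."""
        i = min(max(self.rank + delta, 0), len(_COMPREHENSION_ORDER) - 1)
        return _COMPREHENSION_ORDER[i]

    def at_or_below(self) -> list["ComprehensionLevel"]:
        """Levels from this one downward (used by retrieval fallback)."""
        return list(reversed(_COMPREHENSION_ORDER[: self.rank + 1]))


_COMPREHENSION_ORDER = [
    ComprehensionLevel.LOW,
    ComprehensionLevel.MEDIUM,
    ComprehensionLevel.HIGH,
]


class BloomLevel(str, Enum):
    """Simplified two-level Bloom taxonomy: lower < higher order learning."""

    LOWER = "lower"
    HIGHER = "higher"

    @property
    def rank(self) -> int:
        return 0 if self is BloomLevel.LOWER else 1


class Theme(str, Enum):
    """Sub-topic axis for treatment-related BUKs.

    ``GENERAL`` is the wildcard theme used for scope items that are not
    treatment options.
    """

    DOSAGE = "dosage"
    MONITORING_TESTS = "monitoring_tests"
    DIRECT_EFFECTS = "direct_effects"
    SIDE_EFFECTS = "side_effects"
    RISKY_EVENTS = "risky_events"
    DIET_RESTRICTIONS = "diet_restrictions"
    GENERAL = "general"


#: Theme traversal order for treatment-option lessons (config default).
DEFAULT_THEME_ORDER = (
    Theme.DOSAGE,
    Theme.MONITORING_TESTS,
    Theme.DIRECT_EFFECTS,
    Theme.SIDE_EFFECTS,
    Theme.RISKY_EVENTS,
    Theme.DIET_RESTRICTIONS,
)


class ConceptCategory(str, Enum):
    CONDITION = "condition"
    OBSERVATION = "observation"
    TREATMENT_OPTION = "treatment_option"


class TreatmentSubtype(str, Enum):
    MEDICATION = "medication"
    SERVICE = "service"
    NUTRITION_ORDER = "nutrition_order"
    CARE_PLAN = "care_plan"


class BUKKind(str, Enum):
    CONTENT = "content"
    QA = "qa"


#: Q&A questions are rendered only in aural or read/write modalities.
QUESTION_STYLES = frozenset({VARKStyle.A, VARKStyle.R})


@dataclass(frozen=True)
class ConceptCode:
    """Preferred name and code from a controlled clinical vocabulary."""

    system: str
    code: str
    preferred_name: str


@dataclass
class MedicalConcept:
    """A coded clinical concept; ``parent_id`` links form generality hierarchies."""

    id: str
    code: ConceptCode
    category: ConceptCategory
    treatment_subtype: Optional[TreatmentSubtype] = None
    parent_id: Optional[str] = None
    may_treat: set[str] = field(default_factory=set)
    may_prevent: set[str] = field(default_factory=set)


@dataclass
class ConditionFact:
    """Free-text fact about a condition, outside any controlled terminology."""

    id: str
    text: str
    about_condition: str


#: Fixed property order of a condition profile — the course skeleton.
PROFILE_PROPERTIES = (
    "condition_facts",
    "findings",
    "complications",
    "risk_factors",
    "treatment_options",
    "prevention_options",
)


@dataclass
class ConditionProfile:
    """The fixed skeleton of a course about one condition.

    The six property lists are always traversed in :data:`PROFILE_PROPERTIES`
    order; order within each list is author-controlled.
    """

    condition_id: str
    condition_facts: list[str] = field(default_factory=list)
    findings: list[str] = field(default_factory=list)
    complications: list[str] = field(default_factory=list)
    risk_factors: list[str] = field(default_factory=list)
    treatment_options: list[str] = field(default_factory=list)
    prevention_options: list[str] = field(default_factory=list)


@dataclass
class RenderableText:
    """One rendering of a piece of educational text in a single VARK style.

    Non-textual media (video, audio, an interactive exercise) are represented
    by ``asset_ref``; at least one of ``text`` / ``asset_ref`` must be set.
    ``text`` may contain ``{treatment}``/``{dose}``/``{timing}`` placeholders
    bound at presentation time (see :func:`instantiate_template`).
    """

    style: VARKStyle
    text: str = ""
    asset_ref: Optional[str] = None


@dataclass
class BUK:
    """Basic unit of knowledge: atomic content or multiple-choice Q&A item.

    A Q&A BUK carries question renderings (A/R styles only), >=2 choices and
    the index of the correct choice; the explanation is shown after a correct
    answer.  ``sequence_index`` orders alternative questions within the group
    sharing (concept, theme, Bloom level) so that a failed question can be
    followed by a different one instead of an immediate repeat.
    """

    id: str
    kind: BUKKind
    refers_to: str  # concept or condition-fact id
    theme: Theme
    bloom: BloomLevel
    comprehension: ComprehensionLevel
    explanation_renderings: dict[VARKStyle, RenderableText] = field(default_factory=dict)
    question: Optional[dict[VARKStyle, RenderableText]] = None
    choices: Optional[list[str]] = None
    correct_choice_index: Optional[int] = None
    sequence_index: Optional[int] = None


@dataclass
class TreatmentRequest:
    """Prescription detail: which treatment option, dose, rate, timing."""

    treatment_option_id: str
    dose: str = ""
    timing: str = ""
    rate: Optional[str] = None


@dataclass
class PerformanceEntry:
    """One answered Q&A BUK; ``tick`` is a monotone session tick, not wall-clock."""

    buk_id: str
    correct: bool
    tick: int


@dataclass
class PerformanceLog:
    """Append-only record of Q&A correctness; drives comprehension updates."""

    entries: list[PerformanceEntry] = field(default_factory=list)

    def append(self, entry: PerformanceEntry) -> None:
        self.entries.append(entry)


@dataclass
class Patient:
    """The learner model."""

    id: str
    comprehension: ComprehensionLevel
    preferred_styles: list[VARKStyle]
    condition_id: str
    treatment_request: TreatmentRequest
    demographics: dict[str, str] = field(default_factory=dict)
    performance_log: PerformanceLog = field(default_factory=PerformanceLog)


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class ValidationIssue:
    rule: str
    entity_id: str
    message: str
    severity: str = "error"  # "error" | "warning"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.issues

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def rules(self) -> set[str]:
        return {i.rule for i in self.issues}

    def add(self, rule: str, entity_id: str, message: str, severity: str = "error") -> None:
        self.issues.append(ValidationIssue(rule, entity_id, message, severity))


#: Rules whose violation makes the KB structurally unusable (dangling ids).
REFERENTIAL_RULES = frozenset(
    {
        "concept-parent-resolves",
        "fact-condition-resolves",
        "profile-ref-resolves",
        "profile-condition-resolves",
        "buk-refers-resolves",
        "patient-condition-resolves",
        "patient-treatment-resolves",
        "performance-log-buk-resolves",
    }
)


def validate_kb(kb: "KnowledgeBase") -> ValidationReport:
    """Check every model invariant; violations become report items, never exceptions.

    Idempotent and side-effect free.  An empty report means the KB satisfies
    all invariants (warnings included).
    """
    rep = ValidationReport()
    _validate_concepts(kb, rep)
    _validate_facts(kb, rep)
    _validate_profiles(kb, rep)
    _validate_buks(kb, rep)
    _validate_patients(kb, rep)
    return rep


def _validate_concepts(kb: "KnowledgeBase", rep: ValidationReport) -> None:
    for c in kb.concepts.values():
        if not c.code.code:
            rep.add("concept-code-nonempty", c.id, "vocabulary code is empty")
        if not c.code.preferred_name:
            rep.add("concept-name-nonempty", c.id, "preferred name is empty")
        if (c.treatment_subtype is not None) != (c.category is ConceptCategory.TREATMENT_OPTION):
            rep.add(
                "treatment-subtype-iff-treatment-option",
                c.id,
                "treatment_subtype must be present exactly for treatment_option concepts",
            )
        if c.parent_id is not None and c.parent_id not in kb.concepts:
            rep.add("concept-parent-resolves", c.id, f"parent {c.parent_id!r} unknown")
        for rel, ids in (("may_treat", c.may_treat), ("may_prevent", c.may_prevent)):
            for cid in sorted(ids):
                target = kb.concepts.get(cid)
                if target is None or target.category is not ConceptCategory.CONDITION:
                    rep.add(
                        f"{rel.replace('_', '-')}-targets-condition",
                        c.id,
                        f"{rel} target {cid!r} is not a condition concept",
                    )
    # acyclicity of the parent forest
    for c in kb.concepts.values():
        seen: set[str] = set()
        node: Optional[str] = c.id
        while node is not None and node in kb.concepts:
            if node in seen:
                rep.add("concept-hierarchy-acyclic", c.id, f"parent chain revisits {node!r}")
                break
            seen.add(node)
            node = kb.concepts[node].parent_id


def _validate_facts(kb: "KnowledgeBase", rep: ValidationReport) -> None:
    for f in kb.facts.values():
        if not f.text:
            rep.add("fact-text-nonempty", f.id, "fact text is empty")
        about = kb.concepts.get(f.about_condition)
        if about is None:
            rep.add("fact-condition-resolves", f.id, f"condition {f.about_condition!r} unknown")
        elif about.category is not ConceptCategory.CONDITION:
            rep.add("fact-about-condition", f.id, f"{f.about_condition!r} is not a condition")


def _validate_profiles(kb: "KnowledgeBase", rep: ValidationReport) -> None:
    for cid, p in kb.profiles.items():
        if p.condition_id != cid or p.condition_id not in kb.concepts:
            rep.add("profile-condition-resolves", cid, "profile key/condition mismatch or unknown")
        for prop in PROFILE_PROPERTIES:
            for ref in getattr(p, prop):
                known = ref in kb.concepts or ref in kb.facts
                if not known:
                    rep.add("profile-ref-resolves", cid, f"{prop} entry {ref!r} unknown")
                    continue
                if prop in ("treatment_options", "prevention_options"):
                    c = kb.concepts.get(ref)
                    if c is None or c.category is not ConceptCategory.TREATMENT_OPTION:
                        rep.add(
                            "profile-treatment-option-category",
                            cid,
                            f"{prop} entry {ref!r} is not a treatment_option concept",
                        )
                elif prop == "complications":
                    c = kb.concepts.get(ref)
                    if c is None or c.category is not ConceptCategory.CONDITION:
                        rep.add(
                            "profile-complication-category",
                            cid,
                            f"complications entry {ref!r} is not a condition concept",
                        )


def _validate_renderable(rt: RenderableText, owner: str, rep: ValidationReport) -> None:
    if not rt.text and not rt.asset_ref:
        rep.add("renderable-text-or-asset", owner, "rendering has neither text nor asset_ref")


def _validate_buks(kb: "KnowledgeBase", rep: ValidationReport) -> None:
    for b in kb.buks.values():
        if b.refers_to not in kb.concepts and b.refers_to not in kb.facts:
            rep.add("buk-refers-resolves", b.id, f"refers_to {b.refers_to!r} unknown")
        if not b.explanation_renderings:
            rep.add("buk-explanation-nonempty", b.id, "no explanation renderings")
        for style, rt in b.explanation_renderings.items():
            if rt.style is not style:
                rep.add("rendering-style-consistent", b.id, f"explanation key {style} != {rt.style}")
            _validate_renderable(rt, b.id, rep)
        if b.kind is BUKKind.QA:
            if not b.question:
                rep.add("qa-question-present", b.id, "qa BUK without question renderings")
            else:
                for style, rt in b.question.items():
                    if style not in QUESTION_STYLES:
                        rep.add(
                            "qa-question-style",
                            b.id,
                            f"question rendering in style {style.value}; only A/R allowed",
                        )
                    _validate_renderable(rt, b.id, rep)
            if not b.choices or len(b.choices) < 2:
                rep.add("qa-choices-min2", b.id, "qa BUK needs at least 2 choices")
            if (
                b.correct_choice_index is None
                or not b.choices
                or not 0 <= b.correct_choice_index < len(b.choices)
            ):
                rep.add("qa-correct-index-valid", b.id, "correct_choice_index missing/out of range")
        else:
            if b.question is not None or b.choices is not None or b.correct_choice_index is not None:
                rep.add("content-no-question-fields", b.id, "content BUK carries qa fields")
    # sequence_index unique within each qa group
    groups: dict[tuple, dict[int, str]] = {}
    for b in kb.buks.values():
        if b.kind is BUKKind.QA and b.sequence_index is not None:
            if b.sequence_index < 0:
                rep.add("sequence-index-nonnegative", b.id, "sequence_index is negative")
                continue
            key = (b.refers_to, b.theme, b.bloom)
            seen = groups.setdefault(key, {})
            if b.sequence_index in seen:
                rep.add(
                    "sequence-index-unique",
                    b.id,
                    f"sequence_index {b.sequence_index} duplicates {seen[b.sequence_index]!r}",
                )
            else:
                seen[b.sequence_index] = b.id


def _validate_patients(kb: "KnowledgeBase", rep: ValidationReport) -> None:
    for p in kb.patients.values():
        if not p.preferred_styles:
            rep.add("patient-styles-nonempty", p.id, "no preferred VARK styles")
        if len(set(p.preferred_styles)) != len(p.preferred_styles):
            rep.add("patient-styles-distinct", p.id, "duplicate preferred styles")
        cond = kb.concepts.get(p.condition_id)
        if cond is None or cond.category is not ConceptCategory.CONDITION:
            rep.add("patient-condition-resolves", p.id, f"condition {p.condition_id!r} unknown")
        tid = p.treatment_request.treatment_option_id
        tx = kb.concepts.get(tid)
        if tx is None or tx.category is not ConceptCategory.TREATMENT_OPTION:
            rep.add("patient-treatment-resolves", p.id, f"treatment {tid!r} unknown")
        else:
            profile = kb.profiles.get(p.condition_id)
            listed = profile is not None and (
                tid in profile.treatment_options or tid in profile.prevention_options
            )
            if not listed:
                rep.add(
                    "patient-treatment-in-profile",
                    p.id,
                    f"treatment {tid!r} not among the condition's treatment/prevention options",
                    severity="warning",
                )
        prev = -1
        for e in p.performance_log.entries:
            if e.tick <= prev:
                rep.add("performance-log-ticks-increasing", p.id, f"tick {e.tick} not increasing")
            prev = e.tick
            b = kb.buks.get(e.buk_id)
            if b is None:
                rep.add("performance-log-buk-resolves", p.id, f"log entry buk {e.buk_id!r} unknown")
            elif b.kind is not BUKKind.QA:
                rep.add("performance-log-qa-only", p.id, f"log entry {e.buk_id!r} is not a qa BUK")


# ---------------------------------------------------------------------------
# Hierarchy and templating


def concept_lineage(kb: "KnowledgeBase", concept_id: str) -> list[str]:
    """Parent chain of ``concept_id``, most general concept first.

    Length 1 when the concept has no parent.  Courses traverse lineages
    top-down so general principles are taught before specific ones.
    """
    if concept_id not in kb.concepts:
        raise UnknownEntityError(f"unknown concept {concept_id!r}")
    chain = [concept_id]
    seen = {concept_id}
    node = kb.concepts[concept_id].parent_id
    while node is not None:
        if node not in kb.concepts:
            raise UnknownEntityError(f"unknown parent {node!r} of {chain[-1]!r}")
        if node in seen:
            raise KBError(f"cycle in parent chain at {node!r}")
        chain.append(node)
        seen.add(node)
        node = kb.concepts[node].parent_id
    chain.reverse()
    return chain


_PLACEHOLDER_RE = re.compile(r"\{([a-z_]+)\}")
SUPPORTED_PLACEHOLDERS = frozenset({"treatment", "dose", "timing"})


def instantiate_template(
    rt: RenderableText,
    tr: TreatmentRequest,
    kb: "KnowledgeBase",
    on_warning: Optional[Callable[[str], None]] = None,
) -> RenderableText:
    """Bind ``{treatment}``/``{dose}``/``{timing}`` placeholders to a prescription.

    ``{treatment}`` becomes the preferred name of the prescribed treatment
    option.  Unknown placeholders are left intact and reported through
    ``on_warning``.  Placeholder-free text is returned unchanged (the
    operation is a fixed point on it) and the style field is never altered.
    """
    text, warned = instantiate_text(rt.text, tr, kb)
    if on_warning is not None:
        for w in warned:
            on_warning(w)
    if text == rt.text:
        return rt
    return RenderableText(style=rt.style, text=text, asset_ref=rt.asset_ref)


def instantiate_text(text: str, tr: TreatmentRequest, kb: "KnowledgeBase") -> tuple[str, list[str]]:
    """Placeholder substitution on a bare string; returns (text, warnings)."""
    values = {
        "treatment": _treatment_name(tr, kb),
        "dose": tr.dose,
        "timing": tr.timing,
    }
    warnings: list[str] = []

    def _sub(m: "re.Match[str]") -> str:
        name = m.group(1)
        if name in SUPPORTED_PLACEHOLDERS:
            return values[name]
        warnings.append(f"unknown placeholder {{{name}}} left unreplaced")
        return m.group(0)

    return _PLACEHOLDER_RE.sub(_sub, text), warnings


def _treatment_name(tr: TreatmentRequest, kb: "KnowledgeBase") -> str:
    concept = kb.concepts.get(tr.treatment_option_id)
    if concept is None:
        raise UnknownEntityError(f"unknown treatment option {tr.treatment_option_id!r}")
    return concept.code.preferred_name
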