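"""Knowledge-base container, JSON/YAML persistence, BUK retrieval, OWL export.

The working store is a JSON/YAML dialect (canonical serialization with sorted
keys so round trips are byte-stable); OWL/Turtle is an export for
interoperability, not the operational representation — plan sequencing and
course control flow live in the engine, which ontologies express poorly.

Retrieval implements the comprehension-level fallback: a BUK is looked up at
the patient's current level and, failing that, at successively lower levels.
Alternative questions on the same (concept, theme, Bloom level) form cyclic
sequences ordered by ``sequence_index``.
"""

from __future__ import annotations

import copy
import json
import warnings as _pywarnings
from dataclasses import dataclass, field
from typing import Any, Optional, Union

import yaml

from tutorplan.model import (
    BUK,
    BUKKind,
    BloomLevel,
    ComprehensionLevel,
    ConceptCategory,
    ConceptCode,
    ConditionFact,
    ConditionProfile,
    KBError,
    MedicalConcept,
    Patient,
    PerformanceEntry,
    PerformanceLog,
    REFERENTIAL_RULES,
    RenderableText,
    SchemaError,
    Theme,
    TreatmentRequest,
    TreatmentSubtype,
    UnknownEntityError,
    VARKStyle,
    validate_kb,
)


class KBValidationWarning(UserWarning):
    """Non-fatal invariant violation surfaced while loading a KB."""


class KBIntegrityError(KBError):
    """Dangling references make the KB unusable."""


@dataclass
class KnowledgeBase:
    """All instances of the eLearning ontology: domain knowledge + patient data."""

    concepts: dict[str, MedicalConcept] = field(default_factory=dict)
    facts: dict[str, ConditionFact] = field(default_factory=dict)
    profiles: dict[str, ConditionProfile] = field(default_factory=dict)
    buks: dict[str, BUK] = field(default_factory=dict)
    patients: dict[str, Patient] = field(default_factory=dict)

    def copy(self) -> "KnowledgeBase":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class BUKQuery:
    """Retrieval key: scope item, theme, Bloom level, kind, comprehension level.

    ``theme = GENERAL`` acts as a wildcard matching any theme (used for scope
    items that are not treatment options).
    """

    scope_item: str
    theme: Theme
    bloom: BloomLevel
    kind: BUKKind
    comprehension: ComprehensionLevel


# ---------------------------------------------------------------------------
# Retrieval


def _buk_sort_key(b: BUK) -> tuple:
    return (0, b.sequence_index, b.id) if b.sequence_index is not None else (1, 0, b.id)


def query_buks(kb: KnowledgeBase, q: BUKQuery) -> list[BUK]:
    """All BUKs matching the query at the *exact* comprehension level.

    Ordered by sequence_index ascending (unindexed BUKs after indexed ones),
    then id, so retrieval is total and reproducible.
    """
    out = [
        b
        for b in kb.buks.values()
        if b.refers_to == q.scope_item
        and b.kind is q.kind
        and b.bloom is q.bloom
        and b.comprehension is q.comprehension
        and (q.theme is Theme.GENERAL or b.theme is q.theme)
    ]
    out.sort(key=_buk_sort_key)
    return out


def retrieve_buk_with_fallback(kb: KnowledgeBase, q: BUKQuery) -> Optional[BUK]:
    """First matching BUK scanning comprehension levels strictly downward.

    If nothing exists at or below the queried level the item is unteachable at
    this level and ``None`` is returned (callers skip with a warning); upward
    fallback is never attempted.
    """
    for level in q.comprehension.at_or_below():
        hits = query_buks(
            kb,
            BUKQuery(q.scope_item, q.theme, q.bloom, q.kind, level),
        )
        if hits:
            return hits[0]
    return None


def sequence_group(kb: KnowledgeBase, buk: BUK) -> list[BUK]:
    """The cyclic sequence of qa BUKs sharing (concept, theme, Bloom level)."""
    members = [
        b
        for b in kb.buks.values()
        if b.kind is BUKKind.QA
        and b.refers_to == buk.refers_to
        and b.theme is buk.theme
        and b.bloom is buk.bloom
    ]
    members.sort(key=_buk_sort_key)
    return members


def next_qa_in_sequence(kb: KnowledgeBase, current: BUK) -> BUK:
    """Next qa BUK in the sequence, wrapping to the first after the last.

    On a singleton group the BUK is its own successor.
    """
    if current.id not in kb.buks:
        raise UnknownEntityError(f"buk {current.id!r} not in knowledge base")
    group = sequence_group(kb, current)
    ids = [b.id for b in group]
    idx = ids.index(current.id)
    return group[(idx + 1) % len(group)]


# ---------------------------------------------------------------------------
# Serialization (canonical JSON/YAML)

_SECTIONS = ("concepts", "facts", "profiles", "buks", "patients")


def _renderings_to_dict(renderings: dict[VARKStyle, RenderableText]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for style in sorted(renderings, key=lambda s: s.value):
        rt = renderings[style]
        d: dict[str, Any] = {"text": rt.text}
        if rt.asset_ref is not None:
            d["asset_ref"] = rt.asset_ref
        out[style.value] = d
    return out


def kb_to_dict(kb: KnowledgeBase) -> dict[str, Any]:
    """Canonical plain-dict form: sorted sets, omitted defaults, stable shapes."""
    doc: dict[str, Any] = {s: {} for s in _SECTIONS}
    for c in kb.concepts.values():
        d: dict[str, Any] = {
            "code": {
                "system": c.code.system,
                "code": c.code.code,
                "preferred_name": c.code.preferred_name,
            },
            "category": c.category.value,
        }
        if c.treatment_subtype is not None:
            d["treatment_subtype"] = c.treatment_subtype.value
        if c.parent_id is not None:
            d["parent_id"] = c.parent_id
        if c.may_treat:
            d["may_treat"] = sorted(c.may_treat)
        if c.may_prevent:
            d["may_prevent"] = sorted(c.may_prevent)
        doc["concepts"][c.id] = d
    for f in kb.facts.values():
        doc["facts"][f.id] = {"text": f.text, "about_condition": f.about_condition}
    for cid, p in kb.profiles.items():
        doc["profiles"][cid] = {
            "condition_facts": list(p.condition_facts),
            "findings": list(p.findings),
            "complications": list(p.complications),
            "risk_factors": list(p.risk_factors),
            "treatment_options": list(p.treatment_options),
            "prevention_options": list(p.prevention_options),
        }
    for b in kb.buks.values():
        d = {
            "kind": b.kind.value,
            "refers_to": b.refers_to,
            "theme": b.theme.value,
            "bloom": b.bloom.value,
            "comprehension": b.comprehension.value,
            "explanation": _renderings_to_dict(b.explanation_renderings),
        }
        if b.question is not None:
            d["question"] = _renderings_to_dict(b.question)
        if b.choices is not None:
            d["choices"] = list(b.choices)
        if b.correct_choice_index is not None:
            d["correct_choice_index"] = b.correct_choice_index
        if b.sequence_index is not None:
            d["sequence_index"] = b.sequence_index
        doc["buks"][b.id] = d
    for pt in kb.patients.values():
        tr = pt.treatment_request
        trd: dict[str, Any] = {
            "treatment_option_id": tr.treatment_option_id,
            "dose": tr.dose,
            "timing": tr.timing,
        }
        if tr.rate is not None:
            trd["rate"] = tr.rate
        d = {
            "comprehension": pt.comprehension.value,
            "preferred_styles": [s.value for s in pt.preferred_styles],
            "condition_id": pt.condition_id,
            "treatment_request": trd,
        }
        if pt.demographics:
            d["demographics"] = dict(sorted(pt.demographics.items()))
        if pt.performance_log.entries:
            d["performance_log"] = [
                {"buk_id": e.buk_id, "correct": e.correct, "tick": e.tick}
                for e in pt.performance_log.entries
            ]
        doc["patients"][pt.id] = d
    return doc


def save_kb(kb: KnowledgeBase, format: str = "json") -> bytes:
    """Serialize canonically (sorted keys); identical KBs give identical bytes."""
    doc = kb_to_dict(kb)
    if format == "json":
        return (json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n").encode()
    if format == "yaml":
        return yaml.safe_dump(doc, sort_keys=True, allow_unicode=True).encode()
    raise ValueError(f"unsupported format {format!r}")


def _require(doc: dict, key: str, path: str, typ: type) -> Any:
    if key not in doc:
        raise SchemaError(f"{path}/{key}", "missing required element")
    val = doc[key]
    if not isinstance(val, typ):
        raise SchemaError(f"{path}/{key}", f"expected {typ.__name__}, got {type(val).__name__}")
    return val


def _enum(cls, raw: Any, path: str):
    try:
        return cls(raw)
    except ValueError:
        allowed = ", ".join(e.value for e in cls)
        raise SchemaError(path, f"invalid value {raw!r}; expected one of: {allowed}") from None


def _parse_renderings(raw: dict, path: str) -> dict[VARKStyle, RenderableText]:
    out: dict[VARKStyle, RenderableText] = {}
    for key, val in raw.items():
        style = _enum(VARKStyle, key, f"{path}/{key}")
        if not isinstance(val, dict):
            raise SchemaError(f"{path}/{key}", "rendering must be an object")
        out[style] = RenderableText(
            style=style,
            text=val.get("text", ""),
            asset_ref=val.get("asset_ref"),
        )
    return out


def kb_from_dict(doc: dict[str, Any]) -> KnowledgeBase:
    """Build a KB from a plain dict, with JSON-pointer-style error locations."""
    if not isinstance(doc, dict):
        raise SchemaError("", "document root must be an object")
    for section in _SECTIONS:
        _require(doc, section, "", dict)
    kb = KnowledgeBase()
    for cid, raw in doc["concepts"].items():
        path = f"/concepts/{cid}"
        code_raw = _require(raw, "code", path, dict)
        subtype = raw.get("treatment_subtype")
        kb.concepts[cid] = MedicalConcept(
            id=cid,
            code=ConceptCode(
                system=code_raw.get("system", ""),
                code=_require(code_raw, "code", f"{path}/code", str),
                preferred_name=_require(code_raw, "preferred_name", f"{path}/code", str),
            ),
            category=_enum(ConceptCategory, _require(raw, "category", path, str), f"{path}/category"),
            treatment_subtype=(
                _enum(TreatmentSubtype, subtype, f"{path}/treatment_subtype")
                if subtype is not None
                else None
            ),
            parent_id=raw.get("parent_id"),
            may_treat=set(raw.get("may_treat", [])),
            may_prevent=set(raw.get("may_prevent", [])),
        )
    for fid, raw in doc["facts"].items():
        path = f"/facts/{fid}"
        kb.facts[fid] = ConditionFact(
            id=fid,
            text=_require(raw, "text", path, str),
            about_condition=_require(raw, "about_condition", path, str),
        )
    for cid, raw in doc["profiles"].items():
        path = f"/profiles/{cid}"
        kb.profiles[cid] = ConditionProfile(
            condition_id=cid,
            condition_facts=list(raw.get("condition_facts", [])),
            findings=list(raw.get("findings", [])),
            complications=list(raw.get("complications", [])),
            risk_factors=list(raw.get("risk_factors", [])),
            treatment_options=list(raw.get("treatment_options", [])),
            prevention_options=list(raw.get("prevention_options", [])),
        )
    for bid, raw in doc["buks"].items():
        path = f"/buks/{bid}"
        kind = _enum(BUKKind, _require(raw, "kind", path, str), f"{path}/kind")
        question = raw.get("question")
        kb.buks[bid] = BUK(
            id=bid,
            kind=kind,
            refers_to=_require(raw, "refers_to", path, str),
            theme=_enum(Theme, _require(raw, "theme", path, str), f"{path}/theme"),
            bloom=_enum(BloomLevel, _require(raw, "bloom", path, str), f"{path}/bloom"),
            comprehension=_enum(
                ComprehensionLevel, _require(raw, "comprehension", path, str), f"{path}/comprehension"
            ),
            explanation_renderings=_parse_renderings(
                _require(raw, "explanation", path, dict), f"{path}/explanation"
            ),
            question=_parse_renderings(question, f"{path}/question") if question is not None else None,
            choices=list(raw["choices"]) if "choices" in raw else None,
            correct_choice_index=raw.get("correct_choice_index"),
            sequence_index=raw.get("sequence_index"),
        )
    for pid, raw in doc["patients"].items():
        path = f"/patients/{pid}"
        tr_raw = _require(raw, "treatment_request", path, dict)
        log_raw = raw.get("performance_log", [])
        kb.patients[pid] = Patient(
            id=pid,
            comprehension=_enum(
                ComprehensionLevel, _require(raw, "comprehension", path, str), f"{path}/comprehension"
            ),
            preferred_styles=[
                _enum(VARKStyle, s, f"{path}/preferred_styles")
                for s in _require(raw, "preferred_styles", path, list)
            ],
            condition_id=_require(raw, "condition_id", path, str),
            treatment_request=TreatmentRequest(
                treatment_option_id=_require(
                    tr_raw, "treatment_option_id", f"{path}/treatment_request", str
                ),
                dose=tr_raw.get("dose", ""),
                timing=tr_raw.get("timing", ""),
                rate=tr_raw.get("rate"),
            ),
            demographics=dict(raw.get("demographics", {})),
            performance_log=PerformanceLog(
                entries=[
                    PerformanceEntry(
                        buk_id=e["buk_id"], correct=bool(e["correct"]), tick=int(e["tick"])
                    )
                    for e in log_raw
                ]
            ),
        )
    return kb


def load_kb(source: Union[str, bytes], format: str = "json") -> KnowledgeBase:
    """Parse and validate a KB document.

    Dangling references raise :class:`KBIntegrityError`; other invariant
    violations are surfaced as :class:`KBValidationWarning` warnings.
    """
    if isinstance(source, bytes):
        source = source.decode("utf-8")
    if format == "json":
        try:
            doc = json.loads(source)
        except json.JSONDecodeError as exc:
            raise SchemaError("", f"JSON parse error: {exc}") from exc
    elif format == "yaml":
        try:
            doc = yaml.safe_load(source)
        except yaml.YAMLError as exc:
            raise SchemaError("", f"YAML parse error: {exc}") from exc
    else:
        raise ValueError(f"unsupported format {format!r}")
    kb = kb_from_dict(doc)
    report = validate_kb(kb)
    hard = [i for i in report.issues if i.rule in REFERENTIAL_RULES]
    if hard:
        details = "; ".join(f"{i.entity_id}: {i.message}" for i in hard)
        raise KBIntegrityError(f"unresolvable references: {details}")
    for issue in report.issues:
        if issue.rule not in REFERENTIAL_RULES:
            _pywarnings.warn(
                f"{issue.rule} [{issue.entity_id}]: {issue.message}", KBValidationWarning,
                stacklevel=2,
            )
    return kb


# ---------------------------------------------------------------------------
# OWL export

ONTOLOGY_NS = "http://tutorplan.example.org/ontology#"
INDIVIDUAL_NS = "http://tutorplan.example.org/kb#"

_CATEGORY_CLASS = {
    ConceptCategory.CONDITION: "Condition",
    ConceptCategory.OBSERVATION: "Observation",
    ConceptCategory.TREATMENT_OPTION: "Treatment_Option",
}
_SUBTYPE_CLASS = {
    TreatmentSubtype.MEDICATION: "Medication",
    TreatmentSubtype.SERVICE: "Service",
    TreatmentSubtype.NUTRITION_ORDER: "Nutrition_Order",
    TreatmentSubtype.CARE_PLAN: "Care_Plan",
}

_CLASS_TREE = {
    "Medical_Concept": None,
    "Condition": "Medical_Concept",
    "Observation": "Medical_Concept",
    "Treatment_Option": "Medical_Concept",
    "Medication": "Treatment_Option",
    "Service": "Treatment_Option",
    "Nutrition_Order": "Treatment_Option",
    "Care_Plan": "Treatment_Option",
    "Education_Concept": None,
    "Condition_Profile": "Education_Concept",
    "Condition_Fact": "Education_Concept",
    "BUK": "Education_Concept",
    "Content_BUK": "BUK",
    "QA_BUK": "BUK",
    "Patient": None,
}


def export_owl(kb: KnowledgeBase) -> str:
    """Export the KB as an OWL ontology in Turtle.

    One OWL class per ontology class, one individual per KB entity; object
    properties for has_parent / may_treat / may_prevent / refers_to_concept
    and data properties for the BUK annotations.  Output is deterministic for
    identical KBs.  Within-list ordering of profile properties is a concern of
    the native store and is exported as plain membership triples.
    """
    from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
    from rdflib.namespace import OWL, XSD

    ont = Namespace(ONTOLOGY_NS)
    ind = Namespace(INDIVIDUAL_NS)
    g = Graph()
    g.bind("owl", OWL)
    g.bind("elo", ont)
    g.bind("kb", ind)

    for cls, parent in _CLASS_TREE.items():
        g.add((ont[cls], RDF.type, OWL.Class))
        if parent is not None:
            g.add((ont[cls], RDFS.subClassOf, ont[parent]))
    for prop in ("has_parent", "may_treat", "may_prevent", "refers_to_concept",
                 "about_condition", "profiles_condition", "has_profile_entry",
                 "preferred_style", "has_condition", "requests_treatment"):
        g.add((ont[prop], RDF.type, OWL.ObjectProperty))
    for prop in ("preferred_name", "vocabulary_system", "vocabulary_code", "theme",
                 "bloom_level", "comprehension_level", "explanation_style",
                 "question_style", "sequence_index", "fact_text", "dose", "timing"):
        g.add((ont[prop], RDF.type, OWL.DatatypeProperty))

    def uri(entity_id: str) -> URIRef:
        return ind[entity_id]

    for c in sorted(kb.concepts.values(), key=lambda x: x.id):
        node = uri(c.id)
        cls = _SUBTYPE_CLASS[c.treatment_subtype] if c.treatment_subtype else _CATEGORY_CLASS[c.category]
        g.add((node, RDF.type, ont[cls]))
        g.add((node, ont.preferred_name, Literal(c.code.preferred_name)))
        g.add((node, ont.vocabulary_system, Literal(c.code.system)))
        g.add((node, ont.vocabulary_code, Literal(c.code.code)))
        if c.parent_id:
            g.add((node, ont.has_parent, uri(c.parent_id)))
        for t in sorted(c.may_treat):
            g.add((node, ont.may_treat, uri(t)))
        for t in sorted(c.may_prevent):
            g.add((node, ont.may_prevent, uri(t)))
    for f in sorted(kb.facts.values(), key=lambda x: x.id):
        node = uri(f.id)
        g.add((node, RDF.type, ont.Condition_Fact))
        g.add((node, ont.fact_text, Literal(f.text)))
        g.add((node, ont.about_condition, uri(f.about_condition)))
    for cid in sorted(kb.profiles):
        p = kb.profiles[cid]
        node = uri(f"profile_{cid}")
        g.add((node, RDF.type, ont.Condition_Profile))
        g.add((node, ont.profiles_condition, uri(cid)))
        for prop in ("condition_facts", "findings", "complications", "risk_factors",
                     "treatment_options", "prevention_options"):
            for ref in getattr(p, prop):
                g.add((node, ont.has_profile_entry, uri(ref)))
    for b in sorted(kb.buks.values(), key=lambda x: x.id):
        node = uri(b.id)
        g.add((node, RDF.type, ont.QA_BUK if b.kind is BUKKind.QA else ont.Content_BUK))
        g.add((node, ont.refers_to_concept, uri(b.refers_to)))
        g.add((node, ont.theme, Literal(b.theme.value)))
        g.add((node, ont.bloom_level, Literal(b.bloom.value)))
        g.add((node, ont.comprehension_level, Literal(b.comprehension.value)))
        for style in sorted(b.explanation_renderings, key=lambda s: s.value):
            g.add((node, ont.explanation_style, Literal(style.value)))
        if b.question:
            for style in sorted(b.question, key=lambda s: s.value):
                g.add((node, ont.question_style, Literal(style.value)))
        if b.sequence_index is not None:
            g.add((node, ont.sequence_index, Literal(b.sequence_index, datatype=XSD.integer)))
    for pt in sorted(kb.patients.values(), key=lambda x: x.id):
        node = uri(pt.id)
        g.add((node, RDF.type, ont.Patient))
        g.add((node, ont.comprehension_level, Literal(pt.comprehension.value)))
        for s in pt.preferred_styles:
            g.add((node, ont.preferred_style, Literal(s.value)))
        g.add((node, ont.has_condition, uri(pt.condition_id)))
        g.add((node, ont.requests_treatment, uri(pt.treatment_request.treatment_option_id)))
        g.add((node, ont.dose, Literal(pt.treatment_request.dose)))
        g.add((node, ont.timing, Literal(pt.treatment_request.timing)))
    return g.serialize(format="turtle")
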