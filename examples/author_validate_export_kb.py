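"""Author a minimal knowledge base, validate it, and export it to OWL/Turtle.

Shows the authoring surface: a condition with a profile, a treatment option
hierarchy, one Q&A unit, and what the validator reports when an invariant is
broken (here: a question rendered in a visual style, which the model forbids —
questions exist only in aural and read/write modalities).
"""

from tutorplan import (
    BUK, BUKKind, BloomLevel, ComprehensionLevel, ConceptCategory, ConceptCode,
    ConditionProfile, KnowledgeBase, MedicalConcept, RenderableText, Theme,
    TreatmentSubtype, VARKStyle, export_owl, save_kb, validate_kb,
)

kb = KnowledgeBase()
kb.concepts["hypertension"] = MedicalConcept(
    id="hypertension",
    code=ConceptCode("SNOMED-CT", "38341003", "Hypertension"),
    category=ConceptCategory.CONDITION,
)
kb.concepts["ace_inhibitor"] = MedicalConcept(
    id="ace_inhibitor",
    code=ConceptCode("SNOMED-CT", "372733002", "ACE inhibitor"),
    category=ConceptCategory.TREATMENT_OPTION,
    treatment_subtype=TreatmentSubtype.MEDICATION,
    may_treat={"hypertension"},
)
kb.profiles["hypertension"] = ConditionProfile(
    condition_id="hypertension", treatment_options=["ace_inhibitor"]
)
kb.buks["ht_qa_1"] = BUK(
    id="ht_qa_1",
    kind=BUKKind.QA,
    refers_to="ace_inhibitor",
    theme=Theme.SIDE_EFFECTS,
    bloom=BloomLevel.LOWER,
    comprehension=ComprehensionLevel.MEDIUM,
    question={VARKStyle.R: RenderableText(VARKStyle.R, "Which side effect is common with {treatment}?")},
    choices=["A dry cough", "Hair loss"],
    correct_choice_index=0,
    explanation_renderings={
        VARKStyle.R: RenderableText(VARKStyle.R, "A persistent dry cough is the classic side effect.")
    },
)

report = validate_kb(kb)
print(f"authored KB: {len(kb.concepts)} concepts, {len(kb.buks)} units; "
      f"validation issues: {len(report.issues)}")

# break an invariant on purpose: a visual question rendering
kb.buks["ht_qa_1"].question[VARKStyle.V] = RenderableText(VARKStyle.V, "visual question?")
for issue in validate_kb(kb).issues:
    print(f"  [{issue.severity}] {issue.rule} ({issue.entity_id}): {issue.message}")
del kb.buks["ht_qa_1"].question[VARKStyle.V]

print("\ncanonical JSON (first 3 lines):")
print("\n".join(save_kb(kb).decode().splitlines()[:3]))

turtle = export_owl(kb)
print(f"\nOWL export: {len(turtle.splitlines())} Turtle lines; excerpt:")
print("\n".join(line for line in turtle.splitlines() if "ht_qa_1" in line or "may_treat" in line))
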