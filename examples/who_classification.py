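"""Integrated 2021-WHO classification from molecular + histologic markers.

Classifies four marker profiles and prints the fired rules: an IDH-mutant
1p/19q-codeleted grade-2 tumour (oligodendroglioma), an IDH-mutant
astrocytoma elevated to grade 4 by CDKN2A/B homozygous deletion, an
IDH-wildtype tumour qualifying as glioblastoma through a TERT promoter
mutation despite low-grade histology, and a record with unknown 1p/19q
status that cannot be resolved.
"""

from gliopatch import DiagnosticMarkers, integrate_diagnosis

cases = {
    "codeleted, grade 2": DiagnosticMarkers(
        idh_mutant=True, codel_1p19q=True, histologic_grade=2),
    "CDKN2A/B deleted astrocytoma": DiagnosticMarkers(
        idh_mutant=True, codel_1p19q=False, mvp=False, necrosis=False,
        cdkn2ab_homdel=True, histologic_grade=2),
    "TERT-mutant, low-grade histology": DiagnosticMarkers(
        idh_mutant=False, tert_promoter_mutant=True, mvp=False, necrosis=False,
        egfr_amplified=False, plus7_minus10=False, histologic_grade=2),
    "1p/19q status unknown": DiagnosticMarkers(idh_mutant=True),
}

for name, markers in cases.items():
    d = integrate_diagnosis(markers)
    outcome = d.category if d.status == "classified" else d.status
    print(f"{name}: {outcome}")
    for rule in d.rationale:
        print(f"    - {rule}")
    if d.missing:
        print(f"    missing markers: {', '.join(d.missing)}")
print("-> molecular markers can raise the grade above the histologic "
      "impression; unknowns on the decisive path stay unresolved rather than "
      "defaulting.")
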