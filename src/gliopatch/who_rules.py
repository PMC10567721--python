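"""Deterministic 2021-WHO rule engine for adult-type diffuse gliomas.

Maps molecular and histologic markers to the six categories A2, A3, A4, O2,
O3, GBM:

* IDH-mutant and 1p/19q-codeleted -> oligodendroglioma (O), grade from the
  histologic impression (2 or 3).
* IDH-mutant, non-codeleted -> astrocytoma (A); grade 4 iff microvascular
  proliferation, necrosis, or CDKN2A/B homozygous deletion is present
  (cIMPACT-NOW update 5), else the histologic grade.
* IDH-wildtype -> glioblastoma (GBM, grade 4) iff the histologic
  glioblastoma picture is present or any of TERT promoter mutation,
  high-level EGFR amplification, or whole chromosome 7 gain with whole
  chromosome 10 loss (+7/-10) holds (cIMPACT-NOW update 3); otherwise the
  tumour is not classifiable as an adult-type diffuse glioma in this scheme.

Unknown markers on a decisive path propagate to an "unresolved" outcome
naming the missing marker rather than defaulting, to avoid silent
misclassification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

BOOL_MARKERS = (
    "idh_mutant",
    "codel_1p19q",
    "cdkn2ab_homdel",
    "tert_promoter_mutant",
    "egfr_amplified",
    "plus7_minus10",
    "mvp",
    "necrosis",
)


@dataclass
class DiagnosticMarkers:
    """Molecular + histologic inputs; ``None`` marks an unknown field."""

    idh_mutant: Optional[bool] = None
    codel_1p19q: Optional[bool] = None
    cdkn2ab_homdel: Optional[bool] = None
    tert_promoter_mutant: Optional[bool] = None
    egfr_amplified: Optional[bool] = None
    plus7_minus10: Optional[bool] = None
    mvp: Optional[bool] = None
    necrosis: Optional[bool] = None
    histologic_grade: Optional[int] = None  # pre-molecular impression, 2 or 3

    def __post_init__(self) -> None:
        if self.histologic_grade is not None and self.histologic_grade not in (2, 3):
            raise ValueError("histologic_grade must be 2 or 3")

    def consistency_flags(self) -> list[str]:
        flags = []
        if self.codel_1p19q is True and self.idh_mutant is False:
            flags.append(
                "1p/19q codeletion with IDH-wildtype status is inconsistent with an "
                "adult-type diffuse glioma record"
            )
        return flags


@dataclass
class IntegratedDiagnosis:
    """Outcome of the rule engine.

    ``status`` is "classified" (category one of the six), "indeterminate"
    (IDH-wildtype with no qualifying molecular or histologic feature: not
    classifiable as an adult-type diffuse glioma in this scheme), or
    "unresolved" (a marker needed on the decisive path is unknown, listed in
    ``missing``). ``rationale`` records the fired rules in order.
    """

    status: str
    type: Optional[str] = None        # A, O, or GBM
    grade: Optional[int] = None       # 2, 3, or 4
    category: Optional[str] = None    # A2, A3, A4, O2, O3, GBM
    rationale: list = field(default_factory=list)
    missing: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status == "classified":
            assert self.category == f"{self.type}{self.grade}" or (
                self.type == "GBM" and self.category == "GBM" and self.grade == 4
            )


def _any_true_or_unknowns(values: dict) -> Union[bool, list]:
    """Three-valued OR: True if any value is True; else the unknown names
    (possibly empty, meaning all known False)."""
    if any(v is True for v in values.values()):
        return True
    return [k for k, v in values.items() if v is None]


def integrate_diagnosis(
    m: DiagnosticMarkers,
    gbm_histology_requires_both: bool = False,
) -> IntegratedDiagnosis:
    """Apply the 2021-WHO rules to one marker record.

    ``gbm_histology_requires_both`` switches the IDH-wildtype histologic
    glioblastoma picture from (MVP or necrosis), the classical criterion and
    the default, to the stricter (MVP and necrosis).
    """
    rationale = list(m.consistency_flags())

    if m.idh_mutant is None:
        return IntegratedDiagnosis(
            "unresolved", rationale=rationale, missing=["idh_mutant"]
        )

    if m.idh_mutant:
        if m.codel_1p19q is None:
            return IntegratedDiagnosis(
                "unresolved",
                rationale=rationale + ["IDH-mutant; 1p/19q status required"],
                missing=["codel_1p19q"],
            )
        if m.codel_1p19q:
            rationale.append("IDH-mutant with 1p/19q codeletion -> oligodendroglioma")
            if m.histologic_grade is None:
                return IntegratedDiagnosis(
                    "unresolved", rationale=rationale, missing=["histologic_grade"]
                )
            grade = m.histologic_grade
            return IntegratedDiagnosis(
                "classified", "O", grade, f"O{grade}", rationale
            )
        rationale.append("IDH-mutant, non-codeleted -> astrocytoma")
        grade4 = _any_true_or_unknowns(
            {"mvp": m.mvp, "necrosis": m.necrosis, "cdkn2ab_homdel": m.cdkn2ab_homdel}
        )
        if grade4 is True:
            present = [
                name
                for name, v in (
                    ("MVP", m.mvp),
                    ("necrosis", m.necrosis),
                    ("CDKN2A/B homozygous deletion", m.cdkn2ab_homdel),
                )
                if v is True
            ]
            rationale.append(
                "grade-4 feature present (" + ", ".join(present) + ") -> grade 4"
            )
            return IntegratedDiagnosis("classified", "A", 4, "A4", rationale)
        if grade4:  # unknown markers could still elevate the grade
            return IntegratedDiagnosis(
                "unresolved",
                rationale=rationale + ["grade-4 features not fully assessable"],
                missing=list(grade4),
            )
        if m.histologic_grade is None:
            return IntegratedDiagnosis(
                "unresolved", rationale=rationale, missing=["histologic_grade"]
            )
        grade = m.histologic_grade
        rationale.append(f"no grade-4 feature; histologic grade {grade}")
        return IntegratedDiagnosis("classified", "A", grade, f"A{grade}", rationale)

    # IDH-wildtype
    rationale.append("IDH-wildtype")
    if gbm_histology_requires_both:
        if m.mvp is True and m.necrosis is True:
            hist = True
        elif m.mvp is False or m.necrosis is False:
            hist = False
        else:
            hist = None
    else:
        if m.mvp is True or m.necrosis is True:
            hist = True
        elif m.mvp is False and m.necrosis is False:
            hist = False
        else:
            hist = None
    qualifying = _any_true_or_unknowns(
        {
            "histologic_gbm_picture": hist,
            "tert_promoter_mutant": m.tert_promoter_mutant,
            "egfr_amplified": m.egfr_amplified,
            "plus7_minus10": m.plus7_minus10,
        }
    )
    if qualifying is True:
        present = []
        if hist is True:
            present.append("histologic glioblastoma picture")
        if m.tert_promoter_mutant is True:
            present.append("TERT promoter mutation")
        if m.egfr_amplified is True:
            present.append("EGFR amplification")
        if m.plus7_minus10 is True:
            present.append("+7/-10")
        rationale.append("qualifying feature present (" + ", ".join(present) + ") -> GBM")
        return IntegratedDiagnosis("classified", "GBM", 4, "GBM", rationale)
    if qualifying:
        missing = [
            q if q != "histologic_gbm_picture" else "mvp/necrosis" for q in qualifying
        ]
        return IntegratedDiagnosis(
            "unresolved",
            rationale=rationale + ["glioblastoma criteria not fully assessable"],
            missing=missing,
        )
    rationale.append(
        "no qualifying feature: not classifiable as an adult-type diffuse glioma "
        "in this scheme"
    )
    return IntegratedDiagnosis("indeterminate", rationale=rationale)


# ----------------------------------------------------------------------------
# Marker-table I/O (CSV with true/false/unknown cells)
# ----------------------------------------------------------------------------

def _parse_tristate(value) -> Optional[bool]:
    if pd.isna(value):
        return None
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    if s in ("unknown", "na", ""):
        return None
    raise ValueError(f"cannot parse marker value {value!r}")


def read_marker_table(path: Union[str, Path]) -> "pd.Series":
    """Read one DiagnosticMarkers per row, indexed by patient_id."""
    df = pd.read_csv(path, dtype=str)
    if "patient_id" not in df.columns:
        raise ValueError("marker table needs a patient_id column")
    records = {}
    for _, row in df.iterrows():
        kwargs = {}
        for name in BOOL_MARKERS:
            if name in df.columns:
                kwargs[name] = _parse_tristate(row[name])
        if "histologic_grade" in df.columns and not pd.isna(row["histologic_grade"]):
            kwargs["histologic_grade"] = int(float(row["histologic_grade"]))
        records[str(row["patient_id"])] = DiagnosticMarkers(**kwargs)
    return pd.Series(records, name="markers")


def classify_marker_table(
    path: Union[str, Path],
    out_csv: Optional[Union[str, Path]] = None,
    audit_json: Optional[Union[str, Path]] = None,
    gbm_histology_requires_both: bool = False,
) -> pd.DataFrame:
    """Classify every row of a marker CSV; optional rationale audit trail."""
    markers = read_marker_table(path)
    rows = []
    audit = {}
    for pid, m in markers.items():
        d = integrate_diagnosis(m, gbm_histology_requires_both)
        rows.append(
            {
                "patient_id": pid,
                "status": d.status,
                "type": d.type,
                "grade": d.grade,
                "category": d.category,
                "missing": ";".join(d.missing),
            }
        )
        audit[pid] = {"rationale": d.rationale, "missing": d.missing}
    out = pd.DataFrame(rows)
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    if audit_json is not None:
        Path(audit_json).write_text(json.dumps(audit, indent=2))
    return out
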