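"""Automatic per-patient module selection (the GMIEC-results step).

From the wide results table, pick for each patient the most over-activated
(or most over-suppressed) module that is a drug target, and emit a
simplified four-column table: patient id, module score, genes, drugs.

Categories: AOMD — active oncogenic module with drugs (drug constraint met,
strictly positive S-score); AOM — active module where the drug constraint
or the sign fails; IOMD — inactive oncogenic module with drugs (drug
constraint met, strictly negative S-score); none otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import ModuleRecord, ResultTable

CATEGORIES = ("AOMD", "AOM", "IOMD", "none")


@dataclass
class SelectionRow:
    patient: str
    score: float
    genes: list[str]
    drugs: list[str]
    category: str


def _pick(records: list[ModuleRecord], direction: str) -> ModuleRecord:
    """Extremal s_score; ties to larger score_drugs, then smaller index."""
    sign = 1.0 if direction == "active" else -1.0
    return max(records, key=lambda r: (sign * r.s_score, r.score_drugs, -r.index))


def select_active(
    result: ResultTable, direction: str = "active", min_drugs: int = 1
) -> list[SelectionRow]:
    """Select one module per patient by extremal S-score under a drug constraint.

    Among modules with at least ``min_drugs`` attached drugs, the module
    with maximal (direction=active) or minimal (direction=inactive) S-score
    wins; ties break toward larger druggable fraction, then smaller module
    index. Patients with no module meeting the drug constraint fall back to
    the best-scoring module overall, which can never be AOMD/IOMD.
    """
    if direction not in ("active", "inactive"):
        raise ValueError(f"direction must be active|inactive, got {direction!r}")
    rows = []
    for patient, records in result.modules.items():
        if not records:
            continue
        eligible = [r for r in records if len(r.drugs) >= min_drugs]
        met_constraint = bool(eligible)
        chosen = _pick(eligible if eligible else records, direction)
        if direction == "active":
            category = "AOMD" if met_constraint and chosen.s_score > 0 else "AOM"
        else:
            category = "IOMD" if met_constraint and chosen.s_score < 0 else "none"
        rows.append(
            SelectionRow(
                patient=patient,
                score=chosen.s_score,
                genes=list(chosen.genes),
                drugs=list(chosen.drugs),
                category=category,
            )
        )
    return rows


def cohort_counts(selections: list[SelectionRow]) -> dict[str, int]:
    """Patients per category, plus AOM patients that still carry >= 1 drug."""
    counts = {c: 0 for c in CATEGORIES}
    counts["AOM_with_drug"] = 0
    for row in selections:
        counts[row.category] += 1
        if row.category == "AOM" and row.drugs:
            counts["AOM_with_drug"] += 1
    return counts


def write_selection(
    selections: list[SelectionRow], path, include_category: bool = True
) -> None:
    cols = ["patient_id", "score", "genes", "drugs"]
    if include_category:
        cols.append("category")
    rows = []
    for s in selections:
        row = [
            s.patient,
            repr(float(s.score)),
            ",".join(s.genes) if s.genes else "NA",
            ",".join(s.drugs) if s.drugs else "NA",
        ]
        if include_category:
            row.append(s.category)
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_selection(path) -> list[SelectionRow]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            SelectionRow(
                patient=row["patient_id"],
                score=float(row["score"]),
                genes=[] if row["genes"] == "NA" else row["genes"].split(","),
                drugs=[] if row["drugs"] == "NA" else row["drugs"].split(","),
                category=row.get("category", "AOM"),
            )
        )
    return out
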