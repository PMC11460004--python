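"""Patient-level cohort comparison: free-text NLP versus ICD codes.

Kept mentions are aggregated to per-disease patient sets (a patient with
several documents counts once), ICD diagnosis tables are mapped to the
same diseases through the vocabulary crosswalk, and the two are
compared disease by disease.  Disease identity is the ontology concept
id, so one disease linked to several CUIs aggregates once; ICD codes are
compared dot-free and uppercased ("Q33.0" ≡ "Q330").
"""

from __future__ import annotations

import csv
import json
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .extraction import Document, Mention
from .vocabulary import CrosswalkEntry, normalize_icd_code


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class IcdDiagnosis:
    patient_id: str
    icd_version: int
    icd_code: str

    def __post_init__(self) -> None:
        if self.icd_version not in (9, 10):
            raise CohortError(f"icd_version must be 9 or 10, got {self.icd_version}")
        if not self.icd_code:
            raise CohortError("empty ICD code")


@dataclass(frozen=True)
class ComparisonRow:
    disease_key: str
    n_nlp: int
    n_icd: int
    n_both: int

    @property
    def nlp_only(self) -> bool:
        return self.n_icd == 0 and self.n_nlp > 0


@dataclass(frozen=True)
class CohortSummary:
    n_diseases_nlp: int
    n_patients_nlp: int
    n_diseases_nlp_only: int
    n_diseases_nlp_gt_icd: int

    def to_dict(self) -> dict:
        return {
            "n_diseases_nlp": self.n_diseases_nlp,
            "n_patients_nlp": self.n_patients_nlp,
            "n_diseases_nlp_only": self.n_diseases_nlp_only,
            "n_diseases_nlp_gt_icd": self.n_diseases_nlp_gt_icd,
        }


def aggregate_patients(
    kept: Iterable[Mention], docs: Iterable[Document]
) -> dict[str, set[str]]:
    """Union of patients per disease over all kept mentions."""
    patient_of = {d.doc_id: d.patient_id for d in docs}
    missing = sorted(
        {m.doc_id for m in kept if not patient_of.get(m.doc_id)}
    )
    if missing:
        raise CohortError(f"documents lack patient_id: {missing}")
    out: dict[str, set[str]] = defaultdict(set)
    for m in kept:
        out[m.concept_id].add(patient_of[m.doc_id])
    return dict(out)


def icd_patients(
    diagnoses: Iterable[IcdDiagnosis],
    crosswalk: Sequence[CrosswalkEntry],
) -> dict[str, set[str]]:
    """Patients per disease via version-matched crosswalk codes.

    Unresolved crosswalk entries contribute empty sets; patients coded in
    either ICD era are unioned under the same disease.
    """
    patients_by_code: dict[tuple[int, str], set[str]] = defaultdict(set)
    for d in diagnoses:
        patients_by_code[(d.icd_version, normalize_icd_code(d.icd_code))].add(
            d.patient_id
        )
    out: dict[str, set[str]] = defaultdict(set)
    for entry in crosswalk:
        out.setdefault(entry.concept_id, set())
        for code in entry.icd9_codes:
            out[entry.concept_id] |= patients_by_code.get((9, code), set())
        for code in entry.icd10_codes:
            out[entry.concept_id] |= patients_by_code.get((10, code), set())
    return dict(out)


def compare(
    nlp_map: Mapping[str, set[str]],
    icd_map: Mapping[str, set[str]],
) -> tuple[list[ComparisonRow], CohortSummary]:
    """Per-disease patient counts and their intersection, plus the
    headline summary: diseases seen by NLP, distinct NLP patients,
    diseases found only in free text, and diseases where free text finds
    more patients than the codes do.  Rows sort by n_nlp descending."""
    keys = sorted(set(nlp_map) | set(icd_map))
    rows = []
    for key in keys:
        nlp = nlp_map.get(key, set())
        icd = icd_map.get(key, set())
        rows.append(
            ComparisonRow(
                disease_key=key,
                n_nlp=len(nlp),
                n_icd=len(icd),
                n_both=len(nlp & icd),
            )
        )
    rows.sort(key=lambda r: (-r.n_nlp, r.disease_key))
    all_nlp_patients = set().union(*nlp_map.values()) if nlp_map else set()
    summary = CohortSummary(
        n_diseases_nlp=sum(1 for r in rows if r.n_nlp > 0),
        n_patients_nlp=len(all_nlp_patients),
        n_diseases_nlp_only=sum(1 for r in rows if r.nlp_only),
        n_diseases_nlp_gt_icd=sum(1 for r in rows if r.n_nlp > r.n_icd),
    )
    return rows, summary


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_diagnoses(path: str | Path) -> list[IcdDiagnosis]:
    """Read the diagnoses CSV (patient_id, icd_version, icd_code)."""
    out: list[IcdDiagnosis] = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"patient_id", "icd_version", "icd_code"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise CohortError(f"{path}: diagnoses file must have columns {sorted(required)}")
        for rec in reader:
            out.append(
                IcdDiagnosis(
                    patient_id=rec["patient_id"],
                    icd_version=int(rec["icd_version"]),
                    icd_code=rec["icd_code"],
                )
            )
    return out


def write_diagnoses(diagnoses: Iterable[IcdDiagnosis], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "icd_version", "icd_code"])
        for d in diagnoses:
            writer.writerow([d.patient_id, d.icd_version, d.icd_code])


def write_comparison(
    rows: Sequence[ComparisonRow], summary: CohortSummary, out_dir: str | Path
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "cohort_comparison.csv", "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["disease_key", "n_nlp", "n_icd", "n_both", "nlp_only"])
        for r in rows:
            writer.writerow(
                [r.disease_key, r.n_nlp, r.n_icd, r.n_both, str(r.nlp_only).lower()]
            )
    (out_dir / "cohort_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
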