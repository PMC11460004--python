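"""Build a rare-disease vocabulary from small terminology tables.

Constructs a three-concept source table and matching metathesaurus-style
atom/semantic-type/definition tables in memory, links concepts to CUIs by
normalized exact matching under a disease semantic-type whitelist, and
prints the resulting searchable entries and ICD crosswalk.
"""

import tempfile
from pathlib import Path

from raretext import (
    build_crosswalk,
    build_vocabulary,
    link_concepts,
    read_atoms,
    read_concepts,
    read_definitions,
    read_icd_map,
    read_semantic_types,
)


def rrf(fields, width):
    row = [""] * width
    for i, v in fields.items():
        row[i] = v
    return "|".join(row) + "|"


tmp = Path(tempfile.mkdtemp())
(tmp / "concepts.tsv").write_text(
    "concept_id\tpreferred_label\tsynonyms\tcategory\n"
    "ORPHA:399\tHuntington disease\tHD|Huntington chorea\tdisease\n"
    "ORPHA:324\tFabry disease\tAnderson-Fabry disease\tdisease\n"
    "ORPHA:11890\tCongenital pulmonary airway malformation\t\tdisease\n"
)
(tmp / "MRCONSO.RRF").write_text(
    "\n".join(
        rrf({0: cui, 1: "ENG", 11: "SRC", 12: "PT", 14: s, 16: "N"}, 18)
        for cui, s in [
            ("C0020179", "Huntington Disease"),
            ("C0020179", "Huntington's chorea"),
            ("C0020179", "HD"),
            ("C0016167", "Fabry disease"),
            ("C0016167", "Angiokeratoma corporis diffusum"),
            ("C0158528", "Congenital pulmonary airway malformation"),
        ]
    )
    + "\n"
)
(tmp / "MRSTY.RRF").write_text(
    "\n".join(
        rrf({0: cui, 1: tui, 3: name}, 6)
        for cui, tui, name in [
            ("C0020179", "T047", "Disease or Syndrome"),
            ("C0016167", "T047", "Disease or Syndrome"),
            ("C0158528", "T019", "Congenital Abnormality"),
        ]
    )
    + "\n"
)
(tmp / "MRDEF.RRF").write_text(
    rrf({0: "C0016167", 4: "MSH", 5: "An X-linked lysosomal storage disease."}, 8)
    + "\n"
)
# the congenital-airway concept maps to ICD-10 Q33.0 (congenital cystic lung)
(tmp / "icd.tsv").write_text(
    "cui\ticd_version\ticd_code\nC0158528\t10\tQ33.0\nC0020179\t10\tG10\n"
)

concepts = read_concepts(tmp / "concepts.tsv")
atoms = read_atoms(tmp / "MRCONSO.RRF")
semtypes = read_semantic_types(tmp / "MRSTY.RRF")
links, unresolved = link_concepts(concepts, atoms, semtypes)
vocab = build_vocabulary(
    links, atoms, concepts, definitions=read_definitions(tmp / "MRDEF.RRF")
)
crosswalk = build_crosswalk(links, read_icd_map(tmp / "icd.tsv"))

print(f"{len(links)} concept-CUI links, {len(unresolved)} unresolved")
for entry in vocab.entries:
    print(f"  {entry.concept_id} -> {entry.cui}: "
          f"{sorted(entry.surface_terms)} acronyms={sorted(entry.acronym_terms)}")
for cw in crosswalk:
    print(f"  crosswalk {cw.concept_id}: icd10={sorted(cw.icd10_codes)} "
          f"({cw.resolution})")
# Each vocabulary entry carries every normalized synonym its CUI knows, so
# the matcher can recognise "Huntington's chorea" as ORPHA:399; dot-free
# ICD codes (Q330) let the cohort stage join MIMIC-style diagnosis tables.
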