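import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from raretext import (  # noqa: E402
    SourceConcept,
    SynthParams,
    generate_bundle,
)


# ---------------------------------------------------------------------------
# Terminology fixtures (RRF-dialect tables written to tmp files)
# ---------------------------------------------------------------------------

def mrconso_line(cui, string, lat="ENG", sab="SRC", tty="PT", suppress="N"):
    fields = [""] * 18
    fields[0], fields[1], fields[11], fields[12], fields[14], fields[16] = (
        cui, lat, sab, tty, string, suppress
    )
    return "|".join(fields) + "|"


def mrsty_line(cui, tui, sty="Disease or Syndrome"):
    return "|".join([cui, tui, "", sty, "", ""]) + "|"


def mrdef_line(cui, sab, definition):
    return "|".join([cui, "", "", "", sab, definition, "", ""]) + "|"


@pytest.fixture
def tiny_terminology(tmp_path):
    """Three concepts, four CUIs, one non-whitelisted distractor."""
    concepts = tmp_path / "concepts.tsv"
    concepts.write_text(
        "concept_id\tpreferred_label\tsynonyms\tcategory\n"
        "ORPHA:399\tHuntington disease\tHD|Huntington chorea\tdisease\n"
        "ORPHA:324\tFabry disease\tAnderson-Fabry disease\tdisease\n"
        "ORPHA:558\tMarfan syndrome\t\tdisease\n"
    )
    atoms = tmp_path / "MRCONSO.RRF"
    atoms.write_text(
        "\n".join(
            [
                mrconso_line("C0020179", "Huntington Disease"),
                mrconso_line("C0020179", "Huntington's chorea"),
                mrconso_line("C0020179", "HD"),
                mrconso_line("C0016167", "Fabry disease"),
                mrconso_line("C0016167", "Fabry Disease", suppress="O"),
                mrconso_line("C0024796", "Marfan syndrome"),
                mrconso_line("C0024796", "Marfan's syndrome"),
                # same string as a drug concept: must be excluded by whitelist
                mrconso_line("C0999999", "Fabry disease"),
                mrconso_line("C0021051", "immunodeficiency", lat="FRE"),
            ]
        )
        + "\n"
    )
    semtypes = tmp_path / "MRSTY.RRF"
    semtypes.write_text(
        "\n".join(
            [
                mrsty_line("C0020179", "T047"),
                mrsty_line("C0016167", "T047"),
                mrsty_line("C0024796", "T019", "Congenital Abnormality"),
                mrsty_line("C0999999", "T121", "Pharmacologic Substance"),
                mrsty_line("C0021051", "T047"),
            ]
        )
        + "\n"
    )
    defs = tmp_path / "MRDEF.RRF"
    defs.write_text(
        "\n".join(
            [
                mrdef_line("C0020179", "MSH", "A dominantly inherited disorder."),
                mrdef_line("C0020179", "NCI", "Alternative definition."),
                mrdef_line("C0016167", "MSH", "An X-linked lysosomal disorder."),
            ]
        )
        + "\n"
    )
    icd_map = tmp_path / "icd_map.tsv"
    icd_map.write_text(
        "cui\ticd_version\ticd_code\n"
        "C0020179\t10\tG10\n"
        "C0020179\t9\t333.4\n"
        "C0016167\t10\tE75.21\n"
    )
    return {
        "concepts": concepts,
        "atoms": atoms,
        "semtypes": semtypes,
        "defs": defs,
        "icd_map": icd_map,
    }


# ---------------------------------------------------------------------------
# Synthetic bundles (session-scoped: generation is deterministic)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(SynthParams(n_docs=40, seed=7))


@pytest.fixture(scope="session")
def default_bundle():
    """The default-condition study bundle: 400 documents, seed 0."""
    return generate_bundle(SynthParams(n_docs=400, seed=0))


@pytest.fixture(scope="session")
def hard_bundle():
    return generate_bundle(SynthParams(n_docs=400, seed=0, hard_mode=True))
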