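import pytest

from epimpra.design import LibraryDesign, build_class1, build_class2, build_class3, default_templates
from epimpra.motifs import default_motif_set


@pytest.fixture(scope="session")
def motif_set():
    return default_motif_set()


@pytest.fixture(scope="session")
def motifs8(motif_set):
    """The eight motifs retained after the poly-C dropout exclusion."""
    return [m for m in motif_set if m.name != "NR2F2"]


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def pair_design(motifs8, templates):
    """Class 1 + Class 2 library over the eight usable motifs."""
    elements = build_class1(motifs8, templates) + build_class2(motifs8, templates)
    return LibraryDesign(elements=elements, motif_set=motifs8, templates=templates)


@pytest.fixture(scope="session")
def quad_design(motif_set, templates):
    """Class 3 library over five motifs (five 4-subsets, small but nontrivial)."""
    motifs5 = motif_set[:5]
    return LibraryDesign(
        elements=build_class3(motifs5, templates), motif_set=motifs5, templates=templates
    )
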