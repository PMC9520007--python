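import pytest

from scpdyn.ontology import SCP, HorizontalInteraction, OntologyGraph
from scpdyn.synthetic import OntologySpec, synth_ontology


def build_toy_ontology() -> OntologyGraph:
    """Small hand-built ontology: one root, four level-2 SCPs, known interactions.

    Above a 0.5 top-fraction cutoff (threshold 0.8) the strong edges are
    A-B and B-C; A-C and C-D fall below.
    """
    scps = {
        "ROOT": SCP("ROOT", "root", 1, frozenset()),
        "A": SCP("A", "process A", 2, frozenset({"G1", "G2", "G3", "G4"}), frozenset({"ROOT"})),
        "B": SCP("B", "process B", 2, frozenset({"G5", "G6", "G7", "G8"}), frozenset({"ROOT"})),
        "C": SCP("C", "process C", 2, frozenset({"G9", "G10", "G11", "G12"}), frozenset({"ROOT"})),
        "D": SCP("D", "process D", 2, frozenset({"G13", "G14"}), frozenset({"ROOT"})),
    }
    interactions = (
        HorizontalInteraction("A", "B", 0.9),
        HorizontalInteraction("B", "C", 0.8),
        HorizontalInteraction("A", "C", 0.1),
        HorizontalInteraction("C", "D", 0.2),
    )
    background = frozenset(f"G{i}" for i in range(1, 31))
    return OntologyGraph(scps=scps, interactions=interactions, background=background)


@pytest.fixture
def toy_ontology() -> OntologyGraph:
    return build_toy_ontology()


@pytest.fixture(scope="session")
def synthetic_ontology():
    graph, truth = synth_ontology(OntologySpec(), seed=0)
    return graph, truth


@pytest.fixture
def ontology_files(tmp_path):
    """The toy ontology written out in the package's file dialects."""
    hierarchy = tmp_path / "hierarchy.tsv"
    hierarchy.write_text(
        "scp_id\tparent_id\tlevel\tname\n"
        "ROOT\t\t1\troot\n"
        "A\tROOT\t2\tprocess A\n"
        "B\tROOT\t2\tprocess B\n"
        "C\tROOT\t2\tprocess C\n"
        "D\tROOT\t2\tprocess D\n"
    )
    gmt = tmp_path / "annotations.gmt"
    gmt.write_text(
        "A\tprocess A\tG1\tG2\tG3\tG4\n"
        "B\tprocess B\tG5\tG6\tG7\tG8\n"
        "C\tprocess C\tG9\tG10\tG11\tG12\n"
        "D\tprocess D\tG13\tG14\n"
    )
    interactions = tmp_path / "interactions.tsv"
    interactions.write_text(
        "scp_a\tscp_b\tstrength\nA\tB\t0.9\nB\tC\t0.8\nA\tC\t0.1\nC\tD\t0.2\n"
    )
    background = tmp_path / "background.txt"
    background.write_text("\n".join(f"G{i}" for i in range(1, 31)) + "\n")
    return {
        "hierarchy": hierarchy,
        "annotations": gmt,
        "interactions": interactions,
        "background": background,
    }
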