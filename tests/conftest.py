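import pytest

from seedpath.annotation import AnnotationDatabase, GeneId, SubsystemAssignment


def make_db(rows, counts=None, aliases=None):
    """Build a database from (organism, gene, subsystem) triples."""
    return AnnotationDatabase(
        [SubsystemAssignment(org, GeneId(gene), ss) for org, gene, ss in rows],
        organism_gene_counts=counts,
        aliases=aliases,
    )


@pytest.fixture
def tiny_db():
    """Two organisms, a handful of genes, overlapping subsystem names."""
    rows = [
        ("eco", "eco.g1", "Flagellum"),
        ("eco", "eco.g1", "Chemotaxis"),
        ("eco", "eco.g2", "Flagellum"),
        ("eco", "eco.g3", "Glycolysis"),
        ("bsu", "bsu.g1", "Flagellum"),
        ("bsu", "bsu.g2", "Sporulation"),
    ]
    return make_db(rows, counts={"eco": 5, "bsu": 4}, aliases={"111": "eco.g1"})
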