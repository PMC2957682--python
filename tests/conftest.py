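import pytest

from mpabin.taxonomy import TaxonomyTree, build_tree


def tree_from_rows(rows) -> TaxonomyTree:
    """rows: (tax_id, parent_id, rank, name)"""
    return build_tree(rows)


# A lineage mirroring a real NCBI path, complete with non-canonical nodes
# (cellular organisms, a species complex, a strain), used by the taxonomy
# projection and the evaluation-tier tests.
BURKHOLDERIA_ROWS = [
    (1, 1, "no rank", "root"),
    (131567, 1, "no rank", "cellular organisms"),
    (2, 131567, "superkingdom", "Bacteria"),
    (1224, 2, "phylum", "Proteobacteria"),
    (28216, 1224, "class", "Betaproteobacteria"),
    (80840, 28216, "order", "Burkholderiales"),
    (119060, 80840, "family", "Burkholderiaceae"),
    (32008, 119060, "genus", "Burkholderia"),
    (87882, 32008, "no rank", "Burkholderia cepacia complex"),
    (152480, 87882, "species", "Burkholderia ambifaria"),
    (339670, 152480, "no rank", "Burkholderia ambifaria AMMD"),
    # an off-path sibling genus for Wrong-assignment tests
    (48736, 119060, "genus", "Ralstonia"),
    (305, 48736, "species", "Ralstonia solanacearum"),
    # a distant gammaproteobacterial branch
    (1236, 1224, "class", "Gammaproteobacteria"),
    (91347, 1236, "order", "Enterobacterales"),
    (543, 91347, "family", "Enterobacteriaceae"),
    (561, 543, "genus", "Escherichia"),
    (562, 561, "species", "Escherichia coli"),
]


@pytest.fixture(scope="session")
def burk_tree() -> TaxonomyTree:
    return tree_from_rows(BURKHOLDERIA_ROWS)


@pytest.fixture(scope="session")
def chain_tree() -> TaxonomyTree:
    # root -> A -> B
    return tree_from_rows([
        (1, 1, "no rank", "root"),
        (2, 1, "superkingdom", "A"),
        (3, 2, "phylum", "B"),
    ])
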