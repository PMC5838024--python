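import numpy as np
import pytest

from ambin.simulate import SampleDesign, default_design, generate_reference_db
from ambin.taxonomy import TaxonNode, TaxonomyTree


@pytest.fixture(scope="session")
def small_taxonomy():
    """Two phyla, hand-built: species s1/s2 congeneric, s3 in the other phylum."""
    nodes = [
        TaxonNode("root", "root", "root", None),
        TaxonNode("sk1", "Bacteria", "superkingdom", "root"),
        TaxonNode("p1", "PhylumA", "phylum", "sk1"),
        TaxonNode("p2", "PhylumB", "phylum", "sk1"),
        TaxonNode("c1", "ClassA", "class", "p1"),
        TaxonNode("c2", "ClassB", "class", "p2"),
        TaxonNode("o1", "OrderA", "order", "c1"),
        TaxonNode("o2", "OrderB", "order", "c2"),
        TaxonNode("f1", "FamilyA", "family", "o1"),
        TaxonNode("f2", "FamilyB", "family", "o2"),
        TaxonNode("g1", "GenusA", "genus", "f1"),
        TaxonNode("g2", "GenusB", "genus", "f2"),
        TaxonNode("s1", "GenusA alpha", "species", "g1"),
        TaxonNode("s2", "GenusA beta", "species", "g1"),
        TaxonNode("s3", "GenusB gamma", "species", "g2"),
    ]
    return TaxonomyTree(nodes)


@pytest.fixture(scope="session")
def reference_db():
    """Seed-pinned 10-species reference with one identical-fragment genus."""
    return generate_reference_db(
        10, species_per_genus=2, fragment_length=400, divergence=0.05,
        seed=101, n_identical_genera=1,
    )


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def two_group_design():
    return [
        SampleDesign(f"control_b{i}", "control", i) for i in range(1, 5)
    ] + [SampleDesign(f"Pb_b{i}", "Pb", i) for i in range(1, 5)]


def brute_force_lca(taxa, tree):
    """Independent oracle: intersect full root paths, take the deepest."""
    paths = [tree.path_to_root(t) for t in taxa]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    return max(common, key=lambda t: len(tree.path_to_root(t)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
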