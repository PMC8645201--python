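import random

import dendropy
import pytest

from introlens import parse_tree


@pytest.fixture
def cherry_tree():
    return parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def quartet_species_tree():
    # pectinate ((A,B),C),D with 1 coalescent unit between splits
    return parse_tree("(((A:1,B:1):1,C:2):1,D:3);")


def random_bifurcating_tree(n_tips: int, seed: int, labels=None) -> dendropy.Tree:
    """Random rooted bifurcating tree via recursive random splits (test oracle

    machinery; independent of the package's own tree generators)."""
    rng = random.Random(seed)
    labels = labels or [f"t{i}" for i in range(n_tips)]
    tns = dendropy.TaxonNamespace()

    def build(items):
        node = dendropy.Node()
        node.edge.length = rng.uniform(0.1, 1.0)
        if len(items) == 1:
            node.taxon = tns.require_taxon(label=items[0])
            return node
        k = rng.randint(1, len(items) - 1)
        shuffled = items[:]
        rng.shuffle(shuffled)
        node.add_child(build(shuffled[:k]))
        node.add_child(build(shuffled[k:]))
        return node

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = build(labels)
    tree.seed_node.edge.length = None
    return tree


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    from introlens import make_fixture_bundle

    out = tmp_path_factory.mktemp("bundle")
    paths = make_fixture_bundle(str(out), seed=11)
    return paths
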