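import numpy as np
import pytest

from ebwtax.cluster_detect import ClusterParams, detect_alpha_clusters
from ebwtax.ebwt_core import build_index, make_collection
from ebwtax.fixtures import running_example
from ebwtax.taxonomy import TaxonomyNode, TaxonomyTree


@pytest.fixture(scope="session")
def worked_example():
    """(collection, expected, index) for the three-sequence worked example."""
    collection, expected = running_example()
    return collection, expected, build_index(collection)


@pytest.fixture(scope="session")
def worked_clusters(worked_example):
    _, expected, index = worked_example
    return detect_alpha_clusters(index, ClusterParams(expected["alpha"]))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toy_tree():
    """Two phyla; genus 10 holds species 20+21, genus 11 holds 22; genus 12 in phylum 3.

    Genomes: gA,gB -> species 20; gC -> 21; gD -> 22; gE -> 23 (other phylum).
    """
    nodes = [
        TaxonomyNode(1, 1, "no_rank", "root"),
        TaxonomyNode(2, 1, "phylum", "P1"),
        TaxonomyNode(3, 1, "phylum", "P2"),
        TaxonomyNode(10, 2, "genus", "G1"),
        TaxonomyNode(11, 2, "genus", "G2"),
        TaxonomyNode(12, 3, "genus", "G3"),
        TaxonomyNode(20, 10, "species", "sp20"),
        TaxonomyNode(21, 10, "species", "sp21"),
        TaxonomyNode(22, 11, "species", "sp22"),
        TaxonomyNode(23, 12, "species", "sp23"),
        TaxonomyNode(30, 20, "genome", "gA"),
        TaxonomyNode(31, 20, "genome", "gB"),
        TaxonomyNode(32, 21, "genome", "gC"),
        TaxonomyNode(33, 22, "genome", "gD"),
        TaxonomyNode(34, 23, "genome", "gE"),
    ]
    tree = TaxonomyTree(nodes)
    gmap = {"gA": 30, "gB": 31, "gC": 32, "gD": 33, "gE": 34}
    return tree, gmap
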