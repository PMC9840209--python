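import numpy as np
import pandas as pd
import pytest

import phylograd as pg


@pytest.fixture(scope="session")
def toy_distance():
    """Three-species patristic matrix from the tree ((A:1,B:1):1,C:2)."""
    return pd.DataFrame(
        [[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]],
        index=list("ABC"), columns=list("ABC"))


@pytest.fixture(scope="session")
def small_study():
    """One medium synthetic study shared by read-only tests."""
    params = pg.AssemblyParams(n_species=150)
    return pg.simulate_study(params=params, n_genera=25, seed=42)


def random_tree(n_tips: int, seed: int):
    """Random ultrametric tree with Genus_species labels for oracle tests."""
    return pg.simulate_tree(n_tips, 1.0, 0.0,
                            n_genera=max(2, n_tips // 3), seed=seed)


def brute_force_patristic(tree) -> pd.DataFrame:
    """Independent oracle: patristic distances by graph shortest paths."""
    import networkx as nx

    g = nx.Graph()
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            g.add_edge(id(node.parent_node), id(node), weight=node.edge.length)
    leaves = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}
    labels = sorted(leaves)
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        lengths = nx.single_source_dijkstra_path_length(g, leaves[a])
        for b in labels[i + 1:]:
            out.loc[a, b] = out.loc[b, a] = lengths[leaves[b]]
    return out
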