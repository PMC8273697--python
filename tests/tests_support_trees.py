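"""Shared tree helpers used by the phylo and acceptance suites."""

import itertools

import numpy as np

from pkat.phylo import DistanceMatrix, Node, PhyloTree


def random_tree(rng, n_taxa):
    """Random binary topology with positive branch lengths."""
    nodes = [Node(name=f"T{i}", length=float(rng.uniform(0.5, 3.0)))
             for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        child_j = nodes.pop(j)
        child_i = nodes.pop(i)
        nodes.append(Node(children=[child_i, child_j],
                          length=float(rng.uniform(0.5, 3.0))))
    return PhyloTree(Node(children=nodes))


def path_distances(tree):
    """Leaf-to-leaf path length matrix via per-leaf root paths."""
    paths = {}

    def walk(node, acc):
        acc = acc + [node]
        if node.is_leaf:
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, [])
    labels = sorted(paths)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pa, pb = paths[labels[i]], paths[labels[j]]
        shared = sum(1 for x, y in zip(pa, pb) if x is y)
        dist = sum(x.length for x in pa[shared:]) + \
            sum(y.length for y in pb[shared:])
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(tuple(labels), d)
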