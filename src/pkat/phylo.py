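"""Distance-based phylogenies: p-distance, neighbor joining, bootstrap
support and monophyly checks.

Trees are plain nested nodes; an unrooted tree is represented with a
trifurcating root. Tie-breaks are lexicographic on leaf labels so every
operation is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

GAP = "-"


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

@dataclass
class Node:
    name: str = ""
    length: float = 0.0
    support: int | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


class PhyloTree:
    """A (possibly unrooted) tree with branch lengths and optional
    per-internal-branch bootstrap support in [0, 100]."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        names = root.leaf_names()
        if len(set(names)) != len(names):
            raise ValueError("leaf labels must be unique")

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        def render(node: Node, top: bool) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(render(c, False) for c in node.children)
                label = "" if node.support is None else str(int(node.support))
                body = f"({inner}){label}"
            if top:
                return body
            length = f"{node.length:g}"
            return f"{body}:{length}"

        return render(self.root, True) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        import dendropy

        dtree = dendropy.Tree.get(data=text, schema="newick")

        def convert(dnode) -> Node:
            node = Node()
            if dnode.is_leaf():
                node.name = dnode.taxon.label.replace(" ", "_") if dnode.taxon else ""
            else:
                if dnode.label is not None and dnode.label != "":
                    try:
                        node.support = int(float(dnode.label))
                    except ValueError:
                        pass
                node.children = [convert(c) for c in dnode.child_nodes()]
            node.length = float(dnode.edge.length or 0.0)
            return node

        return cls(convert(dtree.seed_node), rooted=len(dtree.seed_node.child_nodes()) == 2)

    # -- topology queries ---------------------------------------------------

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of every node (including leaves and root)."""
        return [frozenset(n.leaf_names()) for n in self.root.walk()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits of the unrooted topology, each encoded as the
        side that does not contain the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.root.walk():
            side = frozenset(node.leaf_names())
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(side)
        return splits

    def rerooted_at(self, outgroup: str) -> "PhyloTree":
        """Return a rooted copy with ``outgroup`` as one of the root's two
        children (rooted on the outgroup's terminal edge, split midway)."""
        if outgroup not in self.leaf_names():
            raise ValueError(f"outgroup {outgroup!r} is not a leaf")

        def copy(node: Node) -> Node:
            return Node(node.name, node.length, node.support,
                        [copy(c) for c in node.children])

        root = copy(self.root)
        parent: dict[int, Node | None] = {id(root): None}
        target = None
        for node in root.walk():
            for c in node.children:
                parent[id(c)] = node
            if node.is_leaf and node.name == outgroup:
                target = node
        assert target is not None

        half = target.length / 2.0
        target.length = half
        anchor = parent[id(target)]
        anchor.children.remove(target)

        # Reverse every edge on the path anchor -> ... -> old root, keeping
        # each edge's original length.
        path: list[Node] = []
        node: Node | None = anchor
        while node is not None:
            path.append(node)
            node = parent[id(node)]
        orig_len = [n.length for n in path]
        for i in range(1, len(path)):
            path[i].children.remove(path[i - 1])
            path[i - 1].children.append(path[i])
            path[i].length = orig_len[i - 1]
            path[i].support = None
        anchor.length = half
        anchor.support = None

        new_root = Node(children=[target, anchor])

        def suppress_unifurcations(n: Node) -> None:
            for c in list(n.children):
                suppress_unifurcations(c)
            for c in list(n.children):
                if len(c.children) == 1:
                    only = c.children[0]
                    only.length += c.length
                    n.children[n.children.index(c)] = only
        suppress_unifurcations(new_root)
        return PhyloTree(new_root, rooted=True)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.isfinite(self.d).all() or (self.d < 0).any():
            raise ValueError("distances must be finite and non-negative")


def _rows_from(msa) -> list[tuple[str, str]]:
    rows = []
    for item in msa:
        if isinstance(item, tuple):
            rows.append((item[0], item[1].upper()))
        else:  # SeqRecord-like
            rows.append((item.id, item.seq.upper()))
    return rows


def pdistance(msa: Iterable) -> DistanceMatrix:
    """Pairwise p-distance with pairwise gap deletion.

    ``msa`` is an iterable of ``(label, gapped_sequence)`` pairs or
    record objects with ``id``/``seq``. All rows must be equal length.
    """
    rows = _rows_from(msa)
    if len(rows) < 2:
        raise ValueError("need at least 2 rows")
    length = len(rows[0][1])
    if any(len(s) != length for _, s in rows):
        raise ValueError("alignment rows must have equal length")
    labels = tuple(lbl for lbl, _ in rows)
    arr = np.array([list(s) for _, s in rows])
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != GAP) & (arr[j] != GAP)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            d[i, j] = d[j, i] = float((arr[i][ok] != arr[j][ok]).sum()) / m
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Classic Q-criterion neighbor joining.

    Deterministic: ties in Q are broken by the lexicographically smallest
    (cluster, cluster) label pair, where a cluster is labelled by its
    smallest member leaf. Negative branch lengths are clamped to zero with
    a warning. The result is unrooted (trifurcating root) for >= 3 taxa.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("need at least 3 taxa")
    d = dm.d.copy()
    nodes: list[Node] = [Node(name=lbl) for lbl in dm.labels]
    tags: list[str] = list(dm.labels)  # smallest leaf label per cluster

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                warnings.warn(f"negative branch length {x:.4g} clamped to 0")
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((tags[i], tags[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = clamp(d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2)))
        lj = clamp(d[i, j] - (d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))))
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        new = Node(children=[child_i, child_j])
        new_tag = min(tags[i], tags[j])
        dnew = np.array([
            (d[i, k] + d[j, k] - d[i, j]) / 2.0
            for k in range(n) if k not in (i, j)
        ])
        keep = [k for k in range(n) if k not in (i, j)]
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = dnew
        d[:-1, -1] = dnew
        nodes = [nodes[k] for k in keep] + [new]
        tags = [tags[k] for k in keep] + [new_tag]

    # Terminal three-point join.
    (a, b, c) = nodes
    da_b, da_c, db_c = d[0, 1], d[0, 2], d[1, 2]
    a.length = clamp((da_b + da_c - db_c) / 2.0)
    b.length = clamp((da_b + db_c - da_c) / 2.0)
    c.length = clamp((da_c + db_c - da_b) / 2.0)
    root = Node(children=[a, b, c])
    return PhyloTree(root, rooted=False)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(msa: Iterable, n_replicates: int, seed: int,
                      outgroup: str) -> PhyloTree:
    """NJ tree with bootstrap support, rooted at ``outgroup`` for reporting.

    Columns are resampled with replacement; support on each internal branch
    is the percentage of replicate trees containing the same bipartition.
    """
    rows = _rows_from(msa)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels = [lbl for lbl, _ in rows]
    if outgroup not in labels:
        raise ValueError(f"outgroup {outgroup!r} not among alignment rows")
    length = len(rows[0][1])
    arr = np.array([list(s) for _, s in rows])

    base = nj_tree(pdistance(rows))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in base.bipartitions()}

    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        rep_rows = [(lbl, "".join(arr[i, cols])) for i, lbl in enumerate(labels)]
        rep = nj_tree(pdistance(rep_rows))
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1

    rooted = base.rerooted_at(outgroup)
    all_leaves = frozenset(labels)
    anchor = min(all_leaves)
    for node in rooted.root.walk():
        if node.is_leaf or node is rooted.root:
            continue
        side = frozenset(node.leaf_names())
        canon = all_leaves - side if anchor in side else side
        if 2 <= len(canon) <= len(all_leaves) - 2:
            node.support = round(100.0 * counts.get(canon, 0) / n_replicates)
    return rooted


def monophyly_check(tree: PhyloTree, group: Iterable[str]) -> bool:
    """True iff some clade of the (rooted) tree contains exactly ``group``."""
    group = frozenset(group)
    leaves = frozenset(tree.leaf_names())
    unknown = group - leaves
    if unknown:
        raise ValueError(f"unknown leaf labels: {sorted(unknown)}")
    return group in set(tree.clades())
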