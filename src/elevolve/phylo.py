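"""Rooted time-calibrated phylogenies: Newick I/O, covariance, pruning.

Branch lengths are in millions of years (mya) throughout the package; every
rate parameter downstream (Markov switch rates, Brownian variance, OU pull
strength) is therefore "per mya", and phylogenetic half-lives come out in mya.

The :class:`Tree` is a compact array representation: nodes are integers in
preorder (every parent index precedes its children; node 0 is the root), each
non-root node carries the length of the edge above it, and tips carry species
labels.  A tree may additionally carry a ``root_length`` — a stem edge shared
by all tips, which arises when pruning leaves the original root with a single
descendant lineage; it shifts the whole covariance matrix by a constant so
that root-to-tip distances of retained tips are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "PhyloCovariance",
    "NewickError",
    "parse_newick",
    "write_newick",
    "phylo_covariance",
    "prune",
    "is_ultrametric",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


@dataclass(frozen=True)
class Tree:
    """Rooted tree with branch lengths in mya.

    Attributes
    ----------
    parent : (n_nodes,) int array; ``parent[0] == -1`` (root), and
        ``parent[i] < i`` for all other nodes (preorder).
    lengths : (n_nodes,) float array; ``lengths[i]`` is the edge above node
        ``i`` (``lengths[0]`` is 0 and unused).
    labels : tuple of str or None per node; tips are exactly the labelled
        nodes with no children.
    root_length : shared stem above the root (0 for freshly parsed trees).
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: tuple
    root_length: float = 0.0

    def __post_init__(self):
        parent = np.asarray(self.parent, dtype=int)
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "lengths", lengths)
        if parent[0] != -1 or np.any(parent[1:] >= np.arange(1, len(parent))):
            raise NewickError("nodes must be in preorder with node 0 the root")
        if np.any(lengths < 0):
            raise NewickError("negative branch length")
        children = [[] for _ in range(len(parent))]
        for i in range(1, len(parent)):
            children[parent[i]].append(i)
        object.__setattr__(self, "_children", tuple(tuple(c) for c in children))
        tips = tuple(i for i in range(len(parent)) if not children[i])
        object.__setattr__(self, "_tips", tips)
        labs = [self.labels[i] for i in tips]
        if any(l is None for l in labs):
            raise NewickError("unlabelled tip")
        if len(set(labs)) != len(labs):
            dupes = sorted({l for l in labs if labs.count(l) > 1})
            raise NewickError(f"duplicate tip labels: {dupes}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def children(self, node: int) -> tuple:
        return self._children[node]

    @property
    def tips(self) -> tuple:
        """Tip node ids in preorder (= Newick order)."""
        return self._tips

    @property
    def tip_labels(self) -> tuple:
        return tuple(self.labels[i] for i in self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def depths(self) -> np.ndarray:
        """Root-to-node distance for every node, including ``root_length``."""
        d = np.empty(self.n_nodes)
        d[0] = self.root_length
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.lengths[i]
        return d

    @property
    def height(self) -> float:
        """Maximum root-to-tip distance."""
        return float(self.depths()[list(self._tips)].max())

    def tip_index(self) -> dict:
        """Map species label -> position in ``tip_labels`` order."""
        return {lab: k for k, lab in enumerate(self.tip_labels)}

    def path_to_tip(self, tip: int) -> list:
        """Edge node-ids from the root down to ``tip`` (inclusive)."""
        path = []
        node = tip
        while node != 0:
            path.append(node)
            node = self.parent[node]
        return path[::-1]


@dataclass(frozen=True)
class PhyloCovariance:
    """Shared-time matrix C: C_ij = root-to-MRCA(i,j) path length (mya)."""

    species: tuple
    matrix: np.ndarray

    @property
    def tip_heights(self) -> np.ndarray:
        return np.diag(self.matrix).copy()


# -- Newick I/O (dendropy-backed) ------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    root = dtree.seed_node
    parent, lengths, labels = [], [], []
    index = {}

    def visit(node, parent_idx):
        idx = len(parent)
        index[id(node)] = idx
        parent.append(parent_idx)
        if parent_idx == -1:
            lengths.append(0.0)
        else:
            if node.edge.length is None:
                raise NewickError(
                    f"missing branch length above node "
                    f"{node.taxon.label if node.taxon else '(internal)'}"
                )
            lengths.append(float(node.edge.length))
        lab = None
        if node.taxon is not None:
            lab = node.taxon.label
        elif node.label is not None and node.is_leaf():
            lab = node.label
        labels.append(lab)
        for ch in node.child_nodes():
            visit(ch, idx)

    visit(root, -1)
    tree = Tree(np.array(parent), np.array(lengths), tuple(labels))
    return _collapse_zero_internal(tree)


def _collapse_zero_internal(tree: Tree) -> Tree:
    """Collapse zero-length internal edges into the parent (avoids singular
    covariances); zero-length terminal edges are kept."""
    drop = [
        i
        for i in range(1, tree.n_nodes)
        if tree.lengths[i] == 0.0 and tree.children(i)
    ]
    if not drop:
        return tree
    # reattach children of each dropped node to its parent
    new_parent = tree.parent.copy()
    for i in drop:
        for j in range(tree.n_nodes):
            if new_parent[j] == i:
                new_parent[j] = new_parent[i]
    keep = [i for i in range(tree.n_nodes) if i not in set(drop)]
    remap = {old: new for new, old in enumerate(keep)}
    parent = np.array([-1 if tree.parent[i] == -1 else remap[new_parent[i]] for i in keep])
    lengths = tree.lengths[keep]
    labels = tuple(tree.labels[i] for i in keep)
    return Tree(parent, lengths, labels, tree.root_length)


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Quoted labels and ``[...]`` comments are accepted and stripped;
    polytomies are allowed.  Missing branch lengths, duplicate tip labels or
    malformed syntax raise :class:`NewickError` naming the problem.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: Tree) -> str:
    """Serialize a :class:`Tree` back to Newick (lengths at full precision)."""

    def fmt_label(lab: str) -> str:
        if any(c in lab for c in " ()[]:;,'"):
            return "'" + lab.replace("'", "''") + "'"
        return lab

    def emit(node: int) -> str:
        ch = tree.children(node)
        if ch:
            inner = ",".join(emit(c) for c in ch)
            s = f"({inner})"
        else:
            s = fmt_label(tree.labels[node])
        if node != 0:
            s += f":{tree.lengths[node]:.17g}"
        else:
            s += f":{tree.root_length:.17g}" if tree.root_length else ":0"
        return s

    return emit(0) + ";"


def read_newick(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick_file(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# -- covariance ------------------------------------------------------------

def phylo_covariance(tree: Tree) -> PhyloCovariance:
    """Shared evolutionary time between every pair of tips.

    ``C[i, j]`` is the summed branch length from the root down to the most
    recent common ancestor of tips i and j; the diagonal holds root-to-tip
    distances.  Rows/columns follow ``tree.tip_labels`` order.
    """
    depths = tree.depths()
    tips = tree.tips
    pos = {t: k for k, t in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))
    # postorder accumulation of tip sets; cross-subtree pairs share depth[u]
    tipsets = {}
    for node in range(tree.n_nodes - 1, -1, -1):
        ch = tree.children(node)
        if not ch:
            tipsets[node] = [pos[node]]
            C[pos[node], pos[node]] = depths[node]
            continue
        sets = [tipsets.pop(c) for c in ch]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                for i in sets[a]:
                    for j in sets[b]:
                        C[i, j] = C[j, i] = depths[node]
        merged = [i for s in sets for i in s]
        tipsets[node] = merged
    return PhyloCovariance(tree.tip_labels, C)


# -- pruning ---------------------------------------------------------------

@dataclass
class PruneResult:
    """Pruned tree plus the provenance of each retained edge.

    ``edge_sources[new_node]`` lists the original edge node-ids (ordered from
    rootward to tipward) whose lengths were concatenated into the new edge —
    needed to carry stochastic character maps through a prune.
    """

    tree: Tree
    edge_sources: dict = field(default_factory=dict)
    stem_sources: tuple = ()


def prune_with_sources(tree: Tree, keep) -> PruneResult:
    keep = set(keep)
    labels = set(tree.tip_labels)
    unknown = sorted(keep - labels)
    if unknown:
        raise ValueError(f"unknown species in keep set: {unknown}")
    if len(keep) < 2:
        raise ValueError("need at least 2 species to keep")

    keep_nodes = set()
    for t in tree.tips:
        if tree.labels[t] in keep:
            node = t
            while node != -1 and node not in keep_nodes:
                keep_nodes.add(node)
                node = tree.parent[node]

    # children within the induced tree
    kept_children = {n: [c for c in tree.children(n) if c in keep_nodes] for n in keep_nodes}

    # walk down from the old root through any unifurcating chain: those edge
    # lengths become the new stem (root_length), preserving tip depths
    node = 0
    stem = tree.root_length
    stem_sources = []
    while len(kept_children[node]) == 1 and tree.children(node):
        child = kept_children[node][0]
        if not tree.children(child):  # child is a tip; stop, keep node as root
            break
        stem += tree.lengths[child]
        stem_sources.append(child)
        node = child
    new_root_old = node

    parent_out, lengths_out, labels_out = [-1], [0.0], [tree.labels[new_root_old]]
    sources = {}

    def build(old_node: int, new_parent: int):
        for child in kept_children[old_node]:
            # follow chains of unifurcations, summing lengths
            length = tree.lengths[child]
            chain = [child]
            cur = child
            while len(kept_children[cur]) == 1 and tree.children(cur):
                nxt = kept_children[cur][0]
                length += tree.lengths[nxt]
                chain.append(nxt)
                cur = nxt
            idx = len(parent_out)
            parent_out.append(new_parent)
            lengths_out.append(length)
            labels_out.append(tree.labels[cur])
            sources[idx] = chain
            build(cur, idx)

    build(new_root_old, 0)
    out = Tree(np.array(parent_out), np.array(lengths_out), tuple(labels_out), stem)
    return PruneResult(out, sources, tuple(stem_sources))


def prune(tree: Tree, keep) -> Tree:
    """Restrict the tree to ``keep`` tips, suppressing unifurcations.

    Branch lengths of suppressed degree-2 nodes are summed so root-to-tip
    distances of retained tips are unchanged; the covariance of the pruned
    tree equals the corresponding submatrix of the original covariance.
    """
    return prune_with_sources(tree, keep).tree


def is_ultrametric(tree: Tree, tol: float = 1e-8) -> bool:
    """True iff all root-to-tip distances agree within ``tol`` * max depth."""
    d = tree.depths()[list(tree.tips)]
    return bool(d.max() - d.min() <= tol * max(d.max(), 1e-300))
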