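"""Ultrametric phylogeny handling: Newick I/O, branching times, clades, tip grafting.

Trees are rooted, binary, time-calibrated (branch lengths in Myr) and ultrametric:
every root-to-tip path has the same length up to a relative tolerance.  This is the
substrate assumed by every likelihood in the package; malformed trees are rejected on
read rather than repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "NewickParseError",
    "PolytomyError",
    "NonUltrametricError",
    "DuplicateLabelError",
    "UltrametricTree",
    "CladeDefinition",
    "TreeSet",
    "read_newick",
    "write_newick",
    "read_newick_list",
    "read_nexus_trees",
    "branching_times",
    "extract_clade",
    "graft_tip",
]

#: relative tolerance (fraction of tree depth) for the ultrametricity check;
#: BEAST-exported trees carry rounding noise of this order.
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Base class for tree construction/validation failures."""


class NewickParseError(TreeError):
    """The Newick/NEXUS text could not be parsed or lacks branch lengths."""


class PolytomyError(TreeError):
    """An internal node has more than two children (or a unifurcation)."""


class NonUltrametricError(TreeError):
    """Root-to-tip path lengths disagree beyond tolerance."""


class DuplicateLabelError(TreeError):
    """Two tips share a label."""


class UltrametricTree:
    """Rooted binary ultrametric time tree stored as parallel node arrays.

    Nodes are indexed 0..n_nodes-1.  ``parent[i]`` is -1 for the root;
    ``length[i]`` is the branch length above node ``i`` (0 for the root);
    ``label[i]`` is the tip label (None for internal nodes).
    """

    def __init__(
        self,
        parent: Sequence[int],
        length: Sequence[float],
        label: Sequence[str | None],
        validate: bool = True,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.label = list(label)
        n = len(self.parent)
        if not (len(self.length) == n and len(self.label) == n):
            raise TreeError("node arrays have inconsistent lengths")
        self.children: list[list[int]] = [[] for _ in range(n)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                self.children[p].append(i)
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._depth_cache: np.ndarray | None = None
        if validate:
            self._validate()

    # -- construction helpers ------------------------------------------------

    def _validate(self) -> None:
        for i, ch in enumerate(self.children):
            if len(ch) == 0:
                if self.label[i] is None:
                    raise TreeError(f"tip node {i} has no label")
            elif len(ch) != 2:
                raise PolytomyError(
                    f"node {i} has {len(ch)} children; only binary trees are supported"
                )
        if np.any(self.length < 0):
            raise TreeError("negative branch length")
        labels = [self.label[i] for i in self.tip_indices()]
        if len(set(labels)) != len(labels):
            seen, dups = set(), set()
            for lb in labels:
                (dups if lb in seen else seen).add(lb)
            raise DuplicateLabelError(f"duplicate tip labels: {sorted(dups)}")
        depths = self.node_depths()
        tip_d = depths[list(self.tip_indices())]
        scale = float(tip_d.max())
        if scale > 0 and (tip_d.max() - tip_d.min()) > ULTRAMETRIC_RTOL * scale:
            raise NonUltrametricError(
                f"root-to-tip depths span [{tip_d.min():.9g}, {tip_d.max():.9g}]"
            )

    # -- basic queries -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return sum(1 for c in self.children if not c)

    def tip_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.children) if not c]

    def tip_labels(self) -> list[str]:
        return [self.label[i] for i in self.tip_indices()]

    def node_depths(self) -> np.ndarray:
        """Distance from the root to each node."""
        if self._depth_cache is None:
            depth = np.zeros(self.n_nodes)
            for i in self.preorder():
                if self.parent[i] >= 0:
                    depth[i] = depth[self.parent[i]] + self.length[i]
            self._depth_cache = depth
        return self._depth_cache

    def node_ages(self) -> np.ndarray:
        """Age (Myr before present) of each node; tips are ~0."""
        depth = self.node_depths()
        return float(depth[self.tip_indices()].max()) - depth

    @property
    def crown_age(self) -> float:
        return float(self.node_ages()[self.root])

    def total_branch_length(self) -> float:
        return float(self.length.sum() - self.length[self.root])

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            i = stack.pop()
            yield i
            stack.extend(reversed(self.children[i]))

    def postorder(self) -> Iterator[int]:
        return reversed(list(self.preorder()))

    def mrca(self, labels: Iterable[str]) -> int:
        want = set(labels)
        tips = {self.label[i] for i in self.tip_indices()}
        missing = want - tips
        if missing:
            raise TreeError(f"unknown tip label(s): {sorted(missing)}")
        # count of wanted tips below each node, postorder
        count = np.zeros(self.n_nodes, dtype=int)
        for i in self.postorder():
            if not self.children[i]:
                count[i] = 1 if self.label[i] in want else 0
            else:
                count[i] = sum(count[c] for c in self.children[i])
        target = len(want)
        # deepest node containing all wanted tips
        node = self.root
        while True:
            nxt = [c for c in self.children[node] if count[c] == target]
            if not nxt:
                return node
            node = nxt[0]

    def subtree_nodes(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self.children[i])
        return out

    def copy(self) -> "UltrametricTree":
        return UltrametricTree(
            self.parent.copy(), self.length.copy(), list(self.label), validate=False
        )

    # -- conversion ----------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "UltrametricTree":
        dtree = dtree.clone(depth=1)
        if dtree.seed_node is None:
            raise NewickParseError("empty tree")
        # collapse a unifurcating seed node (dendropy artifact for rooted reads)
        while len(dtree.seed_node.child_nodes()) == 1:
            child = dtree.seed_node.child_nodes()[0]
            child.parent_node = None
            dtree.seed_node = child
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, length, label = [], [], []
        for nd in nodes:
            if nd.parent_node is None:
                parent.append(-1)
                length.append(0.0)
            else:
                parent.append(index[id(nd.parent_node)])
                if nd.edge.length is None:
                    raise NewickParseError("branch length missing on an edge")
                length.append(float(nd.edge.length))
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise NewickParseError("unlabelled tip")
                label.append(str(nd.taxon.label))
            else:
                label.append(None)
        return cls(parent, length, label)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = {}
        for i in self.preorder():
            if i == self.root:
                dnodes[i] = dtree.seed_node
            else:
                dnodes[i] = dnodes[int(self.parent[i])].new_child()
                dnodes[i].edge.length = float(self.length[i])
            if not self.children[i]:
                dnodes[i].taxon = taxa.new_taxon(self.label[i])
        return dtree

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<UltrametricTree n_tips={self.n_tips} crown_age={self.crown_age:.4g}>"


@dataclass
class CladeDefinition:
    """A named clade addressed as the MRCA of a set of tip labels."""

    name: str
    tips: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.tips = frozenset(self.tips)
        if not self.tips:
            raise TreeError(f"clade {self.name!r} has an empty tip set")

    def resolve(self, tree: UltrametricTree) -> int:
        """Index of the clade's MRCA node in *tree*."""
        return tree.mrca(self.tips)

    def member_tips(self, tree: UltrametricTree) -> set[str]:
        """All tip labels descending from the clade's MRCA (may exceed ``tips``)."""
        node = self.resolve(tree)
        return {
            tree.label[i] for i in tree.subtree_nodes(node) if not tree.children[i]
        }


class TreeSet:
    """Ordered collection of trees over one tip-label universe (posterior sample)."""

    def __init__(self, trees: Sequence[UltrametricTree]):
        if not trees:
            raise TreeError("TreeSet requires at least one tree")
        universe = set(trees[0].tip_labels())
        for k, t in enumerate(trees[1:], start=1):
            if set(t.tip_labels()) != universe:
                raise TreeError(f"tree {k} has a different tip-label set")
        self.trees = list(trees)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[UltrametricTree]:
        return iter(self.trees)

    def __getitem__(self, i) -> UltrametricTree:
        return self.trees[i]


# -- I/O ---------------------------------------------------------------------


def _get_dendropy_tree(text: str, schema: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=text,
            schema=schema,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except TreeError:
        raise
    except Exception as exc:
        if "uplicate tax" in str(exc):
            raise DuplicateLabelError(str(exc)) from exc
        raise NewickParseError(f"could not parse {schema}: {exc}") from exc


def read_newick(text: str) -> UltrametricTree:
    """Parse a single Newick string into a validated :class:`UltrametricTree`.

    Quoted labels, scientific-notation branch lengths and ``[...]`` comments are
    accepted (comments are skipped).  Polytomies, duplicate tip labels, missing
    branch lengths and non-ultrametric trees each raise a distinct error.
    """
    return UltrametricTree.from_dendropy(_get_dendropy_tree(text, "newick"))


def read_newick_list(text: str) -> TreeSet:
    """Parse a multi-tree Newick document (one tree per statement) into a TreeSet."""
    try:
        dlist = dendropy.TreeList.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise NewickParseError(f"could not parse newick list: {exc}") from exc
    return TreeSet([UltrametricTree.from_dendropy(t) for t in dlist])


def read_nexus_trees(text: str) -> TreeSet:
    """Extract the translated trees of a NEXUS trees block (annotations ignored)."""
    try:
        dlist = dendropy.TreeList.get(
            data=text, schema="nexus", preserve_underscores=True
        )
    except Exception as exc:
        raise NewickParseError(f"could not parse nexus: {exc}") from exc
    return TreeSet([UltrametricTree.from_dendropy(t) for t in dlist])


def write_newick(tree: UltrametricTree, precision: int = 12) -> str:
    """Serialize to a Newick string with terminating semicolon."""

    fmt = f"%.{precision}g"

    def render(i: int) -> str:
        if not tree.children[i]:
            core = _quote(tree.label[i])
        else:
            core = "(" + ",".join(render(c) for c in tree.children[i]) + ")"
        if i == tree.root:
            return core
        return core + ":" + (fmt % tree.length[i])

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * tree.n_nodes + 100))
    try:
        return render(tree.root) + ";"
    finally:
        sys.setrecursionlimit(old)


def _quote(label: str) -> str:
    if any(c in label for c in "()[]{}/\\,;:=*'\"`+<> \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


# -- operations --------------------------------------------------------------


def branching_times(tree: UltrametricTree) -> np.ndarray:
    """Internal-node ages in Myr before present, descending; length n_tips - 1."""
    ages = tree.node_ages()
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    return np.sort(ages[internal])[::-1]


def extract_clade(tree: UltrametricTree, clade: CladeDefinition) -> UltrametricTree:
    """MRCA-rooted subtree containing *all* descendants of the clade's MRCA."""
    node = clade.resolve(tree)
    keep = tree.subtree_nodes(node)
    remap = {old: new for new, old in enumerate(keep)}
    parent = [
        -1 if old == node else remap[int(tree.parent[old])] for old in keep
    ]
    length = [0.0 if old == node else float(tree.length[old]) for old in keep]
    label = [tree.label[old] for old in keep]
    return UltrametricTree(parent, length, label)


def graft_tip(
    tree: UltrametricTree,
    clade: CladeDefinition,
    label: str,
    rng: np.random.Generator | int,
) -> UltrametricTree:
    """Attach a new tip at a random position inside a clade, keeping ultrametricity.

    The attachment branch is drawn uniformly among the branches of the clade's
    MRCA subtree (stem excluded) and the attachment height uniformly along that
    branch; the new pendant reaches the present.  Existing node ages are untouched.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if label in set(tree.tip_labels()):
        raise DuplicateLabelError(f"tip label {label!r} already present")
    mrca = clade.resolve(tree)
    candidates = [i for i in tree.subtree_nodes(mrca) if i != mrca]
    if not candidates:
        raise TreeError("clade subtree has no branches to graft onto")
    target = int(candidates[rng.integers(len(candidates))])
    frac = float(rng.uniform())  # position along the branch, from child end
    ages = tree.node_ages()
    attach_age = ages[target] + frac * float(tree.length[target])

    parent = list(tree.parent)
    length = list(tree.length)
    labels = list(tree.label)
    new_internal = len(parent)
    new_tip = new_internal + 1
    old_parent = int(tree.parent[target])
    # new internal node splits the target branch at attach_age
    parent.append(old_parent)
    length.append(float(ages[old_parent] - attach_age))
    labels.append(None)
    parent.append(new_internal)
    length.append(float(attach_age))
    labels.append(label)
    parent[target] = new_internal
    length[target] = float(attach_age - ages[target])
    return UltrametricTree(parent, length, labels)
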