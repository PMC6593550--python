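"""Rooted timetrees: Newick I/O, pruning, time spans, distances, subsampling.

A :class:`TimeTree` is a rooted tree whose branch lengths are either
durations (million years, for timetrees) or expected substitutions per
site (for ML trees).  All of the allele-probability machinery consumes
this one structure; the only difference between the two kinds of tree is
how the branch lengths are interpreted, tracked with ``is_timetree``.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Node",
    "TimeTree",
    "PruningStage",
    "NewickError",
    "read_newick",
    "write_newick",
    "prune_to",
    "pruning_series",
    "tree_span",
    "positional_time_span",
    "positional_time_spans_batch",
    "residue_time_span",
    "branch_score_distance",
    "subsample_density",
    "subsample_temporal",
]


class NewickError(ValueError):
    """Raised for malformed Newick input (message includes the position
    reported by the underlying parser when available)."""


class Node:
    """Tree node; ``length`` is the branch to the parent (None at the root)."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, {self.length!r}, {len(self.children)} children)"


class TimeTree:
    """Rooted tree with named leaves and non-negative branch lengths.

    Parameters
    ----------
    root:
        Root :class:`Node` of an existing linked structure.
    is_timetree:
        True when branch lengths are in time units; node ages are only
        meaningful in that case.
    clade_map:
        Optional mapping from clade name to a set of leaf labels, used by
        the taxon-sampling schemes.
    """

    def __init__(self, root: Node, is_timetree: bool = True,
                 clade_map: Mapping[str, set[str]] | None = None):
        self.root = root
        self.is_timetree = is_timetree
        self.clade_map = {k: set(v) for k, v in clade_map.items()} if clade_map else None
        self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        names = [lf.name for lf in self.leaves()]
        if any(n is None for n in names):
            raise ValueError("every leaf must be named")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise NewickError(f"duplicate leaf labels: {dupes}")
        for node in self.preorder():
            if node is not self.root and node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length at {node.name or 'internal node'}")

    # -- traversal ------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def leaf_set(self) -> set[str]:
        return set(self.leaf_names)

    def find_leaf(self, name: str) -> Node:
        for lf in self.leaves():
            if lf.name == name:
                return lf
        raise KeyError(f"taxon {name!r} not in tree")

    def has_branch_lengths(self) -> bool:
        return all(n.length is not None for n in self.preorder() if n is not self.root)

    # -- ages and spans --------------------------------------------------

    def depths(self) -> dict[Node, float]:
        """Root-to-node path sums (requires branch lengths)."""
        self._require_lengths()
        d: dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is not self.root:
                d[node] = d[node.parent] + node.length
        return d

    def ages(self) -> dict[Node, float]:
        """Node age = max root-to-leaf path sum minus the node's depth."""
        depths = self.depths()
        height = max(depths[lf] for lf in self.leaves())
        return {n: height - depths[n] for n in depths}

    def age_of(self, node: Node) -> float:
        """Age of a node as the maximum path sum to any descendant leaf.

        Unlike :meth:`ages` this is well defined on non-ultrametric trees,
        where it equals the deepest descendant's distance.
        """
        self._require_lengths()
        best = 0.0
        stack = [(node, 0.0)]
        while stack:
            cur, acc = stack.pop()
            if cur.is_leaf:
                best = max(best, acc)
            for ch in cur.children:
                stack.append((ch, acc + ch.length))
        return best

    def total_length(self) -> float:
        self._require_lengths()
        return sum(n.length for n in self.preorder() if n is not self.root)

    def _require_lengths(self) -> None:
        if not self.has_branch_lengths():
            raise ValueError("tree has nodes without branch lengths")

    # -- copying / editing ----------------------------------------------

    def copy(self) -> "TimeTree":
        def _clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            for ch in node.children:
                new.add_child(_clone(ch))
            return new

        return TimeTree(_clone(self.root), self.is_timetree, self.clade_map)

    def resolve_polytomies(self) -> "TimeTree":
        """Return a binary version; multifurcations are laddered in sorted
        leaf-label order with zero-length inserted branches."""
        tree = self.copy()
        for node in list(tree.postorder()):
            while len(node.children) > 2:
                kids = sorted(node.children, key=_min_leaf_label)
                a, b = kids[0], kids[1]
                node.children = [c for c in node.children if c not in (a, b)]
                joint = Node(None, 0.0)
                joint.add_child(a)
                joint.add_child(b)
                node.add_child(joint)
                # keep deterministic placement: joined pair goes first
                node.children.sort(key=_min_leaf_label)
        return tree

    def __repr__(self) -> str:  # pragma: no cover
        return f"TimeTree({len(self.leaf_names)} leaves, timetree={self.is_timetree})"


def _min_leaf_label(node: Node) -> str:
    if node.is_leaf:
        return node.name
    return min(lf.name for lf in _leaves_below(node))


def _leaves_below(node: Node) -> list[Node]:
    out = []
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            out.append(cur)
        stack.extend(cur.children)
    return out


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy; serialisation is direct)
# ---------------------------------------------------------------------------

def read_newick(text: str, is_timetree: bool | None = None,
                clade_map: Mapping[str, set[str]] | None = None) -> TimeTree:
    """Parse one Newick tree into a :class:`TimeTree`.

    ``is_timetree`` defaults to True when every branch carries a length.
    Malformed input raises :class:`NewickError` carrying the parser's
    position report; duplicate leaf labels are rejected.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed Newick: {exc}") from None

    def _convert(dnode) -> Node:
        name = None
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.label is not None:
            name = dnode.label
        node = Node(name, dnode.edge.length)
        for ch in dnode.child_nodes():
            node.add_child(_convert(ch))
        return node

    root = _convert(dtree.seed_node)
    root.length = None
    tree = TimeTree.__new__(TimeTree)
    tree.root = root
    tree.clade_map = {k: set(v) for k, v in clade_map.items()} if clade_map else None
    tree.is_timetree = tree.has_branch_lengths() if is_timetree is None else is_timetree
    tree._validate()
    return tree


def write_newick(tree: TimeTree, precision: int = 10) -> str:
    """Serialise to a Newick string (round-trips ``read_newick`` up to
    float formatting)."""

    def fmt(x: float) -> str:
        s = f"{x:.{precision}g}"
        return s

    def _write(node: Node, out: io.StringIO) -> None:
        if node.children:
            out.write("(")
            for i, ch in enumerate(node.children):
                if i:
                    out.write(",")
                _write(ch, out)
            out.write(")")
        if node.name:
            out.write(_quote_label(node.name))
        if node.length is not None and node.parent is not None:
            out.write(f":{fmt(node.length)}")

    buf = io.StringIO()
    _write(tree.root, buf)
    buf.write(";")
    return buf.getvalue()


def _quote_label(label: str) -> str:
    if any(c in label for c in "()[]{}/\\,;:=*'\"`+<> \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def prune_to(tree: TimeTree, keep: Iterable[str]) -> TimeTree:
    """Induced subtree on ``keep``, with unifurcations suppressed by
    summing branch lengths, so path lengths between retained leaves (and
    hence retained ancestor ages) are preserved.
    """
    keep = set(keep)
    leaf_set = tree.leaf_set
    unknown = keep - leaf_set
    if unknown:
        raise KeyError(f"taxa not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("prune_to requires at least 2 retained taxa")
    if keep == leaf_set:
        return tree.copy()

    def _prune(node: Node) -> Node | None:
        if node.is_leaf:
            if node.name in keep:
                return Node(node.name, node.length)
            return None
        kept = [c for c in (_prune(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if node.length is not None and child.length is not None:
                child.length = child.length + node.length
            elif node.length is None:
                child.length = child.length  # root handling below
            return child
        new = Node(node.name, node.length)
        for c in kept:
            new.add_child(c)
        return new

    root = _prune(tree.root)
    assert root is not None
    root.length = None
    root.parent = None
    cm = None
    if tree.clade_map:
        cm = {k: v & keep for k, v in tree.clade_map.items() if v & keep}
    return TimeTree(root, tree.is_timetree, cm)


@dataclass
class PruningStage:
    """One stage of the progressive pruning toward the root.

    ``index`` 0 is the full tree; each later stage drops the clade sister
    to the focal lineage at the next ancestral node.  ``t_time`` is the
    divergence time (node age) between the focal species and its closest
    remaining relative; ``t_ets`` is filled by the EP driver when
    span-based weights are requested.
    """

    index: int
    tree: TimeTree
    excluded: set[str]
    t_time: float | None
    t_ets: float | None = None


def _focal_ancestors(tree: TimeTree, focal: str) -> list[Node]:
    node = tree.find_leaf(focal)
    out = []
    while node.parent is not None:
        out.append(node.parent)
        node = node.parent
    return out


def pruning_series(tree: TimeTree, focal: str) -> list[PruningStage]:
    """Progressively prune the sister group closest to the focal species.

    Stage ``i`` excludes the clades that diverged from the focal lineage
    at the ``i`` most recent ancestral nodes; the series stops when only
    the focal species and one outgroup lineage remain.  For a focal
    lineage with ``m`` ancestral nodes this yields ``m`` stages, i.e.
    ``m - 1`` pruning steps.  Multifurcating input is first made binary
    (deterministically, in sorted leaf-label order).
    """
    if len(tree.leaf_names) < 3:
        raise ValueError("pruning series needs at least 3 leaves")
    if focal not in tree.leaf_set:
        raise KeyError(f"focal taxon {focal!r} not in tree")
    work = tree.resolve_polytomies()
    ancestors = _focal_ancestors(work, focal)
    has_lengths = work.has_branch_lengths()

    # Sister leaf sets at each ancestral node, most recent first.
    sisters: list[set[str]] = []
    child = work.find_leaf(focal)
    for anc in ancestors:
        sis = set()
        for ch in anc.children:
            if ch is not child:
                sis |= {lf.name for lf in _leaves_below(ch)}
        sisters.append(sis)
        child = anc

    stages: list[PruningStage] = []
    remaining = set(work.leaf_names)
    n = len(ancestors) - 1
    for i in range(n + 1):
        if i > 0:
            remaining -= sisters[i - 1]
        stage_tree = prune_to(work, remaining) if remaining != work.leaf_set else work.copy()
        t_time = None
        if has_lengths and work.is_timetree:
            t_time = work.age_of(ancestors[i])
        stages.append(PruningStage(i, stage_tree, set(work.leaf_names) - remaining, t_time))
    return stages


# ---------------------------------------------------------------------------
# Time spans
# ---------------------------------------------------------------------------

def tree_span(tree: TimeTree) -> float:
    """Total time spanned: the sum of all branch durations."""
    return tree.total_length()


def positional_time_span(tree: TimeTree, valid: Iterable[str]) -> float:
    """PTS: span of the timetree pruned to taxa with a valid residue at a
    site.  Degenerate sets (0 or 1 taxon) span no time and return 0."""
    valid = set(valid) & tree.leaf_set
    if len(valid) < 2:
        return 0.0
    return tree_span(prune_to(tree, valid))


def residue_time_span(tree: TimeTree, carriers: Iterable[str]) -> float:
    """RTS: span of the timetree pruned to the taxa carrying one specific
    residue at a site (0 when the residue occurs in ≤1 taxon)."""
    return positional_time_span(tree, carriers)


def positional_time_spans_batch(tree: TimeTree, valid: np.ndarray,
                                taxa: Sequence[str]) -> np.ndarray:
    """PTS for many sites at once.

    ``valid`` is a boolean matrix (taxa × sites) aligned with ``taxa``.
    A branch contributes its length to a site's span iff valid taxa exist
    on both sides of it, which reproduces ``prune_to`` + ``tree_span``
    without building each induced subtree.
    """
    tree._require_lengths()
    idx = {t: i for i, t in enumerate(taxa)}
    valid = np.asarray(valid, dtype=bool)
    n_sites = valid.shape[1]
    total = valid.sum(axis=0)
    spans = np.zeros(n_sites)
    # postorder accumulation of per-site valid-leaf counts below each node
    below: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            i = idx.get(node.name)
            cnt = valid[i].astype(np.int32) if i is not None else np.zeros(n_sites, np.int32)
        else:
            cnt = sum(below[ch] for ch in node.children)
        below[node] = cnt
        if node is not tree.root:
            contributes = (cnt > 0) & (total - cnt > 0)
            spans += np.where(contributes, node.length, 0.0)
    return spans


# ---------------------------------------------------------------------------
# Tree distance
# ---------------------------------------------------------------------------

def _bipartition_lengths(tree: TimeTree) -> dict[frozenset, float]:
    """Map each non-trivial-or-terminal bipartition of the unrooted tree to
    its branch length.  Keys are the leaf set on the side not containing
    the reference (lexicographically smallest) taxon; the two root edges
    of a rooted binary tree merge into one."""
    tree._require_lengths()
    all_leaves = frozenset(tree.leaf_names)
    ref = min(all_leaves)
    lengths: dict[frozenset, float] = {}
    root_kids = tree.root.children
    merge_root = len(root_kids) == 2
    for node in tree.postorder():
        if node is tree.root:
            continue
        side = frozenset(lf.name for lf in _leaves_below(node))
        if len(side) == len(all_leaves):
            continue
        key = side if ref not in side else all_leaves - side
        length = node.length
        if merge_root and node.parent is tree.root:
            # unrooting merges the two edges incident to a degree-2 root
            other = root_kids[0] if node is root_kids[1] else root_kids[1]
            length = node.length + other.length
            if node is root_kids[1]:
                continue  # counted once, from the first root child
        lengths[key] = lengths.get(key, 0.0) + length
    return lengths


def branch_score_distance(t1: TimeTree, t2: TimeTree, normalize: bool = False) -> float:
    """Branch-score distance: sqrt of summed squared branch-length
    differences over the union of (unrooted) bipartitions; a bipartition
    present in only one tree contributes its full length.  With
    ``normalize`` the second tree is rescaled so total lengths match,
    which makes relative-time trees comparable to absolute ones.
    """
    if t1.leaf_set != t2.leaf_set:
        raise ValueError("trees must share an identical leaf set")
    b1 = _bipartition_lengths(t1)
    b2 = _bipartition_lengths(t2)
    if normalize:
        s1 = sum(b1.values())
        s2 = sum(b2.values())
        if s2 > 0:
            scale = s1 / s2
            b2 = {k: v * scale for k, v in b2.items()}
    total = 0.0
    for key in set(b1) | set(b2):
        diff = b1.get(key, 0.0) - b2.get(key, 0.0)
        total += diff * diff
    return float(np.sqrt(total))


# ---------------------------------------------------------------------------
# Taxon sampling
# ---------------------------------------------------------------------------

def subsample_density(tree: TimeTree, clades: Mapping[str, set[str]],
                      per_clade: int, focal: str, seed: int) -> TimeTree:
    """Density sampling: keep ``per_clade`` random taxa from every clade
    (clades smaller than that contribute all members) plus the focal
    species.  Deterministic for a fixed seed."""
    if per_clade < 1:
        raise ValueError("per_clade must be >= 1")
    rng = np.random.default_rng(seed)
    keep = {focal}
    for name in sorted(clades):
        members = sorted(clades[name] & tree.leaf_set)
        if not members:
            raise ValueError(f"clade {name!r} has no members in the tree")
        pool = [m for m in members if m != focal]
        if len(pool) <= per_clade:
            keep.update(pool)
        else:
            keep.update(rng.choice(pool, size=per_clade, replace=False).tolist())
    return prune_to(tree, keep)


def subsample_temporal(tree: TimeTree, focal: str, k: int) -> TimeTree:
    """Temporal sampling: iteration ``k`` keeps the focal species plus all
    taxa whose divergence from the focal lineage falls at one of the
    ``k + 1`` most recent ancestral nodes.  Iterations are strictly
    nested; ``k`` past the root simply returns the full tree."""
    if k < 1:
        raise ValueError("k must be >= 1")
    work = tree.resolve_polytomies()
    ancestors = _focal_ancestors(work, focal)
    keep = {focal}
    child = work.find_leaf(focal)
    for anc in ancestors[: k + 1]:
        for ch in anc.children:
            if ch is not child:
                keep |= {lf.name for lf in _leaves_below(ch)}
        child = anc
    if keep == tree.leaf_set:
        return tree.copy()
    return prune_to(tree, keep)
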