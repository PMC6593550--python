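"""Alignment-driven phylogeny inference and relative divergence times.

The front end of the "no prior tree" pipeline: gamma-corrected Poisson
distances seed a neighbour-joining tree, which is polished by
nearest-neighbour-interchange hill climbing on the alignment
log-likelihood; branch lengths are then discarded from the topology and
a relative timetree is derived by a relative-rate transformation in the
spirit of RelTime.  The downstream allele-probability weights only ever
use normalised times, so a relative timetree (root age 1) is exactly as
good as an absolute one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from .alignment import ProteinAlignment
from .likelihood import TreeLikelihood, optimize_branch_lengths
from .model import PoissonGI
from .posterior import fit_branch_lengths, fit_model_and_lengths
from .trees import Node, TimeTree, read_newick, write_newick

__all__ = ["InferenceResult", "pairwise_distances", "infer_topology",
           "reltime", "default_outgroup", "root_on_outgroup"]

_MAX_DISTANCE = 10.0


@dataclass
class InferenceResult:
    """Everything the modified pipeline derives from one alignment."""

    topology: TimeTree          # branch lengths discarded
    ml_tree: TimeTree           # ML branch lengths (substitutions/site)
    relative_timetree: TimeTree | None
    log_likelihood: float
    distances: pd.DataFrame
    model: PoissonGI


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def pairwise_distances(alignment: ProteinAlignment,
                       model: PoissonGI | None = None) -> pd.DataFrame:
    """Gamma-corrected Poisson distances between all sequence pairs.

    From the fraction of differing residues ``p`` over the pair's shared
    valid columns:

        d = (19/20) * alpha * ((1 - (20/19) p)^(-1/alpha) - 1)

    which tends to the logarithmic Poisson correction as alpha grows.
    Saturated pairs (p at or beyond 19/20) are capped at 10
    substitutions/site with a warning; a pair with no shared valid
    columns is an error naming the pair.
    """
    if alignment.n_taxa < 3:
        raise ValueError("need at least 3 sequences")
    alpha = (model.alpha if model is not None else 1.0)
    names = alignment.names
    codes = alignment.codes
    valid = alignment.valid
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = valid[i] & valid[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"sequences {names[i]!r} and {names[j]!r} share no valid columns")
            p = float((codes[i, shared] != codes[j, shared]).mean())
            arg = 1.0 - (20.0 / 19.0) * p
            if arg <= 0:
                warnings.warn(f"pair ({names[i]}, {names[j]}) is saturated "
                              f"(p={p:.3f}); capping distance", stacklevel=2)
                d = _MAX_DISTANCE
            else:
                d = (19.0 / 20.0) * alpha * (arg ** (-1.0 / alpha) - 1.0)
                d = min(d, _MAX_DISTANCE)
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=names, columns=names)


def default_outgroup(alignment: ProteinAlignment, focal: str) -> str:
    """Fallback rooting rule: the taxon with the greatest mean distance
    to all others (ties broken lexicographically)."""
    D = pairwise_distances(alignment, PoissonGI(1.0, 0.0))
    means = D.mean(axis=1).drop(labels=[focal], errors="ignore")
    best = means.max()
    return sorted(means.index[means == best])[0]


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def root_on_outgroup(tree: TimeTree, outgroup: set[str] | str) -> TimeTree:
    """Root (or re-root) a tree on the edge subtending the outgroup,
    splitting that edge at its midpoint.  The outgroup must be a clade of
    the unrooted tree."""
    outgroup = {outgroup} if isinstance(outgroup, str) else set(outgroup)
    if not outgroup <= tree.leaf_set:
        raise ValueError(f"outgroup taxa not in tree: {sorted(outgroup - tree.leaf_set)}")
    dtree = dendropy.Tree.get(data=write_newick(tree), schema="newick",
                              preserve_underscores=True)
    dtree.is_rooted = True
    taxa = [t for t in dtree.taxon_namespace if t.label in outgroup]
    if len(outgroup) == 1:
        node = dtree.find_node_with_taxon_label(next(iter(outgroup)))
    else:
        node = dtree.mrca(taxa=taxa)
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below != outgroup:
            # the complement side may be the clade in the unrooted sense
            comp = tree.leaf_set - outgroup
            node = dtree.mrca(taxa=[t for t in dtree.taxon_namespace
                                    if t.label in comp])
            below = {lf.taxon.label for lf in node.leaf_iter()}
            if below != comp:
                raise ValueError("outgroup is not monophyletic in the tree")
    length = node.edge.length
    if length is None:
        length = 0.0
    dtree.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0,
                         update_bipartitions=False)
    dtree.suppress_unifurcations()
    out = read_newick(dtree.as_string(schema="newick").strip(),
                      is_timetree=tree.is_timetree, clade_map=tree.clade_map)
    return out


# ---------------------------------------------------------------------------
# Topology search
# ---------------------------------------------------------------------------

def _nj_tree(distances: pd.DataFrame) -> TimeTree:
    names = sorted(distances.index)
    dm = DistanceMatrix(distances.loc[names, names].to_numpy(), ids=names)
    sk = nj(dm)
    return _read_clamped(str(sk))


def _read_clamped(newick: str) -> TimeTree:
    """Parse Newick, clamping any negative branch lengths (which NJ can
    produce) to zero."""
    dtree = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return read_newick(dtree.as_string(schema="newick").strip(), is_timetree=False)


def _nni_neighbors(tree: TimeTree):
    """Yield (description, candidate) for every nearest-neighbour
    interchange of the (unrooted) tree, in deterministic order."""
    serial = write_newick(tree)
    # enumerate internal non-root nodes by a stable postorder position
    base = read_newick(serial, is_timetree=False)
    positions = [i for i, n in enumerate(base.postorder())
                 if n.parent is not None and not n.is_leaf]
    for pos in positions:
        for move in (0, 1):
            cand = read_newick(serial, is_timetree=False)
            nodes = list(cand.postorder())
            v = nodes[pos]
            p = v.parent
            siblings = [c for c in p.children if c is not v]
            if not siblings:
                continue
            sib = siblings[0]
            child = v.children[move]
            # swap `child` and `sib`
            v.children[v.children.index(child)] = sib
            p.children[p.children.index(sib)] = child
            sib.parent, child.parent = v, p
            yield (pos, move), cand


def infer_topology(alignment: ProteinAlignment, model: PoissonGI | None = None,
                   outgroup: set[str] | str | None = None, seed: int = 0,
                   nni: bool = True) -> InferenceResult:
    """Infer the tree topology from the alignment.

    Neighbour joining on gamma-corrected Poisson distances gives the
    starting tree; NNI hill climbing then accepts any rearrangement that
    increases the alignment log-likelihood (branch lengths re-optimised
    for every candidate) until no move improves it.  The returned
    topology carries no branch lengths; the ML tree does.  ``seed`` is
    accepted for interface stability — the search itself is
    deterministic.
    """
    if alignment.n_taxa < 3:
        raise ValueError("need at least 3 sequences")
    distances = pairwise_distances(alignment, model)
    start = _nj_tree(distances)
    if outgroup is None:
        og: set[str] | str = default_outgroup(alignment, alignment.names[0])
        warnings.warn(f"no outgroup given; rooting on most divergent taxon {og!r}",
                      stacklevel=2)
    else:
        og = outgroup
    start = root_on_outgroup(start, og)

    fitted, model, ll = fit_model_and_lengths(alignment, start, model)
    if nni and alignment.n_taxa > 3:
        improved = True
        while improved:
            improved = False
            best_ll, best_tree = ll, None
            for _, cand in _nni_neighbors(fitted):
                cand_fit, cand_ll = fit_branch_lengths(cand, alignment, model,
                                                       initial=None, tol=1e-3)
                if cand_ll > best_ll + 1e-6:
                    best_ll, best_tree = cand_ll, cand_fit
            if best_tree is not None:
                fitted, _ = fit_branch_lengths(best_tree, alignment, model,
                                               initial=None)
                ll = max(best_ll, TreeLikelihood(fitted, alignment, model).log_likelihood())
                fitted = root_on_outgroup(fitted, og)
                improved = True

    topology = fitted.copy()
    for node in topology.preorder():
        node.length = None
    topology.is_timetree = False
    rel = reltime(fitted, og)
    return InferenceResult(topology, fitted, rel, ll, distances, model)


# ---------------------------------------------------------------------------
# Relative times
# ---------------------------------------------------------------------------

def reltime(tree: TimeTree, outgroup: set[str] | str) -> TimeTree:
    """Transform an ML branch-length tree into a relative timetree.

    A relative-rate recursion: each node's mean descendant depth is the
    equal-weight average of its child lineages' (depth + branch) values,
    and relative node ages follow by dividing each lineage's observed
    length by its implied rate — equivalently, ``t(child) = t(parent) *
    D(child) / (D(child) + b(child))``.  The result is ultrametric with
    the root age normalised to 1; it is invariant to rescaling all input
    lengths, and on a clock-like tree the ages are proportional to node
    depths.
    """
    outgroup = {outgroup} if isinstance(outgroup, str) else set(outgroup)
    tree._require_lengths()
    # The split of the outgroup branch around the root is not
    # identifiable from sequence data; re-root so the two sides' mean
    # tip depths balance.  This is canonical regardless of the input
    # rooting and recovers the true root exactly on clock-like trees.
    tree = root_on_outgroup(tree, outgroup)
    kids = tree.root.children
    if len(kids) != 2 or not any(
            set(lf.name for lf in _leaves(ch)) == outgroup for ch in kids):
        raise ValueError("outgroup is not monophyletic in the tree")
    work = tree.copy()

    depth: dict[Node, float] = {}
    for node in work.postorder():
        if node.is_leaf:
            depth[node] = 0.0
        else:
            depth[node] = float(np.mean([depth[c] + c.length for c in node.children]))

    c_out, c_in = work.root.children
    if {lf.name for lf in _leaves(c_in)} == outgroup:
        c_out, c_in = c_in, c_out
    total = c_out.length + c_in.length
    b_in = min(max((total + depth[c_out] - depth[c_in]) / 2.0, 0.0), total)
    c_in.length = b_in
    c_out.length = total - b_in
    depth[work.root] = float(np.mean([depth[c] + c.length
                                      for c in work.root.children]))

    age: dict[Node, float] = {work.root: 1.0}
    for node in work.preorder():
        if node is work.root:
            continue
        total = depth[node] + node.length
        age[node] = age[node.parent] * (depth[node] / total) if total > 0 else 0.0
        if node.is_leaf:
            age[node] = 0.0

    for node in work.preorder():
        if node is not work.root:
            node.length = max(age[node.parent] - age[node], 0.0)
    work.is_timetree = True
    return work


def _leaves(node: Node):
    stack, out = [node], []
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            out.append(cur)
        stack.extend(cur.children)
    return out
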