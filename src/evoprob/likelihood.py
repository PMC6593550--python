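"""Felsenstein pruning for the Poisson+G+I model, vectorised over sites.

The Poisson transition matrix is ``P(x,y) = a + E*delta(x,y)`` with
``E = exp(-(20/19) d r)`` and ``a = (1-E)/20``, so a message through a
branch is an axpy, not a matrix product:

    S(x) = sum_y P(x,y) D(y) = a * sum(D) + E * D(x)

All per-site quantities are computed for every alignment column at once;
numerical underflow is handled by per-node, per-site rescaling with the
log scale factors carried alongside.  The invariant (rate-0) class only
admits columns whose unambiguous residues are all identical, and its
contribution is independent of branch lengths.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .alignment import ProteinAlignment
from .model import N_STATES, PoissonGI, poisson_decay
from .trees import Node, TimeTree

_TINY = 1e-300

__all__ = ["TreeLikelihood", "column_log_likelihood", "estimate_rate_params",
           "optimize_branch_lengths"]


def _invariant_profile(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site invariant-class compatibility for a code matrix.

    Returns ``(n_compatible, state)`` where ``n_compatible`` is the number
    of root states compatible with a rate-0 site (20 when every row is
    ambiguous, 1 when all unambiguous rows agree, else 0) and ``state``
    is the agreed residue (-1 when not applicable).
    """
    n_sites = codes.shape[1]
    hi = np.where(codes >= 0, codes, -100).max(axis=0) if codes.size else np.full(n_sites, -100)
    lo = np.where(codes >= 0, codes, 100).min(axis=0) if codes.size else np.full(n_sites, 100)
    none_valid = hi < 0
    consistent = (hi == lo) & ~none_valid
    n_comp = np.where(none_valid, N_STATES, np.where(consistent, 1, 0))
    state = np.where(consistent, hi, -1)
    return n_comp.astype(float), state.astype(np.int64)


class TreeLikelihood:
    """Likelihood of a protein alignment on a rooted tree with
    substitutions-per-site branch lengths, under Poisson+G+I.

    The engine exposes total and per-site log-likelihoods, per-edge
    sufficient statistics for branch-length optimisation, and the
    leave-the-tip-out posterior used by the allele-probability method.
    """

    def __init__(self, tree: TimeTree, alignment: ProteinAlignment,
                 model: PoissonGI, chunk: int = 512):
        missing = set(tree.leaf_names) - set(alignment.names)
        if missing:
            raise ValueError(f"taxa missing from alignment: {sorted(missing)}")
        tree._require_lengths()
        self.tree = tree
        self.alignment = alignment
        self.chunk = chunk

        # flatten to postorder arrays
        self._nodes: list[Node] = list(tree.postorder())
        self._index = {id(n): i for i, n in enumerate(self._nodes)}
        self.n_nodes = len(self._nodes)
        self.root_idx = self._index[id(tree.root)]
        self.children = [[self._index[id(c)] for c in n.children] for n in self._nodes]
        self.parent = np.full(self.n_nodes, -1)
        for i, n in enumerate(self._nodes):
            for c in self.children[i]:
                self.parent[c] = i
        self.leaf_row = np.full(self.n_nodes, -1)
        for i, n in enumerate(self._nodes):
            if n.is_leaf:
                self.leaf_row[i] = alignment.row(n.name)
        self.lengths = np.array(
            [0.0 if n is tree.root else float(n.length) for n in self._nodes])
        self.codes = alignment.codes
        self.n_sites = alignment.n_sites
        tree_rows = [alignment.row(n.name) for n in self._nodes if n.is_leaf]
        self._tree_codes = self.codes[tree_rows]
        self.set_model(model)

    # -- configuration ---------------------------------------------------

    def set_model(self, model: PoissonGI) -> None:
        self.model = model
        self.rates = model.rate_multipliers  # (K,)
        self.K = model.K
        n_comp, _ = _invariant_profile(self._tree_codes)
        if model.p_inv > 0:
            self.log_inv = np.where(
                n_comp > 0,
                np.log(model.p_inv) + np.log(np.maximum(n_comp, 1.0) / N_STATES),
                -np.inf)
        else:
            self.log_inv = np.full(self.n_sites, -np.inf)

    def set_lengths(self, lengths: np.ndarray) -> None:
        """Branch lengths indexed by postorder node position (root entry
        ignored)."""
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != (self.n_nodes,):
            raise ValueError("lengths must align with postorder nodes")
        self.lengths = lengths.copy()
        self.lengths[self.root_idx] = 0.0

    def write_lengths_to_tree(self) -> TimeTree:
        """Return a copy of the tree carrying the engine's current lengths."""
        out = self.tree.copy()
        for node, src in zip(out.postorder(), self._nodes):
            if src is not self.tree.root:
                node.length = float(self.lengths[self._index[id(src)]])
        out.is_timetree = False
        return out

    # -- message passes --------------------------------------------------

    def _decay(self, i: int) -> np.ndarray:
        """(K,) per-category decay factor for node i's parent branch."""
        return poisson_decay(self.lengths[i], self.rates)

    def _down_pass(self, s0: int, s1: int, keep_all: bool = False):
        """Postorder partials for sites [s0, s1).

        Returns (D, lsD, S) lists indexed by node; entries for nodes whose
        parent has been processed are freed unless ``keep_all``.
        """
        ns = s1 - s0
        D: list = [None] * self.n_nodes
        lsD: list = [None] * self.n_nodes
        S: list = [None] * self.n_nodes
        for i in range(self.n_nodes):
            kids = self.children[i]
            if not kids:
                row = self.codes[self.leaf_row[i], s0:s1]
                M = np.zeros((ns, N_STATES))
                valid = row >= 0
                M[valid, row[valid]] = 1.0
                M[~valid, :] = 1.0
                D[i] = np.broadcast_to(M, (self.K, ns, N_STATES))
                lsD[i] = np.zeros(ns)
            else:
                acc = None
                ls = np.zeros(ns)
                for c in kids:
                    E = self._decay(c)[:, None, None]
                    a = (1.0 - E) / N_STATES
                    Sc = a * D[c].sum(axis=2, keepdims=True) + E * D[c]
                    S[c] = Sc if keep_all else None
                    acc = Sc if acc is None else acc * Sc
                    ls = ls + lsD[c]
                    if not keep_all:
                        D[c] = None
                m = acc.max(axis=(0, 2))
                m = np.where(m > 0, m, 1.0)
                acc = acc / m[None, :, None]
                D[i] = acc
                lsD[i] = ls + np.log(m)
        return D, lsD, S

    def _full_pass(self, s0: int, s1: int):
        """Down + outer pass; returns (D, lsD, O, lsO) with every node
        populated (O is prior-included and refers to the state at the
        node's parent)."""
        D, lsD, S = self._down_pass(s0, s1, keep_all=True)
        ns = s1 - s0
        O: list = [None] * self.n_nodes
        lsO: list = [None] * self.n_nodes
        order = list(range(self.n_nodes - 1, -1, -1))  # reverse postorder
        for p in order:
            kids = self.children[p]
            if not kids:
                continue
            if p == self.root_idx:
                inner = np.full((self.K, ns, N_STATES), 1.0 / N_STATES)
                inner_ls = np.zeros(ns)
            else:
                E = self._decay(p)[:, None, None]
                a = (1.0 - E) / N_STATES
                inner = a * O[p].sum(axis=2, keepdims=True) + E * O[p]
                inner_ls = lsO[p]
            for c in kids:
                acc = inner
                ls = inner_ls
                for sib in kids:
                    if sib is c:
                        continue
                    acc = acc * S[sib]
                    ls = ls + lsD[sib]
                m = acc.max(axis=(0, 2))
                m = np.where(m > 0, m, 1.0)
                O[c] = acc / m[None, :, None]
                lsO[c] = ls + np.log(m)
        return D, lsD, O, lsO

    # -- likelihood ------------------------------------------------------

    def site_log_likelihoods(self) -> np.ndarray:
        w = self.model.category_weight
        out = np.empty(self.n_sites)
        for s0 in range(0, self.n_sites, self.chunk):
            s1 = min(s0 + self.chunk, self.n_sites)
            D, lsD, _ = self._down_pass(s0, s1)
            r = self.root_idx
            gamma = w * D[r].sum(axis=2).sum(axis=0) / N_STATES
            log_gamma = np.log(np.maximum(gamma, _TINY)) + lsD[r]
            out[s0:s1] = np.logaddexp(log_gamma, self.log_inv[s0:s1])
        return out

    def log_likelihood(self) -> float:
        return float(self.site_log_likelihoods().sum())

    # -- per-edge sufficient statistics ----------------------------------

    def edge_stats(self):
        """For every non-root node v, per-category sums over states of the
        outer message O, the down partial D, and their elementwise product,
        plus the per-site log scale.  These four arrays make the
        likelihood an O(K) function of that edge's length:

            l_k(t) = a_k * SO_k * SD_k + E_k * OD_k
        """
        K, ns = self.K, self.n_sites
        edges = [i for i in range(self.n_nodes) if i != self.root_idx]
        SO = np.empty((self.n_nodes, K, ns))
        SD = np.empty((self.n_nodes, K, ns))
        OD = np.empty((self.n_nodes, K, ns))
        C = np.empty((self.n_nodes, ns))
        for s0 in range(0, ns, self.chunk):
            s1 = min(s0 + self.chunk, ns)
            D, lsD, O, lsO = self._full_pass(s0, s1)
            for i in edges:
                SO[i, :, s0:s1] = O[i].sum(axis=2)
                SD[i, :, s0:s1] = D[i].sum(axis=2)
                OD[i, :, s0:s1] = (O[i] * D[i]).sum(axis=2)
                C[i, s0:s1] = lsO[i] + lsD[i]
        return edges, SO, SD, OD, C

    # -- tip posterior ---------------------------------------------------

    def tip_posteriors(self, focal: str) -> tuple[np.ndarray, np.ndarray]:
        """Posterior probability of each of the 20 residues at the focal
        tip, per site, with the focal taxon's own residue treated as
        unknown.  Returns (probabilities (n_sites, 20), flag vector);
        a flagged site had no unambiguous residue in any other taxon and
        its posterior is uniform.
        """
        fi = None
        for i, n in enumerate(self._nodes):
            if n.is_leaf and n.name == focal:
                fi = i
        if fi is None:
            raise KeyError(f"focal taxon {focal!r} not in tree")
        other_rows = [self.leaf_row[i] for i in range(self.n_nodes)
                      if self.leaf_row[i] >= 0 and i != fi]
        n_comp, inv_state = _invariant_profile(self.codes[other_rows])
        compat = np.zeros((self.n_sites, N_STATES))
        compat[n_comp == N_STATES, :] = 1.0
        one = inv_state >= 0
        compat[np.nonzero(one)[0], inv_state[one]] = 1.0
        flags = n_comp == N_STATES

        w = self.model.category_weight
        p_inv = self.model.p_inv
        logpp = np.empty((self.n_sites, N_STATES))
        for s0 in range(0, self.n_sites, self.chunk):
            s1 = min(s0 + self.chunk, self.n_sites)
            _, _, O, lsO = self._full_pass(s0, s1)
            E = self._decay(fi)[:, None, None]
            a = (1.0 - E) / N_STATES
            g = a * O[fi].sum(axis=2, keepdims=True) + E * O[fi]  # (K, ns, 20)
            g = w * g.sum(axis=0)
            log_g = np.log(np.maximum(g, _TINY)) + lsO[fi][:, None]
            if p_inv > 0:
                with np.errstate(divide="ignore"):
                    log_i = np.log(p_inv * compat[s0:s1] / N_STATES)
                logpp[s0:s1] = np.logaddexp(log_g, log_i)
            else:
                logpp[s0:s1] = log_g
        logpp -= logpp.max(axis=1, keepdims=True)
        pp = np.exp(logpp)
        pp /= pp.sum(axis=1, keepdims=True)
        return pp, flags


# ---------------------------------------------------------------------------
# Branch-length optimisation
# ---------------------------------------------------------------------------

def _edge_objective(t, SO, SD, OD, C, log_inv, rates, w):
    E = poisson_decay(t, rates)[:, None]
    a = (1.0 - E) / N_STATES
    l = (a * SO * SD + E * OD).sum(axis=0) * w
    return float(np.logaddexp(np.log(np.maximum(l, _TINY)) + C, log_inv).sum())


def optimize_branch_lengths(engine: TreeLikelihood, tol: float = 1e-6,
                            max_sweeps: int = 40, t_max: float = 20.0) -> float:
    """Maximise the alignment log-likelihood over all branch lengths by
    per-edge univariate optimisation (Brent on each edge's closed-form
    profile), sweeping until the total log-likelihood stabilises.

    Within a sweep every edge is optimised against the messages computed
    at the sweep's start; a sweep that fails to improve the likelihood is
    backtracked halfway (at most a few times) before giving up.  Returns
    the final log-likelihood; the engine's lengths are updated in place.
    """
    rates = engine.rates
    w = engine.model.category_weight
    ll = engine.log_likelihood()
    for _ in range(max_sweeps):
        edges, SO, SD, OD, C = engine.edge_stats()
        old = engine.lengths.copy()
        new = old.copy()
        for i in edges:
            res = minimize_scalar(
                lambda t: -_edge_objective(t, SO[i], SD[i], OD[i], C[i],
                                           engine.log_inv, rates, w),
                bounds=(0.0, t_max), method="bounded",
                options={"xatol": 1e-7})
            new[i] = res.x
        engine.set_lengths(new)
        new_ll = engine.log_likelihood()
        tries = 0
        while new_ll < ll - 1e-9 and tries < 5:
            new = 0.5 * (new + old)
            engine.set_lengths(new)
            new_ll = engine.log_likelihood()
            tries += 1
        if new_ll < ll - 1e-9:
            engine.set_lengths(old)
            return ll
        if abs(new_ll - ll) < tol:
            return new_ll
        ll = new_ll
    return ll


# ---------------------------------------------------------------------------
# Convenience entry points
# ---------------------------------------------------------------------------

def column_log_likelihood(tree: TimeTree, column: dict[str, int | str],
                          model: PoissonGI) -> float:
    """Log-likelihood of a single alignment column (residues given as
    one-letter codes or integer indices, ambiguity as '-', '?', 'X' or
    -1) on a tree with substitutions-per-site branch lengths."""
    from .alignment import AA_INDEX
    names = tree.leaf_names
    missing = set(names) - set(column)
    if missing:
        raise ValueError(f"column lacks taxa: {sorted(missing)}")
    codes = np.empty((len(names), 1), dtype=np.int8)
    for i, n in enumerate(names):
        v = column[n]
        codes[i, 0] = AA_INDEX.get(v.upper(), -1) if isinstance(v, str) else int(v)
    aln = ProteinAlignment(names, codes)
    return float(TreeLikelihood(tree, aln, model).log_likelihood())


def estimate_rate_params(alignment: ProteinAlignment, tree: TimeTree,
                         K: int = 5, start: tuple[float, float] = (1.0, 0.1),
                         tol: float = 1e-6) -> tuple[float, float, float]:
    """Maximum-likelihood (alpha, p_inv) for fixed tree and branch
    lengths, by bounded quasi-Newton on (log alpha, logit p_inv).

    Returns ``(alpha_hat, p_inv_hat, log_likelihood)``.  On an alignment
    with no variable sites the likelihood is flat in alpha and the
    invariant fraction is pushed to its upper bound; this is reported,
    not an error.
    """
    if not np.any(alignment.valid):
        raise ValueError("alignment contains no valid residues")
    if alignment.n_taxa < 3:
        raise ValueError("need at least 3 sequences")
    engine = TreeLikelihood(tree, alignment, PoissonGI(start[0], start[1], K))

    def negll(theta):
        alpha = float(np.exp(theta[0]))
        p_inv = float(1.0 / (1.0 + np.exp(-theta[1])))
        engine.set_model(PoissonGI(alpha, min(p_inv, 0.999), K))
        return -engine.log_likelihood()

    x0 = np.array([np.log(start[0]), np.log(start[1] / (1 - start[1]))])
    res = minimize(negll, x0, method="L-BFGS-B",
                   bounds=[(np.log(0.02), np.log(100.0)), (-12.0, 7.0)],
                   options={"ftol": tol, "gtol": 1e-8})
    alpha = float(np.exp(res.x[0]))
    p_inv = float(1.0 / (1.0 + np.exp(-res.x[1])))
    return alpha, p_inv, float(-res.fun)
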