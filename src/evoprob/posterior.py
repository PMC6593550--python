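"""Tip posteriors: the probability of each residue at the focal tip.

The focal species' observed residue is treated as unknown; the posterior
over the 20 amino acids is driven entirely by the other sequences, the
tree, and the substitution model.  Branch lengths on the (possibly
pruned) topology are fitted by maximum likelihood because a timetree in
time units carries no substitution scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import AMINO_ACIDS, ProteinAlignment
from .likelihood import TreeLikelihood, estimate_rate_params, optimize_branch_lengths
from .model import PoissonGI
from .trees import TimeTree

__all__ = ["PosteriorVector", "fit_branch_lengths", "fit_model_and_lengths",
           "tip_posterior", "tip_posterior_matrix"]


@dataclass
class PosteriorVector:
    """Posterior probabilities of the 20 residues at one site/stage.

    ``site`` is 1-based; ``uninformative`` marks a site where every other
    taxon was ambiguous (the vector is then uniform).
    """

    site: int
    stage: int
    probs: np.ndarray
    uninformative: bool = False

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (20,):
            raise ValueError("posterior vector needs 20 entries")
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-9):
            raise ValueError("posterior must sum to 1")

    def prob_of(self, residue: str) -> float:
        return float(self.probs[AMINO_ACIDS.index(residue)])


def fit_branch_lengths(topology: TimeTree, alignment: ProteinAlignment,
                       model: PoissonGI, initial: float | None = 0.1,
                       tol: float = 1e-6) -> tuple[TimeTree, float]:
    """ML branch lengths (substitutions/site) on a fixed topology.

    Every branch starts from ``initial`` (or, with ``initial=None``, from
    the lengths already on the tree — a warm start) and is optimised
    coordinate-wise to ``tol`` in log-likelihood.  Returns
    ``(tree, log_likelihood)`` where the tree carries the fitted lengths
    and is flagged as a non-timetree.
    """
    if len(topology.leaf_names) < 3:
        raise ValueError("need at least 3 taxa to fit branch lengths")
    work = topology.copy()
    if initial is None and not work.has_branch_lengths():
        initial = 0.1
    for node in work.preorder():
        if node is not work.root and initial is not None:
            node.length = initial
    work.is_timetree = False
    engine = TreeLikelihood(work, alignment, model)
    ll = optimize_branch_lengths(engine, tol=tol)
    return engine.write_lengths_to_tree(), ll


def fit_model_and_lengths(alignment: ProteinAlignment, topology: TimeTree,
                          model: PoissonGI | None = None, rounds: int = 2,
                          ) -> tuple[TimeTree, PoissonGI, float]:
    """Fit branch lengths, and (alpha, p_inv) when no model is supplied,
    by a short alternation: lengths given the current model, then rate
    parameters given the lengths.  Two rounds are enough in practice
    because the two blocks are weakly coupled.
    """
    if model is not None:
        tree, ll = fit_branch_lengths(topology, alignment, model)
        return tree, model, ll
    model = PoissonGI(1.0, 0.1, 5)
    tree, ll = fit_branch_lengths(topology, alignment, model)
    for _ in range(rounds):
        alpha, p_inv, ll = estimate_rate_params(alignment, tree, K=model.K,
                                                start=(model.alpha, max(model.p_inv, 1e-3)))
        model = PoissonGI(alpha, min(p_inv, 0.99), model.K)
        tree, ll = fit_branch_lengths(topology, alignment, model)
    return tree, model, ll


def tip_posterior_matrix(tree: TimeTree, alignment: ProteinAlignment,
                         focal: str, model: PoissonGI,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior matrix (n_sites × 20) for the focal tip across all
    sites, plus the per-site uninformative flags.  ``tree`` must carry
    substitutions-per-site branch lengths."""
    if focal not in tree.leaf_set:
        raise KeyError(f"focal taxon {focal!r} not in tree")
    engine = TreeLikelihood(tree, alignment, model)
    return engine.tip_posteriors(focal)


def tip_posterior(tree: TimeTree, alignment: ProteinAlignment, focal: str,
                  site: int, model: PoissonGI, stage: int = 0) -> PosteriorVector:
    """Posterior of the 20 residues at one 1-based ``site`` of the focal
    tip.  Emits a warning (and a uniform vector) when every other taxon
    is ambiguous at the site."""
    if not (1 <= site <= alignment.n_sites):
        raise IndexError(f"site {site} outside 1..{alignment.n_sites}")
    pp, flags = tip_posterior_matrix(tree, alignment, focal, model)
    if flags[site - 1]:
        warnings.warn(f"site {site}: no unambiguous residue in any non-focal taxon; "
                      "posterior is uniform", stacklevel=2)
    return PosteriorVector(site, stage, pp[site - 1], bool(flags[site - 1]))
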