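"""Concordance metrics between EP call sets and taxon-sampling experiments.

Percent agreement treats the two methods symmetrically (intersection
over union of their eForb calls); the classification-error fraction
(share of one method's eForbs missed by the other) is directional and
uses the known-tree method as ground truth.  The ROC sweep follows a
threshold grid rather than a continuous score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import AA_INDEX, AMINO_ACIDS, ProteinAlignment
from .ep import EPMatrix, VariantRecord, compute_ep_modified, compute_ep_original
from .model import PoissonGI
from .trees import (TimeTree, pruning_series, subsample_density,
                    subsample_temporal, tree_span)

__all__ = ["percent_agreement", "delta_eforb", "roc_eforb", "ROCResult",
           "density_experiment", "temporal_experiment"]


# ---------------------------------------------------------------------------
# Agreement metrics
# ---------------------------------------------------------------------------

def percent_agreement(calls_a: set, calls_b: set, universe: set) -> float:
    """Fraction (as a percentage) of alleles called eForb by at least one
    method that both methods called eForb: 100·|A∩B| / |A∪B|.

    Both call sets must come from the same allele universe; two empty
    call sets agree vacuously (100%, with a warning).
    """
    calls_a, calls_b, universe = set(calls_a), set(calls_b), set(universe)
    stray = (calls_a | calls_b) - universe
    if stray:
        raise ValueError(f"calls outside the shared allele universe: {sorted(stray)[:5]}")
    union = calls_a | calls_b
    if not union:
        warnings.warn("both eForb sets are empty; agreement is vacuous",
                      stacklevel=2)
        return 100.0
    return 100.0 * len(calls_a & calls_b) / len(union)


def delta_eforb(original_ep: EPMatrix, modified_ep: EPMatrix,
                variants: list[VariantRecord],
                threshold: float = 0.05) -> float:
    """Per-protein fraction of known-tree eForbs (among the two
    segregating alleles at each variant site) that the inferred-tree
    method failed to call eForb.

    A value of 0.5 means half of the original method's eForbs at
    missense sites received EP >= threshold under the modified method.
    With no original-method eForbs the fraction is 0 (flagged by a
    warning).
    """
    denom = num = 0
    for v in variants:
        if not (1 <= v.site <= original_ep.n_sites) or v.site > modified_ep.n_sites:
            raise ValueError(f"variant site outside EP matrices: {v}")
        for allele in (v.ref, v.alt):
            orig = original_ep.ep_of(v.site, allele)
            mod = modified_ep.ep_of(v.site, allele)
            if np.isnan(orig) or np.isnan(mod):
                continue
            if orig < threshold:
                denom += 1
                if mod >= threshold:
                    num += 1
    if denom == 0:
        warnings.warn("no original-method eForbs at the variant sites; "
                      "error fraction defined as 0", stacklevel=2)
        return 0.0
    return num / denom


@dataclass
class ROCResult:
    """ROC points (one per prediction threshold, plus the (0,0) and (1,1)
    anchors) and the trapezoidal area under them."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float


def roc_eforb(truth_ep: EPMatrix, predicted_ep: EPMatrix,
              truth_threshold: float = 0.05,
              prediction_thresholds: np.ndarray | None = None) -> ROCResult:
    """ROC for eForb detection with the known-tree EP as ground truth.

    Condition positives are alleles with truth EP < ``truth_threshold``;
    the prediction threshold sweeps 10 evenly spaced values in
    [0.01, 0.1] by default.  TPR/FPR per threshold are augmented with the
    (0,0) and (1,1) endpoints for the trapezoid area.
    """
    if prediction_thresholds is None:
        prediction_thresholds = np.linspace(0.01, 0.10, 10)
    thresholds = np.asarray(prediction_thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("prediction thresholds must lie in (0, 1)")
    mask = ~(np.isnan(truth_ep.ep) | np.isnan(predicted_ep.ep))
    truth = truth_ep.ep[mask]
    pred = predicted_ep.ep[mask]
    pos = truth < truth_threshold
    neg = ~pos
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("ROC needs both positive and negative truth classes")
    tpr = np.array([(pred[pos] < t).mean() for t in thresholds])
    fpr = np.array([(pred[neg] < t).mean() for t in thresholds])
    order = np.argsort(fpr, kind="stable")
    fx = np.concatenate([[0.0], fpr[order], [1.0]])
    fy = np.concatenate([[0.0], tpr[order], [1.0]])
    auroc = float(np.trapezoid(fy, fx))
    return ROCResult(thresholds, fpr, tpr, auroc)


# ---------------------------------------------------------------------------
# Taxon-sampling experiments
# ---------------------------------------------------------------------------

def _clades_or_default(tree: TimeTree, clades):
    if clades is None:
        clades = tree.clade_map
    if not clades:
        raise ValueError("no clade map available for density sampling")
    return dict(clades)


def density_experiment(alignment: ProteinAlignment, master_timetree: TimeTree,
                       focal: str, model: PoissonGI | None = None,
                       densities=(1, 2, 3, 4), clades=None,
                       replicates: int = 100, seed: int = 0,
                       sites: list[int] | None = None) -> pd.DataFrame:
    """Density sampling: EP with 1..4 random taxa retained per clade.

    For each density, ``replicates`` random subsamples are drawn (the
    focal species forced in; each clade — the outgroup group included —
    contributes ``density`` random members, or all of them when
    smaller), EP is computed with the known-tree method on each, and the
    per-allele mean, standard error and mean evolutionary time span are
    aggregated.  ``sites`` restricts the report to 1-based sites.
    Deterministic for a fixed seed.
    """
    clades = _clades_or_default(master_timetree, clades)
    rng = np.random.default_rng(seed)
    rows = []
    site_idx = (np.asarray(sites) - 1 if sites is not None
                else np.arange(alignment.n_sites))
    for density in densities:
        eps, spans = [], []
        for _ in range(replicates):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            subtree = subsample_density(master_timetree, clades, density,
                                        focal, sub_seed)
            epm = compute_ep_original(alignment, subtree, focal, model)
            eps.append(epm.ep[site_idx])
            spans.append(tree_span(subtree))
        eps = np.stack(eps)  # (reps, sites, 20)
        mean = np.nanmean(eps, axis=0)
        se = (np.nanstd(eps, axis=0, ddof=1) / np.sqrt(len(eps))
              if len(eps) > 1 else np.zeros_like(mean))
        for si, site0 in enumerate(site_idx):
            for ai, aa in enumerate(AMINO_ACIDS):
                rows.append({"density": density, "site": int(site0) + 1,
                             "allele": aa, "mean_ep": mean[si, ai],
                             "se_ep": se[si, ai],
                             "mean_ets": float(np.mean(spans))})
    return pd.DataFrame(rows)


def temporal_experiment(alignment: ProteinAlignment, master_timetree: TimeTree,
                        focal: str, model: PoissonGI | None = None,
                        sites: list[int] | None = None) -> pd.DataFrame:
    """Temporal sampling: EP trajectories as increasingly distant clades
    are added (iteration 1 is the focal species plus its two closest
    relatives; the final iteration is the full tree)."""
    n_anc = len(pruning_series(master_timetree, focal))
    site_idx = (np.asarray(sites) - 1 if sites is not None
                else np.arange(alignment.n_sites))
    rows = []
    for k in range(1, n_anc):
        subtree = subsample_temporal(master_timetree, focal, k)
        epm = compute_ep_original(alignment, subtree, focal, model)
        span = tree_span(subtree)
        for site0 in site_idx:
            for ai, aa in enumerate(AMINO_ACIDS):
                rows.append({"iteration": k, "n_taxa": len(subtree.leaf_names),
                             "span": span, "site": int(site0) + 1, "allele": aa,
                             "ep": float(epm.ep[site0, ai])})
    return pd.DataFrame(rows)
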