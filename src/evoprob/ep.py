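"""Evolutionary probability (EP) of protein alleles.

EP of an allele at a site is a weighted mean of tip posteriors computed
on a series of progressively pruned trees: stage 0 uses every taxon, and
each later stage drops the clade sister to the focal lineage at the next
ancestral node, until only the focal species and one outgroup lineage
remain.  Two weighting schemes are supported:

* original — the tree and divergence times are known in advance; stage
  ``i`` is weighted by the divergence time between the focal species and
  its closest remaining relative, so deeper stages weigh more;
* modified — phylogeny and (relative) times are inferred from the
  alignment itself, and stage ``i`` is weighted by the evolutionary time
  span (ETS) of the protein on the stage tree, so deeper stages weigh
  less.

Because the weights are normalised, only relative times matter: any
rescaling of the input times leaves EP unchanged.

Alleles with EP below a threshold (0.05 by convention) are classified as
evolutionarily forbidden (eForb), the rest as permissible (ePerm); an
eForb segregating at global allele frequency >= 5% is a candidate
adaptive polymorphism (CAP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .alignment import AA_INDEX, AMINO_ACIDS, ProteinAlignment
from .model import PoissonGI
from .posterior import fit_branch_lengths, fit_model_and_lengths, tip_posterior_matrix
from .trees import (TimeTree, positional_time_spans_batch, prune_to,
                    pruning_series)

__all__ = [
    "EPMatrix", "VariantRecord", "ep_from_stages", "compute_ep_original",
    "compute_ep_modified", "classify", "detect_caps", "codon_missense_rate",
    "expected_missense_mutations", "read_variants_tsv",
]

EFORB_THRESHOLD = 0.05
CAP_AF_CUTOFF = 0.05


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class EPMatrix:
    """Per-site, per-allele EP values for one protein.

    ``ep`` and ``pp0`` are (n_sites × 20) over ``AMINO_ACIDS``; rows of
    ``ep`` are NaN where ``insufficient`` is set (fewer than two valid
    non-focal residues at stage 0, i.e. no evolutionary information).
    ``weights`` are the normalised stage weights actually used.
    """

    protein: str
    focal: str
    method: str  # "original" | "modified" | "reltime-only"
    ep: np.ndarray
    pp0: np.ndarray
    weights: np.ndarray
    stage_times: np.ndarray
    insufficient: np.ndarray
    pp_stages: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return self.ep.shape[0]

    @property
    def n_stages(self) -> int:
        return len(self.weights)

    def ep_of(self, site: int, allele: str) -> float:
        """EP of ``allele`` at 1-based ``site``."""
        return float(self.ep[site - 1, AA_INDEX[allele]])

    def to_frame(self) -> pd.DataFrame:
        sites = np.repeat(np.arange(1, self.n_sites + 1), 20)
        alleles = np.tile(list(AMINO_ACIDS), self.n_sites)
        return pd.DataFrame({
            "protein": self.protein,
            "site": sites,
            "allele": alleles,
            "EP": self.ep.ravel(),
            "PP_0": self.pp0.ravel(),
            "n_stages": self.n_stages,
            "method": self.method,
        })

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# evoprob EP matrix; protein={self.protein} focal={self.focal} "
                     f"method={self.method}; sites are 1-based\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


@dataclass(frozen=True)
class VariantRecord:
    """A segregating missense variant: protein, 1-based site, reference
    and alternate residues, and the global allele frequency of the
    alternate allele."""

    protein: str
    site: int
    ref: str
    alt: str
    af: float

    def __post_init__(self):
        if self.ref not in AA_INDEX or self.alt not in AA_INDEX:
            raise ValueError(f"alleles must be one of the 20 amino acids: {self}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical: {self}")
        if not (0.0 <= self.af <= 1.0):
            raise ValueError(f"allele frequency outside [0,1]: {self}")


def read_variants_tsv(path) -> list[VariantRecord]:
    """Read a variant table (TSV with header ``protein site ref alt af``,
    1-based sites, ``#`` comment lines)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"protein", "site", "ref", "alt", "af"}
    if not required <= set(df.columns):
        raise ValueError(f"variant TSV needs columns {sorted(required)}")
    return [VariantRecord(r.protein, int(r.site), r.ref, r.alt, float(r.af))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# The weighted-mean formulation
# ---------------------------------------------------------------------------

def ep_from_stages(pp: list[np.ndarray], weights) -> np.ndarray:
    """EP as the weighted mean of stage posteriors.

    ``pp`` holds one 20-vector (or (n_sites × 20) matrix) per stage and
    ``weights`` the corresponding times; the result is invariant under
    rescaling all weights by any positive constant.
    """
    weights = np.asarray(weights, dtype=float)
    if len(pp) != len(weights) or len(pp) == 0:
        raise ValueError("need one weight per posterior, at least one stage")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must have a positive sum")
    norm = weights / total
    stacked = np.stack([np.asarray(p, dtype=float) for p in pp])
    return np.tensordot(norm, stacked, axes=(0, 0))


# ---------------------------------------------------------------------------
# EP pipelines
# ---------------------------------------------------------------------------

def _stage_posteriors(stages, alignment: ProteinAlignment, focal: str,
                      model: PoissonGI, fitted_full: TimeTree,
                      refit_per_stage: bool = True) -> np.ndarray:
    """(n_stages, n_sites, 20) tip posteriors, one slice per pruning
    stage.  Stage branch lengths start from the full-tree ML fit
    restricted to the stage's taxa and are re-optimised per stage."""
    pps = []
    for st in stages:
        leaves = st.tree.leaf_set
        sub = prune_to(fitted_full, leaves)
        if refit_per_stage and len(leaves) > 2:
            sub, _ = fit_branch_lengths(sub, alignment, model, initial=None)
        pp, _ = tip_posterior_matrix(sub, alignment, focal, model)
        pps.append(pp)
    return np.stack(pps)


def _finalize(protein, focal, method, pps, weights, stage_times, alignment,
              tree_taxa, keep_pp_stages) -> EPMatrix:
    ep = ep_from_stages(list(pps), weights)
    pp0 = pps[0]
    # sites with <2 valid non-focal residues at stage 0 carry no signal
    rows = [alignment.row(t) for t in tree_taxa if t != focal]
    n_valid = alignment.valid[rows].sum(axis=0)
    insufficient = n_valid < 2
    ep = ep.copy()
    ep[insufficient] = np.nan
    w = np.asarray(weights, dtype=float)
    return EPMatrix(protein, focal, method, ep, pp0, w / w.sum(),
                    np.asarray(stage_times, dtype=float), insufficient,
                    pps if keep_pp_stages else None)


def compute_ep_original(alignment: ProteinAlignment, master_timetree: TimeTree,
                        focal: str, model: PoissonGI | None = None,
                        protein: str = "protein", refit_per_stage: bool = True,
                        keep_pp_stages: bool = False) -> EPMatrix:
    """EP with a known timetree: stage weights are the divergence times
    between the focal species and its closest remaining relative.

    Branch lengths on each stage topology are fitted to the alignment by
    maximum likelihood (a timetree has no substitution scale); when
    ``model`` is None, alpha and p_inv are estimated from the full
    alignment first and reused at every stage.
    """
    if focal not in alignment._index:
        raise KeyError(f"focal taxon {focal!r} not in alignment")
    missing = master_timetree.leaf_set - set(alignment.names)
    if missing:
        raise ValueError(f"timetree taxa missing from alignment: {sorted(missing)}")
    stages = pruning_series(master_timetree, focal)
    weights = np.array([st.t_time for st in stages], dtype=float)
    fitted, model, _ = fit_model_and_lengths(alignment, stages[0].tree, model)
    pps = _stage_posteriors(stages, alignment, focal, model, fitted,
                            refit_per_stage)
    return _finalize(protein, focal, "original", pps, weights, weights,
                     alignment, master_timetree.leaf_set, keep_pp_stages)


def compute_ep_modified(alignment: ProteinAlignment, focal: str,
                        model: PoissonGI | None = None,
                        topology: TimeTree | None = None,
                        outgroup: str | set[str] | None = None,
                        protein: str = "protein", refit_per_stage: bool = True,
                        keep_pp_stages: bool = False, seed: int = 0) -> EPMatrix:
    """EP with phylogeny and relative times inferred from the alignment.

    When ``topology`` is given only the divergence times are inferred
    (method tag ``reltime-only``); otherwise the topology is inferred
    first (tag ``modified``).  Stage ``i`` is weighted by the protein's
    evolutionary time span (ETS) on the stage-``i`` tree — the mean over
    sites of the stage tree restricted to taxa with a valid residue — so
    later, smaller stages contribute less.
    """
    from .phylo import infer_topology, reltime, default_outgroup

    if alignment.n_taxa < 3:
        raise ValueError("need at least 3 sequences")
    if focal not in alignment._index:
        raise KeyError(f"focal taxon {focal!r} not in alignment")
    if not alignment.valid.any(axis=0).any():
        raise ValueError("alignment has no informative columns")

    method = "reltime-only" if topology is not None else "modified"
    if outgroup is None:
        outgroup = default_outgroup(alignment, focal)
        warnings.warn(f"no outgroup given; using most divergent taxon {outgroup!r}",
                      stacklevel=2)
    outgroup_set = {outgroup} if isinstance(outgroup, str) else set(outgroup)

    if topology is None:
        result = infer_topology(alignment, model, outgroup=outgroup_set, seed=seed)
        fitted, model = result.ml_tree, result.model
    else:
        fitted, model, _ = fit_model_and_lengths(alignment, topology, model)
    rel = reltime(fitted, outgroup_set)

    stages = pruning_series(rel, focal)
    taxa = sorted(rel.leaf_set)
    rows = [alignment.row(t) for t in taxa]
    valid = alignment.valid[rows]
    ets = []
    for st in stages:
        in_stage = np.array([t in st.tree.leaf_set for t in taxa])
        spans = positional_time_spans_batch(st.tree, valid[in_stage],
                                            [t for t, m in zip(taxa, in_stage) if m])
        st.t_ets = float(spans.mean())
        ets.append(st.t_ets)
    weights = np.asarray(ets)

    pps = _stage_posteriors(stages, alignment, focal, model, fitted,
                            refit_per_stage)
    return _finalize(protein, focal, method, pps, weights,
                     np.array([st.t_time if st.t_time is not None else np.nan
                               for st in stages]),
                     alignment, rel.leaf_set, keep_pp_stages)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify(ep: EPMatrix, threshold: float = EFORB_THRESHOLD) -> pd.DataFrame:
    """Label every allele at every informative site: eForb iff
    EP < threshold (strict), ePerm otherwise.  Returns a tidy frame with
    a ``cap`` column initialised to False (see :func:`detect_caps`)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    df = ep.to_frame()
    df = df[~np.isnan(df["EP"])].copy()
    df["label"] = np.where(df["EP"] < threshold, "eForb", "ePerm")
    df["cap"] = False
    return df


def detect_caps(classifications: pd.DataFrame, variants: list[VariantRecord],
                af_cutoff: float = CAP_AF_CUTOFF) -> pd.DataFrame:
    """Flag candidate adaptive polymorphisms: alternate alleles that are
    eForbs segregating at global allele frequency >= ``af_cutoff``
    (inclusive).  Raises on variants at sites absent from the
    classification table, listing the offending records."""
    df = classifications.copy()
    known = set(zip(df["protein"], df["site"]))
    bad = [v for v in variants if (v.protein, v.site) not in known]
    if bad:
        raise ValueError(f"variants at sites not covered by EP matrix: {bad}")
    key = {(p, s, a): i for i, (p, s, a)
           in enumerate(zip(df["protein"], df["site"], df["allele"]))}
    cap = df["cap"].to_numpy().copy()
    labels = df["label"].to_numpy()
    for v in variants:
        i = key.get((v.protein, v.site, v.alt))
        if i is not None and labels[i] == "eForb" and v.af >= af_cutoff:
            cap[i] = True
    df["cap"] = cap
    return df


# ---------------------------------------------------------------------------
# Mutation-count arithmetic
# ---------------------------------------------------------------------------

_NUCS = "ACGT"


def codon_missense_rate(per_site_rate: float, code: str | int = "Standard",
                        average_over: str = "sense",
                        change_weights: dict[str, float] | None = None) -> float:
    """Missense mutation rate per codon per year from a per-nucleotide
    mutation rate.

    For each codon the fraction of its 9 single-nucleotide changes that
    replace the encoded amino acid with a different one (changes to stop
    codons are nonsense, not missense) is computed, averaged over sense
    codons (or all 64 with ``average_over='all'``, where stop codons
    contribute 0), and multiplied by ``3 × per_site_rate``.  Custom
    nucleotide-change weights may be supplied as ``{"A>C": w, ...}``;
    by default every change is equally likely.  ``code`` may also be any
    object with ``forward_table`` and ``stop_codons`` attributes (e.g. a
    Biopython codon table, or a hand-built toy table).
    """
    if per_site_rate < 0:
        raise ValueError("per-site rate must be non-negative")
    if average_over not in ("sense", "all"):
        raise ValueError("average_over must be 'sense' or 'all'")
    if hasattr(code, "forward_table") and hasattr(code, "stop_codons"):
        table = code
    else:
        try:
            if isinstance(code, int):
                table = CodonTable.unambiguous_dna_by_id[code]
            else:
                table = CodonTable.unambiguous_dna_by_name[code]
        except KeyError:
            raise ValueError(f"unknown codon translation table: {code!r}") from None

    def w(frm: str, to: str) -> float:
        if change_weights is None:
            return 1.0
        return float(change_weights.get(f"{frm}>{to}", 0.0))

    forward = table.forward_table
    stops = set(table.stop_codons)
    codons = ["".join(c) for c in
              (a + b + d for a in _NUCS for b in _NUCS for d in _NUCS)]
    fractions = []
    for codon in codons:
        if codon in stops:
            if average_over == "all":
                fractions.append(0.0)
            continue
        if codon not in forward:  # not part of this (possibly toy) code
            continue
        aa = forward[codon]
        num = den = 0.0
        for pos in range(3):
            for nuc in _NUCS:
                if nuc == codon[pos]:
                    continue
                mutant = codon[:pos] + nuc + codon[pos + 1:]
                weight = w(codon[pos], nuc)
                den += weight
                if forward.get(mutant, aa) != aa:
                    num += weight
        fractions.append(num / den if den > 0 else 0.0)
    return per_site_rate * 3.0 * float(np.mean(fractions))


def expected_missense_mutations(rate: float, total_time: float) -> float:
    """Expected missense mutations at a codon over the summed time of a
    tree: simply ``rate × total_time``."""
    if rate < 0 or total_time < 0:
        raise ValueError("rate and time must be non-negative")
    return rate * total_time
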