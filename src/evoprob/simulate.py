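"""Synthetic data: alignments evolved on a timetree under Poisson+G+I.

Every other module is exercised on output of this generator, so the
package is testable end to end without any downloads.  The bundled
46-taxon vertebrate fixture reproduces the topology used for human EP
calculations (human focal lineage with exactly 15 pruning steps, seven
density-sampling clades A–G plus the lamprey outgroup); its node ages
are synthetic defaults on the scale of the published vertebrate
timescale, not measured data, and every age-dependent check in the test
suite is either scale-invariant or tolerance-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, ProteinAlignment
from .model import N_STATES, PoissonGI, poisson_decay
from .trees import Node, TimeTree, pruning_series, tree_span

__all__ = ["SimulationConfig", "simulate_alignment", "vertebrate_fixture",
           "neutral_ep_calibration", "NeutralCalibration", "DEFAULT_AGES",
           "VERTEBRATE_CLADES"]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of one simulated alignment.

    ``rate`` is in substitutions/site per unit of the tree's branch
    lengths (per million years for the vertebrate fixture); the default
    5e-4 /site/My is a mid-range vertebrate protein rate.  Gaps are
    injected post hoc as contiguous per-taxon blocks — emulating the
    clustered alignment gaps and missing data of real alignments — not
    evolved under an indel model.
    """

    timetree: TimeTree
    rate: float = 5e-4
    alpha: float = 1.0
    p_inv: float = 0.05
    K: int = 5
    n_sites: int = 1000
    gap_fraction: float = 0.0
    mean_gap_block: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not (0.0 <= self.gap_fraction < 1.0):
            raise ValueError("gap_fraction must lie in [0, 1)")
        if not (0.0 <= self.p_inv <= 1.0):
            raise ValueError("p_inv must lie in [0, 1]")

    @property
    def model(self) -> PoissonGI:
        """Model for inference on the simulated data (p_inv capped just
        below 1, which only matters for the degenerate all-invariant
        simulation)."""
        return PoissonGI(self.alpha, min(self.p_inv, 0.999), self.K)


def simulate_alignment(config: SimulationConfig) -> tuple[ProteinAlignment, pd.DataFrame]:
    """Evolve alignment columns along the timetree.

    Root states are uniform over the 20 residues; each site draws a rate
    (0 with probability ``p_inv``, otherwise one of the K discrete-Gamma
    multipliers) and states evolve branch-wise under the Poisson model.
    Returns the alignment (gaps injected per config) and a truth table
    with each site's rate category and multiplier.
    """
    rng = np.random.default_rng(config.seed)
    tree = config.timetree
    ns = config.n_sites

    cats = np.where(rng.random(ns) < config.p_inv, -1,
                    rng.integers(0, config.K, size=ns))
    if config.p_inv >= 1.0:
        gamma_mult = np.zeros(config.K)
    else:
        from .model import discretize_gamma
        gamma_mult = discretize_gamma(config.alpha, config.K) / (1.0 - config.p_inv)
    multipliers = np.concatenate([[0.0], gamma_mult])
    site_rates = multipliers[cats + 1]

    states: dict[int, np.ndarray] = {}
    order = list(tree.preorder())
    states[id(tree.root)] = rng.integers(0, N_STATES, size=ns)
    rows: dict[str, np.ndarray] = {}
    for node in order:
        if node is tree.root:
            pass
        else:
            parent = states[id(node.parent)]
            E = poisson_decay(config.rate * node.length, 1.0) ** site_rates
            keep = rng.random(ns) < E
            fresh = rng.integers(0, N_STATES, size=ns)
            states[id(node)] = np.where(keep, parent, fresh)
        if node.is_leaf:
            rows[node.name] = states[id(node)]

    names = tree.leaf_names
    codes = np.stack([rows[n] for n in names]).astype(np.int8)

    if config.gap_fraction > 0:
        for i in range(len(names)):
            target = int(round(config.gap_fraction * ns))
            gapped = np.zeros(ns, dtype=bool)
            while gapped.sum() < target:
                start = int(rng.integers(0, ns))
                length = 1 + int(rng.geometric(1.0 / config.mean_gap_block))
                gapped[start:start + length] = True
            # trim overshoot from the end of the last block
            extra = int(gapped.sum()) - target
            if extra > 0:
                idx = np.nonzero(gapped)[0]
                gapped[idx[-extra:]] = False
            codes[i, gapped] = -1

    truth = pd.DataFrame({
        "site": np.arange(1, ns + 1),
        "category": np.where(cats < 0, "invariant", cats.astype(str)),
        "rate": site_rates,
    })
    return ProteinAlignment(names, codes), truth


# ---------------------------------------------------------------------------
# The 46-taxon vertebrate fixture
# ---------------------------------------------------------------------------

# Synthetic default node ages in million years (plausible round values on
# the vertebrate timescale; fixture values, not measurements).
DEFAULT_AGES: dict[str, float] = {
    "human_chimp": 7, "homininae": 9, "hominidae": 16, "owm": 19,
    "catarrhini": 29, "simiiformes": 43, "strepsirrhini": 60,
    "haplorrhini": 65, "primates": 74,
    "murinae": 21, "myomorpha": 69, "rodents_core": 73, "rodentia": 75,
    "lagomorpha": 62, "glires": 82, "scandentia_glires": 88,
    "euarchontoglires": 90,
    "whippomorpha": 56, "cetartiodactyla": 65, "carnivora": 55,
    "zooamata": 78, "chiroptera": 63, "pegasoferae": 80,
    "laurasiatheria_core": 85, "eulipotyphla": 65, "laurasiatheria": 96,
    "boreoeutheria": 97,
    "paenungulata": 65, "afrotheria": 80, "xenarthra": 70,
    "atlantogenata": 95, "eutheria": 102,
    "marsupialia": 80, "theria": 160, "mammalia": 180,
    "neognathae": 100, "sauropsida": 280, "amniota": 312,
    "tetrapoda": 352,
    "tetraodontidae": 60, "atherinomorpha": 110, "euteleostei": 150,
    "teleostei": 230, "osteichthyes": 435,
    "vertebrata": 615,
}

_TOPOLOGY = (
    "vertebrata", [
        "lamprey",
        ("osteichthyes", [
            ("teleostei", [
                "zebrafish",
                ("euteleostei", [
                    ("tetraodontidae", ["tetraodon", "fugu"]),
                    ("atherinomorpha", ["stickleback", "medaka"]),
                ]),
            ]),
            ("tetrapoda", [
                "frog",
                ("amniota", [
                    ("sauropsida", [
                        ("neognathae", ["chicken", "zebra_finch"]),
                        "lizard",
                    ]),
                    ("mammalia", [
                        "platypus",
                        ("theria", [
                            ("marsupialia", ["opossum", "wallaby"]),
                            ("eutheria", [
                                ("atlantogenata", [
                                    ("afrotheria", [
                                        ("paenungulata", ["elephant", "rock_hyrax"]),
                                        "tenrec",
                                    ]),
                                    ("xenarthra", ["armadillo", "sloth"]),
                                ]),
                                ("boreoeutheria", [
                                    ("laurasiatheria", [
                                        ("eulipotyphla", ["hedgehog", "shrew"]),
                                        ("laurasiatheria_core", [
                                            ("cetartiodactyla", [
                                                "alpaca",
                                                ("whippomorpha", ["dolphin", "cow"]),
                                            ]),
                                            ("pegasoferae", [
                                                ("zooamata", [
                                                    "horse",
                                                    ("carnivora", ["cat", "dog"]),
                                                ]),
                                                ("chiroptera", ["microbat", "megabat"]),
                                            ]),
                                        ]),
                                    ]),
                                    ("euarchontoglires", [
                                        ("scandentia_glires", [
                                            "tree_shrew",
                                            ("glires", [
                                                ("rodentia", [
                                                    "squirrel",
                                                    ("rodents_core", [
                                                        "guinea_pig",
                                                        ("myomorpha", [
                                                            "kangaroo_rat",
                                                            ("murinae", ["mouse", "rat"]),
                                                        ]),
                                                    ]),
                                                ]),
                                                ("lagomorpha", ["rabbit", "pika"]),
                                            ]),
                                        ]),
                                        ("primates", [
                                            ("strepsirrhini", ["mouse_lemur", "bushbaby"]),
                                            ("haplorrhini", [
                                                "tarsier",
                                                ("simiiformes", [
                                                    "marmoset",
                                                    ("catarrhini", [
                                                        ("owm", ["rhesus", "baboon"]),
                                                        ("hominidae", [
                                                            "orangutan",
                                                            ("homininae", [
                                                                "gorilla",
                                                                ("human_chimp",
                                                                 ["human", "chimpanzee"]),
                                                            ]),
                                                        ]),
                                                    ]),
                                                ]),
                                            ]),
                                        ]),
                                    ]),
                                ]),
                            ]),
                        ]),
                    ]),
                ]),
            ]),
        ]),
    ])

VERTEBRATE_CLADES: dict[str, set[str]] = {
    "A": {"human", "chimpanzee", "gorilla", "orangutan", "rhesus", "baboon",
          "marmoset", "tarsier", "mouse_lemur", "bushbaby"},
    "B": {"tree_shrew", "mouse", "rat", "kangaroo_rat", "guinea_pig",
          "squirrel", "rabbit", "pika"},
    "C": {"alpaca", "dolphin", "cow", "horse", "cat", "dog", "microbat",
          "megabat", "hedgehog", "shrew"},
    "D": {"elephant", "rock_hyrax", "tenrec", "armadillo", "sloth"},
    "E": {"opossum", "wallaby", "platypus"},
    "F": {"chicken", "zebra_finch", "lizard"},
    "G": {"frog", "tetraodon", "fugu", "stickleback", "medaka", "zebrafish"},
    "outgroup": {"lamprey"},
}


def vertebrate_fixture(ages: dict[str, float] | None = None) -> TimeTree:
    """The 46-taxon vertebrate tree with clade annotations.

    ``ages`` may override any subset of the named internal-node ages (in
    million years); an age table in which a parent is not strictly older
    than each child is rejected.
    """
    table = dict(DEFAULT_AGES)
    if ages:
        unknown = set(ages) - set(table)
        if unknown:
            raise ValueError(f"unknown internal nodes: {sorted(unknown)}")
        table.update(ages)

    def build(spec, parent_age: float | None) -> Node:
        if isinstance(spec, str):
            if parent_age is None or parent_age <= 0:
                raise ValueError(f"leaf {spec!r} needs a positive parent age")
            return Node(spec, float(parent_age))
        name, children = spec
        age = float(table[name])
        if parent_age is not None:
            if age >= parent_age:
                raise ValueError(
                    f"node {name!r} (age {age}) must be younger than its parent "
                    f"(age {parent_age})")
            node = Node(name, parent_age - age)
        else:
            node = Node(name, None)
        for ch in children:
            node.add_child(build(ch, age))
        return node

    root = build(_TOPOLOGY, None)
    return TimeTree(root, is_timetree=True, clade_map=VERTEBRATE_CLADES)


# ---------------------------------------------------------------------------
# Neutral calibration of the eForb threshold
# ---------------------------------------------------------------------------

@dataclass
class NeutralCalibration:
    """Fraction of neutrally simulated sites whose focal-tip residue got
    EP < 0.05; ``deep_enough`` is False when the tree spans too little
    time for the false-eForb rate to be meaningful."""

    fraction: float
    n_sites: int
    span: float
    deep_enough: bool


def neutral_ep_calibration(fixture: TimeTree | None = None, rate: float = 5e-4,
                           n_sites: int = 2000, seed: int = 0,
                           focal: str = "human", alpha: float = 1.0,
                           p_inv: float = 0.05,
                           min_span: float = 5e3) -> NeutralCalibration:
    """Simulate neutral evolution and measure how often the allele
    actually present at the focal tip is called evolutionarily forbidden.

    On a deep, well-sampled tree this fraction should stay below 1%,
    which is what motivates the EP < 0.05 threshold.
    """
    from .ep import compute_ep_original

    tree = vertebrate_fixture() if fixture is None else fixture
    span = tree_span(tree)
    cfg = SimulationConfig(tree, rate=rate, alpha=alpha, p_inv=p_inv,
                           n_sites=n_sites, seed=seed)
    aln, _ = simulate_alignment(cfg)
    epm = compute_ep_original(aln, tree, focal)
    frow = aln.codes[aln.row(focal)]
    usable = (~epm.insufficient) & (frow >= 0)
    ep_true = epm.ep[np.arange(aln.n_sites), frow.clip(min=0)]
    fraction = float((ep_true[usable] < 0.05).mean()) if usable.any() else float("nan")
    return NeutralCalibration(fraction, int(usable.sum()), span, span >= min_span)
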