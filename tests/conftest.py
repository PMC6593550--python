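"""Shared fixtures: small trees and module-scoped simulated datasets.

The heavier simulated datasets are session-scoped so that parameter
recovery, concordance and acceptance checks share one simulation."""

import numpy as np
import pytest

from evoprob import PoissonGI, read_newick
from evoprob.simulate import SimulationConfig, simulate_alignment, vertebrate_fixture

# deep clock-like 8-taxon tree (times in My), OUT as outgroup
EIGHT_TAXON_NEWICK = ("((((A:10,B:10):10,(C:15,D:15):5):20,"
                      "((E:20,F:20):10,G:30):10):60,OUT:100);")


@pytest.fixture(scope="session")
def eight_taxon_tree():
    return read_newick(EIGHT_TAXON_NEWICK)


@pytest.fixture(scope="session")
def fixture46():
    return vertebrate_fixture()


@pytest.fixture(scope="session")
def recovery_sim(eight_taxon_tree):
    """2000 sites simulated with known alpha=1.0, p_inv=0.2 on the deep
    8-taxon tree; used for rate-parameter and branch-length recovery."""
    cfg = SimulationConfig(eight_taxon_tree, rate=5e-3, alpha=1.0, p_inv=0.2,
                           n_sites=2000, seed=42)
    aln, truth = simulate_alignment(cfg)
    return cfg, aln, truth


@pytest.fixture(scope="session")
def fixture46_sim():
    """A small alignment on the 46-taxon fixture (deep tree, modest
    length) for conserved-site and classification checks."""
    tree = vertebrate_fixture()
    cfg = SimulationConfig(tree, rate=5e-4, alpha=1.0, p_inv=0.3,
                           n_sites=60, seed=11)
    aln, truth = simulate_alignment(cfg)
    return tree, cfg, aln, truth


@pytest.fixture(scope="session")
def fixture46_ep(fixture46_sim):
    """Original-method EP on the 46-taxon simulated alignment."""
    from evoprob.ep import compute_ep_original
    tree, cfg, aln, truth = fixture46_sim
    epm = compute_ep_original(aln, tree, "human", keep_pp_stages=True)
    return tree, aln, truth, epm
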