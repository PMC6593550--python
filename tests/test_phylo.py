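"""Distance estimation, topology search, and relative-time transformation."""

import numpy as np
import pytest

from evoprob.alignment import ProteinAlignment
from evoprob.likelihood import TreeLikelihood
from evoprob.model import PoissonGI
from evoprob.phylo import (default_outgroup, infer_topology,
                           pairwise_distances, reltime, root_on_outgroup)
from evoprob.posterior import fit_branch_lengths
from evoprob.simulate import SimulationConfig, simulate_alignment
from evoprob.trees import (_bipartition_lengths, branch_score_distance,
                           read_newick, tree_span, write_newick)

CLOCK8 = ("((((A:10,B:10):10,(C:15,D:15):5):20,"
          "((E:20,F:20):10,G:30):10):60,OUT:100);")


def _topology_key(tree):
    return set(_bipartition_lengths(tree).keys())


class TestPairwiseDistances:
    def test_identical_sequences_zero(self):
        aln = ProteinAlignment.from_sequences(
            {"A": "AWCD", "B": "AWCD", "C": "AWCD"})
        D = pairwise_distances(aln, PoissonGI(1.0, 0.0, 5))
        assert np.allclose(D.to_numpy(), 0.0)

    def test_large_alpha_approaches_log_correction(self):
        rng = np.random.default_rng(0)
        seqs = {"A": "".join(rng.choice(list("ACDEFGHIK"), 400))}
        seqs["B"] = "".join(
            c if rng.random() > 0.1 else "W" for c in seqs["A"])
        seqs["C"] = seqs["A"]
        aln = ProteinAlignment.from_sequences(seqs)
        p = np.mean([a != b for a, b in zip(seqs["A"], seqs["B"])])
        expected = -(19 / 20) * np.log(1 - (20 / 19) * p)
        D = pairwise_distances(aln, PoissonGI(1e6, 0.0, 5))
        assert D.loc["A", "B"] == pytest.approx(expected, rel=1e-3)

    def test_simulated_distance_recovered(self):
        tree = read_newick("((A:75,B:75):10,C:85);")
        cfg = SimulationConfig(tree, rate=2e-3, alpha=1.0, p_inv=0.0,
                               n_sites=2000, seed=8)
        aln, _ = simulate_alignment(cfg)
        D = pairwise_distances(aln, PoissonGI(1.0, 0.0, 5))
        assert D.loc["A", "B"] == pytest.approx(0.3, abs=0.05)

    def test_no_shared_columns_is_error(self):
        aln = ProteinAlignment.from_sequences(
            {"A": "AW--", "B": "--CD", "C": "AWCD"})
        with pytest.raises(ValueError, match="A.*B|B.*A"):
            pairwise_distances(aln, PoissonGI(1.0, 0.0, 5))

    def test_saturated_pair_capped(self):
        rng = np.random.default_rng(1)
        seqs = {"A": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 300)),
                "B": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 300))}
        # force near-total mismatch
        seqs["B"] = "".join("W" if a != "W" else "Y" for a in seqs["A"])
        seqs["C"] = seqs["A"]
        aln = ProteinAlignment.from_sequences(seqs)
        with pytest.warns(UserWarning, match="saturated"):
            D = pairwise_distances(aln, PoissonGI(0.5, 0.0, 5))
        assert np.isfinite(D.loc["A", "B"])


class TestInferTopology:
    def test_three_taxa_trivial(self):
        aln = ProteinAlignment.from_sequences(
            {"A": "AWCDEFGHIK", "B": "AWCDEFGHIW", "C": "AVCDEFGHIK"})
        res = infer_topology(aln, PoissonGI(1.0, 0.0, 5), outgroup="C")
        assert set(res.topology.leaf_names) == {"A", "B", "C"}

    def test_recovery_on_strong_signal(self):
        """True topology recovered in >=90% of clock-like replicates with
        ample signal (500 sites, mid-range rate)."""
        true = read_newick(CLOCK8)
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(true, rate=4e-3, alpha=1.0, p_inv=0.1,
                                   n_sites=500, seed=300 + seed)
            aln, _ = simulate_alignment(cfg)
            res = infer_topology(aln, None, outgroup="OUT")
            hits += _topology_key(res.ml_tree) == _topology_key(true)
        assert hits >= 9

    def test_nni_never_decreases_likelihood(self):
        true = read_newick(CLOCK8)
        cfg = SimulationConfig(true, rate=4e-3, alpha=1.0, p_inv=0.1,
                               n_sites=300, seed=77)
        aln, _ = simulate_alignment(cfg)
        model = PoissonGI(1.0, 0.1, 5)
        res_nni = infer_topology(aln, model, outgroup="OUT")
        res_nj = infer_topology(aln, model, outgroup="OUT", nni=False)
        assert res_nni.log_likelihood >= res_nj.log_likelihood - 1e-6

    def test_default_outgroup_warns(self):
        true = read_newick(CLOCK8)
        cfg = SimulationConfig(true, rate=4e-3, n_sites=200, seed=2)
        aln, _ = simulate_alignment(cfg)
        with pytest.warns(UserWarning, match="outgroup"):
            infer_topology(aln, PoissonGI(1.0, 0.0, 5), nni=False)
        assert default_outgroup(aln, "A") == "OUT"


class TestReltime:
    def test_clock_input_recovers_depth_proportions(self):
        # an ML tree that is exactly clock-like: relative ages must be
        # proportional to node depths and leaves at age 0
        tree = read_newick(CLOCK8)
        ml = tree.copy()
        for n in ml.preorder():
            if n.length is not None:
                n.length *= 1e-3
        ml.is_timetree = False
        rel = reltime(ml, "OUT")
        ages = rel.ages()
        true_ages = tree.ages()
        root_age = true_ages[tree.root]
        want = {lf.name: 0.0 for lf in tree.leaves()}
        got_by_leafset = {
            frozenset(l.name for l in _leaves(n)): a for n, a in ages.items()}
        for node, a in true_ages.items():
            key = frozenset(l.name for l in _leaves(node))
            assert got_by_leafset[key] == pytest.approx(a / root_age, abs=1e-9)

    def test_scale_invariance(self):
        ml = read_newick("((A:0.1,B:0.14):0.05,(C:0.2,OUT:0.4):0.05);",
                         is_timetree=False)
        r1 = reltime(ml, "OUT")
        scaled = ml.copy()
        for n in scaled.preorder():
            if n.length is not None:
                n.length *= 7.3
        r2 = reltime(scaled, "OUT")
        a1, a2 = r1.ages(), r2.ages()
        for n1, n2 in zip(r1.preorder(), r2.preorder()):
            assert a1[n1] == pytest.approx(a2[n2], abs=1e-12)

    def test_hand_derived_two_to_one_rate_ratio(self):
        # ingroup: ((A:2,B:2):1,C:3); the A/B lineage pair has mean tip
        # depth 2 below U, so D(U)=2, and D(R)=((2+1)+3)/2=3;
        # t(U)/t(R) = D(U)/(D(U)+b_U) = 2/3
        ml = read_newick("(((A:2,B:2):1,C:3):1,OUT:4);", is_timetree=False)
        rel = reltime(ml, "OUT")
        ages = rel.ages()
        by_leafset = {frozenset(l.name for l in _leaves(n)): ages[n]
                      for n in rel.preorder()}
        t_r = by_leafset[frozenset("ABC")]
        t_u = by_leafset[frozenset("AB")]
        assert t_u / t_r == pytest.approx(2 / 3)

    def test_root_age_normalised_and_ultrametric(self):
        ml = read_newick("((A:0.1,B:0.3):0.05,(C:0.2,OUT:0.4):0.07);",
                         is_timetree=False)
        rel = reltime(ml, "OUT")
        ages = rel.ages()
        assert ages[rel.root] == pytest.approx(1.0)
        depths = rel.depths()
        for lf in rel.leaves():
            assert depths[lf] == pytest.approx(1.0, abs=1e-9)

    def test_outgroup_not_monophyletic(self):
        ml = read_newick("((A:1,OUT1:1):1,(OUT2:1,B:1):1);", is_timetree=False)
        with pytest.raises(ValueError, match="monophyletic"):
            reltime(ml, {"OUT1", "OUT2"})


def _leaves(node):
    out, stack = [], [node]
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            out.append(cur)
        stack.extend(cur.children)
    return out


class TestEndToEnd:
    def test_tree_distance_shrinks_with_alignment_length(self):
        # compared on the ingroup: the split of the outgroup edge around
        # the root is not identifiable from data, so its (constant)
        # contribution would mask the sampling-noise trend
        from evoprob.trees import prune_to
        true = read_newick(CLOCK8)
        ingroup = true.leaf_set - {"OUT"}
        true_in = prune_to(true, ingroup)
        dists = []
        for n_sites, seed in ((300, 21), (2000, 22)):
            cfg = SimulationConfig(true, rate=4e-3, alpha=1.0, p_inv=0.1,
                                   n_sites=n_sites, seed=seed)
            aln, _ = simulate_alignment(cfg)
            res = infer_topology(aln, None, outgroup="OUT")
            rel_in = prune_to(res.relative_timetree, ingroup)
            dists.append(branch_score_distance(true_in, rel_in,
                                               normalize=True))
        assert dists[1] < dists[0]

    def test_faster_rates_increase_tree_distance(self):
        """With short alignments, faster evolution gives noisier trees
        (monotone trend over three rate levels)."""
        true = read_newick(CLOCK8)
        dists = []
        for rate in (1e-3, 8e-3, 4e-2):
            acc = 0.0
            for seed in (31, 32, 33):
                cfg = SimulationConfig(true, rate=rate, alpha=1.0,
                                       p_inv=0.0, n_sites=150, seed=seed)
                aln, _ = simulate_alignment(cfg)
                res = infer_topology(aln, None, outgroup="OUT", nni=False)
                acc += branch_score_distance(true, res.relative_timetree,
                                             normalize=True)
            dists.append(acc / 3)
        assert dists[0] < dists[-1]
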