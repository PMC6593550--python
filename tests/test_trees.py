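"""Tree model: Newick I/O, pruning, time spans, distances, subsampling."""

import numpy as np
import pytest

from evoprob.trees import (NewickError, TimeTree, branch_score_distance,
                           positional_time_span, positional_time_spans_batch,
                           prune_to, pruning_series, read_newick,
                           residue_time_span, subsample_density,
                           subsample_temporal, tree_span, write_newick)


def _random_tree(rng, n_leaves, max_len=5.0):
    """Random rooted binary tree with random branch lengths, built by
    successive cherry joins (independent of the package's tree logic)."""
    from evoprob.trees import Node
    nodes = [Node(f"t{i}", None) for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = Node(None, None)
        for k in (j, i):
            child = nodes.pop(k)
            child.length = float(rng.uniform(0.05, max_len))
            b.add_child(child)
        nodes.append(b)
    return TimeTree(nodes[0], is_timetree=True)


def _path_lengths(tree):
    """Brute-force leaf-to-leaf path lengths via root-to-node depths."""
    depths = tree.depths()
    leaves = tree.leaves()
    anc = {}
    for lf in leaves:
        chain, node = [], lf
        while node is not None:
            chain.append(node)
            node = node.parent
        anc[lf.name] = chain
    out = {}
    for a in leaves:
        for b in leaves:
            if a.name >= b.name:
                continue
            common = next(n for n in anc[a.name] if n in anc[b.name])
            out[(a.name, b.name)] = depths[a] + depths[b] - 2 * depths[common]
    return out


class TestNewick:
    @pytest.mark.parametrize("nwk", [
        "((A:1,B:1):1,C:2);",
        "(A:0.5,(B:0.25,C:0.25):0.25);",
        "((X:1.5,Y:0.5):2,(Z:1,W:3):0.1);",
    ])
    def test_round_trip(self, nwk):
        t = read_newick(nwk)
        t2 = read_newick(write_newick(t))
        assert t.leaf_names == t2.leaf_names
        for a, b in zip(t.preorder(), t2.preorder()):
            if a.length is not None:
                assert b.length == pytest.approx(a.length)

    def test_three_leaf_ages(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        assert sorted(t.leaf_names) == ["A", "B", "C"]
        assert t.age_of(t.root) == pytest.approx(2.0)

    def test_missing_lengths_flagged(self):
        t = read_newick("(A,B);")
        assert not t.has_branch_lengths()
        assert not t.is_timetree

    def test_unbalanced_is_parse_error(self):
        with pytest.raises(NewickError):
            read_newick("((A:1,B:1):1,C:2;")

    def test_duplicate_leaf_rejected(self):
        with pytest.raises(NewickError):
            read_newick("((A:1,A:1):1,C:2);")


class TestPrune:
    def test_path_sum_preserved_small(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        p = prune_to(t, {"A", "C"})
        assert sorted(p.leaf_names) == ["A", "C"]
        assert tree_span(p) == pytest.approx(4.0)

    def test_identity(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        p = prune_to(t, set(t.leaf_names))
        assert write_newick(p) == write_newick(t)

    def test_errors(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError):
            prune_to(t, {"A"})
        with pytest.raises(KeyError):
            prune_to(t, {"A", "nope"})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pairwise_paths_preserved_random(self, seed):
        rng = np.random.default_rng(seed)
        t = _random_tree(rng, 12)
        full = _path_lengths(t)
        keep = set(rng.choice(t.leaf_names, 6, replace=False))
        p = prune_to(t, keep)
        pruned = _path_lengths(p)
        for pair, d in pruned.items():
            assert d == pytest.approx(full[pair], rel=1e-12)

    def test_clade_span_matches_branch_sum(self, fixture46):
        primates = sorted(fixture46.clade_map["A"])
        sub = prune_to(fixture46, primates)
        # independent oracle: an edge contributes (parent_age - age) iff
        # kept taxa lie both below it and elsewhere among the kept set
        ages = fixture46.ages()
        kept = set(primates)
        expected = 0.0
        for node in fixture46.preorder():
            if node.parent is None:
                continue
            below = {n.name for n in _descendants(node) if n.is_leaf} & kept
            if below and kept - below:
                expected += ages[node.parent] - ages[node]
        assert tree_span(sub) == pytest.approx(expected)


def _descendants(node):
    out, stack = [], [node]
    while stack:
        cur = stack.pop()
        out.append(cur)
        stack.extend(cur.children)
    return out


class TestPruningSeries:
    def test_ladder_counts_and_monotone_times(self):
        # 8-leaf ladder: focal is the deepest tip
        nwk = "(((((((F:1,s1:1):1,s2:2):1,s3:3):1,s4:4):1,s5:5):1,s6:6):1,s7:7);"
        t = read_newick(nwk)
        stages = pruning_series(t, "F")
        assert len(stages) - 1 == 6  # L - 2 pruning steps
        times = [s.t_time for s in stages]
        assert all(b > a for a, b in zip(times, times[1:]))
        assert len(stages[-1].tree.leaf_names) == 2

    def test_minimal_tree_single_step(self):
        t = read_newick("((F:1,S:1):1,O:2);")
        stages = pruning_series(t, "F")
        assert len(stages) == 2
        assert sorted(stages[1].tree.leaf_names) == ["F", "O"]

    def test_vertebrate_fixture_has_15_steps(self, fixture46):
        stages = pruning_series(fixture46, "human")
        assert len(stages) - 1 == 15
        assert sorted(stages[-1].tree.leaf_names) == ["human", "lamprey"]

    def test_stage_leafsets_strictly_shrink(self, fixture46):
        stages = pruning_series(fixture46, "human")
        for a, b in zip(stages, stages[1:]):
            assert b.tree.leaf_set < a.tree.leaf_set

    def test_errors(self):
        t = read_newick("((F:1,S:1):1,O:2);")
        with pytest.raises(KeyError):
            pruning_series(t, "nope")
        with pytest.raises(ValueError):
            pruning_series(read_newick("(A:1,B:1);"), "A")

    def test_polytomy_resolved_deterministically(self):
        t = read_newick("(F:1,S:1,O:2,P:3);")
        s1 = pruning_series(t, "F")
        s2 = pruning_series(t, "F")
        assert [write_newick(a.tree) for a in s1] == \
               [write_newick(a.tree) for a in s2]
        assert all(len(n.children) <= 2 for n in s1[0].tree.preorder())


class TestTimeSpans:
    def test_tree_span_examples(self):
        assert tree_span(read_newick("((A:1,B:1):1,C:2);")) == pytest.approx(5.0)
        assert tree_span(read_newick("(A:3,B:3);")) == pytest.approx(6.0)

    def test_missing_lengths_error(self):
        with pytest.raises(ValueError):
            tree_span(read_newick("(A,B);"))

    def test_pts_boundaries(self, fixture46):
        assert positional_time_span(fixture46, fixture46.leaf_set) == \
            pytest.approx(tree_span(fixture46))
        assert positional_time_span(fixture46, set()) == 0.0
        assert positional_time_span(fixture46, {"human"}) == 0.0

    def test_pts_clade_equals_induced_span(self, fixture46):
        clade = fixture46.clade_map["F"]
        assert positional_time_span(fixture46, clade) == \
            pytest.approx(tree_span(prune_to(fixture46, clade)))

    def test_pts_monotone_under_superset(self, fixture46):
        rng = np.random.default_rng(5)
        taxa = fixture46.leaf_names
        small = set(rng.choice(taxa, 10, replace=False))
        big = small | set(rng.choice(taxa, 10, replace=False))
        assert positional_time_span(fixture46, big) >= \
            positional_time_span(fixture46, small)

    def test_batch_matches_scalar(self, fixture46):
        rng = np.random.default_rng(3)
        taxa = fixture46.leaf_names
        valid = rng.random((len(taxa), 25)) < 0.7
        batch = positional_time_spans_batch(fixture46, valid, taxa)
        for s in range(25):
            expected = positional_time_span(
                fixture46, {t for t, v in zip(taxa, valid[:, s]) if v})
            assert batch[s] == pytest.approx(expected)

    def test_rts(self, fixture46):
        # monomorphic site: carriers = all valid taxa -> RTS = PTS
        valid = set(fixture46.leaf_names[:20])
        assert residue_time_span(fixture46, valid) == \
            pytest.approx(positional_time_span(fixture46, valid))
        assert residue_time_span(fixture46, set()) == 0.0
        sisters = {"mouse", "rat"}
        # two sister taxa: twice the terminal branch time
        assert residue_time_span(fixture46, sisters) == pytest.approx(2 * 21)


class TestBranchScore:
    def test_identity_and_scaling(self):
        t1 = read_newick("((A:1,B:2):1,(C:1,D:1):2);")
        t2 = read_newick("((A:2,B:4):2,(C:2,D:2):4);")
        assert branch_score_distance(t1, t1) == 0.0
        assert branch_score_distance(t1, t2, normalize=True) == pytest.approx(0.0)
        assert branch_score_distance(t1, t2) > 0

    def test_leafset_mismatch(self):
        t1 = read_newick("((A:1,B:2):1,C:1);")
        t2 = read_newick("((A:1,X:2):1,C:1);")
        with pytest.raises(ValueError):
            branch_score_distance(t1, t2)

    def test_nni_hand_computed(self):
        # same terminal lengths; one NNI apart; internal edge length e on
        # both sides.  Bipartition AB|CD (length e) exists only in t1 and
        # AC|BD (length e) only in t2: distance = sqrt(e^2 + e^2).
        e = 0.7
        t1 = read_newick(f"((A:1,B:1):{e},(C:1,D:1):{e});")
        t2 = read_newick(f"((A:1,C:1):{e},(B:1,D:1):{e});")
        # unrooting merges the two root edges: both trees have one
        # internal edge of length 2e
        assert branch_score_distance(t1, t2) == \
            pytest.approx(np.sqrt(2 * (2 * e) ** 2))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_metric_axioms_random(self, seed):
        rng = np.random.default_rng(seed)
        trees = [_random_tree(np.random.default_rng(seed * 10 + i), 7)
                 for i in range(3)]
        # align leaf names (same label set by construction)
        a, b, c = trees
        dab = branch_score_distance(a, b)
        dba = branch_score_distance(b, a)
        assert dab == pytest.approx(dba)
        assert branch_score_distance(a, c) <= dab + branch_score_distance(b, c) + 1e-9
        assert branch_score_distance(a, a) == 0.0


class TestSubsampling:
    def test_density_full_clades_identity(self, fixture46):
        sizes = {k: len(v) for k, v in fixture46.clade_map.items()}
        sub = subsample_density(fixture46, fixture46.clade_map,
                                max(sizes.values()), "human", seed=0)
        assert sub.leaf_set == fixture46.leaf_set

    def test_density_cardinality_bound(self, fixture46):
        clades = {k: v for k, v in fixture46.clade_map.items()
                  if k != "outgroup"}
        sub = subsample_density(fixture46, clades, 1, "human", seed=1)
        assert len(sub.leaf_names) <= 8
        assert "human" in sub.leaf_set

    def test_density_reproducible_and_seed_sensitive(self, fixture46):
        cm = fixture46.clade_map
        a = subsample_density(fixture46, cm, 2, "human", seed=7)
        b = subsample_density(fixture46, cm, 2, "human", seed=7)
        assert write_newick(a) == write_newick(b)
        others = [subsample_density(fixture46, cm, 2, "human", seed=s).leaf_set
                  for s in range(100, 110)]
        assert any(o != a.leaf_set for o in others)

    def test_density_empty_clade_error(self, fixture46):
        with pytest.raises(ValueError):
            subsample_density(fixture46, {"X": set()}, 1, "human", seed=0)

    def test_temporal_first_iteration(self, fixture46):
        sub = subsample_temporal(fixture46, "human", 1)
        assert sorted(sub.leaf_names) == ["chimpanzee", "gorilla", "human"]

    def test_temporal_nested_and_monotone(self, fixture46):
        prev = None
        prev_span = 0.0
        for k in range(1, 20):
            sub = subsample_temporal(fixture46, "human", k)
            if prev is not None:
                assert prev <= sub.leaf_set
            span = tree_span(sub)
            assert span >= prev_span
            prev, prev_span = sub.leaf_set, span
        assert prev == fixture46.leaf_set  # k beyond the root: full tree
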