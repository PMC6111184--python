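"""PCA clade assignment, neighbour joining, Fitch counts, strict clock."""

import itertools

import numpy as np
import pytest

from conftest import make_matrix
from oracle_utils import (
    all_rooted_trees,
    brute_force_parsimony,
    splits,
    tuple_to_phylo,
)
from rostrum import seqio
from rostrum.clades import (
    ClockConfig,
    NoStructureError,
    assign_clades,
    clock_tmrca,
    fitch_counts,
    fitch_site,
    neighbor_joining,
    nj_tree,
    pca,
)


class TestPca:
    def test_two_group_toy_matrix(self):
        # brute-force oracle: covariance of [[0,0],[0,0],[1,1],[1,1]] has one
        # nonzero eigenvalue 2*(1/3) with loading (1,1)/sqrt(2); scores
        # separate the two row groups symmetrically with opposite signs
        m = make_matrix([[0, 0], [0, 0], [1, 1], [1, 1]])
        r = pca(m)
        s1 = r.sample_scores[:, 0]
        assert s1[0] == pytest.approx(s1[1])
        assert s1[2] == pytest.approx(s1[3])
        assert s1[0] == pytest.approx(-s1[2])
        assert abs(r.snp_loadings[0, 0]) == pytest.approx(abs(r.snp_loadings[1, 0]))
        assert r.eigenvalues[0] == pytest.approx(2 / 3)
        assert r.eigenvalues[1:] == pytest.approx(0, abs=1e-12)

    def test_identical_rows_zero_eigenvalues(self):
        m = make_matrix([[1, 0], [1, 0], [1, 0]])
        assert pca(m).eigenvalues == pytest.approx(0, abs=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 2, size=(6, 8))
        r1 = pca(make_matrix(g))
        perm = rng.permutation(6)
        r2 = pca(make_matrix(g[perm]))
        assert r2.sample_scores == pytest.approx(r1.sample_scores[perm], abs=1e-9)

    def test_scores_consistent_with_loadings(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 2, size=(5, 7))
        m = make_matrix(g)
        r = pca(m)
        x = g - g.mean(axis=0)
        assert x @ r.snp_loadings == pytest.approx(r.sample_scores, abs=1e-9)

    def test_site_duplication_invariance(self):
        # duplicating every site scales eigenvalues but leaves score
        # directions (up to global scale) unchanged
        rng = np.random.default_rng(2)
        g = rng.integers(0, 2, size=(6, 5))
        r1 = pca(make_matrix(g))
        r2 = pca(make_matrix(np.hstack([g, g])))
        s1, s2 = r1.sample_scores[:, 0], r2.sample_scores[:, 0]
        assert s2 / np.linalg.norm(s2) == pytest.approx(
            s1 / np.linalg.norm(s1), abs=1e-9
        )

    def test_missing_imputed_to_column_mean(self):
        m = make_matrix([[0, -1], [0, 1], [1, 0], [1, 1]])
        r = pca(m)  # should not raise; -1 treated as missing
        assert np.isfinite(r.sample_scores).all()


class TestAssignClades:
    def test_toy_assignment_and_diagnostics(self):
        m = make_matrix([[0, 0], [0, 0], [1, 1], [1, 1]])
        r = pca(m)
        asg = assign_clades(m, r, anchor_id="s0")
        assert asg.labels["s0"] == asg.labels["s1"] == "eastern"
        assert asg.labels["s2"] == asg.labels["s3"] == "western"
        assert asg.diagnostic_sites == [1, 2]
        assert not asg.flagged

    def test_anchor_names_eastern(self):
        m = make_matrix([[0, 0], [0, 0], [1, 1], [1, 1]])
        r = pca(m)
        asg = assign_clades(m, r, anchor_id="s2")
        assert asg.labels["s2"] == "eastern"
        assert asg.labels["s0"] == "western"

    def test_anchor_absent_rejected(self):
        m = make_matrix([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="anchor"):
            assign_clades(m, pca(m), anchor_id="nope")

    def test_no_structure_error(self):
        m = make_matrix([[1, 0], [1, 0], [1, 0]])
        with pytest.raises(NoStructureError):
            assign_clades(m, pca(m), anchor_id="s0")

    def test_tie_specimen_flagged_to_anchor_clade(self):
        # s4 sits exactly between the groups: PC1 score 0
        m = make_matrix([[0, 0], [0, 0], [1, 1], [1, 1], [0, 1]])
        r = pca(m)
        asg = assign_clades(m, r, anchor_id="s0")
        assert asg.flagged == ["s4"]
        assert asg.labels["s4"] == asg.labels["s0"]

    def test_recovers_simulated_truth(self, small_noise_free):
        aln, truth, _ = small_noise_free(seed=21)
        m = seqio.call_snps(aln)
        asg = assign_clades(m, pca(m), anchor_id="E01")
        assert asg.labels == truth


class TestNeighborJoining:
    def test_four_point_additive_recovery(self):
        # oracle: distances generated on a known tree ((a,b),(c,d)) with
        # positive branch lengths satisfy the four-point condition; NJ must
        # return that topology
        names = ["a", "b", "c", "d"]
        # branch lengths: a=2, b=3, internal=4, c=1, d=5
        d = np.array([
            [0, 5, 7, 11],
            [5, 0, 8, 12],
            [7, 8, 0, 6],
            [11, 12, 6, 0],
        ], dtype=float)
        tree = neighbor_joining(names, d)
        assert splits(tree) == {frozenset(("a", "b"))}
        # recovered branch lengths match the generating ones
        term = {t.name: t.branch_length for t in tree.get_terminals()}
        assert term["a"] == pytest.approx(2)
        assert term["b"] == pytest.approx(3)

    def test_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            leaves = [f"L{i}" for i in range(6)]
            trees = list(all_rooted_trees(leaves[:5]))
            true = trees[rng.integers(len(trees))]
            # assign positive lengths to edges and build the path metric
            import networkx as nx

            g = nx.Graph()
            counter = itertools.count()

            def add(t):
                if isinstance(t, tuple):
                    me = f"i{next(counter)}"
                    for ch in t:
                        g.add_edge(me, add(ch), weight=float(rng.uniform(0.5, 2)))
                    return me
                return t

            root = add(true)
            names = leaves[:5]
            d = np.zeros((5, 5))
            paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
            for i, j in itertools.combinations(range(5), 2):
                d[i, j] = d[j, i] = paths[names[i]][names[j]]
            out = neighbor_joining(names, d)
            true_splits = splits(tuple_to_phylo(true))
            assert splits(out) <= true_splits | {
                s for s in true_splits
            }  # NJ splits subset of generating tree's splits
            assert splits(out) == true_splits

    def test_identical_specimens_zero_cherry(self):
        names = ["a", "b", "c"]
        d = np.array([[0, 0, 4], [0, 0, 4], [4, 4, 0]], dtype=float)
        tree = neighbor_joining(names, d)
        term = {t.name: t.branch_length for t in tree.get_terminals()}
        assert term["a"] == pytest.approx(0)
        assert term["b"] == pytest.approx(0)

    def test_too_few_records_rejected(self, small_noise_free):
        aln, _, _ = small_noise_free(seed=1, n_west=1, n_east=1, n_private=0)
        m = seqio.call_snps(aln)
        # 2 ingroup + outgroup = 3 records: fine; drop one below the limit
        m2 = seqio.call_snps(
            seqio.SpecimenAlignment(
                records=[r for r in aln.records if r[0] != "W01"],
                outgroup_id="OUTGROUP",
            )
        )
        with pytest.raises(ValueError):
            nj_tree(m2)

    def test_clades_sister_in_simulation(self, small_noise_free):
        aln, truth, _ = small_noise_free(seed=23)
        m = seqio.call_snps(aln)
        tree = nj_tree(m)
        for clade in ("western", "eastern"):
            members = [r for r, c in truth.items() if c == clade]
            anc = tree.common_ancestor(members)
            assert {t.name for t in anc.get_terminals()} == set(members)


class TestFitch:
    def test_single_site_internal_branch(self):
        # ((A,B),(C,D)) with A=T,B=T,C=G,D=G: one substitution, on an
        # internal branch (brute-force over all ancestral labelings agrees)
        tree = (("A", "B"), ("C", "D"))
        states = {"A": frozenset("T"), "B": frozenset("T"),
                  "C": frozenset("G"), "D": frozenset("G")}
        root = tuple_to_phylo(tree).root
        count, branch = fitch_site(root, states)
        assert count == 1 == brute_force_parsimony(tree, states)
        internal = [c for c in root.clades]
        assert sum(branch.values()) == 1
        assert branch[id(internal[0])] + branch[id(internal[1])] == 1

    def test_monomorphic_site_zero(self):
        tree = (("A", "B"), ("C", "D"))
        states = {k: frozenset("A") for k in "ABCD"}
        assert fitch_site(tuple_to_phylo(tree).root, states)[0] == 0

    def test_missing_leaf_never_forces_substitution(self):
        tree = (("A", "B"), ("C", "D"))
        states = {"A": frozenset("T"), "B": frozenset("ACGT"),
                  "C": frozenset("T"), "D": frozenset("T")}
        assert fitch_site(tuple_to_phylo(tree).root, states)[0] == 0

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(7)
        leaves = ["A", "B", "C", "D", "E"]
        trees = list(all_rooted_trees(leaves))
        for t in [trees[i] for i in rng.choice(len(trees), 25, replace=False)]:
            root = tuple_to_phylo(t).root
            for _ in range(4):
                states = {
                    l: (frozenset("AG") if rng.random() < 0.15
                        else frozenset(rng.choice(["A", "G"])))
                    for l in leaves
                }
                count, branch = fitch_site(root, states)
                assert count == brute_force_parsimony(t, states)
                assert sum(branch.values()) == count

    def test_mrca_sum_equals_diagnostic_count(self, small_noise_free):
        aln, truth, st = small_noise_free(seed=31)
        m = seqio.call_snps(aln)
        tree = nj_tree(m)
        members = {c: [r for r, t in truth.items() if t == c]
                   for c in ("western", "eastern")}
        gen = fitch_counts(tree, m, clade_members=members)
        assert sum(gen.mrca_to_clade.values()) == len(st.diagnostic_positions)
        # noise-free simulation: every site compatible -> score = #sites
        assert gen.total_score == m.n_sites

    def test_leaf_mismatch_rejected(self, small_noise_free):
        a1, _, _ = small_noise_free(seed=1)
        a2, _, _ = small_noise_free(seed=1, n_west=5)
        m1 = seqio.call_snps(a1)
        tree2 = nj_tree(seqio.call_snps(a2))
        with pytest.raises(ValueError):
            fitch_counts(tree2, m1)


class TestClock:
    def test_zero_substitutions_zero_years(self):
        assert clock_tmrca(0, ClockConfig()) == 0

    def test_rate_ratio_algebra(self):
        cfg = ClockConfig()
        for k in (1, 18, 21, 100):
            ratio = clock_tmrca(k, cfg, "slow") / clock_tmrca(k, cfg, "fast")
            assert ratio == pytest.approx(0.75e-7 / 0.7e-8)

    def test_hand_arithmetic_fast_rate(self):
        # 19.5 substitutions over a 16565 bp genome at the fast rate:
        # 19.5 / 16565 / 0.75e-7 = 15697 years
        y = clock_tmrca(19.5, ClockConfig(), "fast")
        assert y == pytest.approx(19.5 / 16565 / 0.75e-7)
        assert y == pytest.approx(15_697, rel=1e-3)

    def test_monotonicity_grid(self):
        cfg = ClockConfig()
        ys = [clock_tmrca(k, cfg, "fast") for k in range(0, 50, 5)]
        assert all(a < b for a, b in zip(ys, ys[1:]))
        assert clock_tmrca(10, cfg, "slow") > clock_tmrca(10, cfg, "fast")

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ClockConfig(rate_fast=0)
        with pytest.raises(ValueError):
            clock_tmrca(-1, ClockConfig())
        with pytest.raises(ValueError):
            clock_tmrca(1, ClockConfig(), rate="medium")
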