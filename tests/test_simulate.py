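import collections
import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from saxdiv.birthdeath import BDParams
from saxdiv.simulate import (
    SimConfig,
    sim_bd_tree,
    sim_mk,
    sim_sse_tree,
    sim_shift_tree,
    simulate_from_config,
    stationary_distribution,
)
from saxdiv.treeio import UltrametricTree, write_newick


def balanced_tree(depth: int, pendant: float) -> UltrametricTree:
    """Balanced binary tree with zero-length internal branches: 2^depth nearly
    independent tips (a binary stand-in for a star phylogeny)."""
    parent, length, label = [-1], [0.0], [None]
    frontier = [0]
    for level in range(depth):
        last = level == depth - 1
        nxt = []
        for p in frontier:
            for _ in range(2):
                parent.append(p)
                length.append(pendant if last else 0.0)
                label.append(f"t{len(parent)}" if last else None)
                nxt.append(len(parent) - 1)
        frontier = nxt
    return UltrametricTree(parent, length, label)


class TestSimBDTree:
    def test_exact_taxa_stop(self):
        t = sim_bd_tree(0.3, 0.0, {"taxa": 50}, rng=1)
        assert t.n_tips == 50

    def test_determinism(self):
        a = sim_bd_tree(0.3, 0.1, {"taxa": 20}, rng=7)
        b = sim_bd_tree(0.3, 0.1, {"taxa": 20}, rng=7)
        assert write_newick(a) == write_newick(b)
        c = sim_bd_tree(0.3, 0.1, {"taxa": 20}, rng=8)
        assert write_newick(a) != write_newick(c)

    def test_yule_mean_growth(self):
        """Mean extant count from 2 crown lineages is 2 e^{lam t}."""
        lam, T, reps = 0.1, 10.0, 1500
        rng = np.random.default_rng(42)
        counts = [sim_bd_tree(lam, 0.0, {"age": T}, rng=rng).n_tips
                  for _ in range(reps)]
        counts = np.array(counts, dtype=float)
        expected = 2.0 * math.exp(lam * T)
        # conditioning on >= 2 survivors is negligible for a Yule process
        se = counts.std() / math.sqrt(reps)
        assert abs(counts.mean() - expected) < 3 * se + 0.05

    def test_incomplete_sampling_binomial_mean(self):
        rng = np.random.default_rng(3)
        kept = [sim_bd_tree(0.3, 0.0, {"taxa": 200}, rho=0.5, rng=rng).n_tips
                for _ in range(100)]
        kept = np.array(kept, dtype=float)
        se = math.sqrt(200 * 0.25) / math.sqrt(100)
        assert abs(kept.mean() - 100.0) < 3 * se

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sim_bd_tree(0.3, 0.0, {"taxa": 10, "age": 5.0}, rng=0)
        with pytest.raises(ValueError):
            sim_bd_tree(-0.1, 0.0, {"taxa": 10}, rng=0)


class TestSimShiftTree:
    def test_truth_labels_and_crown_age(self):
        tree, truth = sim_shift_tree(
            BDParams(0.15), 8.0, BDParams(0.45), {"age": 25.0}, rng=2,
            min_clade_tips=5,
        )
        assert tree.crown_age == pytest.approx(25.0, rel=1e-6)
        clade_tips = truth.regimes[0].clade.tips
        assert clade_tips <= set(tree.tip_labels())
        assert len(clade_tips) >= 5

    def test_degenerate_shift_matches_plain_bd(self):
        """Shift params equal to background: tip counts indistinguishable."""
        rng = np.random.default_rng(4)
        n_shift, n_plain = [], []
        for _ in range(150):
            t, _ = sim_shift_tree(BDParams(0.15), 8.0, BDParams(0.15),
                                  {"age": 22.0}, rng=rng, min_clade_tips=1)
            n_shift.append(t.n_tips)
            n_plain.append(sim_bd_tree(0.15, 0.0, {"age": 22.0}, rng=rng).n_tips)
        assert ks_2samp(n_shift, n_plain).pvalue > 0.01

    def test_elevated_clade_is_larger(self):
        """A 2.5x speciation clade holds more than its null share of tips."""
        rng = np.random.default_rng(5)
        shares = []
        for _ in range(60):
            t, truth = sim_shift_tree(BDParams(0.171), 10.0, BDParams(0.455),
                                      {"age": 22.0}, rng=rng, min_clade_tips=1)
            shares.append(len(truth.regimes[0].clade.tips) / t.n_tips)
        assert np.mean(shares) > 0.3  # null share would be ~1/alive lineages

    def test_shift_older_than_crown_rejected(self):
        with pytest.raises(ValueError):
            sim_shift_tree(BDParams(0.2), 30.0, BDParams(0.4), {"age": 25.0},
                           rng=0)


class TestSimMk:
    def test_zero_rates_freeze_root_state(self, yule50):
        Q = np.zeros((2, 2))
        states = sim_mk(yule50, Q, root_state=1, rng=0)
        assert set(states.values()) == {1}

    def test_long_branch_stationarity(self):
        """Near-independent long branches approach the stationary frequency."""
        t = balanced_tree(10, 100.0)  # 1024 tips
        Q = np.array([[-0.1, 0.1], [0.1, -0.1]])
        states = sim_mk(t, Q, rng=6)
        freq = np.mean(list(states.values()))
        se = 0.5 / math.sqrt(1024)
        assert abs(freq - 0.5) < 3 * se

    def test_two_tip_transition_probability(self):
        """State frequency after one branch matches P(t) = expm(Qt)."""
        from scipy.linalg import expm

        Q = np.array([[-0.2, 0.2], [0.05, -0.05]])
        t = balanced_tree(1, 5.0)  # two tips on 5 Myr branches
        rng = np.random.default_rng(7)
        hits = [sim_mk(t, Q, root_state=0, rng=rng)["t2"] for _ in range(2000)]
        p1 = expm(Q * 5.0)[0, 1]
        se = math.sqrt(p1 * (1 - p1) / 2000)
        assert abs(np.mean(hits) - p1) < 3 * se

    def test_stationary_distribution(self):
        Q = np.array([[-0.2, 0.2], [0.1, -0.1]])
        pi = stationary_distribution(Q)
        assert pi == pytest.approx([1 / 3, 2 / 3])


class TestSimSSETree:
    def test_determinism(self):
        a = sim_sse_tree("bisse", ([0.1, 0.2], [0.02, 0.02],
                                   np.array([[-0.03, 0.03], [0.03, -0.03]])),
                         {"taxa": 30}, rng=11)
        b = sim_sse_tree("bisse", ([0.1, 0.2], [0.02, 0.02],
                                   np.array([[-0.03, 0.03], [0.03, -0.03]])),
                         {"taxa": 30}, rng=11)
        assert write_newick(a[0]) == write_newick(b[0]) and a[1] == b[1]

    def test_geosse_unreachable_states(self):
        tree, states = sim_sse_tree(
            "geosse", (0.3, 0.3, 0.0, 0.0, 0.0, 0.0, 0.0),
            {"taxa": 25}, rng=12, root_state=0,
        )
        assert set(states.values()) == {0}

    def test_single_state_reduces_to_bd(self):
        """One-state SSE trees share the crown-age law of plain BD trees."""
        rng = np.random.default_rng(13)
        Q = np.zeros((1, 1))
        ages_sse = [
            sim_sse_tree("musse", ([0.3], [0.05], Q), {"taxa": 15},
                         rng=rng, root_state=0)[0].crown_age
            for _ in range(200)
        ]
        ages_bd = [sim_bd_tree(0.3, 0.05, {"taxa": 15}, rng=rng).crown_age
                   for _ in range(200)]
        assert ks_2samp(ages_sse, ages_bd).pvalue > 0.01

    def test_state_independent_marginal_matches_stationary(self):
        """State-independent rates: tip-state frequency tracks the chain."""
        Q = np.array([[-0.06, 0.06], [0.03, -0.03]])
        rng = np.random.default_rng(14)
        pooled = []
        for _ in range(150):
            _, states = sim_sse_tree("bisse", ([0.2, 0.2], [0.0, 0.0], Q),
                                     {"taxa": 12}, rng=rng)
            pooled.extend(states.values())
        # marginal of each tip is the stationary law (root drawn from it)
        assert abs(np.mean(pooled) - 2 / 3) < 0.08

    def test_per_state_sampling(self):
        tree, states = sim_sse_tree(
            "bisse",
            ([0.2, 0.2], [0.0, 0.0], np.array([[-0.05, 0.05], [0.05, -0.05]])),
            {"taxa": 150}, rho=(1.0, 0.2), rng=15,
        )
        counts = collections.Counter(states.values())
        assert counts[0] > counts[1]


class TestSimConfig:
    def test_dispatch_bd(self):
        cfg = SimConfig("bd_tree", {"lam": 0.3, "mu": 0.0},
                        {"taxa": 12}, seed=5)
        t = simulate_from_config(cfg)
        assert t.n_tips == 12

    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig("nope", {}, {"taxa": 5}, seed=1)
        with pytest.raises(ValueError):
            SimConfig("bd_tree", {}, {}, seed=1)
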