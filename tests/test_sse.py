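import math

import numpy as np
import pytest
from scipy.linalg import expm

from saxdiv.birthdeath import BDParams, bd_loglik
from saxdiv.simulate import sim_sse_tree
from saxdiv.sse import (
    GEOSSE_PARAM_NAMES,
    ConstraintSpec,
    GeoSSEParams,
    MuSSEParams,
    TipStates,
    aic_table,
    enumerate_geosse_models,
    fit_ml,
    geosse_loglik,
    mcmc_sse,
    mk_loglik,
    musse_loglik,
    musse_param_names,
)
from saxdiv.treeio import branching_times, read_newick


@pytest.fixture(scope="module")
def bisse_data():
    Q = np.array([[-0.04, 0.04], [0.05, -0.05]])
    tree, states = sim_sse_tree(
        "bisse", ([0.15, 0.15], [0.05, 0.05], Q), {"taxa": 40}, rng=21
    )
    return tree, states


class TestMuSSELoglik:
    def test_absorbing_single_state_equals_bd(self, yule50):
        """q = 0 and all tips in state 0 reduces to the plain BD likelihood."""
        tips = TipStates.binary({lb: 0 for lb in yule50.tip_labels()})
        p = MuSSEParams((0.2, 0.9), (0.05, 0.4), ((0.0, 0.0), (0.0, 0.0)))
        ll = musse_loglik(yule50, tips, p)
        bd = bd_loglik(branching_times(yule50), BDParams(0.2, 0.05))
        assert ll == pytest.approx(bd, abs=1e-6)

    def test_factorization_bd_times_mk(self, bisse_data):
        """State-independent MuSSE = birth-death x Mk (single instance; the
        randomized battery lives in the acceptance suite)."""
        tree, states = bisse_data
        tips = TipStates.binary(states, 0.8, 0.8)
        Q = np.array([[-0.03, 0.03], [0.06, -0.06]])
        p = MuSSEParams((0.2, 0.2), (0.06, 0.06), tuple(map(tuple, Q)))
        ll = musse_loglik(tree, tips, p)
        bd = bd_loglik(branching_times(tree), BDParams(0.2, 0.06, 0.8))
        mk = mk_loglik(tree, tips, Q)
        assert ll == pytest.approx(bd + mk, abs=1e-6)

    def test_rk4_matches_lsoda(self, bisse_data):
        tree, states = bisse_data
        tips = TipStates.binary(states, 0.9, 0.7)
        p = MuSSEParams.bisse(0.1, 0.3, 0.03, 0.05, 0.02, 0.04)
        a = musse_loglik(tree, tips, p, method="rk4")
        b = musse_loglik(tree, tips, p, method="lsoda")
        assert a == pytest.approx(b, abs=1e-6)

    def test_sampling_fraction_continuity(self, bisse_data):
        tree, states = bisse_data
        p = MuSSEParams.bisse(0.1, 0.3, 0.03, 0.05, 0.02, 0.04)
        full = musse_loglik(tree, TipStates.binary(states), p)
        near = musse_loglik(
            tree, TipStates.binary(states, 1 - 1e-12, 1 - 1e-12), p
        )
        assert full == pytest.approx(near, abs=1e-8)

    def test_tip_order_invariance(self):
        p = MuSSEParams.bisse(0.2, 0.4, 0.05, 0.1, 0.03, 0.02)
        states = {"A": 0, "B": 1, "C": 0}
        t1 = read_newick("((A:1,B:1):1,C:2);")
        t2 = read_newick("(C:2,(B:1,A:1):1);")
        tips = TipStates.binary(states)
        assert musse_loglik(t1, tips, p) == pytest.approx(
            musse_loglik(t2, tips, p), abs=1e-9
        )

    def test_unknown_state_rejected(self, tree3):
        tips = TipStates.binary({"A": 0, "B": 1})  # C missing
        p = MuSSEParams.bisse(0.2, 0.4, 0.05, 0.1, 0.03, 0.02)
        with pytest.raises(ValueError):
            musse_loglik(tree3, tips, p)


@pytest.fixture(scope="module")
def geo_data():
    tree, states = sim_sse_tree(
        "geosse", (0.25, 0.15, 0.01, 0.02, 0.05, 0.1, 0.05),
        {"taxa": 40}, rng=31,
    )
    return tree, states


class TestGeoSSELoglik:
    def test_region_swap_symmetry(self, geo_data):
        """With symmetric rates the likelihood is invariant under A<->B."""
        tree, states = geo_data
        p = GeoSSEParams(0.2, 0.2, 0.05, 0.04, 0.04, 0.07, 0.07)
        tips = TipStates(dict(states), 3, np.array([0.8, 0.8, 0.6]))
        swap = {0: 1, 1: 0, 2: 2}
        swapped = TipStates(
            {lb: swap[s] for lb, s in states.items()}, 3,
            np.array([0.8, 0.8, 0.6]),
        )
        a = geosse_loglik(tree, tips, p)
        b = geosse_loglik(tree, swapped, p)
        assert a == pytest.approx(b, abs=1e-10)

    def test_parameter_swap_symmetry(self, geo_data):
        """Relabeling A<->B while swapping (sA,xA,dA)<->(sB,xB,dB) is neutral."""
        tree, states = geo_data
        p = GeoSSEParams(0.25, 0.15, 0.01, 0.02, 0.05, 0.1, 0.05)
        ps = GeoSSEParams(0.15, 0.25, 0.01, 0.05, 0.02, 0.05, 0.1)
        swap = {0: 1, 1: 0, 2: 2}
        tips = TipStates(dict(states), 3, np.array([0.5, 0.7, 0.7]))
        swapped = TipStates(
            {lb: swap[s] for lb, s in states.items()}, 3,
            np.array([0.7, 0.5, 0.7]),
        )
        assert geosse_loglik(tree, tips, p) == pytest.approx(
            geosse_loglik(tree, swapped, ps), abs=1e-10
        )

    def test_rk4_matches_lsoda(self, geo_data):
        tree, states = geo_data
        tips = TipStates(dict(states), 3, np.array([0.5, 0.7, 0.7]))
        p = GeoSSEParams(0.277, 0.156, 0.006, 0.01, 0.076, 0.464, 0.004)
        a = geosse_loglik(tree, tips, p, method="rk4")
        b = geosse_loglik(tree, tips, p, method="lsoda")
        assert a == pytest.approx(b, abs=2e-6)


class TestMkLoglik:
    def test_single_branch_closed_form(self):
        """2-tip tree: Mk likelihood equals the matrix-exponential expression."""
        t = read_newick("(A:2.0,B:2.0);")
        Q = np.array([[-0.3, 0.3], [0.1, -0.1]])
        P = expm(Q * 2.0)
        tips = TipStates.binary({"A": 0, "B": 1})
        # FitzJohn weighting over root states of M_i = P[i,0] * P[i,1]
        M = P[:, 0] * P[:, 1]
        expected = math.log(float((M / M.sum()) @ M))
        assert mk_loglik(t, tips, Q) == pytest.approx(expected, abs=1e-12)


class TestConstraintSpec:
    NAMES = musse_param_names(2)

    def test_resolve_equalities_and_zeros(self):
        c = ConstraintSpec((("lam0", "lam1"),), ("mu1",))
        roots, zeroed, reps = c.resolve(self.NAMES)
        assert c.n_free(self.NAMES) == 4  # lam shared, mu0, q01, q10
        full = c.expand(self.NAMES, dict(zip(reps, [0.2, 0.05, 0.01, 0.02])))
        d = dict(zip(self.NAMES, full))
        assert d["lam0"] == d["lam1"] == 0.2
        assert d["mu1"] == 0.0

    def test_zero_propagates_through_equality(self):
        c = ConstraintSpec((("mu0", "mu1"),), ("mu0",))
        _, zeroed, reps = c.resolve(self.NAMES)
        d = dict(zip(self.NAMES, zeroed))
        assert d["mu0"] and d["mu1"]
        assert "mu1" not in reps

    def test_signature_dedup(self):
        a = ConstraintSpec((("lam0", "lam1"),))
        b = ConstraintSpec((("lam1", "lam0"),))
        assert a.signature(self.NAMES) == b.signature(self.NAMES)

    def test_unknown_param_rejected(self):
        with pytest.raises(ValueError):
            ConstraintSpec((("nope", "lam0"),)).resolve(self.NAMES)


class TestGeoSSEEnumeration:
    def test_count_and_uniqueness(self):
        models = enumerate_geosse_models()
        assert len(models) == 37
        sigs = {m.signature(GEOSSE_PARAM_NAMES) for m in models}
        assert len(sigs) == 37

    def test_full_model_present_and_first(self):
        models = enumerate_geosse_models()
        assert models[0].n_free(GEOSSE_PARAM_NAMES) == 7
        constrained = [m for m in models if m.n_free(GEOSSE_PARAM_NAMES) < 7]
        assert len(constrained) == 36

    def test_contains_pure_birth_in_focal_region(self):
        """The model with xA = 0 and everything else free must be in the set."""
        target = ConstraintSpec((), ("xA",)).signature(GEOSSE_PARAM_NAMES)
        models = enumerate_geosse_models()
        assert any(m.signature(GEOSSE_PARAM_NAMES) == target for m in models)


class TestAICTable:
    def _fit(self, name, ll, k):
        c = ConstraintSpec(name=name)
        f = object.__new__(
            __import__("saxdiv.sse", fromlist=["FitResult"]).FitResult
        )
        f.family = "bisse"
        f.constraints = c
        f.params = {}
        f.loglik = ll
        f.n_free = k
        f.converged = True
        f.n_starts = 1
        return f

    def test_equal_aic_equal_weights(self):
        t = aic_table([self._fit("a", -10.0, 2), self._fit("b", -10.0, 2)])
        assert t["weight"].tolist() == pytest.approx([0.5, 0.5])
        assert t["delta_aic"].iloc[0] == 0.0

    def test_delta_two_gives_ratio_e(self):
        t = aic_table([self._fit("a", -10.0, 2), self._fit("b", -11.0, 2)])
        w = t.set_index("model")["weight"]
        assert w["a"] / w["b"] == pytest.approx(math.e)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(5)
        fits = [self._fit(f"m{i}", -rng.uniform(5, 50), int(rng.integers(1, 7)))
                for i in range(12)]
        t = aic_table(fits)
        assert t["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert (t["delta_aic"] >= 0).all()


class TestFitML:
    def test_pure_birth_degenerate_analytic(self, yule50):
        """Single-state model with mu = 0: lam_hat = (n-2)/T to 1e-6 relative."""
        tips = TipStates({lb: 0 for lb in yule50.tip_labels()}, 1, 1.0)
        fit = fit_ml(yule50, tips, "musse",
                     ConstraintSpec(zeros=("mu0",)), starts=2, seed=0)
        bt = branching_times(yule50)
        lam_exact = (len(bt) - 1) / float(bt[0] + bt.sum())
        assert fit.params["lam0"] == pytest.approx(lam_exact, rel=1e-6)

    def test_nesting(self, bisse_data):
        tree, states = bisse_data
        tips = TipStates.binary(states)
        full = fit_ml(tree, tips, "bisse", starts=2, seed=1)
        constrained = fit_ml(
            tree, tips, "bisse",
            ConstraintSpec((("lam0", "lam1"), ("mu0", "mu1"))),
            starts=2, seed=1,
        )
        assert constrained.loglik <= full.loglik + 1e-6
        assert constrained.n_free == 4 and full.n_free == 6
        assert constrained.aic == pytest.approx(
            2 * 4 - 2 * constrained.loglik
        )


class TestMCMC:
    def test_zero_constrained_parameter_is_exactly_zero(self, bisse_data):
        tree, states = bisse_data
        tips = TipStates.binary(states)
        _, summary = mcmc_sse(
            tree, tips, "bisse", ConstraintSpec(zeros=("mu1",)),
            iterations=400, burn_in=50, seed=2,
        )
        row = summary.set_index("param").loc["mu1"]
        assert row["mean"] == 0.0 and row["hpd_hi"] == 0.0

    def test_conjugate_pure_birth_posterior(self, yule50):
        """Degenerate single-state PB chain matches the Gamma posterior."""
        tips = TipStates({lb: 0 for lb in yule50.tip_labels()}, 1, 1.0)
        trace, summary = mcmc_sse(
            yule50, tips, "musse", ConstraintSpec(zeros=("mu0",)),
            iterations=20_000, burn_in=2_000, seed=3,
        )
        bt = branching_times(yule50)
        n, T = len(bt) + 1, float(bt[0] + bt.sum())
        prior_rate = 1.0 / (2.0 * max((n - 2) / yule50.total_branch_length(),
                                      1e-4))
        # posterior Gamma(n-1, T + prior_rate)
        post_mean = (n - 1) / (T + prior_rate)
        x = trace.post_burnin("lam0")
        from saxdiv.ti import effective_sample_size

        se = x.std() / math.sqrt(effective_sample_size(x))
        assert abs(x.mean() - post_mean) < 3 * se + 1e-4

    def test_derived_net_diversification_reported(self, bisse_data):
        tree, states = bisse_data
        tips = TipStates.binary(states)
        _, summary = mcmc_sse(tree, tips, "bisse", iterations=300,
                              burn_in=50, seed=4)
        params = set(summary["param"])
        assert {"r_0", "r_1"} <= params


class TestTipStates:
    def test_from_csv_integer_states(self):
        tips = TipStates.from_csv("t1,0\nt2,1\n", rho=[0.5, 0.8])
        assert tips.states == {"t1": 0, "t2": 1}
        assert tips.rho.tolist() == [0.5, 0.8]

    def test_from_csv_geographic(self):
        tips = TipStates.from_csv("t1,A\nt2,AB\nt3,B\n")
        assert tips.states == {"t1": 0, "t2": 2, "t3": 1}
        assert tips.n_states == 3

    def test_rho_validation(self):
        with pytest.raises(ValueError):
            TipStates({"a": 0}, 1, 0.0)
        with pytest.raises(ValueError):
            TipStates({"a": 3}, 2, 1.0)
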