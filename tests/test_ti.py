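import math

import numpy as np
import pytest

from saxdiv.birthdeath import Regime, RegimeModel
from saxdiv.simulate import sim_bd_tree
from saxdiv.ti import (
    ExponentialPrior,
    PowerLadder,
    bayes_factor,
    compare_models,
    effective_sample_size,
    hpd_interval,
    interpret_bayes_factor,
    mh_sample,
    thermodynamic_logml,
    ti_logml,
    treeset_logml,
)
from saxdiv.treeio import TreeSet


def conjugate_pb_loglik(k: float, T: float):
    """Pure-birth likelihood L(lam) = lam^k exp(-lam T) for the conjugate oracle."""

    def ll(theta):
        return k * math.log(theta[0]) - T * theta[0]

    return ll


class TestPowerLadder:
    def test_friel_pettitt_shape(self):
        lad = PowerLadder.friel_pettitt(11)
        assert len(lad) == 11
        assert lad.betas[0] == 0.0 and lad.betas[-1] == 1.0
        assert all(b2 > b1 for b1, b2 in zip(lad.betas, lad.betas[1:]))
        # rungs concentrate near zero
        assert lad.betas[5] < 0.1

    def test_validation(self):
        with pytest.raises(ValueError):
            PowerLadder((0.0, 0.5))
        with pytest.raises(ValueError):
            PowerLadder((0.0, 0.5, 0.5, 1.0))


class TestMHSample:
    def test_prior_recovery_at_beta_zero(self):
        prior = ExponentialPrior({"lam": 5.0})
        tr = mh_sample(lambda th: 0.0, prior, 0.0, 20_000, seed=1)
        x = tr.post_burnin("lam")
        se = x.std() / math.sqrt(effective_sample_size(x))
        assert abs(x.mean() - 0.2) < 3 * se + 1e-3

    def test_conjugate_posterior_mean(self):
        # L = lam e^{-2.5 lam}, prior Exp(1) -> posterior Gamma(2, 3.5)
        prior = ExponentialPrior({"lam": 1.0})
        tr = mh_sample(conjugate_pb_loglik(1.0, 2.5), prior, 1.0, 30_000, seed=2)
        x = tr.post_burnin("lam")
        se = x.std() / math.sqrt(effective_sample_size(x))
        assert abs(x.mean() - 2.0 / 3.5) < 3 * se + 1e-3

    def test_determinism(self):
        prior = ExponentialPrior({"lam": 1.0})
        a = mh_sample(conjugate_pb_loglik(1, 2.5), prior, 0.7, 2000, seed=9)
        b = mh_sample(conjugate_pb_loglik(1, 2.5), prior, 0.7, 2000, seed=9)
        assert np.array_equal(a.params, b.params)
        c = mh_sample(conjugate_pb_loglik(1, 2.5), prior, 0.7, 2000, seed=10)
        assert not np.array_equal(a.params, c.params)


class TestThermodynamicIntegration:
    def test_flat_likelihood_exact(self):
        prior = ExponentialPrior({"lam": 1.0})
        const = math.log(7.0)
        traces = [
            mh_sample(lambda th: const, prior, b, 2000, seed=i)
            for i, b in enumerate(PowerLadder.friel_pettitt(5).betas)
        ]
        assert thermodynamic_logml(traces) == pytest.approx(const)

    def test_missing_endpoint_rejected(self):
        prior = ExponentialPrior({"lam": 1.0})
        traces = [mh_sample(lambda th: 0.0, prior, b, 500, seed=1)
                  for b in (0.5, 1.0)]
        with pytest.raises(ValueError):
            thermodynamic_logml(traces)

    def test_ladder_refinement_stable(self):
        """A finer ladder moves the conjugate estimate by less than MC error."""
        prior = ExponentialPrior({"lam": 1.0})
        ll = conjugate_pb_loglik(1.0, 2.5)
        exact = -2.0 * math.log(3.5)
        ests = []
        for k in (11, 21):
            traces = [
                mh_sample(ll, prior, b, 15_000, seed=100 + i)
                for i, b in enumerate(PowerLadder.friel_pettitt(k).betas)
            ]
            ests.append(thermodynamic_logml(traces))
        assert abs(ests[0] - ests[1]) < 0.05
        for e in ests:
            assert abs(e - exact) < 0.05

    def test_logml_below_max_loglik(self, yule50):
        """Jensen bound: the marginal likelihood cannot exceed the peak logL."""
        model = RegimeModel([Regime(None, "PB", "bg")])
        lml, traces = ti_logml(yule50, model, iterations=3000, seed=4)
        assert lml <= max(t.loglik.max() for t in traces)


class TestBayesFactor:
    def test_table_scale(self):
        assert bayes_factor(-665.42, -671.25) == pytest.approx(11.66)
        assert bayes_factor(-665.42, -666.13) == pytest.approx(1.42)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=2) * 100
            assert bayes_factor(a, b) == pytest.approx(-bayes_factor(b, a))

    def test_equal_inputs(self):
        assert bayes_factor(-3.0, -3.0) == 0.0

    def test_interpretation_thresholds(self):
        assert interpret_bayes_factor(1.0).startswith("not worth")
        assert interpret_bayes_factor(11.66) == "very strong"

    def test_compare_models_table(self):
        comp = compare_models({"a": -665.42, "b": -671.25, "c": -666.13})
        assert comp.best == "a"
        assert comp.table.loc["a", "bf_2ln"] == 0.0
        assert comp.table.loc["b", "bf_2ln"] == pytest.approx(11.66)
        assert (comp.table["bf_2ln"] >= 0).all()


class TestHPD:
    def test_constant_trace(self):
        assert hpd_interval([3.0] * 200) == (3.0, 3.0)

    def test_normal_quantiles(self):
        x = np.random.default_rng(1).normal(size=100_000)
        lo, hi = hpd_interval(x, 0.95)
        assert abs(lo + 1.96) < 0.05 and abs(hi - 1.96) < 0.05

    def test_matches_brute_force(self):
        """Sliding-window result equals exhaustive search over all windows."""
        rng = np.random.default_rng(2)
        for _ in range(300):
            x = np.sort(rng.gamma(2.0, 1.0, size=50))
            w = math.ceil(0.95 * 50)
            brute = min(
                ((x[i + w - 1] - x[i], x[i], x[i + w - 1])
                 for i in range(50 - w + 1)),
                key=lambda t: (t[0], t[1]),
            )
            assert hpd_interval(x, 0.95) == (brute[1], brute[2])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval([])


class TestTreeSetTI:
    def test_singleton_matches_single_tree(self, yule50):
        model = RegimeModel([Regime(None, "PB", "bg")])
        res = treeset_logml(TreeSet([yule50]), model, iterations=4000, seed=7)
        lml, _ = ti_logml(yule50, model, iterations=4000, seed=7)
        # same procedure, different derived seeds: agreement within MC error
        assert abs(res.logml - lml) < 0.5

    def test_jittered_copies_average(self):
        base = sim_bd_tree(0.25, 0.0, {"taxa": 25}, rng=3)
        copies = []
        for f in np.linspace(0.999, 1.001, 5):
            t = base.copy()
            t.length = t.length * f
            t._depth_cache = None
            copies.append(t)
        model = RegimeModel([Regime(None, "PB", "bg")])
        res = treeset_logml(TreeSet(copies), model, iterations=4000, seed=8)
        lml, _ = ti_logml(base, model, iterations=4000, seed=8)
        assert abs(res.logml - lml) < 0.5
        assert res.pooled_posterior.shape[0] == 5 * 3600

    def test_end_to_end_determinism(self, yule50):
        model = RegimeModel([Regime(None, "PB", "bg")])
        r1 = treeset_logml(TreeSet([yule50]), model, iterations=1500, seed=5)
        r2 = treeset_logml(TreeSet([yule50]), model, iterations=1500, seed=5)
        assert np.array_equal(r1.per_tree_logml, r2.per_tree_logml)
        assert np.array_equal(r1.pooled_posterior, r2.pooled_posterior)


class TestESS:
    def test_iid_near_n(self):
        x = np.random.default_rng(3).normal(size=4000)
        assert effective_sample_size(x) > 2000

    def test_autocorrelated_much_smaller(self):
        rng = np.random.default_rng(4)
        x = np.empty(4000)
        x[0] = 0.0
        for i in range(1, 4000):
            x[i] = 0.95 * x[i - 1] + rng.normal()
        assert effective_sample_size(x) < 1000
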