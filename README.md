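# saxdiv

Diversification-rate analysis for time-calibrated phylogenies, built around the
question that drives studies of mountain-plant radiations such as *Saxifraga*:
which clades diversified faster than the rest of the tree, and is the
difference attributable to geography or to candidate key-innovation traits?

The package provides three connected analyses plus the simulators needed to
validate them:

1. **Clade-partitioned birth-death models.** An ultrametric tree is divided
   into named crown clades plus a background; each partition follows a
   constant-rate pure-birth (Yule, μ = 0) or birth-death process with its own
   speciation rate λ, extinction rate μ and sampling fraction ρ, and
   partitions may be *linked* to share rates. Models are ranked by log
   marginal likelihoods estimated with power-posterior thermodynamic
   integration, compared by Bayes factors on the 2 ln scale, and averaged over
   a posterior sample of trees.
2. **State-dependent speciation-extinction (SSE) models.** BiSSE/MuSSE for
   binary or multistate characters and GeoSSE for geographic ranges
   {A, B, AB}, with state-specific sampling fractions, a 37-model constrained
   GeoSSE comparison set ranked by AIC and Akaike weights, and MCMC parameter
   estimation with 95% HPD intervals.
3. **Trait-simulation ΔAIC nulls.** The character-only null: traits are
   re-simulated on the fixed tree under the empirically estimated transition
   rates, both competing SSE models are refit to each replicate, and the
   empirical ΔAIC is compared against the simulated ΔAIC distribution — a
   guard against SSE false positives from diversification-independent
   character change.

All likelihoods share one pair of per-branch differential equations in the
extinction probability E(t) and data density D(t); for the single-state
birth-death case they are evaluated in closed form on the branching times,
for SSE models by pruning with either a compiled fixed-step integrator (fast
default) or an adaptive LSODA reference path.

## Worked example

```python
import numpy as np
from saxdiv import (BDParams, bd_loglik, bayes_factor, branching_times,
                    read_newick)
from saxdiv.birthdeath import Regime, RegimeModel, fit_regime_ml
from saxdiv.simulate import sim_shift_tree

# simulate a 22-Myr-old tree in which one lineage alive 10 Myr ago shifts
# from the background rate 0.171 /Myr to 0.455 /Myr (a 2.7x radiation)
tree, truth = sim_shift_tree(BDParams(0.171), 10.0, BDParams(0.455),
                             {"age": 22.0}, rng=61, min_clade_tips=8)

one_rate = RegimeModel([Regime(None, "PB", "all")], name="no-shift")
params1, ll1, aic1 = fit_regime_ml(tree, one_rate)
params2, ll2, aic2 = fit_regime_ml(tree, truth)
print(f"no-shift: lam={params1['all'].lam:.3f}  AIC={aic1:.1f}")
print(f"shift   : lam_bg={params2['bg'].lam:.3f} "
      f"lam_clade={params2['shift'].lam:.3f}  AIC={aic2:.1f}")
```

prints (seed 61):

```
no-shift: lam=0.180  AIC=398.0
shift   : lam_bg=0.153 lam_clade=0.361  AIC=391.1
```

The two-regime model wins by ~7 AIC units and separates the clade's
speciation rate (0.36 /Myr) from the background (0.15 /Myr) on a single
75-tip tree — a noisy but directionally correct recovery of the simulated
truth (0.455 vs 0.171 /Myr); averaging over replicate trees sharpens it (see
the recovery study in the test suite). The same comparison is
available in a Bayesian form via `saxdiv.ti.ti_logml` (thermodynamic
integration per model, then `bayes_factor`).

For state-dependent analyses, `saxdiv.sse.fit_ml` fits any constrained
BiSSE/MuSSE/GeoSSE model, `saxdiv.sse.enumerate_geosse_models()` yields the
full-plus-36-constrained GeoSSE comparison set, and
`saxdiv.nulls.delta_aic_null` builds the trait-simulation null. A YAML-driven
pipeline (`saxdiv run --config analysis.yaml`) chains tree statistics, regime
ranking, SSE scans/MCMC and nulls with deterministic per-stage seeds; see
`saxdiv --help` for the full CLI.

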