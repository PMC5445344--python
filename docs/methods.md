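# Methods

This note documents the models implemented in `saxdiv`, the numerical and
design choices behind them, what the synthetic-data generators do and do not
emulate, and the problem sizes used in the validation suite.

## Birth-death likelihoods on branching times

An ultrametric, binary, time-calibrated tree with complete extant sampling of
probability ρ per tip is modelled by a constant-rate birth-death process with
speciation rate λ and extinction rate μ (both /Myr). The likelihood is the
single-state specialization of the SSE equations: along a branch

    E' = μ − (λ+μ)E + λE²,    D' = −(λ+μ)D + 2λED,

with tip conditions E(0) = 1 − ρ, D(0) = ρ; each internal node contributes a
factor λ and multiplies the daughter D values; at the root the product is
divided by λ(1 − E_root)², i.e. the likelihood is conditioned on the crown
age and on both crown lineages surviving to the present. Because the rates
are constant, E and the per-branch D propagator have closed forms in the node
ages (with a separate analytic branch for the critical case λ = μ), so the
likelihood is a function of the branching times only — no ODE solver is
involved in production use. The closed forms are verified against a generic
stiff ODE integration of the equations above to < 1e-8 across a grid of
(λ, μ/λ, ρ) in the test suite.

Conventions: no (n−1)! labelled-history factor; under pure birth with ρ = 1
the log-likelihood is (n−2)·ln λ − λT with T the total branch length below
the crown, maximized analytically at λ̂ = (n−2)/T. Only likelihood
*differences* between parameter values matter for every comparison the
package performs, so the constant convention is harmless.

Incomplete sampling enters through the tip initial conditions (the
"skeleton-tree" treatment), not by rescaling tip counts, for consistency with
the SSE module. Sampling fractions are typically derived from sampled vs
published-total species counts; because published totals disagree, a
`SamplingSpec` carries a minimum and maximum total and analyses are expected
to be run with both.

### Clade-partitioned regime models

A `RegimeModel` assigns named crown clades (resolved as the MRCA of a tip
set) and the residual background to rate regimes. Each named clade
contributes the likelihood of its crown subtree's branching times; the
background contributes the remaining branching times. The shift is placed at
the clade's crown — the stem branch belongs to the surrounding regime —
because empirical shift hypotheses address named crown groups. Each regime
subtree is conditioned on its own crown age and survival; this
per-partition conditioning convention is shared by all compared models, so
model ranking is unaffected by it. Link groups tie regimes to common (λ, μ),
which is how "same rates in two radiating clades" hypotheses are expressed;
linked regimes must share a process type (PB vs BD).

## Thermodynamic integration and Bayes factors

Marginal likelihoods are estimated by power-posterior path sampling:
log m = ∫₀¹ E_β[log L] dβ, with the expectation under
prior(θ)·L(θ)^β taken from a Metropolis-Hastings run per rung and the
integral evaluated by the trapezoidal rule. The ladder places K = 11 rungs at
Beta(0.3, 1) quantiles, β_k = (k/10)^{1/0.3}, concentrating rungs near β = 0
where E[log L] changes fastest. Proposals are multiplicative (sliding window
on the log scale) on one randomly chosen rate per iteration, with the
Jacobian term in the acceptance ratio. Defaults: 20,000 iterations per rung,
10% burn-in, independent exponential priors on all rates with mean 10× the
crude rate n/(crown age). Effective sample sizes (initial-positive-sequence
autocorrelation estimator) are reported per rung.

The estimator is validated against a conjugate oracle: for a pure-birth
likelihood λ^k e^{−λT} with an Exp(α) prior the marginal likelihood is
α·k!/(T+α)^{k+1} exactly; TI reproduces it within 0.05, and refining the
ladder (21 vs 11 rungs) moves the estimate by less than Monte-Carlo error.

Bayes factors are reported on the 2 ln scale (so Kass-Raftery thresholds
2/6/10 apply) as BF = 2·(log m_best − log m_other). For posterior tree sets,
per-tree marginal likelihoods are averaged at the tree level and parameter
posteriors are pooled from the concatenated post-burn-in β = 1 traces;
per-tree seeds derive deterministically from the master seed.

HPD intervals are the shortest window containing ⌈mass·n⌉ sorted samples,
ties broken toward the lowest lower bound (verified against exhaustive window
search).

## SSE models

MuSSE-k (BiSSE as k = 2; binary-trait analyses run through the same engine)
and GeoSSE likelihoods use the standard E/D pruning equations with
state-specific sampling fractions in the tip conditions. GeoSSE's states are
A, B (endemics) and AB (widespread); dispersal d expands ranges, local
extinction x contracts them (AB→B at x_A, AB→A at x_B, endemics die at x),
widespread lineages additionally undergo between-region speciation s_AB, and
a widespread parent node combines daughters by the symmetrized half-sum over
the three speciation modes. The forward simulator implements the mirror-image
event table, so simulator and likelihood check each other's conventions.

Root treatment: FitzJohn weighting (w_i ∝ D_i) with survival conditioning by
Σ w_i λ_i (1 − E_i)², where λ for a widespread root is s_A + s_B + s_AB;
fixed equal weights are available behind a flag for sensitivity checks. With
state-independent rates this root treatment makes the MuSSE likelihood
factorize *exactly* into (birth-death) × (Mk character likelihood with
FitzJohn-weighted root), which is the module's strongest oracle and is
asserted over randomized instances at 1e-6.

### Integration strategy

Two interchangeable engines compute the per-branch integrations:

- `lsoda`: adaptive, stiff-capable per-branch integration at rtol 1e-8 /
  atol 1e-10 — the high-accuracy reference, used by the 3-tip hand-assembled
  oracle comparisons at 1e-8.
- `rk4` (default): a compiled fixed-step classic Runge-Kutta pruning kernel,
  step count proportional to branch length × total rate (at least 8 per
  branch, capped at 1000), with D renormalized at every node against an
  accumulated log scaler. It agrees with `lsoda` to better than 1e-6 on
  realistic trees and is ~100× faster, which is what makes the replicate
  studies (multi-start ML over dozens of simulated trees, null distributions
  with dozens of refits each) tractable.

The step-count cap deliberately coarsens integration for absurdly high rate
proposals during optimization; such regions are effectively at −∞
log-likelihood and never near the optimum.

### Fitting, model sets, MCMC

ML fits maximize over the free parameters on the log scale (L-BFGS-B, box
bounds 1e-7..50 /Myr) with jittered multi-start (default 5) from a heuristic
initial point scaled by the Yule estimate r̂ = (n−2)/T. A `ConstraintSpec`
ties parameters equal (union-find groups) and/or fixes them to zero; zero
constraints propagate through equality groups. Nested fits are checked for
the logL(constrained) ≤ logL(full) invariant.

The GeoSSE comparison set is the full model plus 36 constrained models: the
product of speciation hypotheses {free, s_A=s_B, s_AB=0}, extinction
hypotheses {free, x_A=x_B, x_A=0, x_B=0} and dispersal hypotheses
{free, d_A=d_B, d_A=d_B=0}, plus one region-neutral speciation model
(s_A=s_B with s_AB=0). The published best-supported structure — pure birth in
the focal region, x_A = 0, all else free — is a member by construction.
Models are ranked by AIC with Akaike weights; ΔAIC < 6 is flagged as "good
model fit".

MCMC parameter estimation mirrors the ML constraint machinery: MH on the free
rates with exponential priors of rate 1/(2r̂), defaults 50,000 iterations
with the first 500 discarded, reporting posterior means and 95% HPDs for all
parameters including derived net diversification rates (r_i = λ_i − μ_i;
r_A = s_A − x_A, r_B = s_B − x_B).

## Trait-simulation ΔAIC null

For a fitted model pair (unconstrained vs constrained/state-independent), the
null distribution simulates character sets on the *fixed* empirical tree
under a plain Markov chain with the empirically estimated transition rates —
binary q01/q10, or for geographic ranges the 3-state chain with dispersal and
range-loss rates — refits both models to every replicate, and records
ΔAIC = AIC(constrained) − AIC(unconstrained). The exceedance
p = #(simulated ΔAIC ≥ empirical)/nsim. Root states draw from the simulating
chain's stationary distribution (switchable to a fixed root). Replicates in
which every tip ends in the same state are resampled rather than dropped,
keeping the requested nsim; the resample count is reported. The empirical
sampling fractions are reused in null refits.

When the fitted transition rates are used as simulating rates, a rate can
collapse to ~0 (boundary ML), making variable characters unreachable; the
validation suite floors each simulating rate at 1/(total tree length) — the
smallest rate for which about one change is expected on the tree.

## Synthetic-data generators

All generators are exact Gillespie simulations from two crown lineages,
conditioned on survival by resimulation (attempt counts are recorded; the
bias of rejection conditioning is negligible at the acceptance rates involved
but is not corrected). Taxa-stopping draws the present uniformly within the
waiting interval after the target count is reached. ρ-sampling drops tips
independently (per-state ρ for SSE trees) and re-roots at the crown of the
retained tips. The generators emulate the data regime of a mid-sized plant
radiation — 50–300 tips, crown ages of tens of Myr, net diversification
0.05–0.5 /Myr, character transition rates 0.003–0.06 /Myr, sampling fractions
0.5–0.9 — and their defaults in the validation studies use the published
rate contrasts (0.455 vs 0.171 /Myr for the clade shift; the geographic-model
posterior means for GeoSSE recovery).

What they do *not* emulate: phylogenetic error (topology/age uncertainty is
represented only by jittered tree sets in tests), rate variation in time,
diffuse extinction-rate signal of real trees, character-state measurement
error, and non-random (clade-biased) incomplete sampling. Passing recovery
tests therefore demonstrates correctness of the estimators under their own
generating model, not robustness to these real-data complications.

Random tip grafting (for taxa of known membership but unknown position)
draws the attachment branch uniformly among the branches of the clade's MRCA
subtree and the attachment height uniformly along that branch — the simplest
defensible null for placement uncertainty; heights are not drawn from any
posterior of neighbouring node ages. Existing node ages and the crown age are
never altered.

## Problem sizes in the validation suite

The replicate studies run at reduced editions of the full-scale designs, as
the package's own choice of desk-scale defaults: BiSSE ratio recovery uses 31
replicates of 150-tip trees (λ1/λ0 = 2); GeoSSE regional-asymmetry recovery
uses 20 replicates of 100-tip trees at the published rate values; the regime
shift study uses 100 replicates (22 Myr crown, shift 10 Myr ago, shifted
clade ≥ 40 tips); null calibration uses 12 meta-replicates at nsim = 20 on a
fixed 80-tip tree; the power study uses 10 runs of 150-tip trees (λ1 = 3λ0)
at nsim = 20. The asserted thresholds are the same proportions as at full
scale.

## Known limitations

- Constant rates within a regime; no time-dependence or diversity-dependence.
- The regime likelihood treats partitions as independent crown-conditioned
  subtrees; alternative conditioning conventions would shift all models by a
  common factor but are not implemented.
- No hidden-state models (HiSSE) and no reversible-jump search over shift
  placements: the model set is user-enumerated.
- The MH sampler is single-chain with a fixed proposal window; badly scaled
  problems may need the window adjusted (acceptance rates are reported).
- GeoSSE MCMC and ML operate on the 7 canonical rates; covarying
  reparameterizations (e.g. r_A directly) are derived quantities only.
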