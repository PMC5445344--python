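"""Constant-rate (pure-)birth-death likelihoods on branching times, with
incomplete-sampling correction and clade-partitioned rate-regime models.

The likelihood follows the single-state specialization of the SSE recursion:
along a branch, E' = mu - (lam+mu) E + lam E^2 and D' = -(lam+mu) D + 2 lam E D,
with tip conditions E(0) = 1 - rho, D(0) = rho; each internal node multiplies
the two daughter D values and lam; at the root the product is divided by
lam (1 - E_root)^2 (conditioning on the crown age and survival of both crown
lineages).  Because the rates are constant the recursion has a closed form in
the node ages, used throughout:

    E(t)   = 1 - r rho / Delta(t)
    ghat(t) = e^{-r t} (r / Delta(t))^2          (per-lineage D propagator)
    Delta(t) = lam rho + (r - lam rho) e^{-r t},  r = lam - mu

Under this convention a pure-birth tree with rho = 1 has
log L = (n-2) ln lam - lam T, with T the total branch length below the crown.
The (n-1)! labelled-history factor is omitted; likelihood *differences* between
parameter values are convention-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .treeio import CladeDefinition, TreeError, UltrametricTree

__all__ = [
    "BDParams",
    "SamplingSpec",
    "Regime",
    "RegimeModel",
    "bd_loglik",
    "regime_loglik",
    "net_diversification",
    "fit_bd_ml",
    "fit_regime_ml",
]

_R_TINY = 1e-12  # below this |r|/lam the critical (lam == mu) limit is used


@dataclass(frozen=True)
class BDParams:
    """Birth-death parameters: speciation lam, extinction mu (/Myr), sampling rho."""

    lam: float
    mu: float = 0.0
    rho: float = 1.0

    def __post_init__(self):
        if not (self.lam > 0 and math.isfinite(self.lam)):
            raise ValueError(f"lam must be positive and finite, got {self.lam}")
        if not (self.mu >= 0 and math.isfinite(self.mu)):
            raise ValueError(f"mu must be >= 0 and finite, got {self.mu}")
        if not (0 < self.rho <= 1):
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")

    @property
    def r(self) -> float:
        """Net diversification rate lam - mu (/Myr)."""
        return self.lam - self.mu


def net_diversification(params: BDParams) -> float:
    """r = lam - mu, in species per Myr."""
    return params.r


@dataclass(frozen=True)
class SamplingSpec:
    """Sampled vs published-total species counts; yields min/max sampling fractions.

    Published totals often differ between sources, so analyses are run with both
    the minimum and maximum assumed totals.
    """

    sampled: int
    total_min: int
    total_max: int

    def __post_init__(self):
        if not (0 < self.sampled <= self.total_min <= self.total_max):
            raise ValueError(
                "require 0 < sampled <= total_min <= total_max, got "
                f"{self.sampled}/{self.total_min}/{self.total_max}"
            )

    @property
    def rho_max(self) -> float:
        """Sampling fraction under the minimum assumed total (larger rho)."""
        return self.sampled / self.total_min

    @property
    def rho_min(self) -> float:
        """Sampling fraction under the maximum assumed total (smaller rho)."""
        return self.sampled / self.total_max


# -- core likelihood ---------------------------------------------------------


def _log_ghat_and_logs(t: np.ndarray, lam: float, mu: float, rho: float):
    """ln ghat(t) and ln(1 - E(t)) for node ages t (vectorized)."""
    t = np.asarray(t, dtype=float)
    r = lam - mu
    a = lam * rho
    if abs(r) <= _R_TINY * lam:
        # critical-branch limit lam == mu
        denom = 1.0 + a * t
        log_ghat = -2.0 * np.log(denom)
        log_one_minus_e = math.log(rho) - np.log(denom)
    else:
        # Delta = a + (r - a) e^{-rt}; keep logs stable for either sign of r
        ert = np.exp(-r * t)
        delta = a + (r - a) * ert
        # r and Delta always share sign, so r/Delta > 0
        log_ratio = math.log(abs(r)) - np.log(np.abs(delta))
        log_ghat = -r * t + 2.0 * log_ratio
        log_one_minus_e = log_ratio + math.log(rho)
    return log_ghat, log_one_minus_e


def bd_loglik(
    times: Sequence[float],
    params: BDParams,
    conditioning: str = "crown_survival",
) -> float:
    """Log-likelihood (nats) of a descending branching-time sequence.

    ``conditioning='crown_survival'`` (default) conditions on the crown age and
    the survival of both crown lineages; ``'none'`` skips the survival factor
    (the root's lam is still divided out, preserving the pure-birth convention).
    """
    x = np.asarray(times, dtype=float)
    if x.ndim != 1 or len(x) < 1:
        raise ValueError("times must be a non-empty 1-d sequence")
    if np.any(np.diff(x) > 0):
        raise ValueError("times must be sorted in descending order")
    if conditioning not in ("crown_survival", "none"):
        raise ValueError(f"unknown conditioning {conditioning!r}")
    lam, mu, rho = params.lam, params.mu, params.rho
    m = len(x)  # = n - 1 internal nodes
    n = m + 1
    log_ghat, log_1me = _log_ghat_and_logs(x, lam, mu, rho)
    loglik = (
        n * math.log(rho)
        + (n - 2) * math.log(lam)
        + float(log_ghat[0])  # crown age counted twice (two crown lineages)
        + float(np.sum(log_ghat))
    )
    if conditioning == "crown_survival":
        loglik -= 2.0 * float(log_1me[0])
    return loglik


# -- regime models -----------------------------------------------------------

BACKGROUND = None  #: sentinel clade meaning "everything not in a named clade"


@dataclass(frozen=True)
class Regime:
    """One rate regime: a clade (or background), its process, link group and rho."""

    clade: CladeDefinition | None  # None = background regime
    process: str = "BD"  # "PB" (mu fixed at 0) or "BD"
    link: Hashable = None  # regimes sharing a link id share parameters
    rho: float = 1.0

    def __post_init__(self):
        if self.process not in ("PB", "BD"):
            raise ValueError(f"process must be 'PB' or 'BD', got {self.process!r}")
        if not (0 < self.rho <= 1):
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if self.link is None:
            object.__setattr__(
                self, "link", self.clade.name if self.clade else "background"
            )


class RegimeModel:
    """Assignment of tree partitions to linked birth-death regimes.

    Named clades are crown groups (the shift applies from the clade's crown;
    the stem branch belongs to the surrounding regime).  The background regime
    covers everything outside the named clades.  Linked regimes must share a
    process type.
    """

    def __init__(self, regimes: Sequence[Regime], name: str = "model"):
        if not regimes:
            raise ValueError("RegimeModel needs at least one regime")
        n_bg = sum(1 for r in regimes if r.clade is None)
        if n_bg > 1:
            raise ValueError("at most one background regime allowed")
        by_link: dict[Hashable, set[str]] = {}
        for r in regimes:
            by_link.setdefault(r.link, set()).add(r.process)
        for link, procs in by_link.items():
            if len(procs) > 1:
                raise ValueError(f"link group {link!r} mixes PB and BD regimes")
        self.regimes = list(regimes)
        self.name = name

    @property
    def links(self) -> list[Hashable]:
        out = []
        for r in self.regimes:
            if r.link not in out:
                out.append(r.link)
        return out

    @property
    def n_free_params(self) -> int:
        """Free rate parameters: 1 per PB link group, 2 per BD link group."""
        k = 0
        seen = set()
        for r in self.regimes:
            if r.link in seen:
                continue
            seen.add(r.link)
            k += 1 if r.process == "PB" else 2
        return k

    def partition_times(self, tree: UltrametricTree) -> list[np.ndarray]:
        """Per-regime descending branching-time sequences.

        Each named clade gets its crown subtree's node ages; the background gets
        the remaining internal-node ages.  Clades must be mutually exclusive and,
        with the background, cover the whole tree.
        """
        ages = tree.node_ages()
        in_clade = np.zeros(tree.n_nodes, dtype=bool)
        clade_nodesets = []
        for reg in self.regimes:
            if reg.clade is None:
                clade_nodesets.append(None)
                continue
            mrca = reg.clade.resolve(tree)
            nodes = tree.subtree_nodes(mrca)
            mask = np.zeros(tree.n_nodes, dtype=bool)
            mask[nodes] = True
            if np.any(mask & in_clade):
                raise TreeError(
                    f"clades in model {self.name!r} overlap on the tree"
                )
            in_clade |= mask
            clade_nodesets.append(mask)
        has_background = any(r.clade is None for r in self.regimes)
        internal = np.array([bool(tree.children[i]) for i in range(tree.n_nodes)])
        tips_uncovered = [
            tree.label[i]
            for i in tree.tip_indices()
            if not in_clade[i]
        ]
        if not has_background and tips_uncovered:
            raise TreeError(
                f"model {self.name!r} leaves tips uncovered and has no "
                f"background regime (e.g. {tips_uncovered[:3]})"
            )
        out = []
        for reg, mask in zip(self.regimes, clade_nodesets):
            if mask is None:
                sel = internal & ~in_clade
            else:
                sel = internal & mask
            t = np.sort(ages[sel])[::-1]
            if len(t) == 0:
                raise TreeError(
                    f"regime {reg.link!r} of model {self.name!r} has no "
                    "branching times on this tree"
                )
            out.append(t)
        return out


def regime_loglik(
    tree: UltrametricTree,
    model: RegimeModel,
    params: Mapping[Hashable, BDParams],
    conditioning: str = "crown_survival",
) -> float:
    """Sum of independent per-regime birth-death log-likelihoods.

    ``params`` maps link-group ids to :class:`BDParams`; each regime's own
    sampling fraction overrides the one in its link group's BDParams.
    """
    total = 0.0
    for reg, times in zip(model.regimes, model.partition_times(tree)):
        p = params[reg.link]
        if reg.process == "PB" and p.mu != 0:
            raise ValueError(f"regime {reg.link!r} is PB but mu = {p.mu} != 0")
        p_use = BDParams(p.lam, p.mu, reg.rho)
        total += bd_loglik(times, p_use, conditioning=conditioning)
    return total


# -- maximum likelihood ------------------------------------------------------


def fit_bd_ml(
    times: Sequence[float],
    process: str = "BD",
    rho: float = 1.0,
    conditioning: str = "crown_survival",
) -> tuple[BDParams, float]:
    """Maximize bd_loglik over (lam[, mu]); returns (params, max log-likelihood).

    Pure birth with complete sampling has the closed form lam_hat = (n-2)/T,
    used directly; everything else is optimized numerically on the log scale.
    """
    x = np.asarray(times, dtype=float)
    m = len(x)
    if process == "PB" and rho == 1.0 and conditioning == "crown_survival":
        T = float(x[0] + x.sum())
        if m == 1:  # two tips: likelihood is monotone decreasing in lam
            lam_hat = 1e-8
        else:
            lam_hat = (m - 1) / T
        p = BDParams(lam_hat, 0.0, 1.0)
        return p, bd_loglik(x, p, conditioning)

    crude = max(m, 2) / float(x[0])  # crude rate scale for initialization

    def nll(theta):
        lam = math.exp(theta[0])
        mu = math.exp(theta[1]) if process == "BD" else 0.0
        try:
            return -bd_loglik(x, BDParams(lam, mu, rho), conditioning)
        except (ValueError, OverflowError):
            return 1e10

    ndim = 2 if process == "BD" else 1
    best = None
    for mu_frac in (0.05, 0.5):
        x0 = [math.log(crude)] + ([math.log(crude * mu_frac)] if ndim == 2 else [])
        res = minimize(nll, x0[:ndim], method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
        if ndim == 1:
            break
    lam = math.exp(best.x[0])
    mu = math.exp(best.x[1]) if ndim == 2 else 0.0
    p = BDParams(lam, mu, rho)
    return p, -best.fun


def fit_regime_ml(
    tree: UltrametricTree,
    model: RegimeModel,
    conditioning: str = "crown_survival",
) -> tuple[dict[Hashable, BDParams], float, float]:
    """ML fit of a regime model; returns (params per link, logL, AIC).

    Link groups are independent in the likelihood, so each group is maximized
    separately over its pooled branching-time components.
    """
    parts = model.partition_times(tree)
    groups: dict[Hashable, list[tuple[Regime, np.ndarray]]] = {}
    for reg, times in zip(model.regimes, parts):
        groups.setdefault(reg.link, []).append((reg, times))
    fitted: dict[Hashable, BDParams] = {}
    total = 0.0
    for link, members in groups.items():
        process = members[0][0].process
        rhos = {reg.rho for reg, _ in members}
        if len(members) == 1 or (len(rhos) == 1 and process == "PB"
                                 and rhos == {1.0} and conditioning == "crown_survival"):
            if len(members) == 1:
                reg, times = members[0]
                p, ll = fit_bd_ml(times, process, reg.rho, conditioning)
                fitted[link] = p
                total += ll
                continue
            # pooled analytic pure-birth fit across linked components
            ks = sum(len(t) - 1 for _, t in members)
            T = sum(float(t[0] + t.sum()) for _, t in members)
            lam_hat = max(ks, 1e-8) / T if ks > 0 else 1e-8
            p = BDParams(lam_hat, 0.0, 1.0)
            fitted[link] = p
            total += sum(bd_loglik(t, p, conditioning) for _, t in members)
            continue

        def nll(theta, members=members, process=process):
            lam = math.exp(theta[0])
            mu = math.exp(theta[1]) if process == "BD" else 0.0
            try:
                return -sum(
                    bd_loglik(t, BDParams(lam, mu, reg.rho), conditioning)
                    for reg, t in members
                )
            except (ValueError, OverflowError):
                return 1e10

        crude = max(
            (len(t) for _, t in members)
        ) / max(float(t[0]) for _, t in members)
        ndim = 2 if process == "BD" else 1
        x0 = [math.log(crude), math.log(crude * 0.1)][:ndim]
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        lam = math.exp(res.x[0])
        mu = math.exp(res.x[1]) if ndim == 2 else 0.0
        fitted[link] = BDParams(lam, mu, members[0][0].rho)
        total += -res.fun
    k = model.n_free_params
    aic = 2 * k - 2 * total
    return fitted, total, aic
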