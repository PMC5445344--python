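"""State-dependent speciation-extinction likelihoods (BiSSE / MuSSE-k / GeoSSE)
with state-specific sampling fractions, constraint-based model enumeration,
ML fitting with AIC/Akaike weights, and MCMC parameter estimation.

Along every branch the per-state extinction probabilities E_i and data
densities D_i evolve by

    E_i' = mu_i - (lam_i + mu_i) E_i + lam_i E_i^2 + sum_j q_ij E_j
    D_i' = -(lam_i + mu_i) D_i + 2 lam_i E_i D_i + sum_j q_ij D_j

(q_ii = -sum of the row) with tip conditions D_i = rho_i * 1[state = i],
E_i = 1 - rho_i; internal nodes combine daughters as D_i <- lam_i D_i^L D_i^R;
the root sums over states with FitzJohn weights w_i proportional to D_i and is
conditioned on survival by dividing by sum_i w_i lam_i (1 - E_i)^2.  GeoSSE
replaces the transition structure by range dynamics on states {A, B, AB}
(dispersal d expands ranges, local extinction x contracts them, widespread
lineages also speciate between regions at rate sAB) and combines widespread
parents with the symmetrized half-sum over the three speciation modes.

Binary-trait analyses are run as the k=2 case of the multistate engine.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import minimize

from . import _kernels
from .treeio import UltrametricTree

__all__ = [
    "TipStates",
    "MuSSEParams",
    "GeoSSEParams",
    "ConstraintSpec",
    "FitResult",
    "musse_loglik",
    "geosse_loglik",
    "mk_loglik",
    "make_loglik",
    "musse_param_names",
    "GEOSSE_PARAM_NAMES",
    "fit_ml",
    "enumerate_geosse_models",
    "aic_table",
    "mcmc_sse",
]

GEOSSE_PARAM_NAMES = ("sA", "sB", "sAB", "xA", "xB", "dA", "dB")
GEOSSE_STATE_INDEX = {"A": 0, "B": 1, "AB": 2}

#: LSODA tolerances for the reference integration path
ODE_RTOL = 1e-8
ODE_ATOL = 1e-10


# -- data containers ---------------------------------------------------------


@dataclass
class TipStates:
    """Tip label -> state index, plus per-state sampling fractions rho_i.

    States are 0..k-1; the geographic coding maps A -> 0, B -> 1, AB -> 2.
    """

    states: dict[str, int]
    n_states: int
    rho: np.ndarray

    def __post_init__(self):
        self.rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        if len(self.rho) == 1:
            self.rho = np.repeat(self.rho, self.n_states)
        if len(self.rho) != self.n_states:
            raise ValueError("need one sampling fraction per state")
        if np.any(self.rho <= 0) or np.any(self.rho > 1):
            raise ValueError("sampling fractions must be in (0, 1]")
        bad = {s for s in self.states.values() if not 0 <= s < self.n_states}
        if bad:
            raise ValueError(f"states out of range 0..{self.n_states - 1}: {bad}")

    @classmethod
    def binary(cls, states: Mapping[str, int], rho0: float = 1.0, rho1: float = 1.0):
        return cls(dict(states), 2, np.array([rho0, rho1]))

    @classmethod
    def geographic(cls, ranges: Mapping[str, str], rho=(1.0, 1.0, 1.0)):
        """From tip -> range labels in {A, B, AB}; rho ordered (A, B, AB)."""
        states = {}
        for lb, r in ranges.items():
            if r not in GEOSSE_STATE_INDEX:
                raise ValueError(f"range for {lb!r} must be A, B or AB, got {r!r}")
            states[lb] = GEOSSE_STATE_INDEX[r]
        return cls(states, 3, np.asarray(rho, dtype=float))

    @classmethod
    def from_csv(cls, text: str, n_states: int | None = None, rho=1.0):
        """Two-column CSV (label, state); states may be ints or A/B/AB letters."""
        df = pd.read_csv(io.StringIO(text), header=None, comment="#",
                         skipinitialspace=True, dtype=str)
        if df.shape[1] < 2:
            raise ValueError("states CSV needs two columns: label, state")
        raw = dict(zip(df[0].astype(str), df[1].astype(str)))
        if all(v in GEOSSE_STATE_INDEX for v in raw.values()):
            return cls.geographic(raw, rho if not np.isscalar(rho) else (rho,) * 3)
        states = {lb: int(v) for lb, v in raw.items()}
        k = n_states if n_states is not None else max(states.values()) + 1
        return cls(states, k, rho)

    def state_vector(self, tree: UltrametricTree) -> np.ndarray:
        missing = [lb for lb in tree.tip_labels() if lb not in self.states]
        if missing:
            raise ValueError(f"tips without a state: {missing[:5]}")
        out = np.full(tree.n_nodes, -1, dtype=np.int64)
        for i in tree.tip_indices():
            out[i] = self.states[tree.label[i]]
        return out


@dataclass(frozen=True)
class MuSSEParams:
    """Per-state speciation/extinction rates and the transition rate matrix."""

    lam: tuple
    mu: tuple
    Q: tuple  # full k x k matrix, rows summing to zero

    def __post_init__(self):
        lam = np.asarray(self.lam, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        Q = np.asarray(self.Q, dtype=float)
        k = len(lam)
        if len(mu) != k or Q.shape != (k, k):
            raise ValueError("inconsistent parameter dimensions")
        if np.any(lam < 0) or np.any(mu < 0):
            raise ValueError("rates must be non-negative")
        off = Q - np.diag(np.diag(Q))
        if np.any(off < 0):
            raise ValueError("off-diagonal transition rates must be >= 0")
        object.__setattr__(self, "lam", tuple(lam))
        object.__setattr__(self, "mu", tuple(mu))
        Q = off - np.diag(off.sum(axis=1))
        object.__setattr__(self, "Q", tuple(map(tuple, Q)))

    @classmethod
    def bisse(cls, lam0, lam1, mu0, mu1, q01, q10) -> "MuSSEParams":
        return cls((lam0, lam1), (mu0, mu1), ((-q01, q01), (q10, -q10)))

    @property
    def k(self) -> int:
        return len(self.lam)

    def arrays(self):
        return (
            np.asarray(self.lam, float),
            np.asarray(self.mu, float),
            np.asarray(self.Q, float),
        )


@dataclass(frozen=True)
class GeoSSEParams:
    """GeoSSE rates: within-region speciation sA/sB, between-region sAB,
    local extinction xA/xB, dispersal dA (A->AB) and dB (B->AB), all /Myr."""

    sA: float
    sB: float
    sAB: float
    xA: float
    xB: float
    dA: float
    dB: float

    def __post_init__(self):
        if any(getattr(self, nm) < 0 for nm in GEOSSE_PARAM_NAMES):
            raise ValueError("all GeoSSE rates must be >= 0")

    @property
    def rA(self) -> float:
        """Net diversification in region A: sA - xA."""
        return self.sA - self.xA

    @property
    def rB(self) -> float:
        return self.sB - self.xB

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, nm) for nm in GEOSSE_PARAM_NAMES])


# -- tree flattening ---------------------------------------------------------


def _flatten(tree: UltrametricTree):
    order = np.fromiter(tree.postorder(), dtype=np.int64, count=tree.n_nodes)
    child1 = np.full(tree.n_nodes, -1, dtype=np.int64)
    child2 = np.full(tree.n_nodes, -1, dtype=np.int64)
    for i, ch in enumerate(tree.children):
        if ch:
            child1[i], child2[i] = ch
    return order, child1, child2, np.asarray(tree.length, dtype=float)


def _tip_d(tree, tips: TipStates, k: int) -> np.ndarray:
    sv = tips.state_vector(tree)
    td = np.zeros((tree.n_nodes, k))
    for i in tree.tip_indices():
        td[i, sv[i]] = tips.rho[sv[i]]
    return td


def _steps_per_myr(max_rate: float) -> float:
    # fixed-step RK4 resolution: ~>=12 steps per unit of total rate x time,
    # capped so that absurd proposals during optimization stay cheap
    return min(max(8.0, 12.0 * max_rate), 80.0)


# -- likelihood engines ------------------------------------------------------


def _root_loglik(E_root, D_root, lam_root, logscale, root_mode, condition_surv):
    D_root = np.asarray(D_root, float)
    E_root = np.asarray(E_root, float)
    total = D_root.sum()
    if not np.isfinite(total) or total <= 0:
        return -math.inf
    if root_mode == "fitzjohn":
        w = D_root / total
    elif root_mode == "equal":
        w = np.full(len(D_root), 1.0 / len(D_root))
    else:
        raise ValueError(f"unknown root mode {root_mode!r}")
    num = float(np.dot(w, D_root))
    if num <= 0:
        return -math.inf
    out = math.log(num) + logscale
    if condition_surv:
        den = float(np.dot(w, lam_root * (1.0 - E_root) ** 2))
        if den <= 0:
            return -math.inf
        out -= math.log(den)
    return out


def _lsoda_traverse(order, child1, child2, length, tip_d, tip_e, rhs, combine, k):
    nnodes = len(order)
    Etop = np.zeros((nnodes, k))
    Dtop = np.zeros((nnodes, k))
    logscale = 0.0
    root = order[-1]
    for node in order:
        c1 = child1[node]
        if c1 < 0:
            E = tip_e.copy()
            D = tip_d[node].copy()
        else:
            c2 = child2[node]
            E = 0.5 * (Etop[c1] + Etop[c2])
            D = combine(Dtop[c1], Dtop[c2])
        mx = D.max()
        if mx > 0:
            D /= mx
            logscale += math.log(mx)
        if node != root:
            y0 = np.concatenate([E, D])
            sol = solve_ivp(
                rhs, (0.0, float(length[node])), y0,
                method="LSODA", rtol=ODE_RTOL, atol=ODE_ATOL,
            )
            if not sol.success:
                raise RuntimeError(
                    f"ODE integration failed on the branch above node {node}: "
                    f"{sol.message}"
                )
            E, D = sol.y[:k, -1], sol.y[k:, -1]
        Etop[node] = E
        Dtop[node] = D
    return Etop[root], Dtop[root], logscale


def _musse_core(tree, tips, params: MuSSEParams, method):
    lam, mu, Q = params.arrays()
    k = params.k
    order, child1, child2, length = _flatten(tree)
    tip_d = _tip_d(tree, tips, k)
    tip_e = 1.0 - tips.rho
    if method == "rk4":
        max_rate = float((lam + mu - np.diag(Q)).max())
        return _kernels.musse_prune(
            order, child1, child2, length, tip_d, tip_e, lam, mu, Q,
            _steps_per_myr(max_rate), 8,
        )
    if method != "lsoda":
        raise ValueError(f"unknown method {method!r}")

    def rhs(_t, y):
        E, D = y[:k], y[k:]
        tot = lam + mu
        dE = mu - tot * E + lam * E * E + Q @ E
        dD = -tot * D + 2.0 * lam * E * D + Q @ D
        return np.concatenate([dE, dD])

    return _lsoda_traverse(
        order, child1, child2, length, tip_d, tip_e, rhs,
        lambda dl, dr: lam * dl * dr, k,
    )


def musse_loglik(
    tree: UltrametricTree,
    tips: TipStates,
    params: MuSSEParams,
    method: str = "rk4",
    root_mode: str = "fitzjohn",
    condition_surv: bool = True,
) -> float:
    """MuSSE (k-state; BiSSE when k=2) log-likelihood of tree + tip states.

    ``method='rk4'`` uses the compiled fixed-step pruning kernel (default);
    ``'lsoda'`` integrates each branch with an adaptive stiff-capable solver
    at rtol 1e-8 / atol 1e-10.
    """
    if tips.n_states != params.k:
        raise ValueError("tip states and parameters disagree on state count")
    E, D, logscale = _musse_core(tree, tips, params, method)
    lam = np.asarray(params.lam, float)
    return _root_loglik(E, D, lam, logscale, root_mode, condition_surv)


def _geosse_core(tree, tips, p: np.ndarray, method):
    order, child1, child2, length = _flatten(tree)
    tip_d = _tip_d(tree, tips, 3)
    tip_e = 1.0 - tips.rho
    if method == "rk4":
        sA, sB, sAB, xA, xB, dA, dB = p
        max_rate = max(sA + dA + xA, sB + dB + xB, sA + sB + sAB + xA + xB)
        return _kernels.geosse_prune(
            order, child1, child2, length, tip_d, tip_e, p,
            _steps_per_myr(float(max_rate)), 8,
        )
    if method != "lsoda":
        raise ValueError(f"unknown method {method!r}")
    sA, sB, sAB, xA, xB, dA, dB = p

    def rhs(_t, y):
        EA, EB, EAB, DA, DB, DAB = y
        totA, totB = sA + dA + xA, sB + dB + xB
        totAB = sA + sB + sAB + xA + xB
        return np.array([
            xA - totA * EA + sA * EA * EA + dA * EAB,
            xB - totB * EB + sB * EB * EB + dB * EAB,
            -totAB * EAB + xA * EB + xB * EA
            + sA * EA * EAB + sB * EB * EAB + sAB * EA * EB,
            -totA * DA + 2 * sA * EA * DA + dA * DAB,
            -totB * DB + 2 * sB * EB * DB + dB * DAB,
            -totAB * DAB + xA * DB + xB * DA
            + sA * (EA * DAB + EAB * DA) + sB * (EB * DAB + EAB * DB)
            + sAB * (EA * DB + EB * DA),
        ])

    def combine(dl, dr):
        return np.array([
            sA * dl[0] * dr[0],
            sB * dl[1] * dr[1],
            0.5 * (
                sA * (dl[0] * dr[2] + dl[2] * dr[0])
                + sB * (dl[1] * dr[2] + dl[2] * dr[1])
                + sAB * (dl[0] * dr[1] + dl[1] * dr[0])
            ),
        ])

    return _lsoda_traverse(
        order, child1, child2, length, tip_d, tip_e, rhs, combine, 3
    )


def geosse_loglik(
    tree: UltrametricTree,
    tips: TipStates,
    params: GeoSSEParams,
    method: str = "rk4",
    root_mode: str = "fitzjohn",
    condition_surv: bool = True,
) -> float:
    """GeoSSE log-likelihood; tip states coded 0=A, 1=B, 2=AB."""
    if tips.n_states != 3:
        raise ValueError("GeoSSE needs 3-state tip data (A, B, AB)")
    p = params.vector()
    E, D, logscale = _geosse_core(tree, tips, p, method)
    lam_root = np.array([params.sA, params.sB, params.sA + params.sB + params.sAB])
    return _root_loglik(E, D, lam_root, logscale, root_mode, condition_surv)


def mk_loglik(
    tree: UltrametricTree,
    tips: TipStates,
    Q: np.ndarray,
    root_mode: str = "fitzjohn",
) -> float:
    """Plain k-state Markov (Mk) trait log-likelihood by Felsenstein pruning.

    Root states are weighted like the SSE root (FitzJohn weights by default),
    so that a state-independent MuSSE likelihood factorizes exactly into
    birth-death x Mk.
    """
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    sv = tips.state_vector(tree)
    logscale = 0.0
    partial = {}
    cache: dict[float, np.ndarray] = {}
    for node in tree.postorder():
        if not tree.children[node]:
            v = np.zeros(k)
            v[sv[node]] = 1.0
        else:
            c1, c2 = tree.children[node]
            v = partial.pop(c1) * partial.pop(c2)
        mx = v.max()
        if mx > 0:
            v = v / mx
            logscale += math.log(mx)
        if node != tree.root:
            t = float(tree.length[node])
            if t not in cache:
                cache[t] = expm(Q * t)
            v = cache[t] @ v
        partial[node] = v
    M = partial[tree.root]
    total = M.sum()
    if total <= 0:
        return -math.inf
    if root_mode == "fitzjohn":
        w = M / total
    elif root_mode == "uniform":
        w = np.full(k, 1.0 / k)
    else:
        raise ValueError(f"unknown root mode {root_mode!r}")
    return math.log(float(np.dot(w, M))) + logscale


# -- constraints and model enumeration ---------------------------------------


@dataclass(frozen=True)
class ConstraintSpec:
    """Equality (param_i = param_j) and zero (param_i = 0) constraints."""

    equalities: tuple = ()
    zeros: tuple = ()
    name: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "equalities", tuple(tuple(pair) for pair in self.equalities)
        )
        object.__setattr__(self, "zeros", tuple(self.zeros))
        if not self.name:
            parts = [f"{a}={b}" for a, b in self.equalities]
            parts += [f"{z}=0" for z in self.zeros]
            object.__setattr__(self, "name", ",".join(parts) or "full")

    def resolve(self, param_names: Sequence[str]):
        """(group id per param, zeroed flag per param, representative names).

        Parameters linked by equality share a group; a zero constraint on any
        member zeroes the whole group.
        """
        names = list(param_names)
        index = {nm: i for i, nm in enumerate(names)}
        for a, b in self.equalities:
            for nm in (a, b):
                if nm not in index:
                    raise ValueError(f"unknown parameter {nm!r} in constraint")
        for z in self.zeros:
            if z not in index:
                raise ValueError(f"unknown parameter {z!r} in zero constraint")
        group = list(range(len(names)))

        def find(i):
            while group[i] != i:
                group[i] = group[group[i]]
                i = group[i]
            return i

        for a, b in self.equalities:
            ra, rb = find(index[a]), find(index[b])
            if ra != rb:
                group[max(ra, rb)] = min(ra, rb)
        roots = [find(i) for i in range(len(names))]
        zero_roots = {find(index[z]) for z in self.zeros}
        zeroed = [r in zero_roots for r in roots]
        reps = []
        for i, nm in enumerate(names):
            if roots[i] == i and not zeroed[i]:
                reps.append(nm)
        return roots, zeroed, reps

    def signature(self, param_names: Sequence[str]) -> tuple:
        roots, zeroed, _ = self.resolve(param_names)
        return tuple("0" if z else f"g{r}" for r, z in zip(roots, zeroed))

    def n_free(self, param_names: Sequence[str]) -> int:
        return len(self.resolve(param_names)[2])

    def expand(self, param_names: Sequence[str], free: Mapping[str, float]) -> np.ndarray:
        roots, zeroed, _ = self.resolve(param_names)
        names = list(param_names)
        out = np.zeros(len(names))
        for i, nm in enumerate(names):
            if zeroed[i]:
                out[i] = 0.0
            else:
                out[i] = free[names[roots[i]]]
        return out


def musse_param_names(k: int) -> tuple:
    names = [f"lam{i}" for i in range(k)] + [f"mu{i}" for i in range(k)]
    names += [f"q{i}{j}" for i in range(k) for j in range(k) if i != j]
    return tuple(names)


def _family_names(family: str, n_states: int) -> tuple:
    if family == "geosse":
        return GEOSSE_PARAM_NAMES
    if family == "bisse":
        return musse_param_names(2)
    if family == "musse":
        return musse_param_names(n_states)
    raise ValueError(f"unknown family {family!r}")


def enumerate_geosse_models() -> list[ConstraintSpec]:
    """The GeoSSE comparison set: the full model plus 36 constrained models.

    Constrained models are the product of speciation hypotheses
    {free, sA=sB, sAB=0}, extinction hypotheses {free, xA=xB, xA=0, xB=0} and
    dispersal hypotheses {free, dA=dB, dA=dB=0}, plus one region-neutral
    speciation model (sA=sB with sAB=0, everything else free).  Includes the
    single-constraint model xA=0 (pure birth in the focal region A).
    """
    s_opts = [((), ()), ((("sA", "sB"),), ()), ((), ("sAB",))]
    x_opts = [((), ()), ((("xA", "xB"),), ()), ((), ("xA",)), ((), ("xB",))]
    d_opts = [((), ()), ((("dA", "dB"),), ()), ((), ("dA", "dB"))]
    specs = []
    for (se, sz), (xe, xz), (de, dz) in itertools.product(s_opts, x_opts, d_opts):
        specs.append(ConstraintSpec(se + xe + de, sz + xz + dz))
    specs.append(ConstraintSpec((("sA", "sB"),), ("sAB",)))
    seen = set()
    out = []
    for spec in specs:
        sig = spec.signature(GEOSSE_PARAM_NAMES)
        if sig not in seen:
            seen.add(sig)
            out.append(spec)
    # full model first, then by decreasing free-parameter count
    out.sort(key=lambda s: (-s.n_free(GEOSSE_PARAM_NAMES), s.name))
    return out


# -- fitting -----------------------------------------------------------------


def make_loglik(
    tree: UltrametricTree,
    tips: TipStates,
    family: str,
    method: str = "rk4",
    root_mode: str = "fitzjohn",
    condition_surv: bool = True,
) -> tuple[Callable[[np.ndarray], float], tuple]:
    """(log-likelihood of a full parameter vector, parameter names).

    The tree is flattened once, so the returned closure is cheap to call
    repeatedly during optimization or MCMC.
    """
    names = _family_names(family, tips.n_states)
    order, child1, child2, length = _flatten(tree)
    k = tips.n_states
    tip_d = _tip_d(tree, tips, k)
    tip_e = 1.0 - tips.rho

    if family == "geosse":
        def fn(vec: np.ndarray) -> float:
            p = np.asarray(vec, dtype=float)
            if np.any(p < 0) or not np.all(np.isfinite(p)):
                return -math.inf
            if method == "rk4":
                mx = max(p[0] + p[5] + p[3], p[1] + p[6] + p[4],
                         p[0] + p[1] + p[2] + p[3] + p[4])
                E, D, ls = _kernels.geosse_prune(
                    order, child1, child2, length, tip_d, tip_e, p,
                    _steps_per_myr(float(mx)), 8,
                )
            else:
                E, D, ls = _geosse_core(tree, tips, p, method)
            lam_root = np.array([p[0], p[1], p[0] + p[1] + p[2]])
            return _root_loglik(E, D, lam_root, ls, root_mode, condition_surv)
    else:
        nq = k * (k - 1)

        def fn(vec: np.ndarray) -> float:
            v = np.asarray(vec, dtype=float)
            if np.any(v < 0) or not np.all(np.isfinite(v)):
                return -math.inf
            lam, mu = v[:k], v[k: 2 * k]
            Q = np.zeros((k, k))
            pos = 2 * k
            for i in range(k):
                for j in range(k):
                    if i != j:
                        Q[i, j] = v[pos]
                        pos += 1
            Q -= np.diag(Q.sum(axis=1))
            if method == "rk4":
                max_rate = float((lam + mu - np.diag(Q)).max())
                E, D, ls = _kernels.musse_prune(
                    order, child1, child2, length, tip_d, tip_e, lam, mu, Q,
                    _steps_per_myr(max_rate), 8,
                )
            else:
                E, D, ls = _musse_core(
                    tree, tips, MuSSEParams(tuple(lam), tuple(mu), tuple(map(tuple, Q))),
                    method,
                )
            return _root_loglik(E, D, lam, ls, root_mode, condition_surv)

    return fn, names


def _heuristic_init(tree: UltrametricTree, family: str, names: Sequence[str]) -> np.ndarray:
    n = tree.n_tips
    T = tree.total_branch_length()
    r_hat = max((n - 2) / T, 1e-4)  # Yule point estimate as the rate scale
    init = {}
    for nm in names:
        if nm.startswith(("lam", "s")):
            init[nm] = 1.5 * r_hat
        elif nm.startswith(("mu", "x")):
            init[nm] = 0.5 * r_hat
        else:  # transition / dispersal
            init[nm] = 0.2 * r_hat
    if family == "geosse":
        init["sAB"] = 0.5 * r_hat
    return np.array([init[nm] for nm in names])


@dataclass
class FitResult:
    """Maximum-likelihood fit of one constrained SSE model."""

    family: str
    constraints: ConstraintSpec
    params: dict[str, float]
    loglik: float
    n_free: int
    converged: bool
    n_starts: int

    @property
    def name(self) -> str:
        return self.constraints.name

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free - 2.0 * self.loglik

    def full_vector(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.params[nm] for nm in names])


_LOG_LO, _LOG_HI = math.log(1e-7), math.log(50.0)


def fit_ml(
    tree: UltrametricTree,
    tips: TipStates,
    family: str,
    constraints: ConstraintSpec | None = None,
    starts: int = 5,
    seed: int = 0,
    method: str = "rk4",
    init: Mapping[str, float] | None = None,
    root_mode: str = "fitzjohn",
    condition_surv: bool = True,
) -> FitResult:
    """Box-constrained ML fit on the log scale with jittered multi-start.

    ``constraints`` fixes parameters to zero and/or ties them equal; the free
    representatives are optimized by L-BFGS-B.  Raises if every start fails.
    """
    if constraints is None:
        constraints = ConstraintSpec()
    loglik, names = make_loglik(tree, tips, family, method, root_mode, condition_surv)
    roots, zeroed, reps = constraints.resolve(names)
    if not reps:
        raise ValueError("model has no free parameters")
    base = _heuristic_init(tree, family, names)
    if init is not None:
        for nm, v in init.items():
            base[list(names).index(nm)] = v
    rep_idx = [list(names).index(r) for r in reps]

    def expand(free_vec: np.ndarray) -> np.ndarray:
        full = np.zeros(len(names))
        rep_map = dict(zip(reps, free_vec))
        for i, nm in enumerate(names):
            if not zeroed[i]:
                full[i] = rep_map[names[roots[i]]]
        return full

    def nll(x: np.ndarray) -> float:
        val = loglik(expand(np.exp(x)))
        return -val if math.isfinite(val) else 1e10

    rng = np.random.default_rng(seed)
    best = None
    ok = 0
    for s in range(starts):
        x0 = np.log(np.clip(base[rep_idx], 1e-7, None))
        if s > 0:
            x0 = x0 + rng.normal(0.0, 0.6, size=len(x0))
        x0 = np.clip(x0, _LOG_LO, _LOG_HI)
        try:
            res = minimize(
                nll, x0, method="L-BFGS-B",
                bounds=[(_LOG_LO, _LOG_HI)] * len(x0),
                options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-7},
            )
        except Exception:
            continue
        if not math.isfinite(res.fun) or res.fun >= 1e9:
            continue
        ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {starts} optimization starts failed for model "
            f"{constraints.name!r}"
        )
    free_hat = np.exp(best.x)
    full = expand(free_hat)
    return FitResult(
        family=family,
        constraints=constraints,
        params=dict(zip(names, full)),
        loglik=-float(best.fun),
        n_free=len(reps),
        converged=bool(best.success),
        n_starts=ok,
    )


def aic_table(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Ranked AIC table: logL, k, AIC, dAIC, Akaike weight, good-fit flag.

    Models within dAIC < 6 of the best are flagged as having good model fit.
    """
    if not fits:
        raise ValueError("need at least one fit")
    df = pd.DataFrame(
        {
            "model": [f.name for f in fits],
            "loglik": [f.loglik for f in fits],
            "k": [f.n_free for f in fits],
            "aic": [f.aic for f in fits],
        }
    ).sort_values("aic", kind="mergesort").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    rel = np.exp(-0.5 * df["delta_aic"].to_numpy())
    df["weight"] = rel / rel.sum()
    df["good_fit"] = df["delta_aic"] < 6.0
    return df


def mcmc_sse(
    tree: UltrametricTree,
    tips: TipStates,
    family: str,
    constraints: ConstraintSpec | None = None,
    iterations: int = 50_000,
    burn_in: int = 500,
    seed: int = 0,
    init: Mapping[str, float] | None = None,
    method: str = "rk4",
    window: float = 0.7,
):
    """MH posterior sampling of a (constrained) SSE model.

    Exponential priors with rate 1/(2 r_hat) on every free rate, r_hat being
    the crude Yule estimate (n-2)/T.  Returns (Trace, summary DataFrame with
    posterior means and 95% HPDs, including the derived net diversification
    rates and exact zeros for parameters fixed by the constraints).
    """
    from .ti import ExponentialPrior, hpd_interval, mh_sample

    if constraints is None:
        constraints = ConstraintSpec()
    loglik, names = make_loglik(tree, tips, family, method)
    roots, zeroed, reps = constraints.resolve(names)
    r_hat = max((tree.n_tips - 2) / tree.total_branch_length(), 1e-4)
    prior = ExponentialPrior({nm: 1.0 / (2.0 * r_hat) for nm in reps})

    def free_loglik(theta: np.ndarray) -> float:
        return loglik(constraints.expand(names, dict(zip(reps, theta))))

    if init is None:
        base = _heuristic_init(tree, family, names)
        theta0 = np.array([base[list(names).index(r)] for r in reps])
    else:
        theta0 = np.array([init[r] for r in reps])
    trace = mh_sample(
        free_loglik, prior, 1.0, iterations, seed,
        init=theta0, window=window,
        burn_in_frac=burn_in / iterations,
    )
    # summarize full parameter set plus derived net diversification rates
    post = trace.post_burnin()
    rows = []
    rep_col = {r: post[:, i] for i, r in enumerate(reps)}
    full_cols = {}
    for i, nm in enumerate(names):
        col = np.zeros(len(post)) if zeroed[i] else rep_col[names[roots[i]]]
        full_cols[nm] = col
        lo, hi = hpd_interval(col) if col.std() > 0 else (col[0], col[0])
        rows.append((nm, float(col.mean()), lo, hi))
    if family == "geosse":
        derived = {"r_A": full_cols["sA"] - full_cols["xA"],
                   "r_B": full_cols["sB"] - full_cols["xB"]}
    else:
        k = tips.n_states
        derived = {
            f"r_{i}": full_cols[f"lam{i}"] - full_cols[f"mu{i}"] for i in range(k)
        }
    for nm, col in derived.items():
        lo, hi = hpd_interval(col) if col.std() > 0 else (col[0], col[0])
        rows.append((nm, float(col.mean()), lo, hi))
    summary = pd.DataFrame(rows, columns=["param", "mean", "hpd_lo", "hpd_hi"])
    return trace, summary
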