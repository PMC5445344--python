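"""Forward simulators: birth-death trees (with clade rate shifts and incomplete
sampling), Markov characters on fixed trees, and joint tree+state simulation
under BiSSE-type and GeoSSE processes.

All generators are exact Gillespie simulations started from two crown lineages,
conditioned on survival to the stopping rule by resimulation.  They emulate the
empirical data regime of a mid-sized plant radiation: trees of 50-300 tips,
crown ages of tens of Myr, net diversification rates of ~0.05-0.5 /Myr,
character transition rates of ~0.003-0.06 /Myr and sampling fractions 0.5-0.9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .birthdeath import BDParams, Regime, RegimeModel
from .treeio import CladeDefinition, UltrametricTree

__all__ = [
    "SimulationFailure",
    "SimConfig",
    "sim_bd_tree",
    "sim_shift_tree",
    "sim_mk",
    "sim_sse_tree",
    "stationary_distribution",
    "simulate_from_config",
]

MAX_ATTEMPTS = 10_000

GEOSSE_STATES = ("A", "B", "AB")


class SimulationFailure(RuntimeError):
    """Raised when conditioning on survival fails too many times."""


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(int(rng))


@dataclass
class SimConfig:
    """Declarative simulation request: kind, parameters, stopping rule, seed."""

    kind: str  # bd_tree | shift_tree | mk_traits | sse_tree
    params: dict
    stop: dict = field(default_factory=dict)  # {"taxa": n} or {"age": t}
    rho: float | dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("bd_tree", "shift_tree", "mk_traits", "sse_tree"):
            raise ValueError(f"unknown simulation kind {self.kind!r}")
        if self.kind != "mk_traits" and len(self.stop) != 1:
            raise ValueError("exactly one stopping rule (taxa or age) required")
        if self.seed is None:
            raise ValueError("seed is mandatory")


# -- internal event-record bookkeeping --------------------------------------


class _Recorder:
    """Grows node records during forward simulation.

    ``tau[i]`` is the absolute time of node i's own event (speciation,
    extinction, or the present for surviving tips); branch length above i is
    tau[i] - tau[parent[i]].
    """

    def __init__(self):
        self.parent: list[int] = []
        self.tau: list[float] = []

    def new_node(self, parent: int) -> int:
        self.parent.append(parent)
        self.tau.append(math.nan)
        return len(self.parent) - 1


def _prune_and_build(
    rec: _Recorder,
    tip_ids: Sequence[int],
    present: float,
    tip_payload: Mapping[int, object] | None = None,
) -> tuple[UltrametricTree, dict[str, object]]:
    """Build an UltrametricTree from surviving tip ids, suppressing dead and
    unsampled lineages and re-rooting at the crown of the retained tips."""
    if len(tip_ids) < 2:
        raise SimulationFailure("fewer than 2 surviving tips")
    n = len(rec.parent)
    keep = np.zeros(n, dtype=bool)
    for tid in tip_ids:
        i = tid
        while i >= 0 and not keep[i]:
            keep[i] = True
            i = rec.parent[i]
    tipset = set(tip_ids)
    kept_children: dict[int, list[int]] = {i: [] for i in range(n) if keep[i]}
    for i in range(n):
        if keep[i] and rec.parent[i] >= 0 and keep[rec.parent[i]]:
            kept_children[rec.parent[i]].append(i)
    # crown of the retained tips: descend while a single kept child
    root = 0
    while root not in tipset and len(kept_children[root]) == 1:
        root = kept_children[root][0]
    # retained nodes: the new root, tips, and internal nodes with 2 kept children
    order: list[int] = []
    stack = [root]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(kept_children[i])
    retained = [
        i for i in order if i == root or i in tipset or len(kept_children[i]) == 2
    ]
    rset = set(retained)
    remap = {old: new for new, old in enumerate(retained)}
    parent_new, length_new, label_new = [], [], []
    payload: dict[str, object] = {}
    tip_counter = 0
    tau = list(rec.tau)
    for tid in tip_ids:
        tau[tid] = present
    for old in retained:
        if old == root:
            parent_new.append(-1)
            length_new.append(0.0)
        else:
            anc = rec.parent[old]
            while anc not in rset:
                anc = rec.parent[anc]
            parent_new.append(remap[anc])
            length_new.append(tau[old] - tau[anc])
        if old in tipset:
            tip_counter += 1
            lb = f"t{tip_counter}"
            label_new.append(lb)
            if tip_payload is not None:
                payload[lb] = tip_payload[old]
        else:
            label_new.append(None)
    tree = UltrametricTree(parent_new, length_new, label_new)
    return tree, payload


# -- birth-death trees -------------------------------------------------------


def _check_stop(stop: dict) -> tuple[str, float]:
    if len(stop) != 1 or next(iter(stop)) not in ("taxa", "age"):
        raise ValueError("stop must be exactly one of {'taxa': n} or {'age': t}")
    ((kind, value),) = stop.items()
    if kind == "taxa" and (int(value) != value or value < 2):
        raise ValueError("taxa stop must be an integer >= 2")
    if value <= 0:
        raise ValueError("stopping value must be positive")
    return kind, float(value)


def sim_bd_tree(
    lam: float,
    mu: float,
    stop: dict,
    rho: float = 1.0,
    rng=0,
) -> UltrametricTree:
    """Simulate a constant-rate birth-death tree from two crown lineages.

    ``stop`` is ``{"taxa": n}`` (n extant lineages; the present is drawn
    uniformly within the waiting interval that follows) or ``{"age": t}``.
    Each surviving tip is then retained independently with probability ``rho``.
    Resimulates on extinction (or <2 retained tips); the attempt count is
    stored on the returned tree as ``sim_attempts``.
    """
    if lam <= 0 or mu < 0:
        raise ValueError("need lam > 0 and mu >= 0")
    if not (0 < rho <= 1):
        raise ValueError("rho must be in (0, 1]")
    rng = _as_rng(rng)
    kind, value = _check_stop(stop)
    per = lam + mu
    for attempt in range(1, MAX_ATTEMPTS + 1):
        rec = _Recorder()
        root = rec.new_node(-1)
        rec.tau[root] = 0.0
        active = [rec.new_node(root), rec.new_node(root)]
        t = 0.0
        present = None
        while True:
            n_act = len(active)
            if n_act == 0:
                break
            if kind == "taxa" and n_act == int(value):
                w = rng.exponential(1.0 / (n_act * per))
                present = t + rng.uniform() * w
                break
            dt = rng.exponential(1.0 / (n_act * per))
            if kind == "age" and t + dt > value:
                present = value
                break
            t += dt
            idx = int(rng.integers(n_act))
            node = active[idx]
            rec.tau[node] = t
            if rng.uniform() < lam / per:
                active[idx] = rec.new_node(node)
                active.append(rec.new_node(node))
            else:
                active.pop(idx)
        if present is None:
            continue
        tips = list(active)
        if rho < 1.0:
            tips = [i for i in tips if rng.uniform() < rho]
        if len(tips) < 2:
            continue
        tree, _ = _prune_and_build(rec, tips, present)
        tree.sim_attempts = attempt
        return tree
    raise SimulationFailure(f"no surviving tree in {MAX_ATTEMPTS} attempts")


def sim_shift_tree(
    background: BDParams,
    shift_age: float,
    shift_params: BDParams,
    stop: dict,
    rng=0,
    min_clade_tips: int = 2,
) -> tuple[UltrametricTree, RegimeModel]:
    """Simulate a tree in which one lineage alive at ``shift_age`` (Myr before
    present) founds a new rate regime inherited by all its descendants.

    Only age stopping is supported (the shift age is anchored to the present).
    Returns the tree and the true two-regime model (shifted clade + background),
    with the shifted clade addressed by its surviving tip labels (crown
    semantics).  Replicates where the shifted clade retains fewer than
    ``min_clade_tips`` tips are resimulated.
    """
    kind, value = _check_stop(stop)
    if kind != "age":
        raise ValueError("sim_shift_tree requires an age stopping rule")
    if shift_age >= value:
        raise ValueError("shift age must be younger than the crown age")
    rng = _as_rng(rng)
    t_shift = value - shift_age
    rates = {
        False: (background.lam, background.mu),
        True: (shift_params.lam, shift_params.mu),
    }
    for attempt in range(1, MAX_ATTEMPTS + 1):
        rec = _Recorder()
        root = rec.new_node(-1)
        rec.tau[root] = 0.0
        active = [rec.new_node(root), rec.new_node(root)]
        shifted = {active[0]: False, active[1]: False}
        t = 0.0
        shift_done = False
        survived = True
        while True:
            if not active:
                survived = False
                break
            tot = sum(sum(rates[shifted[i]]) for i in active)
            dt = rng.exponential(1.0 / tot)
            if not shift_done and t + dt > t_shift:
                t = t_shift
                pick = int(rng.integers(len(active)))
                shifted[active[pick]] = True
                shift_done = True
                continue
            if t + dt > value:
                break
            t += dt
            weights = np.array([sum(rates[shifted[i]]) for i in active])
            idx = int(rng.choice(len(active), p=weights / weights.sum()))
            node = active[idx]
            lam_i, mu_i = rates[shifted[node]]
            rec.tau[node] = t
            if rng.uniform() < lam_i / (lam_i + mu_i):
                c1, c2 = rec.new_node(node), rec.new_node(node)
                shifted[c1] = shifted[c2] = shifted[node]
                active[idx] = c1
                active.append(c2)
            else:
                active.pop(idx)
        if not survived or not shift_done or len(active) < 2:
            continue
        clade_tips = [i for i in active if shifted[i]]
        if len(clade_tips) < min_clade_tips or len(active) - len(clade_tips) < 2:
            continue
        tree, payload = _prune_and_build(
            rec, list(active), value, {i: shifted[i] for i in active}
        )
        shifted_labels = frozenset(lb for lb, s in payload.items() if s)
        clade = CladeDefinition("shifted", shifted_labels)
        truth = RegimeModel(
            [
                Regime(clade, "PB" if shift_params.mu == 0 else "BD", "shift"),
                Regime(None, "PB" if background.mu == 0 else "BD", "bg"),
            ],
            name="true-shift",
        )
        tree.sim_attempts = attempt
        return tree, truth
    raise SimulationFailure(f"no usable shift tree in {MAX_ATTEMPTS} attempts")


# -- Markov characters on a fixed tree ---------------------------------------


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a CTMC rate matrix (rows sum to zero)."""
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def _validate_q(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < 0):
        raise ValueError("off-diagonal rates must be >= 0")
    if not np.allclose(Q.sum(axis=1), 0, atol=1e-10):
        raise ValueError("rows of Q must sum to zero")
    return Q


def sim_mk(
    tree: UltrametricTree,
    Q: np.ndarray,
    root_state: int | str = "stationary",
    rng=0,
) -> dict[str, int]:
    """Exact simulation of a k-state Markov character down a fixed tree.

    Returns tip label -> state.  ``root_state`` is a state index or
    ``"stationary"`` (draw from the chain's stationary distribution).
    """
    Q = _validate_q(Q)
    rng = _as_rng(rng)
    k = Q.shape[0]
    if root_state == "stationary":
        start = int(rng.choice(k, p=stationary_distribution(Q)))
    else:
        start = int(root_state)
        if not 0 <= start < k:
            raise ValueError(f"root state {start} out of range")
    state = np.empty(tree.n_nodes, dtype=int)
    state[tree.root] = start
    exit_rate = -np.diag(Q)
    for i in tree.preorder():
        if i == tree.root:
            continue
        s = state[tree.parent[i]]
        remaining = float(tree.length[i])
        while exit_rate[s] > 0:
            w = rng.exponential(1.0 / exit_rate[s])
            if w > remaining:
                break
            remaining -= w
            probs = Q[s].copy()
            probs[s] = 0.0
            probs /= probs.sum()
            s = int(rng.choice(k, p=probs))
        state[i] = s
    return {tree.label[i]: int(state[i]) for i in tree.tip_indices()}


# -- joint tree + state simulation (BiSSE / MuSSE / GeoSSE) -------------------


def _musse_event_table(lam, mu, Q):
    """Per-state (total_rate, callback) tables for the k-state SSE process."""
    k = len(lam)
    table = []
    for s in range(k):
        events = [("spec", s, lam[s]), ("ext", s, mu[s])]
        for j in range(k):
            if j != s and Q[s, j] > 0:
                events.append(("trans", j, Q[s, j]))
        table.append(events)
    return table


def _geosse_event_table(p):
    """GeoSSE per-state events; states 0=A, 1=B, 2=AB.

    Widespread (AB) lineages: within-region speciation leaves one daughter
    widespread and one endemic; between-region speciation splits AB into
    daughters A and B; local extinction contracts the range.
    """
    sA, sB, sAB, xA, xB, dA, dB = p
    return [
        [("spec", (0, 0), sA), ("ext", None, xA), ("trans", 2, dA)],
        [("spec", (1, 1), sB), ("ext", None, xB), ("trans", 2, dB)],
        [
            ("spec", (2, 0), sA),
            ("spec", (2, 1), sB),
            ("spec", (0, 1), sAB),
            ("trans", 1, xA),  # lose region A -> endemic B
            ("trans", 0, xB),  # lose region B -> endemic A
        ],
    ]


def sim_sse_tree(
    family: str,
    params,
    stop: dict,
    rho=1.0,
    rng=0,
    root_state: int | str = "stationary",
) -> tuple[UltrametricTree, dict[str, int]]:
    """Joint Gillespie simulation of tree and states under BiSSE/MuSSE/GeoSSE.

    ``params`` is (lam, mu, Q) for bisse/musse or a 7-sequence
    (sA, sB, sAB, xA, xB, dA, dB) for geosse.  ``rho`` is a scalar or a
    per-state sequence of sampling fractions applied to the surviving tips.
    Returns the pruned tree and tip label -> state index (GeoSSE: 0=A, 1=B,
    2=AB).
    """
    rng = _as_rng(rng)
    kind, value = _check_stop(stop)
    if family in ("bisse", "musse"):
        lam, mu, Q = params
        lam = np.asarray(lam, float)
        mu = np.asarray(mu, float)
        Q = _validate_q(Q)
        k = len(lam)
        table = _musse_event_table(lam, mu, Q)
        if root_state == "stationary":
            pi = stationary_distribution(Q)
        else:
            pi = np.zeros(k)
            pi[int(root_state)] = 1.0
    elif family == "geosse":
        p = [float(v) for v in params]
        if len(p) != 7 or any(v < 0 for v in p):
            raise ValueError("geosse params must be 7 non-negative rates")
        k = 3
        table = _geosse_event_table(p)
        if root_state == "stationary":
            pi = np.zeros(3)
            pi[2] = 1.0  # widespread crown ancestor by default
        else:
            pi = np.zeros(3)
            pi[int(root_state)] = 1.0
    else:
        raise ValueError(f"unknown family {family!r}")
    rho_vec = np.full(k, rho, dtype=float) if np.isscalar(rho) else np.asarray(rho, float)
    if len(rho_vec) != k or np.any(rho_vec <= 0) or np.any(rho_vec > 1):
        raise ValueError("rho must be scalar or per-state fractions in (0, 1]")
    totals = np.array([sum(e[2] for e in evs) for evs in table])

    for attempt in range(1, MAX_ATTEMPTS + 1):
        rec = _Recorder()
        root = rec.new_node(-1)
        rec.tau[root] = 0.0
        s0 = int(rng.choice(k, p=pi))
        active = [rec.new_node(root), rec.new_node(root)]
        state = {active[0]: s0, active[1]: s0}
        t = 0.0
        present = None
        while True:
            if not active:
                break
            rate_sum = float(sum(totals[state[i]] for i in active))
            if rate_sum <= 0:
                if kind == "age":
                    present = value
                break
            if kind == "taxa" and len(active) == int(value):
                w = rng.exponential(1.0 / rate_sum)
                present = t + rng.uniform() * w
                break
            dt = rng.exponential(1.0 / rate_sum)
            if kind == "age" and t + dt > value:
                present = value
                break
            t += dt
            weights = np.array([totals[state[i]] for i in active])
            idx = int(rng.choice(len(active), p=weights / weights.sum()))
            node = active[idx]
            s = state[node]
            events = table[s]
            probs = np.array([e[2] for e in events])
            ev, arg, _ = events[int(rng.choice(len(events), p=probs / probs.sum()))]
            if ev == "trans":
                state[node] = arg
            elif ev == "ext":
                rec.tau[node] = t
                active.pop(idx)
                del state[node]
            else:  # speciation
                rec.tau[node] = t
                c1, c2 = rec.new_node(node), rec.new_node(node)
                if isinstance(arg, tuple):
                    state[c1], state[c2] = arg
                else:
                    state[c1] = state[c2] = s
                del state[node]
                active[idx] = c1
                active.append(c2)
        if present is None:
            continue
        tips = [i for i in active if rng.uniform() < rho_vec[state[i]]]
        if len(tips) < 2:
            continue
        tree, payload = _prune_and_build(rec, tips, present, state)
        tree.sim_attempts = attempt
        return tree, {lb: int(s) for lb, s in payload.items()}
    raise SimulationFailure(f"no surviving tree in {MAX_ATTEMPTS} attempts")


# -- config dispatch ---------------------------------------------------------


def simulate_from_config(config: SimConfig, tree: UltrametricTree | None = None):
    """Run the generator a SimConfig describes (mk_traits requires ``tree``)."""
    rng = np.random.default_rng(config.seed)
    if config.kind == "bd_tree":
        return sim_bd_tree(
            config.params["lam"],
            config.params.get("mu", 0.0),
            config.stop,
            rho=config.rho if config.rho is not None else 1.0,
            rng=rng,
        )
    if config.kind == "shift_tree":
        return sim_shift_tree(
            BDParams(**config.params["background"]),
            config.params["shift_age"],
            BDParams(**config.params["shift"]),
            config.stop,
            rng=rng,
        )
    if config.kind == "mk_traits":
        if tree is None:
            raise ValueError("mk_traits simulation needs a tree")
        return sim_mk(
            tree,
            np.asarray(config.params["Q"], float),
            config.params.get("root_state", "stationary"),
            rng=rng,
        )
    return sim_sse_tree(
        config.params["family"],
        config.params["params"],
        config.stop,
        rho=config.rho if config.rho is not None else 1.0,
        rng=rng,
        root_state=config.params.get("root_state", "stationary"),
    )
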