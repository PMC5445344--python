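"""Compiled pruning kernels for the SSE likelihoods.

Each kernel performs the post-order tree traversal, integrating the coupled
(E, D) ODE system along every branch with a fixed-step classic Runge-Kutta
scheme (step count proportional to branch length) and rescaling D at every
node to prevent underflow.  These are the fast default compute path; the
LSODA per-branch path in :mod:`saxdiv.sse` is the high-accuracy reference.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["musse_prune", "geosse_prune"]


@njit(cache=False)
def _musse_rhs(E, D, lam, mu, Q, dE, dD):
    k = E.shape[0]
    for i in range(k):
        qe = 0.0
        qd = 0.0
        for j in range(k):
            qe += Q[i, j] * E[j]
            qd += Q[i, j] * D[j]
        tot = lam[i] + mu[i]
        dE[i] = mu[i] - tot * E[i] + lam[i] * E[i] * E[i] + qe
        dD[i] = -tot * D[i] + 2.0 * lam[i] * E[i] * D[i] + qd


@njit(cache=False)
def _musse_branch(E, D, length, lam, mu, Q, steps_per, min_steps):
    k = E.shape[0]
    nst = min_steps + int(length * steps_per)
    if nst > 1000:
        nst = 1000
    h = length / nst
    k1e = np.empty(k); k1d = np.empty(k)
    k2e = np.empty(k); k2d = np.empty(k)
    k3e = np.empty(k); k3d = np.empty(k)
    k4e = np.empty(k); k4d = np.empty(k)
    te = np.empty(k); td = np.empty(k)
    for _ in range(nst):
        _musse_rhs(E, D, lam, mu, Q, k1e, k1d)
        for i in range(k):
            te[i] = E[i] + 0.5 * h * k1e[i]
            td[i] = D[i] + 0.5 * h * k1d[i]
        _musse_rhs(te, td, lam, mu, Q, k2e, k2d)
        for i in range(k):
            te[i] = E[i] + 0.5 * h * k2e[i]
            td[i] = D[i] + 0.5 * h * k2d[i]
        _musse_rhs(te, td, lam, mu, Q, k3e, k3d)
        for i in range(k):
            te[i] = E[i] + h * k3e[i]
            td[i] = D[i] + h * k3d[i]
        _musse_rhs(te, td, lam, mu, Q, k4e, k4d)
        for i in range(k):
            E[i] += h * (k1e[i] + 2.0 * k2e[i] + 2.0 * k3e[i] + k4e[i]) / 6.0
            D[i] += h * (k1d[i] + 2.0 * k2d[i] + 2.0 * k3d[i] + k4d[i]) / 6.0


@njit(cache=False)
def musse_prune(order, child1, child2, length, tip_d, tip_e,
                lam, mu, Q, steps_per, min_steps):
    """Post-order pruning; returns (E_root, D_root, log_scaler).

    ``order`` lists node indices in post-order with the root last; ``child1``
    is -1 for tips.  ``tip_d[node]`` holds D(0) for tips; ``tip_e`` holds the
    shared per-state E(0) = 1 - rho.
    """
    nnodes = order.shape[0]
    k = lam.shape[0]
    Etop = np.zeros((nnodes, k))
    Dtop = np.zeros((nnodes, k))
    logscale = 0.0
    root = order[nnodes - 1]
    for idx in range(nnodes):
        node = order[idx]
        c1 = child1[node]
        E = np.empty(k)
        D = np.empty(k)
        if c1 < 0:
            for i in range(k):
                E[i] = tip_e[i]
                D[i] = tip_d[node, i]
        else:
            c2 = child2[node]
            for i in range(k):
                E[i] = 0.5 * (Etop[c1, i] + Etop[c2, i])
                D[i] = lam[i] * Dtop[c1, i] * Dtop[c2, i]
        mx = 0.0
        for i in range(k):
            if D[i] > mx:
                mx = D[i]
        if mx > 0.0:
            for i in range(k):
                D[i] /= mx
            logscale += np.log(mx)
        if node != root:
            _musse_branch(E, D, length[node], lam, mu, Q, steps_per, min_steps)
        for i in range(k):
            Etop[node, i] = E[i]
            Dtop[node, i] = D[i]
    return Etop[root], Dtop[root], logscale


@njit(cache=False)
def _geosse_rhs(E, D, p, dE, dD):
    sA, sB, sAB, xA, xB, dA, dB = p[0], p[1], p[2], p[3], p[4], p[5], p[6]
    EA, EB, EAB = E[0], E[1], E[2]
    DA, DB, DAB = D[0], D[1], D[2]
    totA = sA + dA + xA
    totB = sB + dB + xB
    totAB = sA + sB + sAB + xA + xB
    dE[0] = xA - totA * EA + sA * EA * EA + dA * EAB
    dE[1] = xB - totB * EB + sB * EB * EB + dB * EAB
    dE[2] = -totAB * EAB + xA * EB + xB * EA \
        + sA * EA * EAB + sB * EB * EAB + sAB * EA * EB
    dD[0] = -totA * DA + 2.0 * sA * EA * DA + dA * DAB
    dD[1] = -totB * DB + 2.0 * sB * EB * DB + dB * DAB
    dD[2] = -totAB * DAB + xA * DB + xB * DA \
        + sA * (EA * DAB + EAB * DA) \
        + sB * (EB * DAB + EAB * DB) \
        + sAB * (EA * DB + EB * DA)


@njit(cache=False)
def _geosse_branch(E, D, length, p, steps_per, min_steps):
    nst = min_steps + int(length * steps_per)
    if nst > 1000:
        nst = 1000
    h = length / nst
    k1e = np.empty(3); k1d = np.empty(3)
    k2e = np.empty(3); k2d = np.empty(3)
    k3e = np.empty(3); k3d = np.empty(3)
    k4e = np.empty(3); k4d = np.empty(3)
    te = np.empty(3); td = np.empty(3)
    for _ in range(nst):
        _geosse_rhs(E, D, p, k1e, k1d)
        for i in range(3):
            te[i] = E[i] + 0.5 * h * k1e[i]
            td[i] = D[i] + 0.5 * h * k1d[i]
        _geosse_rhs(te, td, p, k2e, k2d)
        for i in range(3):
            te[i] = E[i] + 0.5 * h * k2e[i]
            td[i] = D[i] + 0.5 * h * k2d[i]
        _geosse_rhs(te, td, p, k3e, k3d)
        for i in range(3):
            te[i] = E[i] + h * k3e[i]
            td[i] = D[i] + h * k3d[i]
        _geosse_rhs(te, td, p, k4e, k4d)
        for i in range(3):
            E[i] += h * (k1e[i] + 2.0 * k2e[i] + 2.0 * k3e[i] + k4e[i]) / 6.0
            D[i] += h * (k1d[i] + 2.0 * k2d[i] + 2.0 * k3d[i] + k4d[i]) / 6.0


@njit(cache=False)
def geosse_prune(order, child1, child2, length, tip_d, tip_e, p,
                 steps_per, min_steps):
    """GeoSSE post-order pruning (states 0=A, 1=B, 2=AB); see musse_prune.

    A widespread parent combines daughters with the symmetrized half-sum over
    the three speciation modes.
    """
    sA, sB, sAB = p[0], p[1], p[2]
    nnodes = order.shape[0]
    Etop = np.zeros((nnodes, 3))
    Dtop = np.zeros((nnodes, 3))
    logscale = 0.0
    root = order[nnodes - 1]
    for idx in range(nnodes):
        node = order[idx]
        c1 = child1[node]
        E = np.empty(3)
        D = np.empty(3)
        if c1 < 0:
            for i in range(3):
                E[i] = tip_e[i]
                D[i] = tip_d[node, i]
        else:
            c2 = child2[node]
            for i in range(3):
                E[i] = 0.5 * (Etop[c1, i] + Etop[c2, i])
            D[0] = sA * Dtop[c1, 0] * Dtop[c2, 0]
            D[1] = sB * Dtop[c1, 1] * Dtop[c2, 1]
            D[2] = 0.5 * (
                sA * (Dtop[c1, 0] * Dtop[c2, 2] + Dtop[c1, 2] * Dtop[c2, 0])
                + sB * (Dtop[c1, 1] * Dtop[c2, 2] + Dtop[c1, 2] * Dtop[c2, 1])
                + sAB * (Dtop[c1, 0] * Dtop[c2, 1] + Dtop[c1, 1] * Dtop[c2, 0])
            )
        mx = 0.0
        for i in range(3):
            if D[i] > mx:
                mx = D[i]
        if mx > 0.0:
            for i in range(3):
                D[i] /= mx
            logscale += np.log(mx)
        if node != root:
            _geosse_branch(E, D, length[node], p, steps_per, min_steps)
        for i in range(3):
            Etop[node, i] = E[i]
            Dtop[node, i] = D[i]
    return Etop[root], Dtop[root], logscale
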