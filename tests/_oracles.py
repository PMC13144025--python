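"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here is deliberately written from first principles (union-find,
run-length scans, hand-built CTMC generators, closed forms) so it exercises
none of the package code paths it is used to check.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm


# ---------------------------------------------------------------------------
# geometry

def union_find_clusters(positions_nm: np.ndarray, link_radius: float):
    """Connected components by naive union-find on pairwise distances."""
    n = len(positions_nm)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(positions_nm[i] - positions_nm[j])) <= link_radius:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


# ---------------------------------------------------------------------------
# Markov chains

def two_ryr_generator(k_plus: float, k_minus: float, ej: float) -> np.ndarray:
    """4-state CTMC (cc, co, oc, oo) for two adjacent coupled RyRs.

    num_net for an opening is (open - closed) neighbors; for a closing the
    negation; each channel has exactly one neighbor.
    """
    ko_closed_nbr = k_plus * np.exp(-ej)   # opening next to a closed channel
    ko_open_nbr = k_plus * np.exp(+ej)
    kc_open_nbr = k_minus * np.exp(-ej)    # closing next to an open channel
    kc_closed_nbr = k_minus * np.exp(+ej)
    Q = np.zeros((4, 4))
    # states: 0=cc, 1=co (B open), 2=oc (A open), 3=oo
    Q[0, 1] = ko_closed_nbr   # B opens, A closed
    Q[0, 2] = ko_closed_nbr
    Q[1, 3] = ko_open_nbr     # A opens next to open B
    Q[1, 0] = kc_closed_nbr   # B closes next to closed A
    Q[2, 3] = ko_open_nbr
    Q[2, 0] = kc_closed_nbr
    Q[3, 1] = kc_open_nbr     # A closes next to open B
    Q[3, 2] = kc_open_nbr
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def ctmc_occupancy(Q: np.ndarray, state0: int, t: float) -> np.ndarray:
    """Occupancy row of exp(Q t) from ``state0``."""
    return expm(Q * t)[state0]


def detailed_balance_pi(q12, q21, q23, q32, q26, q62, q24, q42, q45, q54):
    """Stationary vector of the six-state tree by edge-product weights."""
    w = np.empty(6)
    w[1] = 1.0                 # state 2 reference
    w[0] = q21 / q12
    w[2] = q23 / q32
    w[5] = q26 / q62
    w[3] = q24 / q42
    w[4] = w[3] * q45 / q54
    return w / w.sum()


# ---------------------------------------------------------------------------
# traces

def run_length_episodes(total_open: np.ndarray):
    """Brute-force scan for maximal nonzero runs; returns (i0, i1, peak)."""
    eps = []
    cur = None
    for i, v in enumerate(total_open):
        if v > 0:
            if cur is None:
                cur = [i, i, v]
            else:
                cur[1] = i
                cur[2] = max(cur[2], v)
        elif cur is not None:
            eps.append(tuple(cur))
            cur = None
    if cur is not None:
        eps.append(tuple(cur))
    return eps


def riemann_integral(y: np.ndarray, t: np.ndarray, refine: int = 200):
    """Fine-grid midpoint integral of the piecewise-linear interpolant."""
    total = 0.0
    for i in range(len(t) - 1):
        ts = np.linspace(t[i], t[i + 1], refine + 1)
        ys = np.interp(ts, [t[i], t[i + 1]], [y[i], y[i + 1]])
        total += np.sum(0.5 * (ys[1:] + ys[:-1]) * np.diff(ts))
    return total
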