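"""Six-state park/drive IP3R2 Markov gating.

States 1-6; open states {5, 6}; park mode {4, 5} (low open probability,
P_O ~ 1e-3 via the slow 4<->5 edge), drive mode {1, 2, 3, 6} (high open
probability, P_O ~ 0.68 via the fast 2<->6 edge).  The transition graph is a
tree: 1-2, 2-3, 2-6, 2-4, 4-5.  Intra-modal rates are fixed; the intermodal
rates q24 (drive->park) and q42 (park->drive) carry all Ca²⁺ and IP3
dependence:

    q24 = a24(p) + v24 * (1 - m24(c,p) * h24(c,p))
    q42 = a42(p) + v42 * m42(c,p) * h42(c,p)

The modal gates are Hill forms (see :func:`modal_gates`): ``m`` activates
with Ca³, ``h`` inhibits with Ca³ at a threshold that IP3 relieves, and the
h42 gate additionally requires IP3 binding, so the drive mode — and hence
conduction — is unreachable without IP3.
"""

from __future__ import annotations

import warnings

import numpy as np
from numba import njit
from scipy.linalg import null_space

from .params import IP3RParams, StabilityError

__all__ = [
    "OPEN_STATES", "PARK_STATES", "DRIVE_STATES",
    "modal_gates", "intermodal_rates", "build_generator",
    "stationary_distribution", "step_ip3r", "po_curve", "initial_state",
    "max_exit_rate",
]

OPEN_STATES = (5, 6)
PARK_STATES = (4, 5)
DRIVE_STATES = (1, 2, 3, 6)

# tree edges as (from, to) in 1-based labels
_EDGES = ((1, 2), (2, 3), (2, 6), (2, 4), (4, 5))


@njit(cache=True)
def _gates_scalar(c, p, k_ip3, km_act, kh_base, kh_amp, kh_kp):
    """Modal gate values (m, h, g_ip3) at Ca ``c`` and IP3 ``p`` (µM)."""
    c3 = c * c * c
    km3 = km_act ** 3
    m = c3 / (c3 + km3)
    kh = kh_base + kh_amp * p * p / (p * p + kh_kp * kh_kp)
    kh3 = kh ** 3
    h = kh3 / (kh3 + c3)
    gp = p * p / (p * p + k_ip3 * k_ip3)
    return m, h, gp


@njit(cache=True)
def _intermodal_scalar(c, p, v24, a24_max, a42_max, k_ip3, km_act,
                       kh_base, kh_amp, kh_kp, v42):
    m, h, gp = _gates_scalar(c, p, k_ip3, km_act, kh_base, kh_amp, kh_kp)
    a24 = a24_max * (1.0 - gp)
    a42 = a42_max * gp
    q24 = a24 + v24 * (1.0 - m * h)
    q42 = a42 + v42 * m * h * gp
    return q24, q42


def modal_gates(c: float, p: float, params: IP3RParams):
    """Return the gate values ``(m24, h24, m42, h42, a24, a42)``.

    This is the single replaceable component housing the Ca/IP3 dependence:
    ``m24 = m42 = c³/(c³+km³)``; ``h24 = kh(p)³/(kh(p)³+c³)`` with
    ``kh(p) = kh_base + kh_amp·p²/(p²+kh_kp²)``; ``h42 = h24·g(p)`` with the
    IP3 occupancy ``g(p) = p²/(p²+k_ip3²)``; ``a24`` decays and ``a42`` rises
    with ``g(p)``.
    """
    m, h, gp = _gates_scalar(float(c), float(p), params.k_ip3, params.km_act,
                             params.kh_base, params.kh_amp, params.kh_kp)
    a24 = params.a24_max * (1.0 - gp)
    a42 = params.a42_max * gp
    return m, h, m, h * gp, a24, a42


def intermodal_rates(c_ds: float, ip3: float,
                     params: IP3RParams) -> tuple[float, float]:
    """(q24, q42) in ms⁻¹ at dyadic Ca ``c_ds`` and IP3 ``ip3`` (µM)."""
    if c_ds < 0 or ip3 < 0:
        raise ValueError("concentrations must be >= 0")
    q24, q42 = _intermodal_scalar(
        float(c_ds), float(ip3), params.v24, params.a24_max, params.a42_max,
        params.k_ip3, params.km_act, params.kh_base, params.kh_amp,
        params.kh_kp, params.v42)
    return float(q24), float(q42)


def build_generator(q24: float, q42: float, params: IP3RParams) -> np.ndarray:
    """6x6 generator with the tree topology; rows sum to zero."""
    if q24 < 0 or q42 < 0:
        raise ValueError("intermodal rates must be >= 0")
    rate = {(1, 2): params.q12, (2, 1): params.q21,
            (2, 3): params.q23, (3, 2): params.q32,
            (2, 6): params.q26, (6, 2): params.q62,
            (2, 4): q24, (4, 2): q42,
            (4, 5): params.q45, (5, 4): params.q54}
    Q = np.zeros((6, 6))
    for (i, j), r in rate.items():
        Q[i - 1, j - 1] = r
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(gen: np.ndarray) -> np.ndarray:
    """Stationary probability vector of the six-state generator.

    Solved from the null space of Qᵀ.  Because the transition graph is a
    tree, the result also satisfies detailed balance edge by edge.  When the
    intermodal edge is severed (q24 or q42 zero) the chain is reducible; a
    warning is emitted and the distribution restricted to the absorbing mode
    is returned.
    """
    Q = np.asarray(gen, dtype=float)
    q24, q42 = Q[1, 3], Q[3, 1]
    if q24 == 0.0 or q42 == 0.0:
        warnings.warn("reducible six-state chain (q24*q42 == 0); returning "
                      "mode-restricted distribution", stacklevel=2)
        pi = np.zeros(6)
        if q42 == 0.0 and q24 > 0.0:    # park mode absorbs
            r = Q[3, 4] / Q[4, 3]       # q45/q54
            pi[3], pi[4] = 1.0 / (1.0 + r), r / (1.0 + r)
        elif q24 == 0.0 and q42 > 0.0:  # drive mode absorbs
            w = np.array([Q[1, 0] / Q[0, 1], 1.0, Q[1, 2] / Q[2, 1],
                          Q[1, 5] / Q[5, 1]])  # states 1,2,3,6 rel. to 2
            w /= w.sum()
            pi[[0, 1, 2, 5]] = w
        else:                            # both zero: split within start mode
            pi[3] = 1.0
        return pi
    ns = null_space(Q.T)
    if ns.shape[1] != 1:
        raise np.linalg.LinAlgError("generator null space is not 1-D")
    pi = np.abs(ns[:, 0])
    return pi / pi.sum()


def max_exit_rate(params: IP3RParams) -> float:
    """Upper bound on the total exit rate from any state, ms⁻¹."""
    q24_max = params.a24_max + params.v24
    q42_max = params.a42_max + params.v42
    exits = (params.q12,
             params.q21 + params.q23 + params.q26 + q24_max,
             params.q32,
             q42_max + params.q45,
             params.q54,
             params.q62)
    return max(exits)


def step_ip3r(state: int, gen: np.ndarray, dt: float,
              rng: np.random.Generator) -> int:
    """One fixed-dt step of a single channel; states are 1-based."""
    if not 1 <= state <= 6:
        raise ValueError("state must be in 1..6")
    row = np.asarray(gen, dtype=float)[state - 1].copy()
    row[state - 1] = 0.0
    p = dt * row
    total = p.sum()
    if total > 0.1:
        raise StabilityError("total exit probability per step exceeds 0.1; "
                             "reduce dt")
    u = rng.random()
    acc = 0.0
    for j in range(6):
        acc += p[j]
        if u < acc:
            return j + 1
    return state


@njit(cache=True)
def _evolve_states(states, n_steps, dt, Q, seed):
    """Evolve an ensemble of chains; returns total open (state 5/6) dwell steps."""
    np.random.seed(seed)
    n = states.shape[0]
    open_steps = 0
    for _ in range(n_steps):
        for k in range(n):
            s = states[k]
            u = np.random.random()
            acc = 0.0
            new = s
            for j in range(6):
                if j == s:
                    continue
                acc += dt * Q[s, j]
                if u < acc:
                    new = j
                    break
            states[k] = new
            if new >= 4:
                open_steps += 1
    return open_steps


def simulate_ensemble(n_chains: int, state0: int, c: float, p: float,
                      duration: float, params: IP3RParams, seed: int,
                      dt: float | None = None):
    """Fixed-dt simulation of independent channels at clamped (c, p).

    Returns ``(final_states, open_fraction)`` where ``open_fraction`` is the
    time fraction spent in the open states {5, 6}, pooled over chains.
    """
    q24, q42 = intermodal_rates(c, p, params)
    Q = build_generator(q24, q42, params)
    rates = Q.copy()
    np.fill_diagonal(rates, 0.0)
    if dt is None:
        dt = 0.1 / max(rates.sum(axis=1).max(), 1e-12)
    elif dt * rates.sum(axis=1).max() > 0.1:
        raise StabilityError("total exit probability per step exceeds 0.1")
    n_steps = max(1, int(round(duration / dt)))
    states = np.full(n_chains, state0 - 1, dtype=np.int64)
    open_steps = _evolve_states(states, n_steps, dt, Q, seed % 2**31)
    return states + 1, open_steps / (n_steps * n_chains)


def initial_state(c: float, p: float, params: IP3RParams,
                  rng: np.random.Generator) -> int:
    """Draw a 1-based state from the stationary distribution at (c, p).

    With no IP3 the channel is unliganded and inert: state 4 (closed park).
    """
    if p <= 0:
        return 4
    q24, q42 = intermodal_rates(c, p, params)
    pi = stationary_distribution(build_generator(q24, q42, params))
    return int(rng.choice(6, p=pi)) + 1


def po_curve(ca_grid, ip3: float, duration: float = 1000.0,
             mode: str = "STATIONARY", seed: int = 0,
             params: IP3RParams | None = None):
    """Open probability versus clamped dyadic [Ca²⁺].

    ``STATIONARY`` evaluates pi_5 + pi_6 of the stationary distribution at
    each Ca value; ``SIMULATED`` reproduces the single-channel protocol (one
    channel, fields clamped, ``duration`` ms of gating, open-time fraction).
    At ip3 = 0 the simulated channel is inert and P_O is exactly 0.
    """
    params = params or IP3RParams()
    out = []
    for i, c in enumerate(np.asarray(ca_grid, dtype=float)):
        if mode == "STATIONARY":
            q24, q42 = intermodal_rates(c, ip3, params)
            if q24 == 0.0 or q42 == 0.0:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pi = stationary_distribution(build_generator(q24, q42, params))
            else:
                pi = stationary_distribution(build_generator(q24, q42, params))
            po = float(pi[4] + pi[5])
        elif mode == "SIMULATED":
            if ip3 <= 0:
                po = 0.0
            else:
                rng = np.random.default_rng([seed, i])
                s0 = initial_state(c, ip3, params, rng)
                _, po = simulate_ensemble(1, s0, c, ip3, duration, params,
                                          seed=int(rng.integers(2**31)))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out.append((float(c), po))
    return out
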