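"""Two-state stochastic RyR2 gating.

Opening is a Hill function of dyadic [Ca²⁺] whose threshold K_r falls
linearly with JSR load (luminal regulation); closing is Ca-independent.
Edge-sharing neighbors interact through an exponential allosteric factor
``k_coup**num_net`` with ``k_coup = exp(EJ)``, where ``num_net`` counts open
minus closed 4-neighbors for an opening transition (and the negation for a
closing one), so coupling favors conformity with the neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RYR, CruGeometry, Site
from .params import RyRParams, StabilityError

__all__ = [
    "OPENING", "CLOSING", "RyRStateField",
    "activation_threshold", "opening_rate", "coupling_factor",
    "count_num_net", "step_ryr", "build_state_field", "max_transition_prob",
]

OPENING = "OPENING"
CLOSING = "CLOSING"

_NBR_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def activation_threshold(c_jsr, params: RyRParams):
    """K_r(c_jsr) = max(K_r,max - alpha_r * c_jsr, floor), in µM."""
    return np.maximum(params.k_r_max - params.alpha_r * np.asarray(c_jsr, float),
                      params.k_r_floor)


def opening_rate(c_ds, k_r, params: RyRParams):
    """Hill-type opening rate, ms⁻¹, bounded by k⁺_max."""
    c = np.asarray(c_ds, dtype=float)
    ch = np.where(c > 0, c, 0.0) ** params.hill
    kh = np.asarray(k_r, dtype=float) ** params.hill
    with np.errstate(invalid="ignore"):
        out = params.kplus_max * ch / (ch + kh)
    return np.where(ch == 0, 0.0, out)


def coupling_factor(num_net, params: RyRParams):
    """exp(EJ * num_net)."""
    return np.exp(params.ej * np.asarray(num_net, dtype=float))


@dataclass
class RyRStateField:
    """Open/closed flags for every RyR in a geometry.

    ``sites`` is the ordered RyR site list; ``nbr`` holds, per channel, the
    indices of its edge-sharing RyR neighbors (-1 padding); ``open_flags``
    is the binary state vector.
    """

    geom: CruGeometry
    sites: tuple[Site, ...]
    nbr: np.ndarray          # (n, 4) int64
    open_flags: np.ndarray   # (n,) uint8

    @property
    def n(self) -> int:
        return len(self.sites)

    def copy(self) -> "RyRStateField":
        return RyRStateField(self.geom, self.sites, self.nbr,
                             self.open_flags.copy())


def build_state_field(geom: CruGeometry) -> RyRStateField:
    """All-closed state field with precomputed 4-neighbor indices."""
    sites = geom.ryr_sites()
    index = {(s.ix, s.iy): k for k, s in enumerate(sites)}
    nbr = np.full((len(sites), 4), -1, dtype=np.int64)
    for k, s in enumerate(sites):
        for m, (dx, dy) in enumerate(_NBR_OFFSETS):
            nbr[k, m] = index.get((s.ix + dx, s.iy + dy), -1)
    return RyRStateField(geom=geom, sites=sites, nbr=nbr,
                         open_flags=np.zeros(len(sites), dtype=np.uint8))


def count_num_net(site: Site, states: RyRStateField, geom: CruGeometry,
                  direction: str = OPENING) -> int:
    """Open-minus-closed count over the RyR 4-neighborhood of ``site``.

    For ``CLOSING`` the sign is flipped, so a positive ``num_net`` always
    accelerates the transition under consideration.
    """
    if site.kind != RYR:
        raise ValueError("num_net is defined for RyR sites only")
    try:
        k = states.sites.index(site)
    except ValueError:
        raise ValueError(f"site ({site.ix},{site.iy}) not in state field") from None
    n_open, n_closed = _neighbor_counts(states, k)
    net = int(n_open - n_closed)
    if direction == CLOSING:
        net = -net
    elif direction != OPENING:
        raise ValueError(f"unknown direction {direction!r}")
    return net


def _neighbor_counts(states: RyRStateField, k: int):
    idx = states.nbr[k]
    valid = idx >= 0
    flags = states.open_flags[idx[valid]]
    return int(flags.sum()), int(valid.sum() - flags.sum())


def max_transition_prob(dt: float, params: RyRParams) -> float:
    """Worst-case per-step transition probability (4 aligned neighbors)."""
    boost = np.exp(4.0 * abs(params.ej))
    return dt * max(params.kplus_max, params.kminus) * boost


def step_ryr(states: RyRStateField, c_ds_field: np.ndarray,
             c_jsr_field: np.ndarray, dt: float, params: RyRParams,
             rng: np.random.Generator) -> RyRStateField:
    """Advance every RyR by one fixed time step.

    Closed channels open with ``p = dt * k+_r(x,y) * kcoup**num_net`` and open
    channels close with ``p = dt * k-_r * kcoup**num_net``; ``num_net`` is
    evaluated from the pre-step state and one independent uniform draw is
    spent per channel.  Fields are indexed ``field[iy, ix]``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if max_transition_prob(dt, params) > 0.1:
        raise StabilityError(
            "per-channel transition probability exceeds 0.1; reduce dt")
    n = states.n
    if n == 0:
        return states.copy()
    ix = np.array([s.ix for s in states.sites])
    iy = np.array([s.iy for s in states.sites])
    c = np.asarray(c_ds_field, dtype=float)[iy, ix]
    cj = np.asarray(c_jsr_field, dtype=float)[iy, ix]
    flags = states.open_flags.astype(np.int64)

    padded = np.concatenate([flags, [0]])           # -1 -> closed, not counted
    nbr_open = padded[states.nbr].sum(axis=1)
    nbr_total = (states.nbr >= 0).sum(axis=1)
    net_open = nbr_open - (nbr_total - nbr_open)    # open - closed

    k_r = activation_threshold(cj, params)
    k_plus = opening_rate(c, k_r, params)
    p_open = dt * k_plus * np.exp(params.ej * net_open)
    p_close = dt * params.kminus * np.exp(params.ej * (-net_open))
    p = np.where(flags == 1, p_close, p_open)
    if np.any(p > 1.0):
        raise StabilityError("transition probability exceeded 1; reduce dt")
    u = rng.random(n)
    flip = u < p
    new = states.open_flags.copy()
    new[flip] ^= 1
    return RyRStateField(states.geom, states.sites, states.nbr, new)
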