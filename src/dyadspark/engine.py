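"""Single-trial spark simulation, detection, and morphology metrics.

A trial forces one RyR2 open at t = 0 in a resting CRU and advances channel
gating and both concentration fields on a shared fixed time step for the
trial duration (200 ms by default).  The inner loop is a fused numba kernel;
channel transitions are evaluated from the pre-step state, channel fluxes
from the post-transition open flags, and the field update is explicit Euler.

An *episode* is a maximal interval of the recorded series with at least one
channel open; an episode is a *spark* when its peak simultaneous open count
(RyR + IP3R) exceeds the detection threshold (default > 5, i.e. the trigger
recruited at least five others).  Morphology metrics: Ca²⁺ mass is the time
integral of total release current (pA·ms = fC), duration is the 10 %-of-max
width of the spatially averaged dyadic Ca²⁺ trace, and max_n_open the peak
simultaneous open count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit

from .fields import resting_fields, stability_dt
from .geometry import CruGeometry
from .ip3r import initial_state, max_exit_rate
from .params import FARADAY, SimParams, StabilityError
from .ryr import build_state_field, max_transition_prob

__all__ = [
    "TrialConfig", "TrialRecord", "SparkSummary", "Episode",
    "run_trial", "detect_episodes", "classify_spark", "ca_mass",
    "spark_duration", "max_n_open", "summarize", "write_trial_csv",
    "write_summary_jsonl",
]


# ---------------------------------------------------------------------------
# deterministic counter-free RNG (xoroshiro128+ seeded by splitmix64)

@njit(cache=True, inline="always")
def _u01(s):
    s0 = s[0]
    s1 = s[1]
    r = s0 + s1
    s1 = s1 ^ s0
    s[0] = ((s0 << np.uint64(55)) | (s0 >> np.uint64(9))) ^ s1 ^ (s1 << np.uint64(14))
    s[1] = (s1 << np.uint64(36)) | (s1 >> np.uint64(28))
    return float(r >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _seed_state(seed):
    s = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed)
    for i in range(2):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        t = z
        t = (t ^ (t >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        t = (t ^ (t >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        s[i] = t ^ (t >> np.uint64(31))
    for _ in range(8):
        _u01(s)
    return s


# ---------------------------------------------------------------------------
# scalar transition helpers (shared by the kernel and the gating tests)

@njit(cache=True, inline="always")
def _ryr_open_rate(c, cj, krmax, alpha, kpmax, hill, krfloor):
    kr = krmax - alpha * cj
    if kr < krfloor:
        kr = krfloor
    if c <= 0.0:
        return 0.0
    ch = c ** hill
    return kpmax * ch / (ch + kr ** hill)


@njit(cache=True)
def _ryr_transition(open_flag, c, cj, n_open_nbr, n_closed_nbr,
                    krmax, alpha, kpmax, hill, kminus, ej, krfloor, dt, u):
    """One RyR per-step transition; returns the new open flag."""
    if open_flag == 1:
        net = n_closed_nbr - n_open_nbr
        pr = dt * kminus
        if net != 0:
            pr *= math.exp(ej * net)
        return 0 if u < pr else 1
    net = n_open_nbr - n_closed_nbr
    pr = dt * _ryr_open_rate(c, cj, krmax, alpha, kpmax, hill, krfloor)
    if net != 0:
        pr *= math.exp(ej * net)
    return 1 if u < pr else 0


@njit(cache=True)
def _ip3r_transition(s, c, q12, q21, q23, q26, q32, q45, q54, q62,
                     v42, v24, a24, a42, km3, kh3, gp, dt, u):
    """One six-state transition from 1-based state ``s`` at dyadic Ca ``c``."""
    c3 = c * c * c
    m = c3 / (c3 + km3)
    h = kh3 / (kh3 + c3)
    q24 = a24 + v24 * (1.0 - m * h)
    q42 = a42 + v42 * m * h * gp
    if s == 1:
        if u < dt * q12:
            return 2
    elif s == 2:
        acc = dt * q21
        if u < acc:
            return 1
        acc += dt * q23
        if u < acc:
            return 3
        acc += dt * q26
        if u < acc:
            return 6
        acc += dt * q24
        if u < acc:
            return 4
    elif s == 3:
        if u < dt * q32:
            return 2
    elif s == 4:
        acc = dt * q42
        if u < acc:
            return 2
        acc += dt * q45
        if u < acc:
            return 5
    elif s == 5:
        if u < dt * q54:
            return 4
    elif s == 6:
        if u < dt * q62:
            return 2
    return s


# ---------------------------------------------------------------------------
# fused trial kernel

@njit(cache=True)
def _run_kernel(n_steps, stride, dt, c_ds, c_jsr, bf, cds_new, cjsr_new,
                ryr_iy, ryr_ix, ryr_nbr, ryr_open, ryr_scratch,
                ip3_iy, ip3_ix, ip3_state, ip3_active,
                rp, ipk, tp, kon, koff, btot, rng_state, rec):
    ny, nx = c_ds.shape
    krmax, alpha, kpmax, hill, kminus, ej, krfloor = (
        rp[0], rp[1], rp[2], rp[3], rp[4], rp[5], rp[6])
    q12, q21, q23, q32, q26, q62, q45, q54 = (
        ipk[0], ipk[1], ipk[2], ipk[3], ipk[4], ipk[5], ipk[6], ipk[7])
    v42, v24, a24, a42, km3, kh3, gp = (
        ipk[8], ipk[9], ipk[10], ipk[11], ipk[12], ipk[13], ipk[14])
    dmyo, djsr, dx2, cryr, cip3 = tp[0], tp[1], tp[2], tp[3], tp[4]
    nsr, tau, beta, crest = tp[5], tp[6], tp[7], tp[8]
    refill = tp[9] > 0.5
    dirichlet = tp[10] > 0.5
    paryr, paip3 = tp[11], tp[12]
    n_ryr = ryr_open.shape[0]
    n_ip3 = ip3_state.shape[0]
    rec_idx = 0

    for step in range(n_steps + 1):
        if step % stride == 0:
            nro = 0
            for k in range(n_ryr):
                nro += ryr_open[k]
            nio = 0
            itot = 0.0
            for k in range(n_ip3):
                if ip3_state[k] >= 5:
                    nio += 1
                    y = ip3_iy[k]
                    x = ip3_ix[k]
                    itot += paip3 * (c_jsr[y, x] - c_ds[y, x])
            for k in range(n_ryr):
                if ryr_open[k] == 1:
                    y = ryr_iy[k]
                    x = ryr_ix[k]
                    itot += paryr * (c_jsr[y, x] - c_ds[y, x])
            smean = 0.0
            smax = -1.0
            jmin = 1e300
            for iy in range(ny):
                for ix in range(nx):
                    v = c_ds[iy, ix]
                    smean += v
                    if v > smax:
                        smax = v
                    if c_jsr[iy, ix] < jmin:
                        jmin = c_jsr[iy, ix]
            rec[rec_idx, 0] = step * dt
            rec[rec_idx, 1] = nro
            rec[rec_idx, 2] = nio
            rec[rec_idx, 3] = itot
            rec[rec_idx, 4] = smean / (ny * nx)
            rec[rec_idx, 5] = smax
            rec[rec_idx, 6] = jmin
            rec_idx += 1
        if step == n_steps:
            break

        # --- channel gating from the pre-step state ---
        for k in range(n_ryr):
            y = ryr_iy[k]
            x = ryr_ix[k]
            no = 0
            ncl = 0
            for m in range(4):
                j = ryr_nbr[k, m]
                if j >= 0:
                    if ryr_open[j] == 1:
                        no += 1
                    else:
                        ncl += 1
            u = _u01(rng_state)
            ryr_scratch[k] = _ryr_transition(
                ryr_open[k], c_ds[y, x], c_jsr[y, x], no, ncl,
                krmax, alpha, kpmax, hill, kminus, ej, krfloor, dt, u)
        for k in range(n_ryr):
            ryr_open[k] = ryr_scratch[k]
        if ip3_active:
            for k in range(n_ip3):
                y = ip3_iy[k]
                x = ip3_ix[k]
                u = _u01(rng_state)
                ip3_state[k] = _ip3r_transition(
                    ip3_state[k], c_ds[y, x], q12, q21, q23, q26, q32,
                    q45, q54, q62, v42, v24, a24, a42, km3, kh3, gp, dt, u)

        # --- field update (explicit Euler, pre-step fields on the RHS) ---
        for iy in range(ny):
            for ix in range(nx):
                cc = c_ds[iy, ix]
                jb = 0.0
                for b in range(3):
                    v = bf[b, iy, ix]
                    j = koff[b] * (btot[b] - v) - kon[b] * v * cc
                    nv = v + dt * j
                    if nv < 0.0:
                        nv = 0.0
                    elif nv > btot[b]:
                        nv = btot[b]
                    bf[b, iy, ix] = nv
                    jb += j
                rim = iy == 0 or iy == ny - 1 or ix == 0 or ix == nx - 1
                if dirichlet and rim:
                    cds_new[iy, ix] = crest
                else:
                    up = c_ds[iy - 1, ix] if iy > 0 else cc
                    dn = c_ds[iy + 1, ix] if iy < ny - 1 else cc
                    lf = c_ds[iy, ix - 1] if ix > 0 else cc
                    rt = c_ds[iy, ix + 1] if ix < nx - 1 else cc
                    lap = (up + dn + lf + rt - 4.0 * cc) / dx2
                    cds_new[iy, ix] = cc + dt * (dmyo * lap + jb)
                cj = c_jsr[iy, ix]
                up = c_jsr[iy - 1, ix] if iy > 0 else cj
                dn = c_jsr[iy + 1, ix] if iy < ny - 1 else cj
                lf = c_jsr[iy, ix - 1] if ix > 0 else cj
                rt = c_jsr[iy, ix + 1] if ix < nx - 1 else cj
                lapj = (up + dn + lf + rt - 4.0 * cj) / dx2
                jr = (nsr - cj) / tau if refill else 0.0
                cjsr_new[iy, ix] = cj + dt * beta * (jr + djsr * lapj)

        # --- channel fluxes (post-transition states, pre-step gradients) ---
        for k in range(n_ryr):
            if ryr_open[k] == 1:
                y = ryr_iy[k]
                x = ryr_ix[k]
                g = c_jsr[y, x] - c_ds[y, x]
                cds_new[y, x] += dt * cryr * g
                cjsr_new[y, x] -= dt * beta * cryr * g
                if cds_new[y, x] < 0.0:
                    cds_new[y, x] = 0.0
                if cjsr_new[y, x] < 0.0:
                    cjsr_new[y, x] = 0.0
        for k in range(n_ip3):
            if ip3_state[k] >= 5:
                y = ip3_iy[k]
                x = ip3_ix[k]
                g = c_jsr[y, x] - c_ds[y, x]
                cds_new[y, x] += dt * cip3 * g
                cjsr_new[y, x] -= dt * beta * cip3 * g
                if cds_new[y, x] < 0.0:
                    cds_new[y, x] = 0.0
                if cjsr_new[y, x] < 0.0:
                    cjsr_new[y, x] = 0.0

        tmp = c_ds
        c_ds = cds_new
        cds_new = tmp
        tmp = c_jsr
        c_jsr = cjsr_new
        cjsr_new = tmp
    return rec_idx


# ---------------------------------------------------------------------------
# trial configuration and record containers

@dataclass(frozen=True)
class TrialConfig:
    """Per-trial settings.

    ``forced`` selects the RyR opened at t = 0: ``"center"`` (centermost RyR,
    default, reproducible), ``"random"``, an explicit ``(ix, iy)`` tuple, or
    ``None`` for an unperturbed (diagnostic) trial.  ``spark_threshold`` is
    the open-count an episode peak must *exceed* to count as a spark.
    """

    duration: float = 200.0      # ms
    dt: float | None = None      # ms; None -> auto from the stability guards
    seed: int = 0
    ip3: float = 0.1             # µM
    forced: object = "center"
    record_dt: float = 0.05      # ms between saved samples
    spark_threshold: int = 5
    boundary: str = "dirichlet"
    refill_on: bool = True


@dataclass
class TrialRecord:
    """Sampled time series of one trial (arrays share one length)."""

    t: np.ndarray
    n_open_ryr: np.ndarray
    n_open_ip3r: np.ndarray
    i_total: np.ndarray          # pA
    cds_mean: np.ndarray         # µM
    cds_max: np.ndarray          # µM
    cjsr_min: np.ndarray         # µM
    seed: int = 0
    config: TrialConfig | None = None
    geometry: CruGeometry | None = None
    final_fields: object = None

    @property
    def n_total(self) -> np.ndarray:
        return self.n_open_ryr + self.n_open_ip3r


@dataclass(frozen=True)
class Episode:
    i0: int       # first sample index with channels open
    i1: int       # last sample index with channels open
    t0: float
    t1: float
    peak: int     # peak simultaneous open count


@dataclass(frozen=True)
class SparkSummary:
    is_spark: bool
    n_sparks: int
    n_episodes: int
    ca_mass: float        # fC
    duration: float       # ms
    max_n_open: int


def auto_dt(sim: SimParams, with_ip3r: bool) -> float:
    """Largest dt satisfying the diffusion and gating-probability guards."""
    bound = stability_dt(sim.transport)
    rate = max(sim.ryr.kplus_max, sim.ryr.kminus)
    if rate > 0:
        bound = min(bound, 0.1 / rate / math.exp(4.0 * abs(sim.ryr.ej)))
    if with_ip3r:
        bound = min(bound, 0.1 / max_exit_rate(sim.ip3r))
    return 0.995 * bound


def _pa_per_uM(p_Lms: float) -> float:
    # i[pA] = 2 F * P[L/ms] * 1e3 [ms/s] * dC[µM] * 1e-6 [mol/L per µM] * 1e12
    return 2.0 * FARADAY * p_Lms * 1e9


def _forced_index(states, policy, rng):
    if policy is None:
        return -1
    if not states.sites:
        raise ValueError("geometry has no RyR to force open")
    if policy == "center":
        pos = np.array([(s.ix, s.iy) for s in states.sites], dtype=float)
        centroid = pos.mean(axis=0)
        d = np.abs(pos - centroid).sum(axis=1)
        best = np.flatnonzero(d == d.min())
        keyed = sorted(best, key=lambda k: (states.sites[k].iy,
                                            states.sites[k].ix))
        return int(keyed[0])
    if policy == "random":
        return int(rng.integers(len(states.sites)))
    ix, iy = policy
    for k, s in enumerate(states.sites):
        if (s.ix, s.iy) == (ix, iy):
            return k
    raise ValueError(f"forced site ({ix},{iy}) is not an RyR site")


def run_trial(geom: CruGeometry, sim: SimParams,
              cfg: TrialConfig) -> TrialRecord:
    """Simulate one trial and return its sampled record.

    The initial state is a resting CRU (dyad at c_rest, JSR at the NSR load,
    buffers equilibrated, RyRs closed, each IP3R drawn from its stationary
    distribution at (c_rest, [IP3])); the forced RyR is opened at t = 0 and
    gates freely afterwards.  Fully reproducible from (seed, config,
    geometry).
    """
    sim.validate()
    if cfg.forced is not None and geom.n_ryr == 0:
        raise ValueError("geometry has no RyR channels")
    if cfg.duration <= 0:
        raise ValueError("duration must be > 0")
    tr, bu = sim.transport, sim.buffers
    with_ip3r = geom.n_ip3r > 0 and cfg.ip3 > 0
    dt = cfg.dt if cfg.dt is not None else auto_dt(sim, with_ip3r)
    if dt > stability_dt(tr):
        raise StabilityError(
            f"dt={dt} violates the diffusion bound {stability_dt(tr):.3e} ms")
    if max_transition_prob(dt, sim.ryr) > 0.1:
        raise StabilityError("dt violates the RyR transition-probability guard")
    if with_ip3r and dt * max_exit_rate(sim.ip3r) > 0.1:
        raise StabilityError("dt violates the IP3R exit-probability guard")

    rng = np.random.default_rng(cfg.seed)
    states = build_state_field(geom)
    forced = _forced_index(states, cfg.forced, rng)
    if forced >= 0:
        states.open_flags[forced] = 1

    ip3_sites = geom.ip3r_sites()
    ip3_state = np.array(
        [initial_state(tr.c_rest, cfg.ip3, sim.ip3r, rng) for _ in ip3_sites],
        dtype=np.int64) if ip3_sites else np.empty(0, dtype=np.int64)

    f0 = resting_fields(geom.nx, geom.ny, tr, bu)

    stride = max(1, int(round(cfg.record_dt / dt)))
    n_chunks = max(1, math.ceil(cfg.duration / (dt * stride)))
    n_steps = n_chunks * stride
    rec = np.empty((n_chunks + 1, 7))

    rp = np.array([sim.ryr.k_r_max, sim.ryr.alpha_r, sim.ryr.kplus_max,
                   sim.ryr.hill, sim.ryr.kminus, sim.ryr.ej,
                   sim.ryr.k_r_floor])
    ip = sim.ip3r
    c3 = ip.km_act ** 3
    p = cfg.ip3
    kh = ip.kh_base + ip.kh_amp * p * p / (p * p + ip.kh_kp ** 2)
    gp = p * p / (p * p + ip.k_ip3 ** 2)
    ipk = np.array([ip.q12, ip.q21, ip.q23, ip.q32, ip.q26, ip.q62,
                    ip.q45, ip.q54, ip.v42, ip.v24,
                    ip.a24_max * (1.0 - gp), ip.a42_max * gp,
                    c3, kh ** 3, gp])
    tp = np.array([tr.d_myo, tr.d_jsr, tr.dx_um ** 2,
                   tr.p_ryr / tr.v_ds, tr.p_ip3r / tr.v_ds,
                   tr.ca_nsr, tr.tau_refill, tr.beta, tr.c_rest,
                   1.0 if cfg.refill_on else 0.0,
                   1.0 if cfg.boundary == "dirichlet" else 0.0,
                   _pa_per_uM(tr.p_ryr), _pa_per_uM(tr.p_ip3r)])
    if cfg.boundary not in ("dirichlet", "noflux"):
        raise ValueError(f"unknown boundary {cfg.boundary!r}")

    ryr_iy = np.array([s.iy for s in states.sites], dtype=np.int64)
    ryr_ix = np.array([s.ix for s in states.sites], dtype=np.int64)
    ip3_iy = np.array([s.iy for s in ip3_sites], dtype=np.int64)
    ip3_ix = np.array([s.ix for s in ip3_sites], dtype=np.int64)

    rng_state = _seed_state(int(rng.integers(2**63)))
    cds_scratch, cjsr_scratch = f0.c_ds.copy(), f0.c_jsr.copy()
    n_rec = _run_kernel(
        n_steps, stride, dt,
        f0.c_ds, f0.c_jsr, f0.b_free, cds_scratch, cjsr_scratch,
        ryr_iy, ryr_ix, states.nbr,
        states.open_flags.astype(np.int64),
        np.zeros(len(states.sites), dtype=np.int64),
        ip3_iy, ip3_ix, ip3_state, with_ip3r,
        rp, ipk, tp,
        np.array(bu.k_on), np.array(bu.k_off), np.array(bu.b_total),
        rng_state, rec)
    rec = rec[:n_rec]
    # the kernel ping-pongs between the two buffers; pick the live one
    from .fields import FieldState
    if n_steps % 2 == 0:
        final = FieldState(f0.c_ds, f0.c_jsr, f0.b_free)
    else:
        final = FieldState(cds_scratch, cjsr_scratch, f0.b_free)
    return TrialRecord(
        t=rec[:, 0].copy(), n_open_ryr=rec[:, 1].astype(np.int64),
        n_open_ip3r=rec[:, 2].astype(np.int64), i_total=rec[:, 3].copy(),
        cds_mean=rec[:, 4].copy(), cds_max=rec[:, 5].copy(),
        cjsr_min=rec[:, 6].copy(), seed=cfg.seed, config=cfg, geometry=geom,
        final_fields=final)


# ---------------------------------------------------------------------------
# spark detection and morphology

def detect_episodes(rec: TrialRecord) -> list[Episode]:
    """Maximal intervals of the sampled series with any channel open."""
    total = np.asarray(rec.n_total)
    episodes = []
    in_ep = False
    i0 = 0
    for i, v in enumerate(total):
        if v > 0 and not in_ep:
            in_ep = True
            i0 = i
        elif v == 0 and in_ep:
            in_ep = False
            episodes.append((i0, i - 1))
    if in_ep:
        episodes.append((i0, len(total) - 1))
    return [Episode(i0=a, i1=b, t0=float(rec.t[a]), t1=float(rec.t[b]),
                    peak=int(total[a:b + 1].max())) for a, b in episodes]


def classify_spark(episodes: list[Episode],
                   threshold: int = 5) -> tuple[bool, int]:
    """(is_spark, n_sparks): episodes whose peak open count > ``threshold``."""
    n = sum(1 for e in episodes if e.peak > threshold)
    return n >= 1, n


def ca_mass(rec: TrialRecord) -> float:
    """Released Ca²⁺ charge over the trial: trapezoidal ∫ i dt, in fC."""
    return float(np.trapezoid(rec.i_total, rec.t))


def spark_duration(rec: TrialRecord, use_max: bool = False) -> float:
    """10 %-of-maximum width (ms) of the dyadic Ca²⁺ trace.

    Uses the spatially averaged trace (``use_max=True`` switches to the
    spatial maximum).  Crossing times are linearly interpolated; the result
    is the last downward crossing minus the first upward crossing, 0 when
    the trace never crosses upward after the initial sample, and the trial
    end stands in for a missing final downward crossing.
    """
    y = np.asarray(rec.cds_max if use_max else rec.cds_mean, dtype=float)
    t = np.asarray(rec.t, dtype=float)
    if len(y) < 2:
        return 0.0
    thr = 0.1 * y.max()
    above = y > thr
    up = np.flatnonzero(~above[:-1] & above[1:])
    if len(up) == 0:
        return 0.0
    i = up[0]
    t_up = t[i] + (t[i + 1] - t[i]) * (thr - y[i]) / (y[i + 1] - y[i])
    down = np.flatnonzero(above[:-1] & ~above[1:])
    down = down[down >= i]
    if len(down) == 0:
        t_down = t[-1]
    else:
        j = down[-1]
        t_down = t[j] + (t[j + 1] - t[j]) * (y[j] - thr) / (y[j] - y[j + 1])
    return float(t_down - t_up)


def max_n_open(rec: TrialRecord) -> int:
    """Peak simultaneous open-channel count over the trial."""
    total = rec.n_total
    return int(total.max()) if len(total) else 0


def summarize(rec: TrialRecord, threshold: int | None = None) -> SparkSummary:
    thr = threshold if threshold is not None else (
        rec.config.spark_threshold if rec.config else 5)
    eps = detect_episodes(rec)
    is_spark, n_sparks = classify_spark(eps, thr)
    return SparkSummary(
        is_spark=is_spark, n_sparks=n_sparks, n_episodes=len(eps),
        ca_mass=ca_mass(rec), duration=spark_duration(rec),
        max_n_open=max_n_open(rec))


# ---------------------------------------------------------------------------
# plumbing

def write_trial_csv(rec: TrialRecord, path: str | Path) -> None:
    header = "t_ms,n_open_ryr,n_open_ip3r,i_total_pA,cds_mean_uM,cds_max_uM,cjsr_min_uM"
    data = np.column_stack([rec.t, rec.n_open_ryr, rec.n_open_ip3r,
                            rec.i_total, rec.cds_mean, rec.cds_max,
                            rec.cjsr_min])
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def write_summary_jsonl(summaries, path: str | Path, meta: dict | None = None):
    """Append one JSON line per (seed, SparkSummary) pair."""
    with open(path, "a") as fh:
        for seed, s in summaries:
            row = {"seed": seed, "is_spark": s.is_spark,
                   "n_sparks": s.n_sparks, "n_episodes": s.n_episodes,
                   "ca_mass_fC": s.ca_mass, "duration_ms": s.duration,
                   "max_n_open": s.max_n_open}
            if meta:
                row.update(meta)
            fh.write(json.dumps(row) + "\n")
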