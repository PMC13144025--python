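"""Dyadic and JSR Ca²⁺ fields: fluxes, buffering, refill, explicit stepping.

The dyadic cleft and the junctional SR are each a 2D grid of 30-nm
sub-volumes.  Dyadic Ca²⁺ diffuses (5-point Laplacian, D_myo), exchanges
with three cytosolic buffers, and receives channel flux; JSR Ca²⁺ diffuses
with D_JSR, loses the channel flux, and refills from a fixed NSR store with
first-order kinetics, all scaled by the luminal rapid-buffering factor beta.
The dyadic rim is clamped at the resting cytosolic concentration (escape to
bulk), the JSR rim is no-flux.  Integration is explicit Euler under the
standard stability bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import FARADAY, BufferParams, StabilityError, TransportParams

__all__ = [
    "FieldState", "calibrate_permeability", "current_from_permeability",
    "flux_ryr", "flux_ip3r", "buffer_step", "refill_flux", "step_fields",
    "stability_dt", "resting_fields",
]


@dataclass
class FieldState:
    """Per-site concentration grids (µM); ``b_free`` is stacked (3, ny, nx)."""

    c_ds: np.ndarray
    c_jsr: np.ndarray
    b_free: np.ndarray

    def copy(self) -> "FieldState":
        return FieldState(self.c_ds.copy(), self.c_jsr.copy(),
                          self.b_free.copy())


def calibrate_permeability(i_single: float, delta_c: float) -> float:
    """Permeability (L/ms) from a unitary current (pA) at a gradient (µM).

    Inverts ``i = 2 F P ΔC``: the molar flow through one open channel is
    ``P·ΔC`` and each Ca²⁺ ion carries two elementary charges.
    """
    if i_single <= 0 or delta_c <= 0:
        raise ValueError("current and gradient must be > 0")
    # pA/(C/mol * mol/L) -> 1e-12 L/s -> L/ms
    return i_single * 1e-12 / (2.0 * FARADAY * delta_c * 1e-6) * 1e-3


def current_from_permeability(p: float, delta_c: float) -> float:
    """Unitary current (pA) through permeability ``p`` (L/ms) at ΔC (µM)."""
    return 2.0 * FARADAY * p * 1e3 * delta_c * 1e-6 * 1e12


def flux_ryr(n_open, c_jsr, c_ds, params: TransportParams):
    """RyR channel flux into the dyadic sub-volume, µM/ms (Ohmic in ΔC)."""
    return np.asarray(n_open, float) * params.p_ryr * \
        (np.asarray(c_jsr, float) - np.asarray(c_ds, float)) / params.v_ds


def flux_ip3r(n_open, c_jsr, c_ds, params: TransportParams):
    """IP3R channel flux into the dyadic sub-volume, µM/ms."""
    return np.asarray(n_open, float) * params.p_ip3r * \
        (np.asarray(c_jsr, float) - np.asarray(c_ds, float)) / params.v_ds


def buffer_step(b_free: np.ndarray, c_ds: np.ndarray, dt: float,
                params: BufferParams):
    """Advance the three buffers one step and return (new_b_free, j_total).

    Buffer ``i`` releases free Ca at ``k_off,i (B_tot,i - B_i) - k_on,i B_i c``
    (negative when net binding), and its free concentration changes by the
    same amount, so free-plus-bound Ca and total buffer sites are conserved
    exactly.  ``j_total`` (µM/ms) is the term added to the dyadic Ca
    equation.  Updates that would leave [0, B_total] are clamped.
    """
    b = np.asarray(b_free, dtype=float)
    c = np.asarray(c_ds, dtype=float)
    new = np.empty_like(b)
    j_total = np.zeros_like(c)
    for i, (kon, koff, btot) in enumerate(zip(params.k_on, params.k_off,
                                              params.b_total)):
        j = koff * (btot - b[i]) - kon * b[i] * c
        new[i] = np.clip(b[i] + dt * j, 0.0, btot)
        j_total += j
    return new, j_total


def refill_flux(c_jsr, params: TransportParams):
    """NSR-to-JSR refill, µM/ms: (Ca_NSR - Ca_JSR)/tau_refill."""
    return (params.ca_nsr - np.asarray(c_jsr, float)) / params.tau_refill


def stability_dt(params: TransportParams) -> float:
    """Explicit-scheme bound 0.5 Δx² / (4 max(D_myo, D_JSR)), ms."""
    return 0.5 * params.dx_um ** 2 / (4.0 * max(params.d_myo, params.d_jsr))


def _lap_dirichlet(f: np.ndarray, boundary: float, dx2: float) -> np.ndarray:
    p = np.pad(f, 1, constant_values=boundary)
    return (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]
            - 4.0 * f) / dx2


def _lap_neumann(f: np.ndarray, dx2: float) -> np.ndarray:
    p = np.pad(f, 1, mode="edge")
    return (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]
            - 4.0 * f) / dx2


def step_fields(fields: FieldState, channel_fluxes, dt: float,
                transport: TransportParams, buffers: BufferParams,
                boundary: str = "dirichlet",
                refill_on: bool = True) -> FieldState:
    """One explicit-Euler update of both concentration fields.

    ``channel_fluxes`` is ``(j_ryr, j_ip3r)``, grids of the per-site channel
    flux in µM/ms (already summed over open channels); the same molar flux
    leaves the JSR, scaled by beta.  ``boundary`` selects the dyadic rim
    treatment: ``dirichlet`` clamps it at ``c_rest`` (default), ``noflux``
    reflects (used by the conservation audit).  The JSR rim is always
    no-flux.  Raises :class:`StabilityError` if ``dt`` violates the
    diffusion bound.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt > stability_dt(transport):
        raise StabilityError(
            f"dt={dt} exceeds diffusion stability bound "
            f"{stability_dt(transport):.3e} ms")
    j_ryr, j_ip3r = channel_fluxes
    dx2 = transport.dx_um ** 2
    c, cj = fields.c_ds, fields.c_jsr

    if boundary == "dirichlet":
        lap_ds = _lap_dirichlet(c, transport.c_rest, dx2)
    elif boundary == "noflux":
        lap_ds = _lap_neumann(c, dx2)
    else:
        raise ValueError(f"unknown boundary {boundary!r}")
    new_b, j_buf = buffer_step(fields.b_free, c, dt, buffers)
    j_chan = np.asarray(j_ryr, float) + np.asarray(j_ip3r, float)
    c_new = c + dt * (transport.d_myo * lap_ds + j_chan + j_buf)

    lap_jsr = _lap_neumann(cj, dx2)
    j_ref = refill_flux(cj, transport) if refill_on else 0.0
    cj_new = cj + dt * transport.beta * (j_ref + transport.d_jsr * lap_jsr
                                         - j_chan)
    if boundary == "dirichlet":
        c_new[0, :] = c_new[-1, :] = transport.c_rest
        c_new[:, 0] = c_new[:, -1] = transport.c_rest
    np.maximum(c_new, 0.0, out=c_new)
    np.maximum(cj_new, 0.0, out=cj_new)
    return FieldState(c_new, cj_new, new_b)


def write_field_snapshots(fields: FieldState, out_dir, label: str = "final"):
    """Dump each field as a dense CSV matrix (units µM), one file per field."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / f"c_ds_{label}.csv", fields.c_ds, delimiter=",")
    np.savetxt(out / f"c_jsr_{label}.csv", fields.c_jsr, delimiter=",")
    for i in range(fields.b_free.shape[0]):
        np.savetxt(out / f"b_free{i}_{label}.csv", fields.b_free[i],
                   delimiter=",")


def resting_fields(nx: int, ny: int, transport: TransportParams,
                   buffers: BufferParams) -> FieldState:
    """Uniform resting state: c_rest in the dyad, NSR load in the JSR,
    buffers equilibrated with c_rest."""
    c = np.full((ny, nx), transport.c_rest)
    cj = np.full((ny, nx), transport.ca_nsr)
    beq = buffers.equilibrium_free(transport.c_rest)
    b = np.stack([np.full((ny, nx), v) for v in beq])
    return FieldState(c, cj, b)
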