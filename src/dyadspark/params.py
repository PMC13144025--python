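"""Parameter registry and configuration loading.

Every model constant lives in one of the frozen dataclasses below, together
with a provenance tag recorded in :data:`PROVENANCE`:

``paper``
    printed in the source publication for this model (fixed six-state rates,
    single-channel currents, sub-volume, NSR load, refill time constant, ...).
``prior-work``
    standard values from the dyadic-cleft modeling literature (cytosolic
    buffer kinetics, diffusion coefficients in the hindered junctional cleft).
``chosen``
    free parameters of this implementation, calibrated once against the
    qualitative constraints the model is documented to satisfy (quiescent
    resting CRU, checkerboard spark fidelity of order 10-25 %, biphasic
    IP3R open-probability curve with its peak at intermediate Ca).

Units throughout: concentrations in µM, time in ms, rates in ms⁻¹,
lengths in nm (lattice) or µm (diffusion), volumes in L, currents in pA.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

FARADAY = 96485.33212  # C/mol

__all__ = [
    "FARADAY",
    "RyRParams",
    "IP3RParams",
    "BufferParams",
    "TransportParams",
    "SimParams",
    "ConfigurationError",
    "StabilityError",
    "load_config",
    "PROVENANCE",
]


class ConfigurationError(ValueError):
    """Invalid configuration value or file."""


class StabilityError(RuntimeError):
    """Time step violates an explicit-scheme or transition-probability bound."""


@dataclass(frozen=True)
class RyRParams:
    """Two-state RyR2 gating constants.

    The activation threshold is luminal-load dependent,
    ``K_r = max(k_r_max - alpha_r * c_JSR, k_r_floor)``, opening follows a
    Hill function of dyadic Ca²⁺ and neighbors interact through the
    exponential allosteric factor ``exp(ej * num_net)``.
    """

    k_r_max: float = 400.0     # µM, K_r at an empty JSR
    alpha_r: float = 0.376     # µM threshold per µM JSR load
    kplus_max: float = 0.7     # ms^-1, saturating opening rate
    hill: float = 2.2          # Hill coefficient of Ca activation
    kminus: float = 1.0        # ms^-1, closing rate (mean open time 1 ms)
    ej: float = 0.2            # dimensionless coupling energy
    k_r_floor: float = 1.0     # µM, lower clamp on K_r

    def validate(self) -> None:
        if min(self.k_r_max, self.kplus_max, self.kminus) < 0:
            raise ConfigurationError("RyR rates and thresholds must be >= 0")
        if self.hill <= 0:
            raise ConfigurationError("RyR hill coefficient must be > 0")
        if self.k_r_floor <= 0:
            raise ConfigurationError("RyR K_r floor must be > 0")


@dataclass(frozen=True)
class IP3RParams:
    """Six-state park/drive IP3R2 gating constants.

    States 1-6 with open set {5, 6}; park mode {4, 5}, drive mode {1, 2, 3, 6}.
    The fixed intra-modal rates (q12 ... q62, v42) are the published table
    values.  The intermodal rates are

    ``q24 = a24(p) + v24 * (1 - m24(c,p) * h24(c,p))``
    ``q42 = a42(p) + v42 * m42(c,p) * h42(c,p)``

    with Hill-form gates (see :func:`dyadspark.ip3r.modal_gates`): ``m`` is
    Ca²⁺ activation, ``h`` Ca²⁺ inhibition whose threshold is relieved by
    IP3, and ``a24/a42`` set the IP3-dependent floor rates.
    """

    # fixed rates, ms^-1  [paper]
    q12: float = 1.14
    q21: float = 0.0958
    q23: float = 4.75e-3
    q32: float = 0.0119
    q26: float = 10.1
    q62: float = 3.27
    q45: float = 4.14e-3
    q54: float = 3.42
    v42: float = 100.0
    # modal-gate constants  [chosen, calibrated to the printed P_O constraints]
    v24: float = 40.0        # ms^-1, ceiling of the drive->park rate
    a24_max: float = 20.0    # ms^-1, drive->park floor at zero IP3
    a42_max: float = 0.4     # ms^-1, park->drive floor at saturating IP3
    k_ip3: float = 0.25      # µM, IP3 half-activation of the modal floors
    km_act: float = 1.0      # µM, Ca activation threshold (n=3)
    kh_base: float = 10.0    # µM, Ca inhibition threshold at zero IP3
    kh_amp: float = 70.0     # µM, added inhibition threshold at high IP3
    kh_kp: float = 2.0       # µM, IP3 half-relief of Ca inhibition
    n_act: int = 3           # Hill order of m gates
    n_inh: int = 3           # Hill order of h gates

    def fixed_rates(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("q12", "q21", "q23", "q32", "q26", "q62", "q45", "q54", "v42")}

    def validate(self) -> None:
        if any(v < 0 for v in self.fixed_rates().values()):
            raise ConfigurationError("IP3R fixed rates must be >= 0")


@dataclass(frozen=True)
class BufferParams:
    """Three dyadic Ca²⁺ buffers: calmodulin, sarcolemmal and SR membrane.

    k_on in µM⁻¹ms⁻¹, k_off in ms⁻¹, total site concentration in µM.
    Values follow the common dyad-model buffer set.  [prior-work]
    """

    names: tuple[str, ...] = ("calmodulin", "sarcolemma", "sr_membrane")
    k_on: tuple[float, ...] = (0.100, 0.115, 0.115)
    k_off: tuple[float, ...] = (0.038, 1.000, 0.100)
    b_total: tuple[float, ...] = (24.0, 1124.0, 47.0)

    def validate(self) -> None:
        if not len(self.k_on) == len(self.k_off) == len(self.b_total) == len(self.names):
            raise ConfigurationError("buffer parameter tuples must have equal length")
        if any(v < 0 for v in self.k_on + self.k_off + self.b_total):
            raise ConfigurationError("buffer constants must be >= 0")

    def equilibrium_free(self, c: float) -> tuple[float, ...]:
        """Free buffer concentrations in equilibrium with free Ca ``c``."""
        return tuple(bt * koff / (koff + kon * c)
                     for kon, koff, bt in zip(self.k_on, self.k_off, self.b_total))


@dataclass(frozen=True)
class TransportParams:
    """Diffusion, geometry and store-refill constants.

    Single-channel permeabilities are calibrated from the specified unitary
    currents at the reference 850 µM JSR-to-dyad gradient
    (see :func:`dyadspark.fields.calibrate_permeability`).
    """

    d_myo: float = 0.08          # µm²/ms, dyadic Ca diffusion  [prior-work]
    d_jsr: float = 0.08          # µm²/ms, luminal JSR coupling  [chosen]
    v_ds_uL: float = 1.8e-14     # µL per 30-nm sub-volume  [paper]
    i_ryr_pA: float = 0.16       # pA, unitary RyR2 current  [paper]
    i_ip3r_pA: float = 0.05      # pA, unitary IP3R2 current  [paper]
    delta_c_ref: float = 850.0   # µM, calibration gradient  [paper]
    ca_nsr: float = 850.0        # µM, bulk NSR store  [paper]
    tau_refill: float = 8.0      # ms, JSR refill time constant  [paper]
    beta: float = 0.05           # JSR rapid-buffering factor  [chosen]
    c_rest: float = 0.1          # µM, resting cytosolic Ca  [prior-work]
    pitch_nm: float = 30.0       # nm, lattice pitch  [paper]

    @property
    def v_ds(self) -> float:
        """Sub-volume in litres."""
        return self.v_ds_uL * 1e-6

    @property
    def dx_um(self) -> float:
        return self.pitch_nm * 1e-3

    @property
    def p_ryr(self) -> float:
        """RyR2 permeability, L/ms."""
        from .fields import calibrate_permeability
        return calibrate_permeability(self.i_ryr_pA, self.delta_c_ref)

    @property
    def p_ip3r(self) -> float:
        """IP3R2 permeability, L/ms."""
        from .fields import calibrate_permeability
        return calibrate_permeability(self.i_ip3r_pA, self.delta_c_ref)

    def validate(self) -> None:
        if min(self.d_myo, self.d_jsr, self.v_ds_uL, self.tau_refill,
               self.i_ryr_pA, self.i_ip3r_pA, self.delta_c_ref) <= 0:
            raise ConfigurationError("transport constants must be > 0")
        if not (0.0 < self.beta <= 1.0):
            raise ConfigurationError("beta must lie in (0, 1]")


@dataclass(frozen=True)
class SimParams:
    """Bundle of all model parameter groups."""

    ryr: RyRParams = field(default_factory=RyRParams)
    ip3r: IP3RParams = field(default_factory=IP3RParams)
    buffers: BufferParams = field(default_factory=BufferParams)
    transport: TransportParams = field(default_factory=TransportParams)

    def validate(self) -> None:
        self.ryr.validate()
        self.ip3r.validate()
        self.buffers.validate()
        self.transport.validate()


#: provenance tag for every registry entry
PROVENANCE: dict[str, str] = {
    "ryr.k_r_max": "chosen", "ryr.alpha_r": "chosen", "ryr.kplus_max": "chosen",
    "ryr.hill": "prior-work", "ryr.kminus": "chosen", "ryr.ej": "chosen",
    "ryr.k_r_floor": "chosen",
    **{f"ip3r.{k}": "paper" for k in
       ("q12", "q21", "q23", "q32", "q26", "q62", "q45", "q54", "v42")},
    **{f"ip3r.{k}": "chosen" for k in
       ("v24", "a24_max", "a42_max", "k_ip3", "km_act", "kh_base",
        "kh_amp", "kh_kp", "n_act", "n_inh")},
    "buffers.k_on": "prior-work", "buffers.k_off": "prior-work",
    "buffers.b_total": "prior-work",
    "transport.d_myo": "prior-work", "transport.d_jsr": "chosen",
    "transport.v_ds_uL": "paper", "transport.i_ryr_pA": "paper",
    "transport.i_ip3r_pA": "paper", "transport.delta_c_ref": "paper",
    "transport.ca_nsr": "paper", "transport.tau_refill": "paper",
    "transport.beta": "chosen", "transport.c_rest": "prior-work",
    "transport.pitch_nm": "paper",
}

_SECTIONS = {"ryr": RyRParams, "ip3r": IP3RParams, "buffers": BufferParams,
             "transport": TransportParams}


def _build(cls, table: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    bad = set(table) - known
    if bad:
        raise ConfigurationError(
            f"unknown key(s) {sorted(bad)} in [{section}]")
    for key in ("names", "k_on", "k_off", "b_total"):
        if key in table and isinstance(table[key], list):
            table[key] = tuple(table[key])
    return cls(**table)


def load_config(path: str | Path) -> tuple[SimParams, dict]:
    """Read a TOML configuration file.

    Recognized sections: [ryr], [ip3r], [buffers], [transport] override the
    registry defaults; any other sections (e.g. [geometry], [trial],
    [protocol]) are returned verbatim in the second element for the caller
    to interpret.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigurationError(f"malformed TOML in {path}: {exc}") from exc
    groups = {}
    extra = {}
    for name, table in raw.items():
        if name in _SECTIONS:
            groups[name] = _build(_SECTIONS[name], dict(table), name)
        else:
            extra[name] = table
    params = SimParams(**groups)
    params.validate()
    return params, extra
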