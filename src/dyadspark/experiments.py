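"""Batch protocols: the fidelity sweep and the control-vs-HF comparison.

Each protocol runs ``n_trials`` independent 200-ms trials per condition,
derives per-trial seeds deterministically from (base seed, condition index,
trial index), re-randomizes the IP3R2 placement every trial (the default;
placement can be frozen per condition), and tabulates spark fidelity with
its Monte-Carlo standard error plus mean ± SD spark morphology computed
over qualifying spark trials only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import TrialConfig, run_trial, summarize
from .geometry import (CruGeometry, ctrl_preset, hf_preset, make_checkerboard,
                       place_ip3rs)
from .params import ConfigurationError, SimParams

__all__ = [
    "ProtocolSpec", "derive_seed", "round_half_up", "run_condition",
    "run_fidelity_sweep", "run_ctrl_vs_hf",
    "DEFAULT_SWEEP_N_IP3R", "DEFAULT_SWEEP_IP3",
]

DEFAULT_SWEEP_N_IP3R = tuple(range(11))          # 0..10 channels
DEFAULT_SWEEP_IP3 = (0.0, 0.1, 1.0, 10.0)        # µM


@dataclass(frozen=True)
class ProtocolSpec:
    """Protocol configuration shared by both experiment drivers."""

    n_trials: int = 100
    base_seed: int = 0
    n_ryr: int = 50
    duration: float = 200.0
    ip3_values: tuple[float, ...] = DEFAULT_SWEEP_IP3
    n_ip3r_values: tuple[int, ...] = DEFAULT_SWEEP_N_IP3R
    reseed_placement: bool = True     # re-randomize IP3R placement per trial
    spark_threshold: int = 5
    hf_fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0)
    ctrl_n_ip3r: tuple[int, ...] = (0, 1)
    ctrl_hf_ip3: float = 0.1          # µM, baseline IP3 for ctrl-vs-HF

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if not self.n_ip3r_values or not self.ip3_values:
            raise ConfigurationError("condition grid must be non-empty")


def derive_seed(base_seed: int, *indices: int) -> int:
    """Deterministic per-trial seed below 2^31, no global state."""
    ss = np.random.SeedSequence(entropy=[int(base_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2**31))


def round_half_up(x: float) -> int:
    """Fractional channel counts round half away from zero (12.5 -> 13)."""
    return int(math.floor(x + 0.5))


def run_condition(base_geom: CruGeometry, n_ip3r: int, ip3: float,
                  sim: SimParams, spec: ProtocolSpec, cond_index: int,
                  jsonl_path=None) -> dict:
    """Run all trials of one condition and reduce them to a table row.

    When ``jsonl_path`` is given, one JSON line per trial (seed + spark
    summary + condition metadata) is appended there.
    """
    summaries = []
    seeds = []
    placement_seed_fixed = derive_seed(spec.base_seed, cond_index, 10**6)
    for trial in range(spec.n_trials):
        seed = derive_seed(spec.base_seed, cond_index, trial)
        pseed = (derive_seed(spec.base_seed, cond_index, trial, 1)
                 if spec.reseed_placement else placement_seed_fixed)
        geom = place_ip3rs(base_geom, n_ip3r, seed=pseed)
        cfg = TrialConfig(duration=spec.duration, seed=seed, ip3=ip3,
                          spark_threshold=spec.spark_threshold)
        rec = run_trial(geom, sim, cfg)
        summaries.append(summarize(rec))
        seeds.append(seed)
    if jsonl_path is not None:
        import hashlib

        from .engine import write_summary_jsonl
        cfg_hash = hashlib.sha1(repr((spec, sim)).encode()).hexdigest()[:12]
        write_summary_jsonl(zip(seeds, summaries), jsonl_path,
                            meta={"n_ip3r": n_ip3r, "ip3_uM": ip3,
                                  "config_hash": cfg_hash})
    n = spec.n_trials
    n_spark = sum(s.is_spark for s in summaries)
    fid = n_spark / n
    spark = [s for s in summaries if s.is_spark]

    def ms(vals):
        if not vals:
            return math.nan, math.nan
        a = np.asarray(vals, dtype=float)
        return float(a.mean()), float(a.std(ddof=1)) if len(a) > 1 else 0.0

    mass_m, mass_s = ms([s.ca_mass for s in spark])
    dur_m, dur_s = ms([s.duration for s in spark])
    nop_m, nop_s = ms([s.max_n_open for s in spark])
    return {
        "n_ip3r": n_ip3r, "ip3_uM": ip3, "n_trials": n,
        "n_sparks": n_spark, "fidelity": fid,
        "fidelity_se": math.sqrt(fid * (1 - fid) / n),
        "ca_mass_mean_fC": mass_m, "ca_mass_sd_fC": mass_s,
        "duration_mean_ms": dur_m, "duration_sd_ms": dur_s,
        "max_n_open_mean": nop_m, "max_n_open_sd": nop_s,
        "n_multispark": sum(1 for s in summaries if s.n_sparks >= 2),
    }


def run_fidelity_sweep(spec: ProtocolSpec, sim: SimParams | None = None,
                       jsonl_path=None) -> pd.DataFrame:
    """Spark fidelity over the (N_IP3R, [IP3]) grid on a 50-RyR checkerboard.

    One row per condition; RyR positions are the fixed checkerboard, IP3R
    placements re-randomized per trial.
    """
    spec.validate()
    sim = sim or SimParams()
    base = make_checkerboard(spec.n_ryr)
    rows = []
    cond = 0
    for ip3 in spec.ip3_values:
        for n_ip3r in spec.n_ip3r_values:
            rows.append(run_condition(base, n_ip3r, ip3, sim, spec, cond,
                                      jsonl_path=jsonl_path))
            cond += 1
    return pd.DataFrame(rows)


def run_ctrl_vs_hf(spec: ProtocolSpec, sim: SimParams | None = None,
                   jsonl_path=None) -> pd.DataFrame:
    """Control versus fragmented-HF CRUs at baseline [IP3].

    CTRL: two compact RyR clusters, N_IP3R in ``spec.ctrl_n_ip3r``.
    HF: eight dispersed clusters, N_IP3R at 0/25/50/100 % of N_RyR with
    half-up rounding.  All trials at [IP3] = ``spec.ctrl_hf_ip3``.
    """
    spec.validate()
    sim = sim or SimParams()
    conditions = []
    ctrl = ctrl_preset(seed=derive_seed(spec.base_seed, 7, 0))
    hf = hf_preset(seed=derive_seed(spec.base_seed, 7, 1))
    for n in spec.ctrl_n_ip3r:
        conditions.append(("CTRL", ctrl, int(n)))
    for frac in spec.hf_fractions:
        conditions.append(("HF", hf, round_half_up(frac * spec.n_ryr)))
    rows = []
    for cond, (label, geom, n_ip3r) in enumerate(conditions):
        row = run_condition(geom, n_ip3r, spec.ctrl_hf_ip3, sim, spec, cond,
                            jsonl_path=jsonl_path)
        row["group"] = label
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = ["group"] + [c for c in df.columns if c != "group"]
    return df[cols]
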