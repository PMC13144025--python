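# dyadspark

Stochastic simulation of cardiac Ca²⁺ sparks from a single calcium release
unit (CRU) containing both ryanodine receptors (RyR2) and IP₃ receptors
(IP₃R2).

Ventricular myocytes release SR Ca²⁺ mainly through clustered RyR2s, but
IP₃R2s co-localize with them at SR junctions and their expression rises in
heart failure, where RyR2 clusters also fragment and disperse.  This
package models the crosstalk between the two channel types at the scale of
one dyad, for anyone studying how cluster remodeling and IP₃R2 expression
shape spark fidelity, spark morphology, and spontaneous ("multi-spark")
release.

## Model

A CRU is a lattice of 30 nm sites, each empty or holding one channel.  Two
fields evolve on the lattice by explicit finite differences:

    ∂[Ca]_ds/∂t  = D_myo ∇²[Ca]_ds + J_RyR + J_IP3R + J_buffer,total
    ∂[Ca]_JSR/∂t = β ( J_refill + D_JSR ∇²[Ca]_JSR − J_RyR − J_IP3R )

with Ohmic channel fluxes J = n_open · P · ([Ca]_JSR − [Ca]_ds)/V_ds,
three mass-action cytosolic buffers, and first-order JSR refill from an
850 µM NSR store (τ = 8 ms).  Permeabilities are calibrated from unitary
currents via i = 2 F P ΔC: 0.16 pA (RyR2) and 0.05 pA (IP₃R2) at the
diastolic 850 µM gradient.

RyR2s gate between closed and open with a Hill-type Ca²⁺-dependent opening
rate whose threshold K_r falls with luminal load
(K_r = K_r,max − α_r·[Ca]_JSR), a fixed closing rate, and exponential
allosteric coupling exp(EJ·num_net) between edge-sharing neighbors.
IP₃R2s follow a six-state park/drive Markov model (open states {5, 6})
whose intermodal rates q24 = a24 + V24(1 − m24·h24) and
q42 = a42 + V42·m42·h42 carry all Ca²⁺/IP₃ dependence; without IP₃ the
channel cannot conduct.  A trial forces one RyR2 open at t = 0 and runs
200 ms; an episode whose peak simultaneous open count exceeds 5 is a
spark.  Full details, parameter provenance, and calibration rationale are
in [docs/methods.md](docs/methods.md).

## Worked example

Run one 200-ms trial on the 50-RyR checkerboard CRU:

```sh
dyadspark spark run --duration 200 --seed 12 --out runs/demo
```

prints

```
spark=True n_sparks=1 mass=33.39 fC duration=96.21 ms max_n_open=27
```

meaning: the forced opening recruited a spark (peak of 27 simultaneously
open channels), the trial released 33.39 fC of Ca²⁺ (time integral of the
total release current), and the spatially averaged dyadic Ca²⁺ stayed
above 10 % of its maximum for 96.21 ms.  The full time series
(`t_ms,n_open_ryr,n_open_ip3r,i_total_pA,cds_mean_uM,cds_max_uM,cjsr_min_uM`)
lands in `runs/demo/trial.csv` together with a reproducibility manifest.
With the default parameters roughly one in eight seeds sparks
(fidelity ≈ 0.12); most seeds print `spark=False ... max_n_open=1`, the
trigger opening and closing without recruitment.

The same library surface is available from Python:

```python
from dyadspark import make_checkerboard, place_ip3rs, run_trial, summarize
from dyadspark.engine import TrialConfig
from dyadspark.params import SimParams

geom = place_ip3rs(make_checkerboard(50), n_ip3r=5, seed=1)
rec = run_trial(geom, SimParams(), TrialConfig(duration=200.0, seed=12, ip3=0.1))
print(summarize(rec))
```

Other entry points: `dyadspark ip3r po-curve` (stationary or simulated
open-probability curves), `dyadspark geometry make|stats` (checkerboard,
fragmented heart-failure-like presets, cluster statistics), and
`dyadspark protocol sweep|ctrl-vs-hf` (batch fidelity protocols with
per-condition result tables).

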