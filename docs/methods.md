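# Methods

## Model overview

`dyadspark` simulates local Ca²⁺ release ("sparks") from a single cardiac
calcium release unit (CRU).  The CRU is a rectangular lattice of
30 nm × 30 nm sites; each site is empty or holds one channel, either a
type-2 ryanodine receptor (RyR2) or a type-2 IP₃ receptor (IP₃R2).  Two
concentration fields live on the same lattice: the dyadic-cleft free Ca²⁺,
[Ca²⁺]_ds(x,y), and the junctional-SR luminal Ca²⁺, [Ca²⁺]_JSR(x,y).  Both
obey discrete 2D reaction–diffusion equations:

    d[Ca]_ds/dt  = D_myo ∇²[Ca]_ds + J_RyR + J_IP3R + J_buffer,total
    d[Ca]_JSR/dt = β ( J_refill + D_JSR ∇²[Ca]_JSR − J_RyR − J_IP3R )

Channel fluxes are Ohmic in the trans-SR gradient,
`J = n_open · P · ([Ca]_JSR − [Ca]_ds) / V_ds`, with the per-channel
permeabilities P_RyR and P_IP3R calibrated so one open channel carries
0.16 pA (RyR2) or 0.05 pA (IP₃R2) at the diastolic 850 µM gradient
(`i = 2 F P ΔC`).  Each 30-nm sub-volume is V_ds = 1.8 × 10⁻¹⁴ µL.  Three
cytosolic buffers (calmodulin, sarcolemmal membrane, SR membrane) exchange
Ca²⁺ with mass-action kinetics; the JSR refills from a fixed 850 µM NSR
store with time constant τ_refill = 8 ms.

A trial starts from rest (dyad at 0.1 µM, JSR at 850 µM, buffers
equilibrated, channels closed / at their stationary gating distribution),
forces one RyR2 open at t = 0 (the centermost RyR by default; it gates
freely afterwards), and runs for 200 ms.  An *episode* is a maximal
interval with at least one channel open; the trial contains a *spark* when
some episode's peak simultaneous open count exceeds 5 (i.e. the trigger
recruited at least five other channels).  Spark morphology: Ca²⁺ mass =
∫ i_total dt (pA·ms = fC), duration = 10 %-of-maximum width of the
spatially averaged dyadic Ca²⁺ trace, and the peak simultaneous open
count.  Spark fidelity over a batch is the fraction of qualifying trials;
a multi-spark is a trial with two or more qualifying episodes separated by
an all-closed interval.

## RyR2 gating

Two states (closed/open) with fixed-step transition probabilities

    p_open  = dt · k⁺(x,y) · exp(EJ · num_net)
    p_close = dt · k⁻      · exp(EJ · num_net)

where `k⁺ = k⁺_max c^h / (c^h + K_r^h)` is a Hill function of local dyadic
Ca²⁺ and the activation threshold falls linearly with luminal load,
`K_r = max(K_r,max − α_r [Ca]_JSR, 1 µM)`.  The floor prevents a
non-positive threshold; the linear form is unbounded below.  `num_net`
counts, over the edge-sharing (4-connected) RyR neighbors, open minus
closed neighbors for an opening transition and the negation for a closing
one, so positive coupling (EJ > 0) always favors conformity with the
neighborhood.  This symmetric sign convention is isolated in
`count_num_net`; an alternative convention is a one-line change.  In a
checkerboard no RyR has an edge-sharing neighbor, so coupling acts only in
the solid, fragmented clusters.  Transition probabilities are evaluated
from the pre-step state, one independent uniform draw per channel per
step, and a guard rejects any dt for which the worst-case per-step
probability exceeds 0.1.

## IP₃R2 gating

Six states with open set {5, 6}, park mode {4, 5} (open probability
≈ 1.2 × 10⁻³ through the slow 4↔5 edge) and drive mode {1, 2, 3, 6}
(open probability ≈ 0.68 through the fast 2↔6 edge).  The transition graph
is the tree 1–2, 2–3, 2–6, 2–4, 4–5.  Intra-modal rates are the fixed
table values (ms⁻¹): q12 = 1.14, q21 = 0.0958, q23 = 4.75 × 10⁻³,
q32 = 0.0119, q26 = 10.1, q62 = 3.27, q45 = 4.14 × 10⁻³, q54 = 3.42,
V42 = 100.  All Ca²⁺/IP₃ dependence sits on the intermodal edge:

    q24 = a24(p) + V24 (1 − m24 h24)
    q42 = a42(p) + V42 m42 h42

One printed source uses the symbol V24 inside the q42 expression while
defining only the constant V42 = 100 ms⁻¹; we read that as a typographical
inconsistency and use V42 in q42 (V24 is a separate, IP₃-level constant in
q24).

The published functional forms and constants of the modal gates
m24, h24, m42, h42, a24, a42 live in a prior parameterization that is not
reproduced in the sources available to this package.  We therefore author
them as Hill forms with the qualitative structure that parameterization is
described to have, and calibrate the constants once against the documented
behavior of the six-state channel (see "Calibration" below):

    g(p)   = p² / (p² + 0.25²)                      IP₃ occupancy
    m(c)   = c³ / (c³ + 1³)                         Ca activation
    K_h(p) = 10 + 70 · p² / (p² + 2²)   (µM)        inhibition threshold
    h(c,p) = K_h(p)³ / (K_h(p)³ + c³)               Ca inhibition
    m24 = m42 = m;  h24 = h;  h42 = h · g(p)
    a24 = 20 (1 − g(p));  a42 = 0.4 g(p);  V24 = 40 ms⁻¹

Rising IP₃ relieves Ca²⁺ inhibition (K_h grows), lowers the drive→park
floor a24 and raises the park→drive floor a42.  Because h42 carries the
IP₃-occupancy factor, q42 → 0 as [IP₃] → 0: the drive mode (and with it
essentially all conduction) is unreachable without IP₃.  Consistent with
the biophysics that IP₃ binding is required before the pore opens at all,
the simulation engine holds IP₃R2s fully closed (state 4) when [IP₃] = 0,
so a zero-IP₃ condition is exactly equivalent to removing the channels.
These gates satisfy: biphasic stationary open probability in Ca²⁺; peak
P_O ≈ 0.67 near 5 µM Ca²⁺ at [IP₃] = 1 µM (within the 1–10 µM window) and
near 9 µM at [IP₃] = 10 µM (≤ 100 µM); low P_O at 0.01 µM and 1000 µM
Ca²⁺; resting leak P_O that grows from ≈ 0.4 % at [IP₃] = 0.1 µM to ≈ 4 %
at 10 µM.  IP₃Rs carry no allosteric coupling.

The stationary distribution is solved from the null space of Qᵀ; because
the graph is a tree it coincides with the detailed-balance edge-product
closed form, which the test suite verifies to 10⁻¹⁰.  When the intermodal
edge is severed (q24 q42 = 0) the chain is reducible; the solver warns and
returns the distribution restricted to the absorbing mode.

## Numerics

Explicit Euler on a shared fixed step.  The default dt is derived at run
time as the largest value satisfying (i) the diffusion bound
0.5 Δx²/(4 max(D_myo, D_JSR)); (ii) worst-case RyR transition probability
≤ 0.1 (including the exp(4 EJ) coupling boost); (iii) worst-case IP₃R
total exit probability ≤ 0.1 (the binding constraint — state 4 can exit at
up to ≈ V42, giving dt ≈ 1.0 × 10⁻³ ms when IP₃Rs are active).  A
user-supplied dt that violates any guard is rejected before the run.

Per step: channel transitions are drawn from the pre-step fields and
states; channel fluxes use the post-transition open flags with pre-step
gradients; the field update is a single fused pass (5-point Laplacians,
buffer mass-action, refill).  The dyadic rim is Dirichlet-clamped at
c_rest = 0.1 µM — the escape path to bulk cytosol without which sparks
could not collapse — and the JSR rim is no-flux; a no-flux dyadic option
exists for conservation audits.  Buffer updates are clamped to
[0, B_total] as a safety net (never exercised at the default step).  In a
closed configuration (no-flux, refill off, β = 1) total Ca²⁺
(free + buffer-bound + luminal) is conserved to well under 0.1 % over
50 ms, and halving dt changes mean-field trajectories by < 1 %.

The inner loop is a numba kernel with its own xoroshiro128+ generator
seeded from the trial seed, so trials are bit-reproducible from
(seed, config, geometry) and independent of NumPy's global state.  A
parallel NumPy implementation of the same field update (`step_fields`)
exists for testing; the suite checks the kernel against it to 10⁻¹² on a
single step, and checks the kernel's gating helpers against binomial and
matrix-exponential oracles.

## Parameters

| group | parameter | value | units | provenance |
|---|---|---|---|---|
| transport | i_RyR | 0.16 | pA | paper |
| transport | i_IP3R | 0.05 | pA | paper |
| transport | V_ds | 1.8e-14 | µL | paper |
| transport | [Ca]_NSR | 850 | µM | paper |
| transport | τ_refill | 8 | ms | paper |
| transport | pitch | 30 | nm | paper |
| transport | D_myo | 0.08 | µm²/ms | prior-work (hindered cleft diffusion) |
| transport | D_JSR | 0.08 | µm²/ms | chosen (fast luminal coupling) |
| transport | β | 0.05 | – | chosen (calsequestrin-like luminal buffering) |
| transport | c_rest | 0.1 | µM | prior-work |
| buffers | calmodulin | k_on 0.1, k_off 0.038, B_T 24 | µM⁻¹ms⁻¹, ms⁻¹, µM | prior-work |
| buffers | sarcolemma | k_on 0.115, k_off 1.0, B_T 1124 | – | prior-work |
| buffers | SR membrane | k_on 0.115, k_off 0.1, B_T 47 | – | prior-work |
| ryr | K_r,max | 400 | µM | chosen (calibrated) |
| ryr | α_r | 0.376 | µM/µM | chosen (calibrated) |
| ryr | k⁺_max | 0.7 | ms⁻¹ | chosen |
| ryr | hill | 2.2 | – | prior-work |
| ryr | k⁻ | 1.0 | ms⁻¹ | chosen |
| ryr | EJ | 0.2 | – | chosen |
| ip3r | fixed rates | table above | ms⁻¹ | paper |
| ip3r | modal gates | forms above | – | chosen (calibrated) |

## Calibration

The RyR gating constants and the IP₃R modal-gate constants are free
parameters of this implementation (their published values are in sources
unavailable here).  They were fixed once, before the acceptance protocols
were frozen, against the following documented behaviors, and have not been
revisited since:

* a resting CRU (0.1 µM dyadic Ca²⁺, 850 µM JSR) is quiescent — the
  per-channel resting opening rate is ≈ 5 × 10⁻⁷ ms⁻¹, so spontaneous
  openings are rare on the 200-ms trial scale;
* forcing one RyR open in the 50-RyR checkerboard yields spark fidelity of
  order 10–25 % (≈ 0.12–0.16 at the defaults);
* sparks terminate within the trial: the strong luminal dependence
  (α_r = 0.376) raises K_r from 80 µM at full load toward ≈ 250 µM as the
  JSR falls to ~400 µM, which shuts recruitment down as the store
  depletes.  With a weak α_r the simulated CRU reaches a refill-balanced
  steady leak and sparks never collapse;
* the IP₃R stationary P_O curve satisfies the peak-location and
  biphasicity constraints listed above.

At these defaults a checkerboard spark recruits ≈ 25–30 channels, releases
≈ 30 fC and lasts tens of ms — the right order, though larger than the
reference events, which were produced with measured cluster geometries and
a parameter set we do not have.  Fidelity, not morphology, is the
calibrated quantity.

## Geometries

Real CRU maps come from super-resolution (dSTORM) imaging.  Those maps and
their segmentation pipeline are out of scope here; instead:

* `make_checkerboard` — the idealized healthy arrangement: alternating
  cells of a near-square block, so no two RyRs share an edge;
* `make_fragmented` — heart-failure-like arrangements: RyRs split into
  n connected blobs grown from scattered seed points whose spacing is set
  by `spread`; blob growth keeps distinct clusters > 100 nm apart so the
  requested cluster count is what the statistics report.  The CTRL preset
  (2 compact clusters) and HF preset (8 dispersed clusters) reproduce the
  qualitative fragmentation signature: fewer RyRs per cluster and shorter
  inter-cluster nearest-neighbor distances;
* `place_ip3rs` — uniform-random interspersal of IP₃Rs into free sites
  within the RyR bounding box (+1 site), re-randomized per trial by
  default, mirroring the random-placement assumption for channels whose
  true positions are unknown;
* a CSV reader (`kind,ix,iy`) accepts externally derived channel maps.

Cluster statistics use connected components under a 100-nm center-distance
link radius (configurable).

Because the generators are synthetic stand-ins, passing tests demonstrate
the *mechanisms* (recruitment, luminal termination, IP₃R-boosted fidelity,
fragmentation effects) rather than reproduction of measured spark
statistics from real geometries.

## Protocols and problem sizes

`run_fidelity_sweep` runs the (N_IP3R ∈ 0..10) × ([IP₃] ∈ {0, 0.1, 1, 10}
µM) grid on the 50-RyR checkerboard, 100 trials × 200 ms per condition by
default.  `run_ctrl_vs_hf` compares the CTRL preset (N_IP3R ∈ {0, 1}) with
the HF preset (N_IP3R at 0/25/50/100 % of N_RyR, half-up rounding:
12.5 → 13) at [IP₃] = 0.1 µM, 500 trials per condition by default.
Per-trial seeds derive deterministically from (base seed, condition,
trial) via `SeedSequence`, with no hidden global state; spark-morphology
statistics are computed over qualifying trials only, fidelity over all
trials.

The test suite exercises the same machinery at reduced scale — 50 trials
of 60 ms per condition on a coarser N_IP3R grid — which is sufficient for
the rank-correlation trend and the exact zero-effect invariances (trials
are seed-paired across conditions, so conditions that cannot differ
physically match bit for bit).  One 200-ms trial costs roughly half a
second on one core.

## Known limitations

* 2D single-CRU model: no inter-CRU coupling, hence no wave propagation.
* No L-type channel trigger; sparks are initiated by forcing one RyR open.
* SERCA appears only through the first-order refill; no pump kinetics.
* β is a constant rapid-buffering factor; luminal buffering is not
  state-dependent.
* The IP₃R modal-gate constants are this package's own calibration, not
  the published patch-clamp fit; absolute IP₃R leak rates should be read
  qualitatively.
* Boundary treatment (Dirichlet rim at c_rest) is an assumption; the rim
  margin (10 sites) sets the escape distance and is configurable.
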