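# Model and methods

`excitosim` simulates excitotoxic degeneration of dopaminergic neurons in
the substantia nigra pars compacta (SNc) driven by the subthalamic nucleus
(STN), with the external globus pallidus (GPe) closing the subcortical
loop.  This note documents the model equations as implemented, the
calibrated constants and why they have the values they do, what the
simulations can and cannot show, and the numerical choices that matter.

## Populations and membrane dynamics

Three 2D lattices of Izhikevich neurons: SNc 8×8, STN 32×32, GPe 32×32
(rat basal-ganglia proportions).  Each neuron follows

    dv/dt = 0.04 v² + 5 v + 140 − u + I_bias + I_syn
    du/dt = a (b v − u),        v ≥ 30 mV  ⇒  v ← c, u ← u + d

integrated by forward Euler at dt = 0.1 ms with the voltage advanced in two
half-steps (the reference Izhikevich scheme) and the reset applied after
the update.  Parameters per nucleus (a, b, c, d; bias current):

| nucleus | a | b | c | d | I_bias | basal rate |
|---|---|---|---|---|---|---|
| STN | 0.005 | 0.265 | −65 | 1.5 | 3 | ~13 Hz |
| SNc | 0.0025 | 0.2 | −55 | 2 | 9 | ~4 Hz (events) |
| GPe | 0.1 | 0.2 | −65 | 2 | 4.25 | ~30 Hz |

At its operating point the SNc neuron fires doublets (two spikes ~5 ms
apart every ~215 ms).  Its pacemaker **event** rate is ~4.7 Hz, inside the
experimental 3–8 Hz band, while the raw spike count is ~9.5 /s; rate
characterizations therefore merge spikes closer than 20 ms into one firing
event.  STN and GPe fire singlets, so event and spike rates coincide.

**Heterogeneity.**  Real nuclei are not homogeneous; identical model
neurons form fragile, bistable synchrony attractors and an all-or-nothing
stress distribution.  Each neuron's bias current therefore carries a fixed
fractional offset: an evenly spaced profile spanning ±5 % (STN, GPe) or
±8 % (SNc), randomly assigned to lattice positions by the run seed.  The
stratified profile makes the population's excitability *distribution*
identical across seeds (only its spatial arrangement varies), which keeps
the degeneration experiments reproducible.

## Synapses

Receptor-resolved conductance-style currents
`I = W · h · (E_rev − v_post)` with AMPA (τ = 6 ms, E = 0), NMDA
(τ = 160 ms, E = 0, voltage-dependent magnesium block
`B(v) = 1 / (1 + (Mg/3.57) e^(−0.062 v))`, Mg = 1) and GABA-A (τ = 4 ms,
E = −60 mV).  A presynaptic spike increments the source's gate, which then
decays exponentially.  The gate increment is the one free scale of the
synaptic model: GABA gates use the unit-normalized convention (jump = 1,
scaled by 2.0 as part of calibration), while the glutamatergic jump is
0.03, chosen once so that the published STN lateral strength puts the
dopamine-depleted STN at the edge of its synchronized-bursting regime and
the dopamine-intact STN at its ~13 Hz tonic rate.

Connectivity: Gaussian lateral kernels `w = A exp(−d²/R²)` truncated to an
nlat×nlat window and at lattice edges (no wraparound, no self-connection);
STN↔GPe one-to-one; STN→SNc convergent (each SNc neuron pools a 4×4 STN
block, in-degree 16).  Lateral parameters (A, R, nlat): STN (1.3, 1.4, 11),
SNc (0.1, 1.6, 5), GPe (0.1, 1.6, 15).  The inter-nucleus base weights are
not published; the shipped defaults (W_STN→GPe = 0.5, W_GPe→STN = 0.5,
W_STN→SNc = 0.125) were calibrated once so that the dopamine-intact
network reproduces the basal rates and an SNc stress distribution
straddling the published apoptotic thresholds (below).

## Dopamine

The instantaneous dopamine level is the SNc population spike rate in a
trailing 100 ms window over **all** lattice positions (dead cells count
zero), normalized by `n_total · r_ref` and clipped to [0, 1], then low-pass
filtered with τ_DA = 200 ms before it modulates the network (dopamine tone
varies slowly; at the 10 ms scale the DA–STN loop would oscillate).
`r_ref` is on the scale of the healthy in-network SNc spike rate
(~10–11 Hz); the full profile uses 12 Hz, which leaves the intact network
just below DA = 1 and makes the dopamine signal respond promptly to cell
loss, while the scaled profile (whose raised weight elevates the healthy
rate) uses 10 Hz, pegging its healthy state at DA = 1.

Dopamine modulates the network in two ways:

* lateral strengths — `A_STN = 1.3 e^(−cd_stn·DA)` (excitatory laterals
  weaken with dopamine), `A_GPe = 0.1 e^(+cd_gpe·DA)`,
  `A_SNc = 0.1 e^(+cd_snc·DA)` (inhibitory laterals strengthen).  The
  exponents are not published; defaults cd_stn = 2.2, cd_gpe = 0.5,
  cd_snc = 1.0 place the STN synchronized-bursting transition at low
  dopamine and give the SNc a disinhibition reservoir that is released as
  dopamine falls;
* afferent scaling — every modulated pathway is multiplied by
  `(1 − cd2·DA)` with cd2 = 0.1 (published).

With these defaults the clamped-dopamine sweep reproduces the qualitative
structure of the published dopamine study: STN rate falls with dopamine
(~37 Hz bursting at DA = 0 → ~13.6 Hz at DA = 1) and its synchrony is
non-monotonic (asynchronous tonic at DA ≈ 1, synchronized at low DA); SNc
rate and synchrony fall as dopamine rises.  The GPe **rate** direction of
the published figure (rising with dopamine) does not reproduce — in this
architecture every dopamine-sensitive input to GPe weakens with dopamine —
and is not asserted by the test suite; GPe stays in its experimental
17–52 Hz band throughout.

## Stress and apoptosis

Each SNc neuron's stress Q relaxes toward its 1-s sliding-window spike
rate with τ_stress = 1 s (a free constant; matching the rate window keeps
the published thresholds on the firing-rate scale).  When Q exceeds the
apoptotic threshold the cell dies irreversibly: membrane clamped to 0,
outgoing gates zeroed, excluded from dopamine and metrics.

The three-phase experiment runs 50 s: threshold 11.3 from t = 0 (healthy —
no deaths), lowered to 10.8 at t = 10 s (the energy-deficit proxy).  The
healthy network is calibrated so per-cell stress spans ≈ 9.4–11.2: all
cells clear 11.3, the upper tail crosses 10.8 soon after the switch, and
the resulting dopamine decline disinhibits STN, releases SNc lateral
inhibition and drags the remaining cells over threshold — the runaway
phase, complete near the end of the run.  Sustained STN synchrony
elevation (onset of the 1-s-smoothed Kuramoto trace crossing the midpoint
between its phase-I baseline and its post-rise plateau, sustained for
≥ 80 % of the remaining run) appears only after ≥ 50 % cell loss,
typically between 35 and 49 s; the exact onset varies by several seconds
across seeds, so the experiment harness reports the median of three
replicate seeds.

Degeneration kinetics: t_1/2 is the first (interpolated) time after the
threshold switch at which the surviving count halves; λ = ln 2 / t_1/2;
the instantaneous λ(t) is the log-decrement on 1-s bins.

## Therapies

All interventions latch when the surviving count first reaches the
configured stage (25/50/75 % loss = 48/32/16 of 64 survivors):

* **Glutamate inhibition** — dose X % multiplies W_STN→SNc by 1 − X/100
  (a 90 % dose leaves 10 % of the drive).
* **Dopamine restoration** — dose X % adds X/100 to the dopamine level,
  clipped at 1.
* **Subthalamotomy** — a seeded uniform-random ⌊P_les·1024/100⌋-subset of
  STN neurons is permanently silenced.
* **DBS** — periodic current pulses (130 Hz; monophasic 650 / biphasic
  1000 amplitude; 100/200 µs width) delivered through a Gaussian contact
  field (single contact σ = 5 at (16,16); four contacts σ = 2; all-points
  uniform).  A fraction Per_AA of the amplitude is routed to the GPe
  lattice (antidromic activation), and a seeded fraction Per_ASF of STN
  axons is silenced toward both SNc and GPe while stimulation is on
  (axonal/synaptic failure).

Therapy grids and parameter sweeps run on a **scaled profile**: the same
physics with the threshold drop at 2 s (11.3 → 10.5), 14 s duration, and
W_STN→SNc raised to 0.25.  The stronger drive compresses the disease
course into desk-scale runs while preserving the key asymmetry of the
model: under pathological drive every SNc cell sits above the lowered
threshold, so restoring dopamine (which returns the drive toward its
healthy level) delays but can never arrest the loss, whereas removing
enough of the excitatory drive itself (high-dose glutamate inhibition,
near-total lesion) can.  A run is classified *halted* when the surviving
count is constant from 1 s after the trigger to the end of the run, and an
extinct course is never halted; outcome matrices additionally report the
survival ratio (0 = untreated course, 1 = no loss after the trigger) with
forthwith/delayed/halted bands at 0.15/0.85.

In this regime glutamate inhibition arrests the loss only for doses above
50 %, dopamine restoration delays but never arrests it at any stage even
at 100 %, and subthalamotomy arrests it at every intervention stage only
at a 100 % lesion (an 80 % lesion still fails at the early stage) — the
three published therapy boundaries.

## What the simulations show — and what they do not

All experiments are self-generated: the network is its own data source and
the published parameter tables are its inputs.  Passing tests show that
the implemented equations reproduce the model-level phenomenology
(basal rates, dopamine-dependent synchrony regimes, threshold-gated
runaway degeneration, therapy-outcome orderings) at desk scale.  They say
nothing about real patients or animals; the 50-s disease course is a
deliberate compression of years of neurodegeneration, striatal input is
absent by design, and the stress threshold is a fixed constant rather than
an energy variable.

## Numerical choices

* dt = 0.1 ms throughout (halving dt changes single-neuron 10-s rates by
  < 5 %).  The 130 Hz DBS pulse period (~77 steps) and the 100–200 µs
  pulse widths (1–2 steps) require this resolution.
* Initial conditions: v ~ U[c, c+10] mV, u = b·v, gates zero, stress zero,
  all seeded; all stochastic pieces (initial state, lesion subsets,
  failure masks) derive from one `SeedSequence`, and reruns with the same
  config and seed are bit-identical.
* The simulation loop is a single numba kernel; separable Gaussian
  convolutions evaluate the lateral sums exactly (zero padding equals
  edge truncation).  A consistency test checks the kernel step-for-step
  against the public module operations composed in numpy.
* Numerical guards: |v| leaving (−1000, 1000) mV (including NaN) aborts
  the run with a diagnostic; spike buffers are preallocated from a
  configurable per-neuron rate cap.
* Synchrony R(t) uses linear spike-phase interpolation between bracketing
  spikes; neurons without bracketing spikes (including the dead) are
  excluded, and R is undefined with fewer than two contributors.  The
  burst index `B = (2 Var(ISI₁) − Var(ISI₂)) / (2 E[ISI₁]²)` is 0 for
  periodic and Poisson trains and 0.64 for a 10/90 ms alternating-ISI
  doublet train.
* Analysis rate window 100 ms; stress window 1 s; both configurable.

## Reported problem sizes

Single-neuron characterizations integrate 10 s at dt = 0.1 ms.  The
three-phase experiment is the full 2112-neuron network for 50 s; sweeps
and therapy grids use the scaled 14-s profile at full network size.
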