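# Methods

## The question

An ensemble of excitatory neurons delivers a fixed total amount of charge
q to a quiescent target neuron.  The delivery can be tight (a compressed
current pulse, or a pulse train with short inter-arrival interval Δ) or
loose.  We quantify the "cost" of making the target fire under two
stopping rules for the input:

1. the input stops as soon as the target has *crossed threshold* (firing
   is inevitable without further input), or
2. the input continues until the target *actually fires*.

Under rule 1 the leaky-integrator intuition holds: tighter synchrony never
costs more (the charge-to-threshold φ and the pulse count N_Δ both grow
with Δ).  Under rule 2, input that arrives between threshold crossing and
the actual spike is wasted, and that waste grows as the input is
compressed; the pulse count M_Δ is minimized at an interior, imperfect
degree of synchrony and diverges like Δ^(-1/2) as Δ → 0.

## Target-neuron models

* **LIF** — dv/dt = −v/τ + I for v < 1, reset v → 0 at threshold 1.
  Dimensionless v; t, τ in ms; I in 1/ms.
* **Theta / QIF** — dv/dt = −v(1−v)/τ + I, threshold at +∞, reset from
  −∞, integrated exclusively in the phase variable
  θ = 2 arctan(2v − 1), in which the voltage blow-up at firing is an
  ordinary crossing of θ = π.  Conductance drives g·s·(v_rev − v) are
  mapped through the same coordinate change; the resulting vector field
  is smooth through θ = π.  For I < 1/(4τ) the voltage fixed points are
  v± = 1/2 ± √(1/4 − τI); the pair annihilates in a saddle-node
  bifurcation at τI = 1/4.
* **WB** — Wang–Buzsáki fast-spiking interneuron: spike-generating
  sodium (g_Na = 35 mS/cm², E_Na = 55 mV, instantaneous activation
  m = m∞(v)), delayed-rectifier potassium (g_K = 9, E_K = −90), leak
  (g_L = 0.1, E_L = −65), temperature factor 5 on the h and n kinetics,
  C = 1 µF/cm².
* **RTM** — reduced Traub–Miles pyramidal cell: g_Na = 100 (E_Na = 50),
  g_K = 80 (E_K = −100), g_L = 0.1 (E_L = −67), C = 1, with *dynamic*
  sodium activation m (state v, m, h, n), the form in which the reduction
  was published.  The gating-rate expressions for both models are the
  classical published ones; the removable singularities of the
  x/(1−e^(−x/s)) rate functions are filled by their limits.

Spike times: for the LIF, the upward crossing of 1; for the theta model,
of θ = π; for WB/RTM, of a detection level of 0 mV — each localized by
linear interpolation between the bracketing grid points (O(dt²)
accuracy).  WB/RTM runs start from the zero-drive resting state, found by
200 ms of relaxation followed by Newton root polishing to derivative
residuals below 1e−10.

## Numerical integration

Fixed-step classical RK4, default dt = 0.01 ms.  Time-varying drives are
sampled on a half-step grid so every RK4 stage uses the exact drive
value; synaptic gating for pulse trains is evaluated by piecewise
closed-form exponentials (geometric superposition), never by ODE
stepping, so the inter-arrival decay carries no discretization error.
Instantaneous charge injections are grid-aligned jumps v → v + w applied
as right limits (for the theta model, through the v ↔ θ coordinate
change).  Train sweeps choose dt = Δ/⌈Δ/0.01⌉ so arrivals are exactly
grid-aligned; compressed pulses use dt = min(0.01, ε/50) during the pulse
(first 30ε ms, which carries all but ~3·10⁻¹² of the charge) and the
default step afterwards.  Adaptivity was deliberately rejected:
reproducibility and exact event placement matter more here than step-size
economy, and halving dt moves spike times by ≲1e−5 ms (tested).

## Metrics and search procedures

* **M_ε** (peak response): LIF integrated *without* reset; the horizon
  doubles until >1−1e−8 of the charge has arrived and the membrane is
  decaying.  For the theta neuron, M_ε > 1 is equivalent to blow-up, so
  the ∞ flag is returned as soon as v exceeds 1.
* **ε₀** (critical compression): exists iff q > 1; located by doubling
  bracket plus log-axis bisection on the spike predicate to relative
  tolerance 1e−6.
* **T̂_ε** (firing time): earliest spike; a run is declared spike-free
  only once >99.999% of the charge has arrived *and* the membrane is
  below its unstable level (1 for LIF/theta, the detection level for HH
  models) *and* decaying (HH models: or back within 0.1 mV of rest).
  Near ε₀ no fixed horizon is correct — the trajectory can hover near the
  repelling level v = 1 arbitrarily long — hence horizon doubling.
* **Q̂_ε** (charge to fire): quadrature of the *unscaled* pulse over
  [0, R̂_ε], equal to ∫₀^{T̂_ε} I_ε dt by substitution (the equality is a
  test, at 1e−6 relative).
* **N_Δ** (pulses to threshold): smallest k such that delivering exactly
  k pulses and then nothing still yields a spike; truncation removes
  later gating jumps but lets s decay on.  Because the response is
  monotone in k, the smallest such k is found by doubling plus bisection
  (equivalent to, and cheaper than, incremental search).  Trains whose
  saturated response stays subthreshold get an ∞ flag (detected when the
  peak response stops growing).
* **M_Δ** (pulses until firing): the train runs on; arrivals strictly
  before the interpolated spike time are counted (an arrival exactly at
  the spike time is not).
* Sweeps use logarithmic ε grids; the minimum of R̂_ε is refined by
  golden-section search on the log axis.  For the conductance-based
  models the firing region in ε is a window (very compressed weak pulses
  reduce to a subthreshold instantaneous kick); its edges are found by
  grid scan plus bisection.  For the r = 7 WB pulse the kick is ~7 mV,
  which still (slowly) fires the model, so only the upper edge is a
  genuine boundary.

## The PING network

200 RTM E-cells with graded drives 1.5 + j/200 µA/cm² and 50 undriven WB
I-cells; all-to-all synapses with per-synapse conductance = population
total / presynaptic count (ĝ_EI = 0.4, ĝ_IE = 1, ĝ_II = 0.6, ĝ_EE = 0
mS/cm²); excitatory reversal 0 mV, inhibitory −67 mV; rise/decay time
constants 0.1/3 ms (excitatory) and 0.3/9 ms (inhibitory).  Each cell
carries one gating variable with

    ds/dt = ((1 + tanh(v/10))/2)·(1 − s)/τ_rise − s/τ_decay,

a standard saturating form.  Tonic inhibition adds g_tonic·(−67 − v) to
every E-cell.  There is no stochasticity anywhere; runs are
bit-reproducible at fixed dt.

Initial conditions (a genuinely open choice): every cell starts at its
zero-input resting state with s = 0.  The drive gradient desynchronizes
the E-cells and the rhythm settles within ~100 ms; metrics discard the
first 150 ms of a 650 ms run and are unchanged (to <0.1 Hz and <0.1
cells) under perturbed initial voltages, halved dt, and doubled run
length.  Because the I-cells are identically parameterized and driven,
they remain exactly interchangeable and fire as one.

Rhythm metrics: E-spikes after the transient are pooled and segmented
into volleys by a gap threshold iterated to half the median *silent gap*
between volleys.  (Iterating on half the median volley-to-volley interval
instead — the more obvious rule — can exceed the silent gap when volleys
have long straggler tails and then merges volleys; the silent-gap rule is
the robust variant of the same idea.)  Volleys touching the window edges
are dropped.  Participation is the number of distinct E-cells per volley,
averaged and rounded; frequency is the reciprocal mean inter-volley
interval; the volley duration is the mean time from the first to the
100th distinct E-cell of a volley.

With these choices the baseline network yields participation ≈ 150,
frequency ≈ 69.7 Hz, volley duration ≈ 2.7 ms, and the tonic network
(g_tonic = 0.2) participation ≈ 108, ≈ 46.5 Hz, ≈ 4.8 ms — tonic
inhibition slows the rhythm, loosens the volleys and silences the
weakest-driven cells, which is the phenomenon of interest.  In the
baseline regime the steady state is a period-two alternation in which the
cells near the participation boundary fire on alternate cycles
(per-volley participation alternates ≈ 140/160), so per-volley
participation variance is structural, not numerical.

Known limitation: the baseline frequency is sensitive to details of the
synaptic activation function (its normalization alone shifts the rhythm
by several Hz, trading off against the tonic-case metrics), which caps
the precision that should be expected of the baseline frequency; the
remaining five network metrics and every single-neuron result are robust
to these choices.

## What the synthetic inputs do and do not emulate

The stimulus families are the study's data.  They emulate: charge-
conserving compression of a volley (AlphaPulse), perfectly periodic
arrival of many weak synapses far from saturation (SynapticTrain with
unbounded s), and their singular limits (DeltaTrain).  They do not
emulate: jittered or Poisson arrival times, conductance noise,
saturating single synapses, or dendritic filtering.  Passing tests
therefore demonstrate the stated mechanisms in the deterministic,
periodic-input idealization, not their robustness to biological
variability.

## Problem sizes

The test suite and the acceptance script use the full 250-cell network
(650 ms at dt = 0.01 ms, ~10 s per run with the compiled kernels), ε
sweeps of 25–40 points with golden-section refinement, and pulse-train
counts up to a few hundred pulses; everything runs comfortably on one
CPU core.
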