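# volley

When does synchrony of excitatory input maximize its downstream effect?

A leaky neuron is a coincidence detector: charge that arrives early leaks
away before the rest arrives, so delivering a fixed amount of charge in a
shorter time window seems always better.  `volley` implements the
computational counter-analysis: whether perfect synchrony is actually
optimal depends on *when the input is allowed to stop*.

* If the input may cease the moment the target **crosses its firing
  threshold**, tighter synchrony is always at least as cheap.
* If the input lasts until the target **actually fires** (e.g. it is shut
  off by feedback from the target, as the E→I interaction in a PING
  rhythm), there is an optimal, distinctly *imperfect* degree of synchrony.

The package provides the models, stimuli and metrics to quantify both
statements, plus the motivating pyramidal–interneuron network gamma (PING)
simulation.

## What is in the box

**Models** (`volley.models`) — normalized leaky integrate-and-fire (LIF,
threshold 1, reset 0, `dv/dt = -v/τ + I`), the theta/quadratic
integrate-and-fire phase model (`dθ/dt = -cos θ/τ + 2I(1+cos θ)`,
firing = θ reaching π), and conductance-based Wang–Buzsáki (WB,
fast-spiking interneuron) and reduced Traub–Miles (RTM, pyramidal cell)
neurons.  Fixed-step RK4 (default dt = 0.01 ms, numba-compiled), spike
times by linear interpolation.

**Stimuli** (`volley.stimuli`) — the synthetic input generator:

* `AlphaPulse` — the compressible pulse `I_ε(t) = (1/ε) I(t/ε)` with
  `I(t) = r t e^{-t}`; total charge q = r for every compression factor ε.
  Smaller ε models a more tightly synchronized presynaptic volley; ε → 0
  is an instantaneous charge injection q·δ(t).
* `DeltaTrain` — instantaneous voltage kicks of size w every Δ ms.
* `SynapticTrain` — unit jumps of a gating variable s every Δ ms, decaying
  with the 3 ms AMPA-like time constant, driving `ḡ s (v_rev − v)`.
* `ConstantDrive` and `RampDrive` — the exactly solvable idealizations.

**Metrics** (`volley.metrics`) — peak response `M_ε`, critical compression
`ε₀` (spike iff q > 1 and ε ≤ ε₀), firing time `T̂_ε`, the firing-time /
input-duration ratio `R̂_ε = T̂_ε/ε`, charge-to-fire
`Q̂_ε = ∫₀^{R̂_ε} I(s) ds`, and the two pulse counts: `N_Δ` (pulses until
the spike is inevitable — monotone increasing in Δ) and `M_Δ` (pulses
arriving before the actual spike — non-monotone with an interior minimum,
and ∝ Δ^{-1/2} as Δ → 0).

**Closed forms** (`volley.analytic`) — constant-drive firing time
`T_Δ = τ ln((τ/Δ)/(τ/Δ−1))`, charge-to-threshold `φ(s) = s ln(s/(s−1))`,
the delta-train geometric-sum count, the theta blow-up time
`τ ln(q/(q−1))`, and the ramp-drive model problem with its
`√(2/c)·Δ^{-1/2}` pulse-count asymptote.  These double as independent
oracles for the simulators in the test suite.

**Network** (`volley.network`) — 200 RTM E-cells (drives 1.5 + j/200
µA/cm²) and 50 WB I-cells, all-to-all, generating a gamma-band PING rhythm;
optional tonic inhibition `g·(−67 − v)` on the E-cells; raster and rhythm
metrics (participation per volley, frequency, volley duration).

## Worked example

```python
import volley as V
from volley.metrics import critical_epsilon, firing_time, time_ratio, charge_to_fire

lif = V.LIFParams(tau=10.0)
pulse = V.AlphaPulse(r=1.25, epsilon=1.0)   # total charge q = 1.25 > 1

critical_epsilon(lif, pulse)                 # 0.5919377615506662
firing_time(lif, V.AlphaPulse(1.25, 0.3))    # 0.9963349907678872 (ms)
time_ratio(lif, V.AlphaPulse(1.25, 0.3))     # 3.3211166358929574
charge_to_fire(lif, V.AlphaPulse(1.25, 0.3)) # 1.0549421768094729
```

Read: a charge-1.25 pulse compressed to ε = 0.3 fires this LIF neuron
1.0 ms after onset, about 3.3 input-durations in; by then 1.05 units of
charge have arrived, so ~0.2 units were wasted relative to the ε → 0
limit — but a pulse stretched beyond ε₀ ≈ 0.59 never fires at all.

The same questions from the shell:

```sh
volley sweep m-eps --model lif --tau 10 --r 1.25 \
    --grid-min 0.01 --grid-max 10 --grid-points 7
# ... "monotone_decreasing": true  (peak response falls with epsilon)

volley analytic ramp --tau 10 --c 0.025 --delta 0.05
# {"T_tilde": 2.0689488478688403, "M_tilde": 41.3789769573768, "asymptotic_M": 40.0}

volley ping run --tonic 0.2 --t-end 650 --dt 0.01 \
    --out raster.csv --metrics metrics.json
```

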