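"""Efficiency metrics for excitatory input driving a single target neuron.

The questions addressed here all have the same shape: an input volley of
total charge q is delivered to a quiescent target neuron either as a
compressed current pulse I_eps (compression factor eps; smaller eps =
tighter synchrony) or as a periodic train of weak pulses (inter-arrival
interval Delta; smaller Delta = tighter synchrony).  The metrics measure
how "expensive" it is to make the target fire:

``peak_response``   M_eps, the maximum membrane response to I_eps
                    (infinite for the theta neuron once v exceeds 1).
``critical_epsilon`` eps0, the largest compression at which I_eps still
                    elicits a spike (exists iff q > 1).
``firing_time``     T_hat(eps), the time of the (first) action potential.
``time_ratio``      R_hat(eps) = T_hat/eps, firing time relative to input
                    duration.
``charge_to_fire``  Q_hat(eps), the charge delivered up to the moment of
                    firing.
``pulses_to_threshold``  N_Delta: the smallest number of train pulses
                    after which the target fires even if the input then
                    stops (input "ceases at threshold crossing").
``pulses_until_fire``    M_Delta: the number of train pulses that arrive
                    strictly before the target actually fires, with the
                    train running on (input "lasts until firing").

The contrast between N_Delta (monotone increasing in Delta: perfect
synchrony cheapest) and M_Delta (non-monotone, with an interior minimum:
approximate synchrony cheapest) is the central phenomenon the package
quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import integrate

from .models import (
    DEFAULT_DT,
    HHParams,
    LIFParams,
    ModelSpec,
    ThetaParams,
    Trace,
    model_kind,
    resting_state,
    simulate_hh,
    simulate_lif,
    simulate_theta,
)
from .stimuli import AlphaPulse, DeltaTrain, StimulusSpec, SynapticTrain

__all__ = [
    "SweepResult",
    "peak_response",
    "critical_epsilon",
    "firing_time",
    "time_ratio",
    "charge_to_fire",
    "pulses_to_threshold",
    "pulses_until_fire",
    "firing_window",
    "min_time_ratio",
    "sweep_epsilon",
    "sweep_delta",
]

_T_END_CAP = 4.0e5  # ms; horizon doubling beyond this aborts
_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@lru_cache(maxsize=8)
def _rest(params: HHParams) -> tuple:
    return tuple(resting_state(params))


def _mem_scale(model: ModelSpec) -> float:
    """Rough membrane relaxation scale used to size simulation horizons."""
    kind = model_kind(model)
    if kind == "lif":
        return model.tau
    if kind == "theta":
        return 4.0 * model.tau
    return 30.0  # HH models: gate kinetics dominate


# ---------------------------------------------------------------------------
# pulse runs with a two-phase grid (fine during the pulse, standard after)


@dataclass
class _PulseRun:
    spikes: np.ndarray
    v_max: float  # max membrane response (theta: max phase, see theta_sup)
    theta_max: float
    end_decreasing: bool
    v_end: float
    delivered: float
    t_end: float


def _run_pulse(model: ModelSpec, pulse: AlphaPulse, t_end: float, reset: bool = True) -> _PulseRun:
    """Simulate the response to I_eps on [0, t_end] from the quiescent state.

    The pulse phase [0, min(30*eps, t_end)] is integrated with
    dt = min(0.01, eps/50) so that strongly compressed pulses stay
    resolved; the remaining interval carries < 1e-11 of the charge and is
    integrated drive-free at the default step from the end state.
    """
    kind = model_kind(model)
    eps = pulse.epsilon
    t1 = min(t_end, 30.0 * eps)
    dt1 = min(DEFAULT_DT, eps / 50.0)
    spikes = []
    if kind == "lif":
        tr1 = simulate_lif(model, pulse, t1, dt1, v0=0.0, reset=reset)
        spikes.append(tr1.spike_times)
        v_max = float(tr1.v.max())
        v_end = float(tr1.v[-1])
        th_max = math.nan
        if t_end > t1 * (1.0 + 1e-12):
            tr2 = simulate_lif(model, None, t_end - t1, DEFAULT_DT, v0=min(v_end, 0.999999), reset=reset)
            # drive-free LIF decays; only threshold logic could matter if v_end ~ 1
            spikes.append(tr2.spike_times + t1)
            v_max = max(v_max, float(tr2.v.max()))
            tail = tr2.v
        else:
            tail = tr1.v
        end_dec = tail[-1] <= tail[max(0, tail.size - 6)]
        v_end = float(tail[-1])
    elif kind == "theta":
        tr1 = simulate_theta(model, pulse, t1, dt1, v0=0.0)
        spikes.append(tr1.spike_times)
        th1 = tr1["theta"]
        th_max = float(th1.max())
        th_end = float(th1[-1])
        if t_end > t1 * (1.0 + 1e-12) and tr1.spike_times.size == 0:
            tr2 = simulate_theta(model, None, t_end - t1, DEFAULT_DT, theta0=th_end)
            spikes.append(tr2.spike_times + t1)
            th2 = tr2["theta"]
            th_max = max(th_max, float(th2.max()))
            tail = th2
        else:
            tail = th1
        end_dec = tail[-1] <= tail[max(0, tail.size - 6)]
        from .models import theta_to_v

        th_end = float(tail[-1])
        v_end = float(theta_to_v(min(th_end, math.pi - 1e-9)))
        v_max = float(theta_to_v(min(th_max, math.pi - 1e-9)))
    else:
        init = np.array(_rest(model))
        tr1 = simulate_hh(model, pulse, t1, dt1, init=init)
        spikes.append(tr1.spike_times)
        v_max = float(tr1.v.max())
        th_max = math.nan
        if t_end > t1 * (1.0 + 1e-12) and tr1.spike_times.size == 0:
            tr2 = simulate_hh(model, None, t_end - t1, DEFAULT_DT, init=tr1.states[-1])
            spikes.append(tr2.spike_times + t1)
            v_max = max(v_max, float(tr2.v.max()))
            tail = tr2.v
        else:
            tail = tr1.v
        end_dec = bool(tail[-1] <= tail[max(0, tail.size - 6)] or abs(tail[-1] - init[0]) < 0.1)
        v_end = float(tail[-1])
    all_spikes = np.concatenate(spikes) if spikes else np.empty(0)
    return _PulseRun(
        spikes=all_spikes,
        v_max=v_max,
        theta_max=th_max,
        end_decreasing=bool(end_dec),
        v_end=v_end,
        delivered=pulse.delivered_fraction(t_end),
        t_end=t_end,
    )


def _no_spike_certified(model: ModelSpec, run: _PulseRun) -> bool:
    """A run is declared spike-free once >99.999% of the charge has
    arrived and the membrane is below its unstable level and decaying."""
    if run.delivered < 0.99999:
        return False
    kind = model_kind(model)
    if kind == "lif":
        level = 1.0
    elif kind == "theta":
        level = 1.0  # v_+ of the zero-drive dynamics
    else:
        level = model.spike_detection_level
    return run.v_end < level and run.end_decreasing


def peak_response(model: ModelSpec, pulse: AlphaPulse) -> float:
    """Peak membrane response M_eps to the pulse I_eps from rest (v = 0).

    For the LIF neuron the trajectory is integrated without reset and the
    maximum of v is returned.  For the theta neuron, math.inf is returned
    as soon as v exceeds 1 (the voltage then blows up in finite time);
    otherwise the supremum of v.
    """
    kind = model_kind(model)
    if kind not in ("lif", "theta"):
        raise ValueError("peak_response is defined for the lif and theta models")
    t_end = 30.0 * pulse.epsilon + 5.0 * _mem_scale(model)
    while True:
        run = _run_pulse(model, pulse, t_end, reset=False)
        if kind == "theta" and (run.spikes.size > 0 or run.theta_max > 0.5 * math.pi):
            return math.inf
        if run.delivered > 1.0 - 1e-8 and run.end_decreasing:
            return run.v_max
        t_end *= 2.0
        if t_end > _T_END_CAP:
            raise RuntimeError("peak_response horizon exceeded without resolution")


def firing_time(model: ModelSpec, pulse: AlphaPulse) -> float:
    """Firing time T_hat(eps), or math.inf if I_eps elicits no spike.

    The target starts quiescent (v = 0 for LIF/theta, the zero-drive
    resting state for WB/RTM).  The horizon doubles until either a spike
    occurs or the no-spike certificate holds (charge essentially all
    arrived, membrane subthreshold and decaying).
    """
    t_end = 30.0 * pulse.epsilon + 5.0 * _mem_scale(model)
    while True:
        run = _run_pulse(model, pulse, t_end, reset=True)
        if run.spikes.size > 0:
            return float(run.spikes[0])
        if _no_spike_certified(model, run):
            return math.inf
        t_end *= 2.0
        if t_end > _T_END_CAP:
            raise RuntimeError("firing_time horizon exceeded without resolution")


def _fires(model: ModelSpec, pulse: AlphaPulse) -> bool:
    return math.isfinite(firing_time(model, pulse))


def critical_epsilon(model: ModelSpec, pulse: AlphaPulse, rtol: float = 1e-6) -> float:
    """Critical compression eps0: I_eps spikes for eps <= eps0, not beyond.

    Exists only when the pulse charge q exceeds the threshold 1 (for
    q <= 1 no compression elicits a spike and a ValueError is raised).
    The spike/no-spike dichotomy in eps is bracketed by doubling from the
    pulse's own eps and refined by bisection on the log axis to relative
    tolerance ``rtol``.
    """
    if pulse.total_charge <= 1.0:
        raise ValueError("no critical epsilon exists: pulse charge q <= 1 never elicits a spike")
    eps = pulse.epsilon
    if _fires(model, pulse):
        lo = eps
        hi = 2.0 * eps
        n = 0
        while _fires(model, pulse.compressed(hi)):
            lo, hi = hi, 2.0 * hi
            n += 1
            if n > 60:
                raise RuntimeError("failed to bracket the critical epsilon from above")
    else:
        hi = eps
        lo = 0.5 * eps
        n = 0
        while not _fires(model, pulse.compressed(lo)):
            hi, lo = lo, 0.5 * lo
            n += 1
            if n > 60:
                raise RuntimeError("failed to bracket the critical epsilon from below")
    while hi / lo > 1.0 + rtol:
        mid = math.sqrt(lo * hi)
        if _fires(model, pulse.compressed(mid)):
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def time_ratio(model: ModelSpec, pulse: AlphaPulse) -> float:
    """R_hat(eps) = T_hat(eps) / eps; math.inf propagates from T_hat."""
    T = firing_time(model, pulse)
    return T / pulse.epsilon


def charge_to_fire(model: ModelSpec, pulse: AlphaPulse) -> float:
    """Charge Q_hat(eps) delivered up to the moment the target fires.

    Computed as the integral of the *unscaled* pulse I over [0, R_hat],
    which equals the integral of I_eps over [0, T_hat] by the substitution
    s = t/eps.  Raises ValueError if the pulse elicits no spike.
    """
    T = firing_time(model, pulse)
    if not math.isfinite(T):
        raise ValueError("charge_to_fire requires a pulse that elicits a spike")
    R = T / pulse.epsilon
    base = AlphaPulse(pulse.r, 1.0)
    upper = min(R, 60.0)  # the integrand is < 1e-24 beyond t = 60
    val, _ = integrate.quad(base.value, 0.0, upper, limit=200)
    return val


# ---------------------------------------------------------------------------
# pulse-train counts


def _train_dt(delta: float) -> float:
    """Step commensurate with the inter-arrival interval (<= the default)."""
    return delta / math.ceil(delta / DEFAULT_DT - 1e-12)


def _simulate_train(model: ModelSpec, train, t_end: float) -> Trace:
    kind = model_kind(model)
    dt = _train_dt(train.delta)
    if kind == "lif":
        return simulate_lif(model, train, t_end, dt, v0=0.0)
    if kind == "theta":
        return simulate_theta(model, train, t_end, dt, v0=0.0)
    return simulate_hh(model, train, t_end, dt, init=np.array(_rest(model)))


def _train_tail(model: ModelSpec, train) -> float:
    tail = 5.0 * _mem_scale(model)
    if isinstance(train, SynapticTrain):
        tail += 10.0 * train.tau_decay
    return tail


def _train_settled(model: ModelSpec, tr: Trace) -> bool:
    """True when the post-truncation trajectory is subthreshold and decaying."""
    kind = model_kind(model)
    if kind == "lif":
        x = tr.v
        level = 1.0
    elif kind == "theta":
        x = tr["theta"]
        level = 0.5 * math.pi
    else:
        x = tr.v
        level = model.spike_detection_level
    return bool(x[-1] < level and x[-1] <= x[max(0, x.size - 6)])


def _fires_with_k_pulses(model: ModelSpec, train, k: int) -> Tuple[bool, float]:
    """Deliver exactly k pulses, then nothing; did the target spike?

    Also returns the peak membrane excursion, used to certify hopeless
    trains (the peak converges as k grows while staying subthreshold).
    """
    trunc = replace(train, n_pulses=k)
    tail = _train_tail(model, train)
    t_end = k * train.delta + tail
    for _ in range(8):
        tr = _simulate_train(model, trunc, t_end)
        if tr.spike_times.size > 0:
            return True, float(tr.v.max())
        if _train_settled(model, tr):
            peak = float(tr["theta"].max()) if model_kind(model) == "theta" else float(tr.v.max())
            return False, peak
        t_end *= 2.0
    raise RuntimeError("truncated-train run did not settle")


def pulses_to_threshold(model: ModelSpec, train) -> float:
    """N_Delta: smallest number of pulses whose delivery guarantees a spike.

    Pulses beyond the N-th are removed entirely (the gating variable stops
    jumping but keeps decaying); the count is the smallest k for which the
    truncated input still produces an action potential.  Returns math.inf
    when no number of pulses ever fires the target.
    """
    if not isinstance(train, (DeltaTrain, SynapticTrain)):
        raise TypeError("pulses_to_threshold expects a DeltaTrain or SynapticTrain")
    k = 1
    prev_peak = -math.inf
    while True:
        fired, peak = _fires_with_k_pulses(model, train, k)
        if fired:
            break
        if peak - prev_peak < 1e-10:
            return math.inf  # response has saturated below threshold
        prev_peak = peak
        k *= 2
        if k > 1 << 16:
            return math.inf
    lo, hi = k // 2, k  # lo did not fire (or k == 1), hi fired
    while hi - lo > 1:
        mid = (lo + hi) // 2
        fired, _ = _fires_with_k_pulses(model, train, mid)
        if fired:
            hi = mid
        else:
            lo = mid
    return hi


def pulses_until_fire(model: ModelSpec, train: SynapticTrain) -> float:
    """M_Delta: pulses arriving strictly before the target fires.

    The train runs continuously (never truncated).  An arrival exactly at
    the spike time is not counted.  Returns math.inf when the ongoing
    train never fires the target (its subthreshold response converges to
    a periodic orbit).
    """
    if not isinstance(train, (SynapticTrain, DeltaTrain)):
        raise TypeError("pulses_until_fire expects a pulse train")
    t_end = max(50.0 * train.delta, 100.0)
    prev_peak = -math.inf
    while True:
        tr = _simulate_train(model, train, t_end)
        if tr.spike_times.size > 0:
            t_sp = float(tr.spike_times[0])
            count = int(math.floor((t_sp - 1e-9) / train.delta))
            if train.n_pulses is not None:
                count = min(count, train.n_pulses)
            return count
        peak = float(tr["theta"].max()) if model_kind(model) == "theta" else float(tr.v.max())
        if peak - prev_peak < 1e-10:
            return math.inf
        prev_peak = peak
        t_end *= 2.0
        if t_end > _T_END_CAP:
            raise RuntimeError("pulses_until_fire horizon exceeded without resolution")


# ---------------------------------------------------------------------------
# sweeps


@dataclass
class SweepResult:
    """A metric evaluated along a swept parameter (eps or Delta)."""

    swept_name: str
    swept_values: np.ndarray
    metric_name: str
    metric_values: np.ndarray
    model: ModelSpec
    stimulus: Optional[dict] = None

    def __post_init__(self) -> None:
        self.swept_values = np.asarray(self.swept_values, dtype=float)
        self.metric_values = np.asarray(self.metric_values, dtype=float)
        if self.swept_values.size != self.metric_values.size:
            raise ValueError("swept and metric value lists must have equal length")
        if np.any(np.diff(self.swept_values) <= 0):
            raise ValueError("swept_values must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        flags = np.where(np.isinf(self.metric_values), "no_spike", "")
        return pd.DataFrame(
            {
                self.swept_name: self.swept_values,
                self.metric_name: self.metric_values,
                "flag": flags,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        """Minimum location/value and monotonicity verdict over finite entries."""
        finite = np.isfinite(self.metric_values)
        out = {
            "metric": self.metric_name,
            "swept": self.swept_name,
            "n_points": int(self.swept_values.size),
            "n_finite": int(finite.sum()),
        }
        if finite.any():
            vals = self.metric_values[finite]
            xs = self.swept_values[finite]
            i = int(np.argmin(vals))
            d = np.diff(vals)
            out.update(
                {
                    "min_value": float(vals[i]),
                    "min_at": float(xs[i]),
                    "monotone_increasing": bool(np.all(d > 0)),
                    "monotone_decreasing": bool(np.all(d < 0)),
                }
            )
        return out


def sweep_epsilon(
    model: ModelSpec,
    r: float,
    eps_values: Sequence[float],
    metric: str = "m_eps",
) -> SweepResult:
    """Evaluate M_eps, T_hat, R_hat or Q_hat along a grid of compressions.

    ``metric`` is one of 'm_eps', 't_hat', 'r_hat', 'q_hat'.  Entries
    where the pulse elicits no spike are math.inf (or, for 'q_hat',
    math.nan, since the charge-to-fire is then undefined).
    """
    eps_values = np.asarray(sorted(eps_values), dtype=float)
    vals = np.empty_like(eps_values)
    for i, eps in enumerate(eps_values):
        pulse = AlphaPulse(r, eps)
        if metric == "m_eps":
            vals[i] = peak_response(model, pulse)
        elif metric == "t_hat":
            vals[i] = firing_time(model, pulse)
        elif metric == "r_hat":
            vals[i] = time_ratio(model, pulse)
        elif metric == "q_hat":
            T = firing_time(model, pulse)
            vals[i] = charge_to_fire(model, pulse) if math.isfinite(T) else math.nan
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return SweepResult("epsilon", eps_values, metric, vals, model, {"family": "alpha", "r": r})


def sweep_delta(
    model: ModelSpec,
    delta_values: Sequence[float],
    metric: str,
    gbar: Optional[float] = None,
    w: Optional[float] = None,
    tau_decay: float = 3.0,
    v_rev: Optional[float] = None,
) -> SweepResult:
    """Evaluate N_Delta or M_Delta along a grid of inter-pulse intervals.

    Give ``gbar`` for synaptic trains or ``w`` for instantaneous charge
    injections.  ``metric`` is 'n_delta' or 'm_delta'.
    """
    if (gbar is None) == (w is None):
        raise ValueError("give exactly one of gbar (synaptic train) or w (delta train)")
    delta_values = np.asarray(sorted(delta_values), dtype=float)
    vals = np.empty_like(delta_values)
    for i, d in enumerate(delta_values):
        train = SynapticTrain(gbar, d, tau_decay, v_rev) if gbar is not None else DeltaTrain(w, d)
        if metric == "n_delta":
            vals[i] = pulses_to_threshold(model, train)
        elif metric == "m_delta":
            vals[i] = pulses_until_fire(model, train)
        else:
            raise ValueError(f"unknown metric {metric!r}")
    stim = {"family": "synaptic_train", "gbar": gbar} if gbar is not None else {"family": "delta_train", "w": w}
    return SweepResult("delta", delta_values, metric, vals, model, stim)


def firing_window(
    model: ModelSpec,
    r: float,
    eps_lo: float = 1e-2,
    eps_hi: float = 1e2,
    n_scan: int = 41,
    rtol: float = 1e-3,
) -> Tuple[float, float]:
    """Range of compressions over which the pulse r*t*e^{-t} elicits a spike.

    For the LIF and theta neurons the window is (0, eps0]; for the
    conductance-based models it is a genuine window: very compressed
    pulses deposit their charge as a too-small instantaneous jump, very
    dilute ones leak away.  Edges are located by log-grid scan followed
    by bisection against the neighbouring non-firing grid points.
    """
    grid = np.geomspace(eps_lo, eps_hi, n_scan)
    fires = [ _fires(model, AlphaPulse(r, e)) for e in grid ]
    if not any(fires):
        raise ValueError("no compression in the scanned range elicits a spike")
    idx = [i for i, f in enumerate(fires) if f]
    i0, i1 = idx[0], idx[-1]

    def _edge(lo, hi, lo_fires: bool) -> float:
        while hi / lo > 1.0 + rtol:
            mid = math.sqrt(lo * hi)
            if _fires(model, AlphaPulse(r, mid)) == lo_fires:
                lo = mid
            else:
                hi = mid
        return math.sqrt(lo * hi)

    lo_edge = grid[i0] if i0 == 0 else _edge(grid[i0 - 1], grid[i0], False)
    hi_edge = grid[i1] if i1 == n_scan - 1 else _edge(grid[i1], grid[i1 + 1], True)
    return lo_edge, hi_edge


def min_time_ratio(
    model: ModelSpec,
    r: float,
    eps_bounds: Optional[Tuple[float, float]] = None,
    n_scan: int = 25,
    log_tol: float = 1e-3,
) -> Tuple[float, float]:
    """Minimize R_hat(eps) = T_hat/eps over the firing window.

    A logarithmic grid scan locates the coarse minimum; golden-section
    search on the log axis between its neighbours refines it.  Returns
    (eps_at_min, min_R_hat).
    """
    if eps_bounds is None:
        lo, hi = firing_window(model, r)
        lo *= 1.05
        hi *= 0.95
    else:
        lo, hi = eps_bounds
    grid = np.geomspace(lo, hi, n_scan)
    vals = np.array([time_ratio(model, AlphaPulse(r, e)) for e in grid])
    i = int(np.nanargmin(np.where(np.isfinite(vals), vals, np.nan)))
    a = math.log(grid[max(0, i - 1)])
    b = math.log(grid[min(n_scan - 1, i + 1)])

    def f(x: float) -> float:
        return time_ratio(model, AlphaPulse(r, math.exp(x)))

    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1, f2 = f(x1), f(x2)
    while b - a > log_tol:
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - _GOLDEN * (b - a)
            f1 = f(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + _GOLDEN * (b - a)
            f2 = f(x2)
    x_star = 0.5 * (a + b)
    return math.exp(x_star), f(x_star)
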