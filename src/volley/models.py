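"""Single-neuron dynamics and spike detection.

Four target-neuron classes are supported:

``lif``
    Linear integrate-and-fire, normalized so the firing threshold is 1 and
    the reset voltage is 0:  dv/dt = -v/tau + I  while v < 1, with reset
    v -> 0 at threshold.
``theta``
    Theta / quadratic integrate-and-fire phase model,
    dtheta/dt = -cos(theta)/tau + 2*I*(1 + cos(theta)), equivalent to
    dv/dt = -v(1-v)/tau + I with v = (1 + tan(theta/2))/2.  Firing means
    theta reaches pi (v reaches +infinity).  Integration is always carried
    out in theta, so the voltage blow-up at firing is benign.
``wb``
    Wang-Buzsaki fast-spiking interneuron (classical Hodgkin-Huxley
    currents: transient sodium, delayed-rectifier potassium, leak;
    instantaneous sodium activation, temperature factor 5 on h and n).
``rtm``
    Reduced Traub-Miles pyramidal cell (same current types, its own
    kinetics).

All models are integrated with fixed-step classical RK4 (default
dt = 0.01 ms); spike times are localized by linear interpolation between
the bracketing grid samples.  Instantaneous charge injections are applied
as grid-aligned jumps of the membrane potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
from scipy import optimize

from . import _kernels
from .stimuli import (
    AlphaPulse,
    ConstantDrive,
    DeltaTrain,
    RampDrive,
    StimulusSpec,
    SynapticTrain,
)

__all__ = [
    "LIFParams",
    "ThetaParams",
    "HHParams",
    "ModelSpec",
    "Trace",
    "IntegrationError",
    "simulate_lif",
    "simulate_theta",
    "simulate_hh",
    "simulate",
    "resting_state",
    "theta_fixed_points",
    "theta_to_v",
    "v_to_theta",
    "model_kind",
]

DEFAULT_DT = 0.01  # ms


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass(frozen=True)
class LIFParams:
    """Normalized leaky integrate-and-fire neuron.

    The threshold and reset are fixed at 1 and 0; only the membrane time
    constant ``tau`` (ms) is free.
    """

    tau: float
    v_threshold: float = 1.0
    v_reset: float = 0.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.v_threshold != 1.0 or self.v_reset != 0.0:
            raise ValueError("the LIF normalization fixes threshold = 1, reset = 0")


@dataclass(frozen=True)
class ThetaParams:
    """Theta (QIF) neuron with membrane time constant ``tau`` (ms)."""

    tau: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class HHParams:
    """Conductance-based single-compartment neuron (``wb`` or ``rtm``).

    Maximal conductances in mS/cm^2, reversal potentials in mV, membrane
    capacitance 1 muF/cm^2.  ``phi`` is the temperature-like factor on the
    h and n kinetics.  ``spike_detection_level`` is the membrane potential
    whose upward crossing defines the spike time (0 mV).
    """

    model_id: str
    g_na: float
    g_k: float
    g_l: float
    v_na: float
    v_k: float
    v_l: float
    phi: float
    spike_detection_level: float = 0.0

    def __post_init__(self) -> None:
        if self.model_id not in ("wb", "rtm"):
            raise ValueError("model_id must be 'wb' or 'rtm'")
        for g in (self.g_na, self.g_k, self.g_l):
            if g < 0:
                raise ValueError("maximal conductances must be nonnegative")
        if not (self.v_k < self.spike_detection_level < self.v_na):
            raise ValueError("spike detection level must lie between trough and peak")

    @classmethod
    def wb(cls, spike_detection_level: float = 0.0) -> "HHParams":
        """Wang-Buzsaki fast-spiking interneuron."""
        return cls("wb", 35.0, 9.0, 0.1, 55.0, -90.0, -65.0, 5.0, spike_detection_level)

    @classmethod
    def rtm(cls, spike_detection_level: float = 0.0) -> "HHParams":
        """Reduced Traub-Miles pyramidal cell."""
        return cls("rtm", 100.0, 80.0, 0.1, 50.0, -100.0, -67.0, 1.0, spike_detection_level)

    @property
    def _int_id(self) -> int:
        return 0 if self.model_id == "wb" else 1

    @property
    def dynamic_m(self) -> bool:
        """RTM integrates sodium activation m; WB uses m = m_inf(v)."""
        return self.model_id == "rtm"

    @property
    def state_names(self) -> Tuple[str, ...]:
        return ("v", "m", "h", "n") if self.dynamic_m else ("v", "h", "n")


ModelSpec = Union[LIFParams, ThetaParams, HHParams]


def model_kind(model: ModelSpec) -> str:
    """'lif', 'theta', 'wb' or 'rtm'."""
    if isinstance(model, LIFParams):
        return "lif"
    if isinstance(model, ThetaParams):
        return "theta"
    if isinstance(model, HHParams):
        return model.model_id
    raise TypeError(f"not a model spec: {model!r}")


@dataclass
class Trace:
    """Time grid, state trajectory and detected spike times of one run."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_state)
    state_names: Tuple[str, ...]
    spike_times: np.ndarray
    blew_up: bool = False

    @property
    def v(self) -> np.ndarray:
        """Membrane potential trajectory."""
        return self.states[:, self.state_names.index("v")]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]

    def to_frame(self):
        """Tidy DataFrame with a time_ms column plus one column per state."""
        import pandas as pd

        data = {"time_ms": self.times}
        for i, name in enumerate(self.state_names):
            data[name] = self.states[:, i]
        return pd.DataFrame(data)

    def export_csv(self, path, spikes_path=None) -> None:
        """Write the trajectory (and optionally spike times) as CSV."""
        self.to_frame().to_csv(path, index=False)
        if spikes_path is not None:
            import pandas as pd

            pd.DataFrame({"spike_time_ms": self.spike_times}).to_csv(spikes_path, index=False)


def theta_to_v(theta) -> np.ndarray:
    """Voltage v = (1 + tan(theta/2))/2 (diverges as theta -> +-pi)."""
    theta = np.asarray(theta, dtype=float)
    with np.errstate(over="ignore"):
        out = 0.5 * (1.0 + np.tan(0.5 * theta))
    return out if out.ndim else float(out)


def v_to_theta(v) -> np.ndarray:
    """Phase theta = 2*arctan(2v - 1) in (-pi, pi)."""
    v = np.asarray(v, dtype=float)
    out = 2.0 * np.arctan(2.0 * v - 1.0)
    return out if out.ndim else float(out)


_EMPTY_JUMPS = (np.empty(0, dtype=np.int64), np.empty(0))


def _compile_drive(drive: Optional[StimulusSpec], kind: str, n_steps: int, dt: float):
    """Sample a stimulus onto the RK4 half-step grid.

    Returns (I_half, G_half, v_rev, jump_steps, jump_sizes).  Delta-train
    arrivals are snapped to the nearest grid point (sweep code chooses dt
    commensurate with the inter-pulse interval, so the snap is exact there).
    """
    n_half = 2 * n_steps + 1
    I_half = np.zeros(n_half)
    G_half = np.zeros(n_half)
    vrev = 0.0
    jump_steps, jump_w = _EMPTY_JUMPS
    if drive is None:
        return I_half, G_half, vrev, jump_steps, jump_w
    t_half = 0.5 * dt * np.arange(n_half)
    if isinstance(drive, (AlphaPulse, ConstantDrive, RampDrive)):
        I_half = np.asarray(drive.value(t_half), dtype=float)
    elif isinstance(drive, DeltaTrain):
        arrivals = drive.arrival_times(n_steps * dt)
        jump_steps = np.round(arrivals / dt).astype(np.int64)
        jump_steps = jump_steps[jump_steps <= n_steps]
        jump_w = np.full(jump_steps.size, drive.w)
    elif isinstance(drive, SynapticTrain):
        G_half = drive.gbar * np.asarray(drive.gating(t_half), dtype=float)
        vrev = drive.resolve_v_rev(kind)
    else:
        raise TypeError(f"unsupported stimulus: {drive!r}")
    return I_half, G_half, vrev, jump_steps, jump_w


def _n_steps(t_end: float, dt: float) -> int:
    if not dt > 0:
        raise ValueError("dt must be positive")
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    return max(1, int(round(t_end / dt)))


def simulate_lif(
    params: LIFParams,
    drive: Optional[StimulusSpec],
    t_end: float,
    dt: float = DEFAULT_DT,
    v0: float = 0.0,
    reset: bool = True,
) -> Trace:
    """Integrate the LIF neuron under ``drive`` on [0, t_end].

    With ``reset=False`` the trajectory is allowed to continue through the
    threshold (used to evaluate the peak response); upward crossings of 1
    are still recorded as spike times.
    """
    if v0 >= 1.0:
        raise ValueError("v0 must be below threshold")
    n = _n_steps(t_end, dt)
    I_half, G_half, vrev, js, jw = _compile_drive(drive, "lif", n, dt)
    v_out, spikes, nsp, err_t = _kernels.lif_rk4(v0, params.tau, dt, n, I_half, G_half, vrev, js, jw, reset)
    if err_t >= 0:
        raise IntegrationError(f"LIF state became non-finite at t = {err_t:.6g} ms")
    times = dt * np.arange(n + 1)
    return Trace(times, v_out[:, None], ("v",), spikes.copy())


def simulate_theta(
    params: ThetaParams,
    drive: Optional[StimulusSpec],
    t_end: float,
    dt: float = DEFAULT_DT,
    theta0: Optional[float] = None,
    v0: Optional[float] = None,
) -> Trace:
    """Integrate the theta neuron in phase coordinates on [0, t_end].

    The initial condition may be given as ``theta0`` in (-pi, pi) or as a
    voltage ``v0`` (default v = 0, the resting state under zero drive).
    Each upward crossing of pi is a spike; the phase continues through it
    (equivalently, v blows up to +infinity and resets from -infinity).
    """
    if theta0 is not None and v0 is not None:
        raise ValueError("give either theta0 or v0, not both")
    if theta0 is None:
        theta0 = float(v_to_theta(0.0 if v0 is None else v0))
    if not (-math.pi < theta0 < math.pi):
        raise ValueError("theta0 must lie in (-pi, pi)")
    n = _n_steps(t_end, dt)
    I_half, G_half, vrev, js, jw = _compile_drive(drive, "theta", n, dt)
    th_out, spikes, nsp, err_t = _kernels.theta_rk4(theta0, params.tau, dt, n, I_half, G_half, vrev, js, jw)
    if err_t >= 0:
        raise IntegrationError(f"theta state became non-finite at t = {err_t:.6g} ms")
    # wrap into (-pi, pi] for reporting; v is reconstructed from the phase
    wrapped = th_out - 2.0 * math.pi * np.floor((th_out + math.pi) / (2.0 * math.pi))
    wrapped = np.where(wrapped <= -math.pi, wrapped + 2.0 * math.pi, wrapped)
    v = theta_to_v(wrapped)
    times = dt * np.arange(n + 1)
    states = np.column_stack([wrapped, v])
    return Trace(times, states, ("theta", "v"), spikes.copy(), blew_up=nsp > 0)


def simulate_hh(
    params: HHParams,
    drive: Optional[StimulusSpec],
    t_end: float,
    dt: float = DEFAULT_DT,
    init: Optional[np.ndarray] = None,
) -> Trace:
    """Integrate a WB or RTM neuron on [0, t_end].

    ``init`` is a full state -- (v, h, n) for WB, (v, m, h, n) for RTM --
    by default the zero-drive resting state.  Current drives add to dv/dt
    directly; conductance drives enter as g*s(t)*(v_rev - v).
    """
    if init is None:
        init = resting_state(params)
    init = [float(x) for x in init]
    if len(init) != len(params.state_names):
        raise ValueError(f"{params.model_id} init must be {params.state_names}")
    if params.dynamic_m:
        v0, m0, h0, n0 = init
    else:
        v0, h0, n0 = init
        m0 = 0.0  # unused: m is instantaneous for WB
    n = _n_steps(t_end, dt)
    I_half, G_half, vrev, js, jw = _compile_drive(drive, params.model_id, n, dt)
    v_out, m_out, h_out, n_out, spikes, nsp, err_t = _kernels.hh_rk4(
        v0,
        m0,
        h0,
        n0,
        params._int_id,
        1 if params.dynamic_m else 0,
        params.g_na,
        params.g_k,
        params.g_l,
        params.v_na,
        params.v_k,
        params.v_l,
        params.phi,
        params.spike_detection_level,
        dt,
        n,
        I_half,
        G_half,
        vrev,
        js,
        jw,
    )
    if err_t >= 0:
        raise IntegrationError(f"{params.model_id} state became non-finite at t = {err_t:.6g} ms")
    times = dt * np.arange(n + 1)
    if params.dynamic_m:
        states = np.column_stack([v_out, m_out, h_out, n_out])
    else:
        states = np.column_stack([v_out, h_out, n_out])
    return Trace(times, states, params.state_names, spikes.copy())


def simulate(model: ModelSpec, drive, t_end, dt: float = DEFAULT_DT, **kw) -> Trace:
    """Dispatch to the model-appropriate simulator."""
    kind = model_kind(model)
    if kind == "lif":
        return simulate_lif(model, drive, t_end, dt, **kw)
    if kind == "theta":
        return simulate_theta(model, drive, t_end, dt, **kw)
    return simulate_hh(model, drive, t_end, dt, **kw)


def _hh_deriv_py(state: np.ndarray, params: HHParams) -> np.ndarray:
    if params.dynamic_m:
        v, m, h, n = state
    else:
        v, h, n = state
        m = 0.0
    dv, dm, dh, dn = _kernels.hh_deriv(
        v, m, h, n, 0.0, 0.0, 0.0,
        params.g_na, params.g_k, params.g_l, params.v_na, params.v_k, params.v_l,
        params.phi, params._int_id, 1 if params.dynamic_m else 0,
    )
    if params.dynamic_m:
        return np.array([dv, dm, dh, dn])
    return np.array([dv, dh, dn])


def resting_state(params: HHParams, tol: float = 1e-10) -> np.ndarray:
    """Zero-drive equilibrium state, by relaxation then root polishing.

    Returns (v, h, n) for WB or (v, m, h, n) for RTM.  The returned state
    has all time derivatives below ``tol`` in magnitude and a subthreshold
    membrane potential.
    """
    # gate steady states at an initial guess voltage
    v = -65.0
    am, bm, ah, bh, an, bn = _kernels.hh_rates(v, params._int_id)
    state = [v, ah / (ah + bh), an / (an + bn)]
    if params.dynamic_m:
        state.insert(1, am / (am + bm))
    tr = simulate_hh(params, None, t_end=200.0, dt=0.05, init=np.array(state))
    state = tr.states[-1]
    sol = optimize.root(_hh_deriv_py, state, args=(params,), tol=1e-13)
    state = sol.x
    resid = np.abs(_hh_deriv_py(state, params))
    if not sol.success or resid.max() >= tol:
        raise RuntimeError(f"resting-state search failed to converge (residual {resid.max():.3g})")
    if state[0] >= params.spike_detection_level:
        raise RuntimeError("resting state is not subthreshold")
    return state


def theta_fixed_points(params: ThetaParams, I: float) -> Optional[Tuple[float, float]]:
    """Voltage fixed points v_-, v_+ = 1/2 -+ sqrt(1/4 - tau*I) of the QIF.

    Returns the (stable, unstable) pair when tau*I < 1/4, the degenerate
    saddle-node pair (1/2, 1/2) at tau*I = 1/4, and None beyond the
    bifurcation (tau*I > 1/4, no fixed points -> periodic firing).
    """
    if I < 0:
        raise ValueError("I must be nonnegative")
    disc = 0.25 - params.tau * I
    if disc < 0:
        return None
    root = math.sqrt(disc)
    return (0.5 - root, 0.5 + root)
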