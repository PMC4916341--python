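"""Input families used to drive the target neurons.

This module is the package's synthetic-data generator: every experiment in
the library is driven by one of the parameterized stimulus families defined
here.  There is no external data anywhere.

The central family is the "alpha" current pulse

    I(t) = r t e^{-t},        I_eps(t) = (1/eps) I(t/eps),

whose compression factor ``eps`` shrinks the pulse duration while holding
the total injected charge q = r fixed.  Smaller ``eps`` models a more
tightly synchronized presynaptic volley; the limit ``eps -> 0`` is an
instantaneous charge injection q*delta(t).  Discrete analogues are the
delta train (instantaneous voltage jumps of size w every Delta ms) and the
synaptic train (unit jumps of a gating variable s decaying with a 3 ms
AMPA-like time constant, driving a conductance g*s*(v_rev - v)).  Constant
and linearly rising drives round out the set; they appear in the
closed-form analyses of :mod:`volley.analytic`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np

__all__ = [
    "AlphaPulse",
    "DeltaTrain",
    "SynapticTrain",
    "ConstantDrive",
    "RampDrive",
    "StimulusSpec",
    "pulse_value",
    "total_charge",
    "gating_series",
    "stimulus_to_dict",
    "stimulus_from_dict",
]


@dataclass(frozen=True)
class AlphaPulse:
    """Charge-conserving compressible current pulse I_eps(t) = (r/eps^2) t e^{-t/eps}.

    Parameters
    ----------
    r:
        Pulse amplitude; also the total injected charge q (1/ms scale for
        the normalized LIF/theta models, muA/cm^2 scale for the
        conductance-based models).
    epsilon:
        Compression factor (> 0).  The pulse is significant for
        t <~ epsilon and negligible for t >> epsilon.
    """

    r: float
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"pulse amplitude r must be positive, got {self.r}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")

    def value(self, t):
        """Drive value I_eps(t); zero for t < 0."""
        t = np.asarray(t, dtype=float)
        tp = np.clip(t, 0.0, None)
        out = (self.r / self.epsilon**2) * tp * np.exp(-tp / self.epsilon)
        return out if out.ndim else float(out)

    @property
    def total_charge(self) -> float:
        """q = integral of I_eps over [0, inf) = r, independent of epsilon."""
        return self.r

    def delivered_fraction(self, t: float) -> float:
        """Fraction of the total charge that has arrived by time t."""
        if t <= 0:
            return 0.0
        x = t / self.epsilon
        return 1.0 - (1.0 + x) * math.exp(-x)

    def compressed(self, epsilon: float) -> "AlphaPulse":
        """The same pulse shape at a different compression factor."""
        return replace(self, epsilon=epsilon)


@dataclass(frozen=True)
class DeltaTrain:
    """Periodic instantaneous charge injections w * sum_k delta(t - k*Delta).

    Each arrival kicks the membrane potential up by ``w`` (dimensionless for
    LIF/theta, mV for the conductance-based models).  The first pulse
    arrives at t = Delta.
    """

    w: float
    delta: float
    n_pulses: Optional[int] = None  # None = unbounded

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError(f"jump size w must be positive, got {self.w}")
        if not self.delta > 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.n_pulses is not None and self.n_pulses < 0:
            raise ValueError("n_pulses must be nonnegative")

    def arrival_times(self, t_end: float) -> np.ndarray:
        """Arrival times k*Delta in [0, t_end]."""
        k_max = int(math.floor(t_end / self.delta + 1e-9))
        if self.n_pulses is not None:
            k_max = min(k_max, self.n_pulses)
        return self.delta * np.arange(1, k_max + 1)


@dataclass(frozen=True)
class SynapticTrain:
    """Periodic excitatory synaptic pulses g*s(t)*(v_rev - v).

    The gating variable s jumps by +1 at each arrival time k*Delta
    (k = 1, 2, ...) and decays exponentially in between with time constant
    ``tau_decay`` (3 ms by default, AMPA-like).  ``s`` is the pooled gating
    of many weak synapses and is not bounded by 1.

    ``v_rev`` defaults to None, meaning "model appropriate": 5 for the
    normalized LIF/theta models (threshold 1 plus four times the
    threshold-reset distance) and 0 mV for the conductance-based models.
    """

    gbar: float
    delta: float
    tau_decay: float = 3.0
    v_rev: Optional[float] = None
    n_pulses: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.gbar > 0:
            raise ValueError(f"gbar must be positive, got {self.gbar}")
        if not self.delta > 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if not self.tau_decay > 0:
            raise ValueError("tau_decay must be positive")

    def resolve_v_rev(self, model_kind: str) -> float:
        if self.v_rev is not None:
            return self.v_rev
        return 5.0 if model_kind in ("lif", "theta") else 0.0

    def gating(self, t) -> np.ndarray:
        """Closed-form gating variable s(t) (right-continuous at arrivals).

        s(t) = sum_{k=1}^{K(t)} exp(-(t - k*Delta)/tau_decay) with
        K(t) = floor(t/Delta) capped at n_pulses, evaluated as a geometric
        sum so that the inter-arrival decay is exact rather than stepped.
        """
        t = np.asarray(t, dtype=float)
        x = t / self.delta
        K = np.floor(x + 1e-9)
        if self.n_pulses is not None:
            K = np.minimum(K, float(self.n_pulses))
        K = np.clip(K, 0.0, None)
        a = math.exp(self.delta / self.tau_decay)
        # sum = a * (exp(-(t - K*Delta)/tau) - exp(-t/tau)) / (a - 1), overflow-safe
        last = np.exp(-(t - K * self.delta) / self.tau_decay)
        first = np.exp(-np.clip(t, 0.0, None) / self.tau_decay)
        with np.errstate(over="ignore"):
            s = a * (last - first) / (a - 1.0)
        s = np.where(K > 0, s, 0.0)
        return s if s.ndim else float(s)

    def arrival_times(self, t_end: float) -> np.ndarray:
        k_max = int(math.floor(t_end / self.delta + 1e-9))
        if self.n_pulses is not None:
            k_max = min(k_max, self.n_pulses)
        return self.delta * np.arange(1, k_max + 1)

    def truncated(self, n_pulses: int) -> "SynapticTrain":
        """The same train cut off after exactly ``n_pulses`` arrivals."""
        return replace(self, n_pulses=n_pulses)


@dataclass(frozen=True)
class ConstantDrive:
    """Constant current; ``amplitude`` plays the role 1/Delta in the
    constant-drive idealization of a rapid input volley."""

    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")

    def value(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.amplitude)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class RampDrive:
    """Linearly rising current (c/Delta) * t.

    Models the early build-up of synaptic drive when the inter-pulse
    interval Delta is much shorter than the synaptic decay time constant.
    """

    c: float
    delta: float

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError("c must be positive")
        if not self.delta > 0:
            raise ValueError("delta must be positive")

    def value(self, t):
        t = np.asarray(t, dtype=float)
        out = (self.c / self.delta) * np.clip(t, 0.0, None)
        return out if out.ndim else float(out)


StimulusSpec = Union[AlphaPulse, DeltaTrain, SynapticTrain, ConstantDrive, RampDrive]


def pulse_value(p: AlphaPulse, t) -> float:
    """Value of the compressed pulse I_eps at time t (module-level alias)."""
    return p.value(t)


def total_charge(p: AlphaPulse) -> float:
    """Total injected charge q of an alpha pulse (= r for every epsilon)."""
    return p.total_charge


def gating_series(tr: SynapticTrain, t_grid) -> np.ndarray:
    """Gating variable s evaluated on a time grid by piecewise closed form."""
    return np.asarray(tr.gating(np.asarray(t_grid, dtype=float)))


_FAMILIES = {
    "alpha": AlphaPulse,
    "delta_train": DeltaTrain,
    "synaptic_train": SynapticTrain,
    "constant": ConstantDrive,
    "ramp": RampDrive,
}
_FAMILY_NAMES = {v: k for k, v in _FAMILIES.items()}


def stimulus_to_dict(stim: StimulusSpec) -> dict:
    """Serialize a stimulus to a plain dict {family: ..., params...}."""
    d = {"family": _FAMILY_NAMES[type(stim)]}
    for k, v in stim.__dict__.items():
        if v is not None:
            d[k] = v
    return d


def stimulus_from_dict(d: dict) -> StimulusSpec:
    """Inverse of :func:`stimulus_to_dict`."""
    d = dict(d)
    family = d.pop("family")
    try:
        cls = _FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown stimulus family {family!r}") from None
    return cls(**d)
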