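"""Closed forms for the exactly solvable drive problems.

These serve as independent oracles for the simulators and sweep code:

* constant drive 1/Delta into a LIF neuron: firing time and the
  charge-to-threshold function phi(s) = s*ln(s/(s-1));
* periodic instantaneous charge injections into a LIF neuron: fire/no-fire
  condition and pulse count via the geometric jump-decay map;
* the time for the QIF voltage to blow up from a suprathreshold start;
* the linearly rising drive (c/Delta)*t into a LIF neuron: threshold
  time, pulse count, and its Delta^(-1/2) small-Delta asymptote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Union

from scipy import optimize

__all__ = [
    "lif_constant_drive_time",
    "charge_phi",
    "DeltaTrainPrediction",
    "delta_train_predict",
    "theta_blowup_time",
    "RampFiringResult",
    "ramp_firing",
]


def lif_constant_drive_time(tau: float, delta: float) -> float:
    """Firing time of a LIF neuron under constant drive 1/Delta.

    T = tau * ln( (tau/Delta) / (tau/Delta - 1) ).  An action potential
    occurs if and only if Delta < tau; otherwise math.inf is returned
    (the drive saturates below threshold).
    """
    if not (tau > 0 and delta > 0):
        raise ValueError("tau and delta must be positive")
    s = tau / delta
    if s <= 1.0:
        return math.inf
    return tau * math.log(s / (s - 1.0))


def charge_phi(s: float) -> float:
    """Charge needed to reach threshold under constant drive: phi(s) = s*ln(s/(s-1)).

    Here s = tau/Delta.  phi is strictly decreasing on (1, inf) with
    phi -> inf as s -> 1+ and phi -> 1 as s -> inf, so the total charge to
    threshold falls monotonically as the drive becomes more concentrated.
    """
    if not s > 1.0:
        raise ValueError("phi(s) requires s > 1")
    # s*ln(s/(s-1)) = -s*log1p(-1/s), stable for large s
    return -s * math.log1p(-1.0 / s)


class DeltaTrainPrediction(NamedTuple):
    fires: bool
    n_pulses: Union[int, float]  # math.inf when the train never reaches threshold


def delta_train_predict(tau: float, w: float, delta: float) -> DeltaTrainPrediction:
    """Outcome of the periodic jump train w*sum_k delta(t - k*Delta) on a LIF neuron.

    Between arrivals the voltage decays by rho = exp(-Delta/tau); just
    after the n-th arrival it equals w*(1 - rho^n)/(1 - rho), which
    increases to the limit w/(1 - rho).  The threshold 1 is therefore
    reached if and only if w > 1 - rho (strict), and the pulse count is
    the smallest n with w*(1 - rho^n)/(1 - rho) >= 1.  The count from the
    closed form is polished against the exact jump-decay map to absorb
    floating-point rounding at the boundary.
    """
    if not (0 < w):
        raise ValueError("w must be positive")
    if not (tau > 0 and delta > 0):
        raise ValueError("tau and delta must be positive")
    rho = math.exp(-delta / tau)
    if w >= 1.0:
        return DeltaTrainPrediction(True, 1)
    if not w > 1.0 - rho:
        return DeltaTrainPrediction(False, math.inf)
    # rho^n <= 1 - (1 - rho)/w
    n = max(1, math.ceil(math.log1p(-(1.0 - rho) / w) / math.log(rho)))
    while w * (1.0 - rho ** n) / (1.0 - rho) < 1.0:
        n += 1
    while n > 1 and w * (1.0 - rho ** (n - 1)) / (1.0 - rho) >= 1.0:
        n -= 1
    return DeltaTrainPrediction(True, n)


def theta_blowup_time(tau: float, q: float) -> float:
    """Time for the QIF voltage to run from v = q > 1 to +infinity, zero drive.

    Separation of variables on dv/dt = -v(1-v)/tau gives
    t = tau * ln(q/(q-1)).  For q <= 1 the voltage never blows up and
    math.inf is returned.
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    if q <= 1.0:
        return math.inf
    return tau * math.log(q / (q - 1.0))


@dataclass(frozen=True)
class RampFiringResult:
    """Threshold crossing of a LIF neuron under the ramp drive (c/Delta)*t."""

    T_tilde: float  # ms, time at which v reaches 1
    M_tilde: float  # T_tilde / Delta, pulses arriving before threshold
    asymptotic_M: float  # sqrt(2/(c*Delta)), the small-Delta limit of M_tilde


def ramp_firing(tau: float, c: float, delta: float) -> RampFiringResult:
    """Solve for the threshold time under dv/dt = -v/tau + (c/Delta)*t.

    The solution v(t) = (c/Delta)*tau*(t - tau) + (c/Delta)*tau^2*e^{-t/tau}
    reaches 1 when  e^{-T/tau} - (1 - T/tau) = Delta/(c*tau^2);  the left
    side is strictly increasing from 0, so the root is found by bracketed
    bisection (bracket grown from the small-Delta approximation
    T ~ sqrt(2*Delta/c)) and polished by Newton iteration to residual
    below 1e-12.
    """
    if not (tau > 0 and c > 0 and delta > 0):
        raise ValueError("tau, c and delta must be positive")
    rhs = delta / (c * tau * tau)

    def g(x: float) -> float:  # x = T/tau
        return math.exp(-x) - 1.0 + x - rhs

    x_lo = 0.0
    x_hi = max(math.sqrt(2.0 * delta / c) / tau * 10.0, 1.0)
    while g(x_hi) < 0.0:
        x_hi *= 2.0
    x = optimize.brentq(g, x_lo, x_hi, xtol=1e-15, rtol=8.9e-16)
    for _ in range(4):  # Newton polish; g'(x) = 1 - e^{-x} > 0
        gp = 1.0 - math.exp(-x)
        if gp <= 0.0:
            break
        x -= g(x) / gp
    T = x * tau
    return RampFiringResult(T, T / delta, math.sqrt(2.0 / (c * delta)))
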