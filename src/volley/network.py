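"""All-to-all PING network: RTM E-cells driving WB I-cells.

The network that motivates the single-neuron analysis: 200 reduced
Traub-Miles pyramidal cells (E) and 50 Wang-Buzsaki interneurons (I) with
all-to-all synaptic connectivity and no gap junctions.  The E-cells
receive a linearly graded tonic drive (1.5 + j/200 muA/cm^2 for the j-th
E-cell); the I-cells receive none and fire only in response to the
E-volleys.  The E-I loop generates a gamma-band (30-80 Hz) PING rhythm
whose period is set by the 9 ms decay of inhibition.  Adding tonic
inhibition 0.2*(-67 - v) to the E-cells slows the rhythm, loosens E-cell
synchrony and reduces the number of participating E-cells.

Each cell carries one synaptic gating variable s with

    ds/dt = ((1 + tanh(v/10))/2) * (1 - s)/tau_rise - s/tau_decay,

and the postsynaptic current is g_syn * s_pre * (v_rev - v); per-synapse
conductances are the stated population totals divided by the presynaptic
population size.  There is no stochastic element anywhere: runs are
bit-reproducible at fixed dt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .models import HHParams, IntegrationError, resting_state

__all__ = [
    "NetworkConfig",
    "SpikeRaster",
    "RhythmMetrics",
    "baseline_config",
    "tonic_config",
    "simulate_network",
    "rhythm_metrics",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the E-I network.

    Conductances are densities in mS/cm^2; ``g_*_total`` are population
    totals (per-synapse value = total / presynaptic count).  ``g_tonic``
    adds the term g_tonic*(v_tonic - v) to every E-cell.
    """

    n_e: int = 200
    n_i: int = 50
    drive_i: float = 0.0
    g_ei_total: float = 0.4
    g_ie_total: float = 1.0
    g_ii_total: float = 0.6
    g_ee_total: float = 0.0
    v_rev_e: float = 0.0
    v_rev_i: float = -67.0
    tau_rise_e: float = 0.1
    tau_decay_e: float = 3.0
    tau_rise_i: float = 0.3
    tau_decay_i: float = 9.0
    g_tonic: float = 0.0
    v_tonic: float = -67.0
    t_end: float = 650.0
    dt: float = 0.01
    transient_discard: float = 150.0
    detection_level: float = 0.0

    def __post_init__(self) -> None:
        for g in (self.g_ei_total, self.g_ie_total, self.g_ii_total, self.g_ee_total, self.g_tonic):
            if g < 0:
                raise ValueError("conductances must be nonnegative")

    def drive_e(self) -> np.ndarray:
        """Graded E-cell drives 1.5 + j/n_e, j = 1..n_e (muA/cm^2)."""
        j = np.arange(1, self.n_e + 1)
        return 1.5 + j / self.n_e


def baseline_config(**overrides) -> NetworkConfig:
    """The network without tonic inhibition of the E-cells."""
    return NetworkConfig(**overrides)


def tonic_config(g_tonic: float = 0.2, **overrides) -> NetworkConfig:
    """The network with tonic inhibition g_tonic*(-67 - v) on the E-cells."""
    return NetworkConfig(g_tonic=g_tonic, **overrides)


@dataclass
class SpikeRaster:
    """Network spikes: I-cells are labeled 1..n_i, E-cells n_i+1..n_i+n_e."""

    cell_ids: np.ndarray
    spike_times: np.ndarray
    config: NetworkConfig

    def e_spikes(self) -> pd.DataFrame:
        """E-cell spikes only, with cell ids re-based to 1..n_e."""
        mask = self.cell_ids > self.config.n_i
        return pd.DataFrame(
            {
                "e_index": self.cell_ids[mask] - self.config.n_i,
                "spike_time_ms": self.spike_times[mask],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "spike_time_ms": self.spike_times})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class RhythmMetrics:
    """Steady-state description of the population rhythm."""

    participation: int  # distinct E-cells firing per volley (rounded mean)
    participation_mean: float
    participation_std: float
    frequency_hz: float
    volley_duration_k: Optional[float]  # ms, first to k-th distinct E-cell
    k: int
    n_volleys_used: int

    def to_dict(self) -> dict:
        return {
            "participation": self.participation,
            "participation_mean": self.participation_mean,
            "participation_std": self.participation_std,
            "frequency_hz": self.frequency_hz,
            "volley_duration_k": self.volley_duration_k,
            "k": self.k,
            "n_volleys_used": self.n_volleys_used,
        }


def simulate_network(cfg: NetworkConfig) -> SpikeRaster:
    """Integrate the network from the zero-input resting state.

    All cells start at their respective zero-drive equilibria with zero
    synaptic gating; the graded drive desynchronizes the E-cells, after
    which the E-I loop settles into the PING rhythm.  Only spike times are
    recorded (upward crossings of the detection level, interpolated).
    """
    n_e, n_i = cfg.n_e, cfg.n_i
    rest_e = resting_state(HHParams.rtm())  # (v, m, h, n)
    rest_i = resting_state(HHParams.wb())  # (v, h, n)
    y0 = np.empty(5 * n_e + 4 * n_i)
    for b in range(4):
        y0[b * n_e : (b + 1) * n_e] = rest_e[b]
    y0[4 * n_e : 5 * n_e] = 0.0
    oI = 5 * n_e
    y0[oI : oI + n_i] = rest_i[0]
    y0[oI + n_i : oI + 2 * n_i] = rest_i[1]
    y0[oI + 2 * n_i : oI + 3 * n_i] = rest_i[2]
    y0[oI + 3 * n_i :] = 0.0
    n_steps = int(round(cfg.t_end / cfg.dt))
    cells, times, nsp, err_t, err_c = _kernels.ping_rk4(
        y0,
        n_e,
        n_i,
        cfg.drive_e().astype(float),
        cfg.dt,
        n_steps,
        cfg.g_ee_total / n_e,
        cfg.g_ie_total / n_i,
        cfg.g_ei_total / n_e,
        cfg.g_ii_total / n_i,
        cfg.v_rev_e,
        cfg.v_rev_i,
        cfg.g_tonic,
        cfg.v_tonic,
        cfg.tau_rise_e,
        cfg.tau_decay_e,
        cfg.tau_rise_i,
        cfg.tau_decay_i,
        cfg.detection_level,
    )
    if err_t >= 0:
        label = err_c + n_i + 1 if err_c < n_e else err_c - n_e + 1
        kind = "E" if err_c < n_e else "I"
        raise IntegrationError(
            f"network state became non-finite at t = {err_t:.6g} ms ({kind}-cell, raster id {label})"
        )
    # kernel labels: E-cells 0..n_e-1, I-cells n_e..; raster labels I first
    raster_ids = np.where(cells < n_e, cells + n_i + 1, cells - n_e + 1)
    order = np.lexsort((times, raster_ids))
    return SpikeRaster(raster_ids[order].astype(int), times[order], cfg)


def _segment_volleys(times: np.ndarray, thr_init: float = 5.0, max_iter: int = 30):
    """Split a pooled, sorted spike train into volleys by gap thresholding.

    Spikes separated by more than the threshold start a new volley.  The
    threshold is iterated to half the median silent gap between volleys
    (last spike of one to first spike of the next) until the segmentation
    stabilizes; this keeps the threshold well below the volley period even
    when volleys have long straggler tails.
    """
    thr = thr_init
    bounds = np.concatenate([[0], np.flatnonzero(np.diff(times) > thr) + 1, [times.size]])
    for _ in range(max_iter):
        starts = times[bounds[:-1]]
        ends = times[bounds[1:] - 1]
        if starts.size < 3:
            break
        silent = starts[1:] - ends[:-1]
        thr = 0.5 * float(np.median(silent))
        bounds_new = np.concatenate([[0], np.flatnonzero(np.diff(times) > thr) + 1, [times.size]])
        if bounds_new.size == bounds.size and np.all(bounds_new == bounds):
            break
        bounds = bounds_new
    return [slice(bounds[i], bounds[i + 1]) for i in range(bounds.size - 1)]


def rhythm_metrics(raster: SpikeRaster, cfg: Optional[NetworkConfig] = None, k: int = 100) -> RhythmMetrics:
    """Participation, rhythm frequency and volley duration from a raster.

    E-cell spikes after the transient are pooled and segmented into
    volleys; volleys touching the analysis-window edges are dropped.
    Participation is the number of distinct E-cells per volley (mean over
    volleys, rounded); frequency is the reciprocal mean inter-volley
    interval; the volley duration is the mean time from the first to the
    k-th distinct E-cell's first spike within a volley (defined only when
    participation reaches k).
    """
    if cfg is None:
        cfg = raster.config
    e = raster.e_spikes()
    e = e[e.spike_time_ms >= cfg.transient_discard]
    if len(e) == 0:
        raise ValueError("no rhythm detected: no E spikes after the transient")
    e = e.sort_values("spike_time_ms")
    times = e.spike_time_ms.to_numpy()
    cells = e.e_index.to_numpy()
    volleys = _segment_volleys(times)
    # drop volleys that may be truncated by the window edges
    if len(volleys) >= 2:
        volleys = volleys[1:-1]
    if len(volleys) < 3:
        raise ValueError("no rhythm detected: fewer than 3 complete volleys")
    parts = []
    centers = []
    durations = []
    for sl in volleys:
        vt = times[sl]
        vc = cells[sl]
        first = pd.Series(vt).groupby(vc).min().sort_values()
        parts.append(first.size)
        centers.append(float(vt.mean()))
        if first.size >= k:
            durations.append(float(first.iloc[k - 1] - first.iloc[0]))
    parts_arr = np.array(parts, dtype=float)
    ivi = np.diff(np.array(centers))
    return RhythmMetrics(
        participation=int(round(parts_arr.mean())),
        participation_mean=float(parts_arr.mean()),
        participation_std=float(parts_arr.std()),
        frequency_hz=1000.0 / float(ivi.mean()),
        volley_duration_k=float(np.mean(durations)) if durations else None,
        k=k,
        n_volleys_used=len(volleys),
    )
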