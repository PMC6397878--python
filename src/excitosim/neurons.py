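"""Izhikevich membrane dynamics: stepping, spike detection/reset.

The voltage update uses the two-half-step scheme of Izhikevich's reference
implementation (v advanced in two half-steps of the quadratic drift, then u
advanced with the updated v), with the reset applied after the update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .config import IzhikevichParams


@dataclass
class MembraneState:
    """Membrane potential, recovery variable and current-step spike flags."""

    v: np.ndarray
    u: np.ndarray
    spiked: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float))
        if self.v.shape != self.u.shape:
            raise ValueError("v and u must have the same shape")
        if self.spiked is None:
            self.spiked = np.zeros(self.v.shape, dtype=bool)


def step_izhikevich(
    state: MembraneState,
    params: IzhikevichParams,
    i_syn: np.ndarray | float,
    dt: float,
) -> MembraneState:
    """Advance every neuron one step of duration ``dt`` (ms).

    Total drive is ``params.i_ext + i_syn``.  Neurons whose voltage reaches
    ``v_peak`` are reset (v <- c, u <- u + d) and flagged in ``spiked``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    i_syn = np.broadcast_to(np.asarray(i_syn, dtype=float), state.v.shape)
    if not np.all(np.isfinite(i_syn)):
        raise ValueError("synaptic current must be finite")
    if not np.all(np.isfinite(state.v)) or not np.all(np.isfinite(state.u)):
        raise ValueError("membrane state must be finite")

    v = state.v.copy()
    u = state.u.copy()
    drive = params.i_ext + i_syn
    half = 0.5 * dt
    v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + drive)
    v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + drive)
    u += dt * params.a * (params.b * v - u)

    spiked = v >= params.v_peak
    v[spiked] = params.c
    u[spiked] += params.d
    return MembraneState(v=v, u=u, spiked=spiked)


def subthreshold_fixed_point(params: IzhikevichParams, i_total: float = 0.0) -> tuple[float, float]:
    """Stable rest state (v*, u*) of the subthreshold dynamics, if it exists.

    Solves 0.04 v^2 + 5 v + 140 - b v + I = 0 and returns the lower
    (stable) root together with u* = b v*.
    """
    a2, a1, a0 = 0.04, 5.0 - params.b, 140.0 + i_total
    disc = a1 * a1 - 4.0 * a2 * a0
    if disc < 0:
        raise ValueError("no subthreshold fixed point for this drive")
    v_star = (-a1 - np.sqrt(disc)) / (2.0 * a2)
    return float(v_star), float(params.b * v_star)


@njit(cache=False)
def _single_neuron_spikes(a, b, c, d, v_peak, i_total, v0, u0, n_steps, dt):
    """Spike times (ms) of one neuron under constant total drive."""
    v = v0
    u = u0
    out = np.empty(n_steps, dtype=np.float64)
    k = 0
    half = 0.5 * dt
    for s in range(n_steps):
        v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + i_total)
        v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + i_total)
        u += dt * a * (b * v - u)
        if v >= v_peak:
            v = c
            u += d
            out[k] = (s + 1) * dt
            k += 1
    return out[:k]


def run_single_neuron(
    params: IzhikevichParams,
    i_ext: float,
    duration_ms: float,
    dt: float = 0.1,
    v0: float | None = None,
) -> np.ndarray:
    """Simulate one neuron under constant drive; return spike times in ms."""
    if v0 is None:
        v0 = params.c
    n_steps = int(round(duration_ms / dt))
    return _single_neuron_spikes(
        params.a, params.b, params.c, params.d, params.v_peak,
        float(i_ext), float(v0), params.b * float(v0), n_steps, dt,
    )


def characterize_single_neuron(
    params: IzhikevichParams,
    current_steps,
    duration_ms: float = 10_000.0,
    dt: float = 0.1,
) -> dict:
    """Rate-vs-current curve for a single neuron.

    Returns ``{"current": array, "rate_hz": array, "spike_times": list}``
    where each entry of ``spike_times`` is the spike raster (ms) for the
    corresponding constant drive.
    """
    currents = np.asarray(list(current_steps), dtype=float)
    rates = np.empty_like(currents)
    rasters = []
    for k, i_ext in enumerate(currents):
        spikes = run_single_neuron(params, i_ext, duration_ms, dt)
        rasters.append(spikes)
        rates[k] = len(spikes) / (duration_ms / 1000.0)
    return {"current": currents, "rate_hz": rates, "spike_times": rasters}
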