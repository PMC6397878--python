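"""Firing-history stress, apoptosis, and degeneration kinetics.

Each SNc neuron carries a stress variable Q that relaxes toward its recent
firing rate (a 1-s sliding-window spike count) with time constant
``tau_stress``.  When Q exceeds the apoptotic threshold the neuron dies
irreversibly: its membrane is clamped, its synaptic output is silenced and
it stops counting toward dopamine and the population metrics.  Survival
courses are summarized by the half-life t_1/2 and the exponential
degeneration rate lambda = ln 2 / t_1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class StressState:
    """Per-SNc-neuron stress and the parameters of its dynamics."""

    q: np.ndarray
    tau_stress: float = 1000.0  # ms
    window_ms: float = 1000.0
    threshold: float = 11.3

    def __post_init__(self) -> None:
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))


def windowed_rate(
    spike_times: list[np.ndarray], t_ms: float, window_ms: float = 1000.0
) -> np.ndarray:
    """Per-neuron spike count in (t - window, t], divided by the window (Hz)."""
    out = np.empty(len(spike_times))
    lo = t_ms - window_ms
    for k, st in enumerate(spike_times):
        out[k] = np.count_nonzero((st > lo) & (st <= t_ms))
    return out / (window_ms / 1000.0)


def update_stress(
    state: StressState, rate_hz: np.ndarray, dt: float
) -> StressState:
    """One Euler step of ``tau dQ/dt = -Q + r(t)`` toward the current rate."""
    q = state.q + (dt / state.tau_stress) * (np.asarray(rate_hz, dtype=float) - state.q)
    return StressState(q=q, tau_stress=state.tau_stress,
                       window_ms=state.window_ms, threshold=state.threshold)


def apply_apoptosis(
    state: StressState, alive: np.ndarray, v: np.ndarray | None = None
) -> np.ndarray:
    """Kill neurons whose stress exceeds the threshold; returns the new mask.

    Death is permanent: the returned mask is the elementwise AND of the old
    mask with ``Q <= threshold``.  If ``v`` is given, dead membranes are
    clamped to 0 in place.
    """
    alive = np.asarray(alive, dtype=bool)
    new_alive = alive & (state.q <= state.threshold)
    if v is not None:
        v[~new_alive] = 0.0
    return new_alive


@dataclass
class DegenerationCourse:
    """Survival curve with derived kinetics."""

    time_s: np.ndarray
    n_sc: np.ndarray
    n_sc0: int
    t_half_s: float = field(default=np.nan)
    lam: float = field(default=np.nan)
    lam_t: np.ndarray = field(default=None)  # type: ignore[assignment]
    lam_t_time_s: np.ndarray = field(default=None)  # type: ignore[assignment]


def estimate_kinetics(
    time_s: np.ndarray, n_sc: np.ndarray, t0_s: float = 0.0
) -> DegenerationCourse:
    """Half-life, rate constant and instantaneous rate of a survival course.

    ``t_half`` is the first (linearly interpolated) time after ``t0_s`` at
    which the surviving count reaches half of its value at ``t0_s``;
    ``lambda = ln2 / t_half``.  If the course never reaches half, both are
    reported as NaN.  The instantaneous rate ``lambda(t)`` is computed on
    1-s bins as the log-decrement of the surviving count, with empty or
    unchanged bins giving 0 and extinct bins NaN.
    """
    time_s = np.asarray(time_s, dtype=float)
    n_sc = np.asarray(n_sc, dtype=float)
    if time_s.size < 2:
        raise ValueError("survival course needs at least two time points")
    if np.any(np.diff(n_sc) > 0):
        raise ValueError("surviving count must be non-increasing")

    i0 = int(np.searchsorted(time_s, t0_s))
    i0 = min(i0, time_s.size - 1)
    n0 = n_sc[i0]
    half = n0 / 2.0

    t_half = np.nan
    below = np.nonzero(n_sc[i0:] <= half)[0]
    if below.size and n0 > 0:
        j = i0 + below[0]
        if n_sc[j] == half or j == i0:
            t_half = time_s[j] - t0_s
        else:
            t1, t2 = time_s[j - 1], time_s[j]
            y1, y2 = n_sc[j - 1], n_sc[j]
            t_half = t1 + (half - y1) * (t2 - t1) / (y2 - y1) - t0_s
    lam = np.log(2.0) / t_half if np.isfinite(t_half) and t_half > 0 else np.nan

    # instantaneous rate on unit-time bins
    t_end = time_s[-1]
    edges = np.arange(np.floor(time_s[0]), np.floor(t_end) + 1.0)
    lam_t = []
    lam_times = []
    for t in edges[1:]:
        n_now = np.interp(t, time_s, n_sc)
        n_prev = np.interp(t - 1.0, time_s, n_sc)
        if n_now <= 0 or n_prev <= 0:
            lam_t.append(np.nan)
        else:
            lam_t.append(np.log(n_prev) - np.log(n_now))
        lam_times.append(t)

    return DegenerationCourse(
        time_s=time_s, n_sc=n_sc, n_sc0=int(round(n0)),
        t_half_s=float(t_half), lam=float(lam),
        lam_t=np.asarray(lam_t), lam_t_time_s=np.asarray(lam_times),
    )


def is_halted(
    time_s: np.ndarray,
    n_sc: np.ndarray,
    t_trigger_s: float,
    grace_s: float = 1.0,
) -> bool:
    """True if the surviving count is constant from shortly after the
    trigger to the end of the course.

    A course that ends extinct is never halted, whatever its shape.
    """
    time_s = np.asarray(time_s, dtype=float)
    n_sc = np.asarray(n_sc, dtype=float)
    sel = time_s >= t_trigger_s + grace_s
    if not np.any(sel):
        return False
    if n_sc[-1] <= 0:
        return False
    return bool(n_sc[sel].max() == n_sc[sel].min())


def survival_ratio(
    n_end_treated: float, n_end_untreated: float, n_trigger: float
) -> float:
    """End-of-run survival relative to untreated (0) and fully protected (1).

    Fully protected means no further loss after the trigger, so the score is
    ``(N_treated - N_untreated) / (N_trigger - N_untreated)``; courses where
    the untreated reference loses nothing after the trigger return NaN.
    """
    denom = n_trigger - n_end_untreated
    if denom <= 0:
        return float("nan")
    return (n_end_treated - n_end_untreated) / denom
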