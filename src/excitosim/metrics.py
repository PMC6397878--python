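"""Firing-rate, synchrony and burst measures on spike rasters.

Synchrony is the Kuramoto order parameter of spike-phase vectors: each
neuron's phase at time t advances linearly from 0 to 2*pi between its
bracketing spikes, and R(t) is the modulus of the population mean unit
phase vector (1 for identical trains, ~N^-1/2 for independent ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SpikeRaster:
    """Ordered spike-time lists (ms) for one population."""

    spike_times: list[np.ndarray]
    duration_ms: float
    population: str = ""
    death_times_ms: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.spike_times = [np.asarray(st, dtype=float) for st in self.spike_times]
        for st in self.spike_times:
            if st.size > 1 and np.any(np.diff(st) <= 0):
                raise ValueError("spike times must be strictly increasing")
        if self.death_times_ms is None:
            self.death_times_ms = np.full(len(self.spike_times), np.inf)

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    def alive_at(self, t_ms: float) -> np.ndarray:
        return self.death_times_ms > t_ms


def firing_rate(
    raster: SpikeRaster,
    window_ms: float = 100.0,
    times_ms: np.ndarray | None = None,
) -> dict:
    """Sliding-window rates: spike count in the trailing window / window.

    Returns per-neuron traces and the population mean over neurons alive at
    each evaluation time.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    if times_ms is None:
        times_ms = np.arange(window_ms, raster.duration_ms + 1e-9, window_ms)
    times_ms = np.atleast_1d(np.asarray(times_ms, dtype=float))
    per_neuron = np.empty((raster.n_neurons, times_ms.size))
    for k, st in enumerate(raster.spike_times):
        hi = np.searchsorted(st, times_ms, side="right")
        lo = np.searchsorted(st, times_ms - window_ms, side="right")
        per_neuron[k] = (hi - lo) / (window_ms / 1000.0)
    alive = raster.death_times_ms[:, None] > times_ms[None, :]
    with np.errstate(invalid="ignore"):
        population = np.where(
            alive.sum(axis=0) > 0,
            (per_neuron * alive).sum(axis=0) / np.maximum(alive.sum(axis=0), 1),
            np.nan,
        )
    return {"times_ms": times_ms, "per_neuron": per_neuron, "population": population}


def synchrony(raster: SpikeRaster, t_ms: np.ndarray | float) -> np.ndarray | float:
    """Kuramoto order parameter R at time(s) t.

    Neurons must bracket t with spikes (last spike <= t < next spike) to
    contribute; dead or non-bracketing neurons are excluded.  With fewer
    than two contributing neurons R is undefined (NaN).
    """
    t_arr = np.atleast_1d(np.asarray(t_ms, dtype=float))
    acc = np.zeros(t_arr.size, dtype=complex)
    cnt = np.zeros(t_arr.size, dtype=int)
    for k, st in enumerate(raster.spike_times):
        if st.size < 2:
            continue
        idx = np.searchsorted(st, t_arr, side="right") - 1
        ok = (idx >= 0) & (idx < st.size - 1) & (t_arr < raster.death_times_ms[k])
        if not np.any(ok):
            continue
        tk = st[idx[ok]]
        tk1 = st[idx[ok] + 1]
        phi = 2.0 * np.pi * (t_arr[ok] - tk) / (tk1 - tk)
        acc[ok] += np.exp(1j * phi)
        cnt[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(acc) / cnt
    r[cnt < 2] = np.nan
    return r if np.ndim(t_ms) else float(r[0])


def burst_index(raster: SpikeRaster) -> np.ndarray:
    """Per-neuron burst measure from interspike-interval variances.

    ``B = (2 Var(ISI1) - Var(ISI2)) / (2 E[ISI1]^2)`` where ISI1 are
    consecutive intervals and ISI2 the two-spike spans.  B is 0 for
    periodic and (in expectation) Poisson trains and positive for bursting.
    Neurons with fewer than 3 spikes get NaN.
    """
    out = np.full(raster.n_neurons, np.nan)
    for k, st in enumerate(raster.spike_times):
        if st.size < 3:
            continue
        isi1 = np.diff(st)
        isi2 = st[2:] - st[:-2]
        out[k] = (2.0 * np.var(isi1) - np.var(isi2)) / (2.0 * np.mean(isi1) ** 2)
    return out


def event_rate(spike_times: np.ndarray, duration_ms: float, merge_ms: float = 20.0) -> float:
    """Firing-event rate in Hz, counting spikes closer than ``merge_ms`` as
    one event (doublets/bursts collapse to a single pacemaker event)."""
    st = np.asarray(spike_times, dtype=float)
    if st.size == 0:
        return 0.0
    events = 1 + int(np.count_nonzero(np.diff(st) >= merge_ms))
    return events / (duration_ms / 1000.0)


def sustained_elevation_onset(
    times_s: np.ndarray,
    trace: np.ndarray,
    baseline_window_s: tuple[float, float],
    search_from_s: float,
    min_margin: float = 0.05,
    min_fraction: float = 0.8,
    smooth_s: float = 1.0,
) -> float:
    """Onset time of a sustained rise of ``trace`` above its baseline.

    The trace is smoothed with a ``smooth_s`` moving average; the baseline
    is its mean over ``baseline_window_s``.  The crossing level is the
    midpoint between the baseline and the post-rise plateau (the 90th
    percentile of the smoothed trace after ``search_from_s``), but at
    least baseline + ``min_margin``.  The onset is the earliest time after
    ``search_from_s`` from which the smoothed trace exceeds that level and
    at least ``min_fraction`` of the remaining samples do as well.
    Returns NaN if the trace never rises or never stays up.
    """
    times_s = np.asarray(times_s, dtype=float)
    trace = np.asarray(trace, dtype=float)
    dt = np.median(np.diff(times_s))
    w = max(1, int(round(smooth_s / dt)))
    kernel = np.ones(w) / w
    filled = pd.Series(trace).interpolate(limit_direction="both").to_numpy()
    smooth = np.convolve(filled, kernel, mode="same")
    base_sel = (times_s >= baseline_window_s[0]) & (times_s <= baseline_window_s[1])
    base = float(np.nanmean(smooth[base_sel]))
    tail_sel = times_s >= search_from_s
    high = float(np.nanpercentile(smooth[tail_sel], 90))
    level = max(0.5 * (base + high), base + min_margin)
    above = smooth > level
    candidates = np.nonzero(tail_sel & above)[0]
    for i in candidates:
        tail = above[i:]
        if tail.mean() >= min_fraction:
            return float(times_s[i])
    return np.nan


def metrics_table(
    rasters: dict[str, SpikeRaster],
    window_ms: float = 100.0,
    grid_ms: float = 10.0,
) -> pd.DataFrame:
    """Tidy (time, population, metric, value) table of rate and synchrony."""
    rows = []
    for name, raster in rasters.items():
        grid = np.arange(window_ms, raster.duration_ms + 1e-9, grid_ms)
        fr = firing_rate(raster, window_ms, grid)
        sy = synchrony(raster, grid)
        for t, r_, s_ in zip(grid, fr["population"], sy):
            rows.append((t / 1000.0, name, "rate_hz", r_))
            rows.append((t / 1000.0, name, "synchrony", s_))
    return pd.DataFrame(rows, columns=["time_s", "population", "metric", "value"])
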