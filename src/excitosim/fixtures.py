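"""Deterministic toy rasters and miniature networks for testing.

These generators produce spike trains with exactly known temporal structure
(periodic, Poisson, alternating-ISI, identical ensembles, antiphase pairs)
and tiny hand-checkable networks, used as independent oracles for the
metrics and current-assembly code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConnectivityConfig, NucleusSpec, default_nuclei
from .connectivity import ConnectivityBundle, build_connectivity
from .metrics import SpikeRaster


@dataclass
class ToyRasterSpec:
    """Parameters of one toy raster (see :func:`make_raster`)."""

    kind: str  # periodic | poisson | alternating | identical | antiphase_pair
    duration_ms: float = 10_000.0
    rate_hz: float = 10.0
    n_neurons: int = 1
    isi_pair_ms: tuple[float, float] = (10.0, 90.0)
    seed: int = 0


def make_raster(spec: ToyRasterSpec) -> SpikeRaster:
    """Build a deterministic toy raster with the requested structure."""
    d = spec.duration_ms
    if spec.kind == "periodic":
        period = 1000.0 / spec.rate_hz
        train = np.arange(period, d + 1e-9, period)
        trains = [train.copy() for _ in range(spec.n_neurons)]
    elif spec.kind == "identical":
        period = 1000.0 / spec.rate_hz
        train = np.arange(period, d + 1e-9, period)
        trains = [train.copy() for _ in range(spec.n_neurons)]
    elif spec.kind == "antiphase_pair":
        period = 1000.0 / spec.rate_hz
        a = np.arange(period, d + 1e-9, period)
        b = np.arange(period * 1.5, d + 1e-9, period)
        trains = [a, b]
    elif spec.kind == "poisson":
        rng = np.random.default_rng(spec.seed)
        trains = []
        for _ in range(spec.n_neurons):
            n_exp = int(spec.rate_hz * d / 1000.0 * 3) + 50
            isi = rng.exponential(1000.0 / spec.rate_hz, size=n_exp)
            st = np.cumsum(isi)
            trains.append(st[st < d])
    elif spec.kind == "alternating":
        s1, s2 = spec.isi_pair_ms
        n_pairs = int(d / (s1 + s2)) + 2
        st = np.cumsum(np.tile([s1, s2], n_pairs).astype(float))
        train = st[st < d]
        trains = [train.copy() for _ in range(spec.n_neurons)]
    else:
        raise ValueError(f"unknown raster kind {spec.kind!r}")
    return SpikeRaster(spike_times=trains, duration_ms=d, population=spec.kind)


def make_mini_network(
    w_stn_gpe: float = 1.0,
    w_gpe_stn: float = 1.0,
    w_stn_snc: float = 1.0,
    rows_stn: int = 4,
    cols_stn: int = 4,
) -> tuple[ConnectivityBundle, dict[str, NucleusSpec]]:
    """A tiny STN/GPe/SNc network whose currents can be hand-computed.

    STN and GPe share a small lattice (one-to-one maps); SNc is the
    coarse-grid reduction (convergent map).  Lateral kernels keep the
    published radii but the small lattices make dense cross-checks cheap.
    """
    base = default_nuclei()
    rows_snc, cols_snc = max(1, rows_stn // 4) , max(1, cols_stn // 4)
    nuclei = {
        "stn": NucleusSpec("stn", rows_stn, cols_stn, base["stn"].izh, nlat=3,
                           radius=base["stn"].radius, strength=base["stn"].strength),
        "gpe": NucleusSpec("gpe", rows_stn, cols_stn, base["gpe"].izh, nlat=3,
                           radius=base["gpe"].radius, strength=base["gpe"].strength),
        "snc": NucleusSpec("snc", rows_snc, cols_snc, base["snc"].izh, nlat=1,
                           radius=base["snc"].radius, strength=base["snc"].strength),
    }
    weights = ConnectivityConfig(
        w_stn_gpe=w_stn_gpe, w_gpe_stn=w_gpe_stn, w_stn_snc=w_stn_snc
    )
    return build_connectivity(nuclei, weights), nuclei
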