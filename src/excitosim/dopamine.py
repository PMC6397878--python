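"""Dopamine signal from SNc activity and its modulation of the network.

The instantaneous dopamine level is the spatially averaged SNc firing rate
normalized by a healthy reference rate and clipped to [0, 1]; cell loss
therefore lowers dopamine in proportion.  Dopamine weakens the excitatory
STN laterals, strengthens the inhibitory GPe and SNc laterals, and scales
all afferent weights down through the post-synaptic factor ``(1 - cd2 DA)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DopamineConfig


@dataclass
class DopamineCoupling:
    """Lateral-modulation exponents and basal strengths of the three nuclei."""

    cd_stn: float
    cd_gpe: float
    cd_snc: float
    cd2: float
    s_max_stn: float
    s_max_gpe: float
    s_max_snc: float
    r_ref: float

    @classmethod
    def from_config(cls, da_cfg: DopamineConfig, nuclei) -> "DopamineCoupling":
        return cls(
            cd_stn=da_cfg.cd_stn, cd_gpe=da_cfg.cd_gpe, cd_snc=da_cfg.cd_snc,
            cd2=da_cfg.cd2,
            s_max_stn=nuclei["stn"].strength,
            s_max_gpe=nuclei["gpe"].strength,
            s_max_snc=nuclei["snc"].strength,
            r_ref=da_cfg.r_ref,
        )


def compute_da_signal(
    snc_rates: np.ndarray, alive: np.ndarray, r_ref: float
) -> float:
    """Dopamine level in [0, 1] from per-neuron SNc rates (Hz).

    Dead neurons contribute zero to the numerator while the denominator
    keeps the full original population size, so cell loss lowers the
    signal even if survivors fire at the reference rate.
    """
    if r_ref <= 0:
        raise ValueError("reference rate must be positive")
    rates = np.asarray(snc_rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    alive = np.asarray(alive, dtype=bool)
    total = float(rates[alive].sum())
    return float(np.clip(total / (rates.size * r_ref), 0.0, 1.0))


def modulate_lateral_strengths(
    da: float, coupling: DopamineCoupling
) -> tuple[float, float, float]:
    """Dopamine-modulated lateral strengths (A_STN, A_GPe, A_SNc).

    STN laterals weaken exponentially with dopamine; GPe and SNc laterals
    strengthen.  At zero dopamine all three equal their basal values.
    """
    a_stn = coupling.s_max_stn * np.exp(-coupling.cd_stn * da)
    a_gpe = coupling.s_max_gpe * np.exp(coupling.cd_gpe * da)
    a_snc = coupling.s_max_snc * np.exp(coupling.cd_snc * da)
    return float(a_stn), float(a_gpe), float(a_snc)


def scale_afferent_weights(w0, da: float, cd2: float = 0.1):
    """Post-synaptic dopamine scaling ``W = (1 - cd2 DA) w`` of base weights.

    Applies to every modulated pathway (STN->GPe, GPe->STN, STN->STN,
    GPe->GPe, STN->SNc, SNc->SNc); ``w0`` may be a scalar, array, or dict of
    either.
    """
    if cd2 * da >= 1.0:
        raise ValueError("cd2 * da must be < 1")
    factor = 1.0 - cd2 * da
    if isinstance(w0, dict):
        return {k: factor * np.asarray(v, dtype=float) if np.ndim(v) else factor * v
                for k, v in w0.items()}
    return factor * w0


def smooth_da(da_raw: np.ndarray, dt: float, tau: float = 10.0) -> np.ndarray:
    """Low-pass filter a raw dopamine trace with time constant ``tau`` (ms)."""
    out = np.empty_like(np.asarray(da_raw, dtype=float))
    acc = da_raw[0]
    k = dt / tau
    for i, x in enumerate(da_raw):
        acc += k * (x - acc)
        out[i] = acc
    return out
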