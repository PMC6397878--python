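"""Neuroprotective intervention protocols.

Every protocol is latched on the first time the surviving SNc count reaches
its trigger stage and stays active afterwards.  The functions here are pure:
they map the protocol parameters and the trigger state to effective weights,
dopamine levels, lesion masks or stimulation currents; the engine applies
them inside the simulation loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DBSSettings
from .connectivity import LatticeLayout


# ---------------------------------------------------------------------------
# Drug / surgical protocols
# ---------------------------------------------------------------------------


def apply_glutamate_inhibition(
    w0: float, n_sc: int, n_i: int, inhibition_pct: float
) -> float:
    """Effective STN->SNc weight under glutamate-inhibition therapy.

    The user-facing dose is the inhibition percentage X; after the trigger
    the residual multiplier on the base weight is ``1 - X/100`` (a 90 %
    dose leaves 10 % of the drive).
    """
    if not 0.0 <= inhibition_pct <= 100.0:
        raise ValueError("inhibition percentage must be in [0, 100]")
    if n_sc > n_i:
        return w0
    return w0 * (1.0 - inhibition_pct / 100.0)


def apply_dopamine_restoration(
    da: float, n_sc: int, n_i: int, restore_pct: float
) -> float:
    """Effective dopamine level under restoration therapy (clipped to 1)."""
    if not 0.0 <= restore_pct <= 100.0:
        raise ValueError("restoration percentage must be in [0, 100]")
    if n_sc > n_i:
        return da
    return float(np.clip(da + restore_pct / 100.0, 0.0, 1.0))


def lesion_count(p_les: float, n_stn: int = 1024) -> int:
    """Number of STN neurons silenced at lesion percentage ``p_les``."""
    if not 0.0 <= p_les <= 100.0:
        raise ValueError("lesion percentage must be in [0, 100]")
    return int(p_les * n_stn // 100)


def apply_subthalamotomy(
    stn_alive: np.ndarray,
    n_sc: int,
    n_i: int,
    p_les: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Silence a seeded uniform-random subset of STN neurons at the trigger.

    Before the trigger the mask is returned unchanged.  The lesion is
    permanent; lesioned neurons are clamped and transmit nothing.
    """
    stn_alive = np.asarray(stn_alive, dtype=bool)
    if n_sc > n_i:
        return stn_alive
    k = lesion_count(p_les, stn_alive.size)
    lesioned = rng.choice(stn_alive.size, size=k, replace=False)
    out = stn_alive.copy()
    out[lesioned] = False
    return out


# ---------------------------------------------------------------------------
# DBS waveforms and fields
# ---------------------------------------------------------------------------


def generate_pulse_train(settings: DBSSettings, t_ms: np.ndarray | float) -> np.ndarray:
    """Instantaneous pulse value at time(s) ``t_ms`` since stimulation onset.

    Monophasic: +A for the pulse width after each onset.  Biphasic: +A for
    the first half-width, -A for the second (charge balanced).  Onsets are
    periodic at 1/f.
    """
    s = settings.resolved()
    period = 1000.0 / s.frequency_hz
    if s.pulse_width_ms >= period:
        raise ValueError("pulse width must be shorter than the pulse period")
    phase = np.mod(np.asarray(t_ms, dtype=float), period)
    if s.waveform == "monophasic":
        out = np.where(phase < s.pulse_width_ms, s.amplitude, 0.0)
    elif s.waveform == "biphasic":
        half = s.pulse_width_ms / 2.0
        out = np.where(
            phase < half, s.amplitude,
            np.where(phase < s.pulse_width_ms, -s.amplitude, 0.0),
        )
    else:
        raise ValueError(f"unknown waveform {s.waveform!r}")
    return out if out.ndim else float(out)


def dbs_spatial_field(
    layout: LatticeLayout,
    contacts,
    sigma: float,
    ) -> np.ndarray:
    """Per-neuron spatial attenuation of the stimulation field.

    Sum over contacts of ``exp(-d^2 / sigma^2)`` where d is the lattice
    distance to the contact.  ``sigma = 0`` with no discrete contacts means
    uniform stimulation of every neuron (the all-contact-points
    configuration).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0.0 or not len(list(contacts)):
        return np.ones(layout.n)
    xy = layout.coords()
    field = np.zeros(layout.n)
    for (ic, jc) in contacts:
        if not (0 <= ic < layout.rows and 0 <= jc < layout.cols):
            raise ValueError("contact point outside the lattice")
        d2 = (xy[:, 0] - ic) ** 2 + (xy[:, 1] - jc) ** 2
        field += np.exp(-d2 / sigma**2)
    return field


def dbs_current_field(
    settings: DBSSettings, layout: LatticeLayout, t_ms: float
) -> np.ndarray:
    """Per-neuron DBS current at time ``t_ms``: pulse value times the
    Gaussian contact field."""
    s = settings.resolved()
    return generate_pulse_train(s, t_ms) * dbs_spatial_field(layout, s.contacts, s.sigma)


def apply_antidromic_split(settings: DBSSettings) -> tuple[float, float]:
    """(A'_STN, A_GPe): DBS amplitude split between direct STN stimulation
    and antidromic GPe activation, per the antidromic fraction."""
    s = settings.resolved()
    if not 0.0 <= s.per_aa <= 1.0:
        raise ValueError("antidromic fraction must be in [0, 1]")
    return (1.0 - s.per_aa) * s.amplitude, s.per_aa * s.amplitude


# ---------------------------------------------------------------------------
# Axonal / synaptic failure
# ---------------------------------------------------------------------------


@dataclass
class FailureMask:
    """Binary transmission mask over STN efferent axons while DBS is on."""

    mask: np.ndarray  # (n_stn,) float 0/1
    per_asf: float


def sample_failure_mask(
    n_stn: int, per_asf: float, rng: np.random.Generator
) -> FailureMask:
    """Zero a ``per_asf`` fraction of STN axons (rounded to whole axons).

    One mask per axon: a failed axon transmits to neither SNc nor GPe.  The
    mask is fixed for as long as DBS stays on.
    """
    if not 0.0 <= per_asf <= 1.0:
        raise ValueError("failure fraction must be in [0, 1]")
    k = int(round(per_asf * n_stn))
    mask = np.ones(n_stn)
    failed = rng.choice(n_stn, size=k, replace=False)
    mask[failed] = 0.0
    return FailureMask(mask=mask, per_asf=per_asf)


def apply_failure_mask(
    weights: np.ndarray, mask: FailureMask, dbs_on: bool
) -> np.ndarray:
    """Elementwise product of per-source weights with the failure mask while
    DBS is on; unchanged when DBS is off."""
    weights = np.asarray(weights, dtype=float)
    if not dbs_on:
        return weights
    return weights * mask.mask
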