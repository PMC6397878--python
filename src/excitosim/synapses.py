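"""Receptor gating, synaptic currents and per-nucleus current assembly.

Gating variables are tracked per presynaptic neuron and receptor kind and
obey first-order decay toward zero, incremented when the source neuron
spikes.  Currents follow the conductance-style form
``I = W * h * (E_rev - v_post)`` with the NMDA component additionally
multiplied by the voltage-dependent magnesium-block factor.
"""

from __future__ import annotations

import numpy as np

from .config import SynapseConfig
from .connectivity import ConnectivityBundle, ProjectionMap


def update_gating(
    h: np.ndarray,
    spikes: np.ndarray,
    tau: float,
    dt: float,
    jump: float = 1.0,
) -> np.ndarray:
    """One Euler step of the gate ODE ``tau dh/dt = -h + S(t)``.

    ``spikes`` is the boolean per-source spike flag for this step; a spike
    adds ``jump`` to the gate, which otherwise decays with time constant
    ``tau`` (ms).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if tau <= 0:
        raise ValueError("tau must be positive")
    return h * (1.0 - dt / tau) + np.asarray(spikes, dtype=float) * jump


def mg_block(v: np.ndarray | float, mg: float = 1.0) -> np.ndarray | float:
    """Voltage-dependent magnesium unblock factor of the NMDA receptor.

    ``B(v) = 1 / (1 + (Mg / 3.57) * exp(-0.062 v))``; 1 when Mg is absent,
    approaching 0 at hyperpolarized potentials.
    """
    return 1.0 / (1.0 + (mg / 3.57) * np.exp(-0.062 * np.asarray(v, dtype=float)))


def synaptic_current(
    h: np.ndarray,
    weights: np.ndarray,
    v_post: np.ndarray | float,
    e_rev: float,
    mg: float | None = None,
) -> np.ndarray:
    """Current onto each target: sum over incoming edges of W*h*(E - v).

    ``weights`` is either an (n_target, n_source) matrix (summed over
    sources) or an array broadcastable against ``h`` for elementwise edges.
    ``mg`` switches on the NMDA magnesium block.
    """
    h = np.asarray(h, dtype=float)
    weights = np.asarray(weights, dtype=float)
    v_post = np.asarray(v_post, dtype=float)
    if weights.ndim == 2:
        if weights.shape[1] != h.shape[0]:
            raise ValueError("weight matrix does not align with gate vector")
        drive = weights @ h
    else:
        drive = weights * h
    i = drive * (e_rev - v_post)
    if mg is not None:
        i = i * mg_block(v_post, mg)
    return i


def projection_gate_sum(proj: ProjectionMap, h: np.ndarray) -> np.ndarray:
    """Per-target sum of source gates along a projection map."""
    return h[proj.sources].sum(axis=1)


def assemble_total_currents(
    v: dict[str, np.ndarray],
    gates: dict[str, np.ndarray],
    alive: dict[str, np.ndarray],
    bundle: ConnectivityBundle,
    da: float,
    syn: SynapseConfig,
    cd2: float = 0.1,
    w_stn_snc_factor: float = 1.0,
    asf_mask: np.ndarray | None = None,
    lateral_strengths: dict[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """Per-nucleus total synaptic currents of the full network.

    ``gates`` holds ``stn_ampa``, ``stn_nmda``, ``gpe_gaba``, ``snc_gaba``
    per-source gate vectors.  Dead neurons (``alive`` masks) neither
    transmit (their gates are forced to zero) nor receive.  ``da`` is the
    dopamine level applied through the afferent-weight factor
    ``(1 - cd2 * da)``.

    ``w_stn_snc_factor`` carries therapy scaling of the STN->SNc weight and
    ``asf_mask`` an optional per-STN-neuron binary transmission mask.
    ``lateral_strengths`` overrides the kernels' stored strengths with
    dopamine-modulated values (per nucleus name).
    """
    wfac = 1.0 - cd2 * da

    def a_fac(name):
        if lateral_strengths is None:
            return 1.0
        return lateral_strengths[name] / bundle.kernels[name].strength
    h_ampa = gates["stn_ampa"] * alive["stn"]
    h_nmda = gates["stn_nmda"] * alive["stn"]
    h_gpe = gates["gpe_gaba"] * alive["gpe"]
    h_snc = gates["snc_gaba"] * alive["snc"]
    if asf_mask is not None:
        h_ampa_eff = h_ampa * asf_mask
        h_nmda_eff = h_nmda * asf_mask
    else:
        h_ampa_eff, h_nmda_eff = h_ampa, h_nmda

    lay = bundle.layouts
    k_stn, k_gpe, k_snc = bundle.kernels["stn"], bundle.kernels["gpe"], bundle.kernels["snc"]

    def grid(x, name):
        return x.reshape(lay[name].rows, lay[name].cols)

    v_stn, v_gpe, v_snc = v["stn"], v["gpe"], v["snc"]
    b_stn = mg_block(v_stn, syn.mg)
    b_gpe = mg_block(v_gpe, syn.mg)
    b_snc = mg_block(v_snc, syn.mg)

    # STN: glutamatergic laterals (AMPA + NMDA) + GABA from GPe (one-to-one)
    lat_ampa = a_fac("stn") * k_stn.lateral_sum(grid(h_ampa, "stn")).ravel()
    lat_nmda = a_fac("stn") * k_stn.lateral_sum(grid(h_nmda, "stn")).ravel()
    gpe_in = projection_gate_sum(bundle.gpe_to_stn, h_gpe)
    i_stn = wfac * (
        lat_ampa * (syn.e_ampa - v_stn)
        + b_stn * lat_nmda * (syn.e_nmda - v_stn)
        + bundle.gpe_to_stn.w0 * gpe_in * (syn.e_gaba - v_stn)
    )

    # GPe: GABA laterals + glutamate from STN (one-to-one)
    lat_gaba = a_fac("gpe") * k_gpe.lateral_sum(grid(h_gpe, "gpe")).ravel()
    stn_in_a = projection_gate_sum(bundle.stn_to_gpe, h_ampa_eff)
    stn_in_n = projection_gate_sum(bundle.stn_to_gpe, h_nmda_eff)
    i_gpe = wfac * (
        lat_gaba * (syn.e_gaba - v_gpe)
        + bundle.stn_to_gpe.w0
        * (stn_in_a * (syn.e_ampa - v_gpe) + b_gpe * stn_in_n * (syn.e_nmda - v_gpe))
    )

    # SNc: GABA laterals + convergent glutamate from STN
    lat_gaba_snc = a_fac("snc") * k_snc.lateral_sum(grid(h_snc, "snc")).ravel()
    snc_in_a = projection_gate_sum(bundle.stn_to_snc, h_ampa_eff)
    snc_in_n = projection_gate_sum(bundle.stn_to_snc, h_nmda_eff)
    w_snc = bundle.stn_to_snc.w0 * w_stn_snc_factor
    i_snc = wfac * (
        lat_gaba_snc * (syn.e_gaba - v_snc)
        + w_snc * (snc_in_a * (syn.e_ampa - v_snc) + b_snc * snc_in_n * (syn.e_nmda - v_snc))
    )

    return {
        "stn": i_stn * alive["stn"],
        "gpe": i_gpe * alive["gpe"],
        "snc": i_snc * alive["snc"],
    }
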