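"""Receptor gating, magnesium block and current assembly."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from excitosim import mg_block, synaptic_current, update_gating
from excitosim.config import SynapseConfig
from excitosim.fixtures import make_mini_network
from excitosim.synapses import assemble_total_currents


def test_gate_decays_exponentially():
    h = np.array([1.0])
    dt, tau = 0.01, 6.0
    for _ in range(int(6.0 / dt)):  # one time constant
        h = update_gating(h, np.array([False]), tau, dt)
    assert h[0] == pytest.approx(np.exp(-1.0), rel=1e-3)


def test_zero_gate_stays_zero():
    h = np.zeros(3)
    for _ in range(100):
        h = update_gating(h, np.zeros(3, dtype=bool), 4.0, 0.1)
    assert np.all(h == 0)


def test_gate_linearity_in_spike_trains():
    """Gate response to superposed spike trains equals the sum of responses."""
    rng = np.random.default_rng(2)
    a = rng.random(2000) < 0.02
    b = rng.random(2000) < 0.05
    h_a = np.zeros(1)
    h_b = np.zeros(1)
    h_ab = np.zeros(1)
    for sa, sb in zip(a, b):
        h_a = update_gating(h_a, np.array([sa]), 160.0, 0.1)
        h_b = update_gating(h_b, np.array([sb]), 160.0, 0.1)
        # superposition: a step where both trains spike adds two jumps
        h_ab = h_ab * (1 - 0.1 / 160.0) + (int(sa) + int(sb)) * 1.0
    assert h_ab[0] == pytest.approx(h_a[0] + h_b[0], rel=1e-9)


def test_gate_tracks_reference_ode_on_periodic_train():
    """Euler gate matches the closed-form impulse response of the gate ODE
    on a 20 Hz periodic train."""
    tau, dt = 160.0, 0.1
    every = 500  # steps between spikes (50 ms)
    n_steps = 20_000
    h = np.zeros(1)
    spike_steps = []
    for step in range(n_steps):
        spk = (step + 1) % every == 0
        if spk:
            spike_steps.append(step + 1)
        h = update_gating(h, np.array([spk]), tau, dt)
    # reference: exponential decay between unit impulses
    h_ref = 0.0
    last = 0.0
    for s_ms in (np.array(spike_steps) * dt):
        h_ref = h_ref * np.exp(-(s_ms - last) / tau) + 1.0
        last = s_ms
    h_ref *= np.exp(-(n_steps * dt - last) / tau)
    assert h[0] == pytest.approx(h_ref, rel=0.02)


@pytest.mark.parametrize(
    "v,mg,expected",
    [
        (0.0, 1.0, 1.0 / (1.0 + 1.0 / 3.57)),  # ~0.7812
        (-40.0, 0.0, 1.0),
        (100.0, 0.0, 1.0),
    ],
)
def test_mg_block_values(v, mg, expected):
    assert mg_block(v, mg) == pytest.approx(expected, rel=1e-12)


def test_mg_block_monotone_in_voltage():
    assert mg_block(-80.0) < mg_block(-40.0) < mg_block(0.0)


def test_current_zero_at_reversal():
    i = synaptic_current(np.array([0.7]), np.array([2.0]), v_post=0.0, e_rev=0.0)
    assert i[0] == 0.0


def test_gaba_driving_force_sign():
    # below E_GABA the current depolarizes, above it hyperpolarizes
    below = synaptic_current(np.array([0.5]), np.array([1.0]), -70.0, -60.0)
    above = synaptic_current(np.array([0.5]), np.array([1.0]), -50.0, -60.0)
    assert below[0] > 0 > above[0]


def test_single_edge_current_value():
    i = synaptic_current(np.array([0.5]), np.array([1.0]), -60.0, 0.0)
    assert i[0] == pytest.approx(30.0)


def test_weight_matrix_alignment_error():
    with pytest.raises(ValueError):
        synaptic_current(np.ones(3), np.ones((2, 4)), -60.0, 0.0)


# ---------------------------------------------------------------------------
# Current assembly on miniature networks
# ---------------------------------------------------------------------------


@pytest.fixture()
def mini():
    bundle, nuclei = make_mini_network(w_stn_gpe=1.0, w_gpe_stn=1.0, w_stn_snc=1.0)
    n_stn = nuclei["stn"].n
    n_snc = nuclei["snc"].n
    v = {"stn": np.full(n_stn, -60.0), "gpe": np.full(n_stn, -60.0),
         "snc": np.full(n_snc, -60.0)}
    gates = {"stn_ampa": np.zeros(n_stn), "stn_nmda": np.zeros(n_stn),
             "gpe_gaba": np.zeros(n_stn), "snc_gaba": np.zeros(n_snc)}
    alive = {"stn": np.ones(n_stn), "gpe": np.ones(n_stn), "snc": np.ones(n_snc)}
    return bundle, nuclei, v, gates, alive


def test_all_gates_zero_gives_zero_currents(mini):
    bundle, nuclei, v, gates, alive = mini
    out = assemble_total_currents(v, gates, alive, bundle, da=0.3, syn=SynapseConfig())
    for cur in out.values():
        assert np.all(cur == 0)


def test_silencing_gpe_removes_stn_gaba_term(mini):
    bundle, nuclei, v, gates, alive = mini
    syn = SynapseConfig()
    gates["stn_ampa"][:] = 0.1
    gates["stn_nmda"][:] = 0.2
    gates["gpe_gaba"][:] = 0.5
    with_gpe = assemble_total_currents(v, gates, alive, bundle, 0.0, syn)
    gates["gpe_gaba"][:] = 0.0
    without = assemble_total_currents(v, gates, alive, bundle, 0.0, syn)
    # GABA at E=-60 with v=-60 is zero anyway; use v=-50 for a real check
    v2 = {k: np.full_like(a, -50.0) for k, a in v.items()}
    gates["gpe_gaba"][:] = 0.5
    with_gpe = assemble_total_currents(v2, gates, alive, bundle, 0.0, syn)
    gates["gpe_gaba"][:] = 0.0
    without = assemble_total_currents(v2, gates, alive, bundle, 0.0, syn)
    diff = with_gpe["stn"] - without["stn"]
    # pure GABA difference: W * h * (E - v) = 1 * 0.5 * (-10) per edge
    assert np.allclose(diff, -5.0)


def test_excitatory_currents_positive_below_zero_mv(mini):
    bundle, nuclei, v, gates, alive = mini
    gates["stn_ampa"][:] = 0.3
    gates["stn_nmda"][:] = 0.3
    out = assemble_total_currents(v, gates, alive, bundle, 0.0, SynapseConfig())
    assert np.all(out["gpe"] >= 0)
    assert np.all(out["snc"] >= 0)


def test_dead_source_contributes_nothing(mini):
    bundle, nuclei, v, gates, alive = mini
    gates["stn_ampa"][:] = 0.3
    gates["stn_nmda"][:] = 0.1
    alive["stn"] = np.zeros_like(alive["stn"])
    out = assemble_total_currents(v, gates, alive, bundle, 0.0, SynapseConfig())
    assert np.all(out["snc"] == 0)
    assert np.all(out["gpe"] == 0)


def test_afferent_scaling_reduces_currents_with_dopamine(mini):
    bundle, nuclei, v, gates, alive = mini
    gates["stn_ampa"][:] = 0.3
    lo = assemble_total_currents(v, gates, alive, bundle, 0.0, SynapseConfig())
    hi = assemble_total_currents(v, gates, alive, bundle, 1.0, SynapseConfig())
    assert np.allclose(hi["snc"], 0.9 * lo["snc"])


def test_single_stn_spike_envelope_matches_reference_ode():
    """One STN spike: the SNc glutamatergic current follows the AMPA/NMDA
    double-exponential envelope of an independent ODE integration."""
    syn = SynapseConfig()
    dt = 0.1
    h_a, h_n = 1.0, 1.0  # gates just after the spike
    v_post = -60.0
    b = mg_block(v_post, syn.mg)
    times = np.arange(0.0, 800.0, dt)

    # package route: Euler decay of both gates
    ha = np.array([h_a])
    hn = np.array([h_n])
    i_pkg = []
    for _ in times:
        i_pkg.append(float(ha[0] * (0 - v_post) + b * hn[0] * (0 - v_post)))
        ha = update_gating(ha, np.array([False]), syn.tau_ampa, dt)
        hn = update_gating(hn, np.array([False]), syn.tau_nmda, dt)

    # reference route: solve the linear ODEs with scipy
    sol = solve_ivp(
        lambda t, y: [-y[0] / syn.tau_ampa, -y[1] / syn.tau_nmda],
        (0, 800.0), [h_a, h_n], t_eval=times, rtol=1e-10, atol=1e-12,
    )
    i_ref = (sol.y[0] + b * sol.y[1]) * (0 - v_post)
    assert np.allclose(i_pkg, i_ref, rtol=0.02, atol=0.05)
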