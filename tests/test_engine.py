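"""Engine orchestration: determinism, module consistency, persistence."""

import numpy as np
import pytest

from excitosim import (
    NetworkConfig,
    NetworkState,
    build_connectivity,
    initial_state,
    run_network,
)
from excitosim.config import ExperimentPlan, StressConfig, TherapyProtocol
from excitosim.engine import SimulationRecord
from excitosim.metrics import SpikeRaster
from excitosim.neurons import MembraneState, step_izhikevich
from excitosim.synapses import assemble_total_currents, update_gating
from excitosim.dopamine import DopamineCoupling, modulate_lateral_strengths


def short_cfg(duration_s=1.0, **stress):
    cfg = NetworkConfig.full_profile()
    cfg.plan = ExperimentPlan(duration_s=duration_s)
    if stress:
        cfg.stress = StressConfig(**stress)
    else:
        cfg.stress = StressConfig(threshold_initial=np.inf, threshold_late=np.inf)
    return cfg


def test_same_seed_is_bit_identical():
    cfg = short_cfg(1.0)
    a = run_network(cfg, seed=42)
    b = run_network(cfg, seed=42)
    for nm in ("stn", "gpe", "snc"):
        for sa, sb in zip(a.rasters[nm].spike_times, b.rasters[nm].spike_times):
            assert np.array_equal(sa, sb)
    assert a.traces.equals(b.traces)
    assert np.array_equal(a.final_state.v["stn"], b.final_state.v["stn"])


def test_different_seed_differs():
    cfg = short_cfg(0.5)
    a = run_network(cfg, seed=1)
    b = run_network(cfg, seed=2)
    assert not np.array_equal(a.final_state.v["stn"], b.final_state.v["stn"])


def test_infinite_threshold_keeps_all_cells():
    cfg = short_cfg(2.0)
    rec = run_network(cfg, seed=0)
    assert np.all(rec.traces["n_sc"] == 64)
    assert rec.final_state.alive["snc"].all()


def test_decoupled_network_matches_single_neuron_stepper():
    """With all synapses silenced the engine reduces to independent
    Izhikevich neurons stepped by the reference module."""
    cfg = short_cfg(0.2)
    cfg.connectivity.w_stn_gpe = 0.0
    cfg.connectivity.w_gpe_stn = 0.0
    cfg.connectivity.w_stn_snc = 0.0
    for spec in cfg.nuclei.values():
        spec.strength = 0.0
        spec.bias_jitter = 0.0
    rng = np.random.default_rng(123)
    init = initial_state(cfg, rng)
    rec = run_network(cfg, seed=5, init=init)

    dt = cfg.plan.dt_ms
    for name in ("stn", "gpe", "snc"):
        p = cfg.nuclei[name].izh
        st = MembraneState(v=init.v[name].copy(), u=init.u[name].copy())
        for _ in range(int(round(0.2 * 1000 / dt))):
            st = step_izhikevich(st, p, 0.0, dt)
        assert np.allclose(st.v, rec.final_state.v[name], atol=1e-9)
        assert np.allclose(st.u, rec.final_state.u[name], atol=1e-9)


def test_engine_consistent_with_module_composition():
    """A coupled 30-step run agrees with the same physics composed from the
    public module operations (currents, membrane step, gates, stress, DA)."""
    cfg = short_cfg(0.003)  # 30 steps
    dt = cfg.plan.dt_ms
    n_steps = 30
    rng = np.random.default_rng(99)
    init = initial_state(cfg, rng)
    # seed some gate activity so currents are non-trivial from step one
    init.gates["stn_ampa"][:] = rng.random(1024) * 0.05
    init.gates["stn_nmda"][:] = rng.random(1024) * 0.5
    init.gates["gpe_gaba"][:] = rng.random(1024) * 0.3
    init.gates["snc_gaba"][:] = rng.random(64) * 0.3
    rec = run_network(cfg, seed=0, init=init, spike_cap_hz=500_000.0)

    bundle = build_connectivity(cfg.nuclei, cfg.connectivity)
    syn, dac, stc = cfg.synapse, cfg.dopamine, cfg.stress
    coup = DopamineCoupling.from_config(dac, cfg.nuclei)
    v = {k: a.copy() for k, a in init.v.items()}
    u = {k: a.copy() for k, a in init.u.items()}
    gates = {k: a.copy() for k, a in init.gates.items()}
    alive = {"stn": np.ones(1024), "gpe": np.ones(1024), "snc": np.ones(64)}
    q = init.stress.copy()
    da_f = init.da
    scnt = np.zeros(64)
    dcnt = np.zeros(64)
    for _ in range(n_steps):
        da_raw = min(dcnt.sum() / (dac.window_ms / 1000.0) / 64 / dac.r_ref, 1.0)
        da_f += (dt / dac.tau_da) * (da_raw - da_f)
        a_stn, a_gpe, a_snc = modulate_lateral_strengths(da_f, coup)
        cur = assemble_total_currents(
            v, gates, alive, bundle, da_f, syn, cd2=dac.cd2,
            lateral_strengths={"stn": a_stn, "gpe": a_gpe, "snc": a_snc})
        spikes = {}
        for name in ("stn", "gpe", "snc"):
            p = cfg.nuclei[name].izh
            st = step_izhikevich(
                MembraneState(v=v[name], u=u[name]), p,
                cur[name] + (init.bias[name] - p.i_ext), dt)
            v[name], u[name], spikes[name] = st.v, st.u, st.spiked
        gates["stn_ampa"] = update_gating(gates["stn_ampa"], spikes["stn"],
                                          syn.tau_ampa, dt, syn.gate_jump_glu)
        gates["stn_nmda"] = update_gating(gates["stn_nmda"], spikes["stn"],
                                          syn.tau_nmda, dt, syn.gate_jump_glu)
        gates["gpe_gaba"] = update_gating(gates["gpe_gaba"], spikes["gpe"],
                                          syn.tau_gaba, dt, syn.gate_jump_gaba)
        gates["snc_gaba"] = update_gating(gates["snc_gaba"], spikes["snc"],
                                          syn.tau_gaba, dt, syn.gate_jump_gaba)
        scnt += spikes["snc"]
        dcnt += spikes["snc"]
        r = scnt * 1000.0 / stc.window_ms
        q += (dt / stc.tau_stress) * (r - q)

    for name in ("stn", "gpe", "snc"):
        assert np.allclose(v[name], rec.final_state.v[name], atol=1e-8)
        assert np.allclose(u[name], rec.final_state.u[name], atol=1e-8)
    assert np.allclose(gates["stn_nmda"], rec.final_state.gates["stn_nmda"], atol=1e-10)
    assert np.allclose(gates["snc_gaba"], rec.final_state.gates["snc_gaba"], atol=1e-10)
    assert np.allclose(q, rec.final_state.stress, atol=1e-10)
    assert da_f == pytest.approx(rec.final_state.da, abs=1e-12)


def test_gates_reconstructable_from_raster():
    """Final gate values equal the decayed sum of the recorded spikes."""
    cfg = short_cfg(1.0)
    rec = run_network(cfg, seed=3)
    syn = cfg.synapse
    dt = cfg.plan.dt_ms
    end = 1000.0
    h = np.zeros(1024)
    for k, st_times in enumerate(rec.rasters["stn"].spike_times):
        h[k] = np.sum(syn.gate_jump_glu
                      * (1 - dt / syn.tau_nmda) ** ((end - st_times) / dt))
    assert np.allclose(h, rec.final_state.gates["stn_nmda"], rtol=1e-6, atol=1e-9)


def test_therapy_trigger_latches_and_plateaus():
    cfg = NetworkConfig.scaled_profile()
    cfg.plan.duration_s = 8.0
    cfg.therapy = TherapyProtocol(kind="glutamate_inhibition", stage_pct=25.0,
                                  inhibition_pct=100.0)
    rec = run_network(cfg, seed=1)
    assert np.isfinite(rec.trigger_time_s)
    t, n = rec.survival_course()
    at_trigger = n[np.searchsorted(t, rec.trigger_time_s)]
    assert at_trigger <= 48
    # full glutamate block: no further deaths after the post-trigger second
    sel = t >= rec.trigger_time_s + 1.0
    assert n[sel].max() == n[sel].min()


def test_blowup_aborts_with_diagnostic():
    cfg = short_cfg(0.5)
    cfg.connectivity.w_stn_snc = 1e9
    with pytest.raises(RuntimeError, match="blow-up"):
        run_network(cfg, seed=0)


def test_record_roundtrip_hdf5(tmp_path):
    cfg = short_cfg(0.3)
    rec = run_network(cfg, seed=8)
    path = tmp_path / "rec.h5"
    rec.save(path)
    loaded = SimulationRecord.load(path)
    assert loaded.seed == 8
    assert loaded.traces.shape == rec.traces.shape
    for nm in ("stn", "gpe", "snc"):
        for a, b in zip(rec.rasters[nm].spike_times, loaded.rasters[nm].spike_times):
            assert np.allclose(a, b)


def test_config_yaml_roundtrip(tmp_path):
    cfg = NetworkConfig.scaled_profile()
    cfg.therapy = TherapyProtocol(kind="subthalamotomy", stage_pct=50.0, lesion_pct=40.0)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = NetworkConfig.from_yaml(path)
    assert back.to_dict() == cfg.to_dict()


def test_raster_objects_satisfy_invariants():
    cfg = short_cfg(0.5)
    rec = run_network(cfg, seed=4)
    for nm, raster in rec.rasters.items():
        assert isinstance(raster, SpikeRaster)
        for st in raster.spike_times:
            assert np.all(np.diff(st) > 0)


def test_connectivity_dump_roundtrip(tmp_path):
    import h5py
    from excitosim.connectivity import load_connectivity, save_connectivity

    bundle = build_connectivity()
    with h5py.File(tmp_path / "conn.h5", "w") as f:
        save_connectivity(bundle, f.create_group("connectivity"))
    with h5py.File(tmp_path / "conn.h5", "r") as f:
        back = load_connectivity(f["connectivity"])
    assert np.allclose(back["kernels"]["stn"], bundle.kernels["stn"].dense())
    kind, w0, src = back["projections"]["stn_to_snc"]
    assert kind == "convergent"
    assert np.array_equal(src, bundle.stn_to_snc.sources)
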