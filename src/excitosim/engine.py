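"""Simulation orchestration: full-network runs, sweeps and therapy grids.

`run_network` assembles the lattice network from a :class:`NetworkConfig`,
executes the compiled step loop and returns a :class:`SimulationRecord`
holding rasters, the dopamine trace, the survival course and derived
kinetics.  Reruns with the same config and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from . import _kernel as K
from .config import NetworkConfig, TherapyProtocol
from .connectivity import ConnectivityBundle, build_connectivity, save_connectivity
from .degeneration import DegenerationCourse, estimate_kinetics, is_halted, survival_ratio
from .metrics import SpikeRaster, firing_rate, sustained_elevation_onset, synchrony
from .therapy import apply_antidromic_split, dbs_spatial_field, sample_failure_mask

THERAPY_CODES = {
    "none": 0,
    "glutamate_inhibition": 1,
    "dopamine_restoration": 2,
    "subthalamotomy": 3,
    "dbs": 4,
}


@dataclass
class NetworkState:
    """Complete dynamical state of the network at one instant."""

    v: dict[str, np.ndarray]
    u: dict[str, np.ndarray]
    gates: dict[str, np.ndarray]     # stn_ampa, stn_nmda, gpe_gaba, snc_gaba
    alive: dict[str, np.ndarray]     # stn, snc (GPe cells never die)
    stress: np.ndarray               # per-SNc-neuron Q
    da: float = 0.0                  # filtered dopamine level
    bias: dict[str, np.ndarray] = None  # type: ignore[assignment]  # per-neuron i_ext


def initial_state(cfg: NetworkConfig, rng: np.random.Generator) -> NetworkState:
    """Desynchronized start: v uniform in [c, c+10] mV, u = b v, all alive.

    Per-neuron bias currents carry a stratified cell-to-cell jitter of
    fractional half-width ``bias_jitter``: an evenly spaced spread profile
    is permuted at random over lattice sites, so the population's
    excitability distribution is identical across seeds while its spatial
    arrangement is seeded.  This is the variability that keeps weakly
    coupled populations asynchronous and staggers the stress of SNc cells.
    """
    v, u, bias = {}, {}, {}
    basal_hz = {"snc": 9.5, "stn": 13.5, "gpe": 31.0}  # decoupled spike rates
    for name, spec in cfg.nuclei.items():
        p = spec.izh
        v[name] = rng.uniform(p.c, p.c + 10.0, size=spec.n)
        # start at the adapted operating point: u carries the steady
        # spike-driven adaptation d * f / a on top of the nullcline value,
        # so the run does not open with an under-adapted population burst
        u_adapt = p.d * (basal_hz.get(name, 10.0) / 1000.0) / p.a
        u[name] = p.b * v[name] + u_adapt
        profile = np.linspace(-1.0, 1.0, spec.n)
        bias[name] = p.i_ext * (1.0 + spec.bias_jitter * rng.permutation(profile))
    gates = {
        "stn_ampa": np.zeros(cfg.nuclei["stn"].n),
        "stn_nmda": np.zeros(cfg.nuclei["stn"].n),
        "gpe_gaba": np.zeros(cfg.nuclei["gpe"].n),
        "snc_gaba": np.zeros(cfg.nuclei["snc"].n),
    }
    alive = {
        "stn": np.ones(cfg.nuclei["stn"].n, dtype=bool),
        "snc": np.ones(cfg.nuclei["snc"].n, dtype=bool),
    }
    # dopamine tone starts at its healthy level
    return NetworkState(v=v, u=u, gates=gates, alive=alive,
                        stress=np.zeros(cfg.nuclei["snc"].n), da=1.0, bias=bias)


@dataclass
class SimulationRecord:
    """Everything one simulation produced, with provenance."""

    config: NetworkConfig
    seed: int
    rasters: dict[str, SpikeRaster]
    traces: pd.DataFrame            # time_s, da, da_eff, n_sc
    q_trace: np.ndarray             # (n_records, n_snc)
    trigger_time_s: float           # NaN if therapy never triggered
    final_state: NetworkState
    status: int = 0

    @property
    def duration_s(self) -> float:
        return self.config.plan.duration_s

    def survival_course(self) -> tuple[np.ndarray, np.ndarray]:
        return self.traces["time_s"].to_numpy(), self.traces["n_sc"].to_numpy()

    def kinetics(self, t0_s: Optional[float] = None) -> DegenerationCourse:
        """Degeneration kinetics, measured from the threshold-switch time by
        default."""
        if t0_s is None:
            t0_s = self.config.stress.switch_time_s
        t, n = self.survival_course()
        return estimate_kinetics(t, n, t0_s=t0_s)

    def population_rate(self, nucleus: str, window_ms: float = 100.0) -> dict:
        return firing_rate(self.rasters[nucleus], window_ms)

    def synchrony_trace(self, nucleus: str, grid_ms: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
        grid = np.arange(grid_ms, self.duration_s * 1000.0, grid_ms)
        return grid / 1000.0, synchrony(self.rasters[nucleus], grid)

    def stn_synchrony_onset(self) -> float:
        """Onset time (s) of the sustained STN synchrony elevation, relative
        to the pre-degeneration baseline."""
        t_s, r = self.synchrony_trace("stn")
        switch = self.config.stress.switch_time_s
        return sustained_elevation_onset(
            t_s, r,
            baseline_window_s=(min(2.0, switch / 2), switch),
            search_from_s=switch,
        )

    def summary(self) -> dict:
        t, n = self.survival_course()
        kin = self.kinetics()
        return {
            "n_sc_end": int(n[-1]),
            "t_half_s": kin.t_half_s,
            "lambda_per_s": kin.lam,
            "trigger_time_s": self.trigger_time_s,
        }

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        import yaml

        with h5py.File(path, "w") as f:
            f.attrs["seed"] = self.seed
            f.attrs["status"] = self.status
            f.attrs["trigger_time_s"] = self.trigger_time_s
            f.attrs["config_yaml"] = yaml.safe_dump(self.config.to_dict())
            for name, raster in self.rasters.items():
                g = f.create_group(f"raster_{name}")
                flat = np.concatenate([st for st in raster.spike_times]) if raster.spike_times else np.empty(0)
                counts = np.array([st.size for st in raster.spike_times])
                g.create_dataset("times_ms", data=flat)
                g.create_dataset("counts", data=counts)
                g.create_dataset("death_times_ms", data=raster.death_times_ms)
                g.attrs["duration_ms"] = raster.duration_ms
            tr = f.create_group("traces")
            for col in self.traces.columns:
                tr.create_dataset(col, data=self.traces[col].to_numpy())
            f.create_dataset("q_trace", data=self.q_trace)
            conn = f.create_group("connectivity")
            save_connectivity(build_connectivity(self.config.nuclei, self.config.connectivity), conn)

    @classmethod
    def load(cls, path) -> "SimulationRecord":
        import yaml

        with h5py.File(path, "r") as f:
            cfg = NetworkConfig.from_dict(yaml.safe_load(f.attrs["config_yaml"]))
            rasters = {}
            for key in f:
                if not key.startswith("raster_"):
                    continue
                g = f[key]
                counts = g["counts"][...]
                flat = g["times_ms"][...]
                splits = np.cumsum(counts)[:-1]
                rasters[key[len("raster_"):]] = SpikeRaster(
                    spike_times=list(np.split(flat, splits)),
                    duration_ms=float(g.attrs["duration_ms"]),
                    population=key[len("raster_"):],
                    death_times_ms=g["death_times_ms"][...],
                )
            traces = pd.DataFrame({col: f["traces"][col][...] for col in f["traces"]})
            return cls(
                config=cfg, seed=int(f.attrs["seed"]), rasters=rasters,
                traces=traces, q_trace=f["q_trace"][...],
                trigger_time_s=float(f.attrs["trigger_time_s"]),
                final_state=None,  # type: ignore[arg-type]
                status=int(f.attrs["status"]),
            )


def _pack_params(cfg: NetworkConfig, bundle: ConnectivityBundle, n_steps: int,
                 da0: float) -> tuple[np.ndarray, np.ndarray]:
    fp = np.zeros(K.N_FP)
    ip = np.zeros(K.N_IP, dtype=np.int64)
    plan, syn, dac, stc = cfg.plan, cfg.synapse, cfg.dopamine, cfg.stress
    dt = plan.dt_ms
    fp[K.FP_DT] = dt
    fp[K.FP_R_REF] = dac.r_ref
    fp[K.FP_TAU_DA] = dac.tau_da
    fp[K.FP_CD_STN] = dac.cd_stn
    fp[K.FP_CD_GPE] = dac.cd_gpe
    fp[K.FP_CD_SNC] = dac.cd_snc
    fp[K.FP_CD2] = dac.cd2
    fp[K.FP_SMAX_STN] = cfg.nuclei["stn"].strength
    fp[K.FP_SMAX_GPE] = cfg.nuclei["gpe"].strength
    fp[K.FP_SMAX_SNC] = cfg.nuclei["snc"].strength
    fp[K.FP_W_STN_GPE] = cfg.connectivity.w_stn_gpe
    fp[K.FP_W_GPE_STN] = cfg.connectivity.w_gpe_stn
    w_snc = cfg.connectivity.w_stn_snc
    if plan.w_stn_snc_override is not None:
        w_snc = plan.w_stn_snc_override
    fp[K.FP_W_STN_SNC] = w_snc
    fp[K.FP_MG] = syn.mg
    fp[K.FP_TAU_AMPA] = syn.tau_ampa
    fp[K.FP_TAU_NMDA] = syn.tau_nmda
    fp[K.FP_TAU_GABA] = syn.tau_gaba
    fp[K.FP_JUMP_GLU] = syn.gate_jump_glu
    fp[K.FP_JUMP_GABA] = syn.gate_jump_gaba
    fp[K.FP_E_GABA] = syn.e_gaba
    fp[K.FP_TAU_STRESS] = stc.tau_stress
    fp[K.FP_TH1] = stc.threshold_initial
    fp[K.FP_TH2] = stc.threshold_late
    fp[K.FP_DA_CLAMP] = -1.0 if dac.clamp is None else dac.clamp
    fp[K.FP_DA0] = da0

    ther = cfg.therapy
    fp[K.FP_GI_FRAC] = 1.0 - ther.inhibition_pct / 100.0
    fp[K.FP_DAA] = ther.restore_pct / 100.0
    dbs = ther.dbs.resolved()
    a_stn, a_gpe = apply_antidromic_split(dbs)
    fp[K.FP_DBS_AMP_STN] = a_stn
    fp[K.FP_DBS_AMP_GPE] = a_gpe
    fp[K.FP_DBS_PERIOD] = 1000.0 / dbs.frequency_hz / dt
    fp[K.FP_DBS_PW] = dbs.pulse_width_ms / dt

    for name, sl in (("stn", (K.FP_A_STN, K.FP_B_STN, K.FP_C_STN, K.FP_D_STN, K.FP_I_STN)),
                     ("gpe", (K.FP_A_GPE, K.FP_B_GPE, K.FP_C_GPE, K.FP_D_GPE, K.FP_I_GPE)),
                     ("snc", (K.FP_A_SNC, K.FP_B_SNC, K.FP_C_SNC, K.FP_D_SNC, K.FP_I_SNC))):
        p = cfg.nuclei[name].izh
        fp[sl[0]], fp[sl[1]], fp[sl[2]], fp[sl[3]], fp[sl[4]] = p.a, p.b, p.c, p.d, p.i_ext
    fp[K.FP_VPEAK] = cfg.nuclei["stn"].izh.v_peak

    ip[K.IP_N_STEPS] = n_steps
    ip[K.IP_STEP0] = 0
    ip[K.IP_REC_EVERY] = max(1, int(round(plan.record_every_ms / dt)))
    ip[K.IP_SW] = int(round(stc.window_ms / dt))
    ip[K.IP_DW] = int(round(dac.window_ms / dt))
    ip[K.IP_SWITCH_STEP] = int(round(stc.switch_time_s * 1000.0 / dt))
    ip[K.IP_THERAPY] = THERAPY_CODES[ther.kind]
    ip[K.IP_N_I] = ther.stage_cells(cfg.nuclei["snc"].n)
    ip[K.IP_ROWS_STN] = cfg.nuclei["stn"].rows
    ip[K.IP_COLS_STN] = cfg.nuclei["stn"].cols
    ip[K.IP_ROWS_SNC] = cfg.nuclei["snc"].rows
    ip[K.IP_COLS_SNC] = cfg.nuclei["snc"].cols
    ip[K.IP_DBS_BIPHASIC] = 1 if dbs.waveform == "biphasic" else 0
    return fp, ip


def _split_raster(spk_t, spk_i, n_neurons, dt, duration_ms, death_ms, name):
    order = np.lexsort((spk_t, spk_i))
    t_sorted = spk_t[order] * dt
    i_sorted = spk_i[order]
    counts = np.bincount(i_sorted, minlength=n_neurons)
    splits = np.cumsum(counts)[:-1]
    trains = list(np.split(t_sorted.astype(float), splits))
    return SpikeRaster(spike_times=trains, duration_ms=duration_ms,
                       population=name, death_times_ms=death_ms)


def run_network(
    cfg: NetworkConfig,
    seed: int = 0,
    init: Optional[NetworkState] = None,
    spike_cap_hz: float = 200.0,
) -> SimulationRecord:
    """Simulate the full network for ``cfg.plan.duration_s`` seconds.

    ``seed`` drives the initial conditions and all therapy randomness
    (lesion subsets, failure masks).  ``init`` overrides the random initial
    state (used by consistency tests and resumed runs).
    """
    if (cfg.nuclei["gpe"].rows, cfg.nuclei["gpe"].cols) != (
        cfg.nuclei["stn"].rows, cfg.nuclei["stn"].cols
    ):
        raise ValueError("STN and GPe lattices must have equal shapes")
    ss = np.random.SeedSequence(seed)
    rng_init, rng_therapy = [np.random.default_rng(s) for s in ss.spawn(2)]

    bundle = build_connectivity(cfg.nuclei, cfg.connectivity)
    state = init if init is not None else initial_state(cfg, rng_init)

    plan = cfg.plan
    dt = plan.dt_ms
    n_steps = int(round(plan.duration_s * 1000.0 / dt))
    fp, ip = _pack_params(cfg, bundle, n_steps, da0=state.da)

    n_stn, n_gpe, n_snc = (cfg.nuclei[k].n for k in ("stn", "gpe", "snc"))
    v_stn = state.v["stn"].astype(float).copy()
    u_stn = state.u["stn"].astype(float).copy()
    v_gpe = state.v["gpe"].astype(float).copy()
    u_gpe = state.u["gpe"].astype(float).copy()
    v_snc = state.v["snc"].astype(float).copy()
    u_snc = state.u["snc"].astype(float).copy()
    alive_stn = state.alive["stn"].astype(np.uint8).copy()
    alive_snc = state.alive["snc"].astype(np.uint8).copy()
    h_ampa = state.gates["stn_ampa"].astype(float).copy()
    h_nmda = state.gates["stn_nmda"].astype(float).copy()
    h_gg = state.gates["gpe_gaba"].astype(float).copy()
    h_sg = state.gates["snc_gaba"].astype(float).copy()
    q = state.stress.astype(float).copy()
    if state.bias is not None:
        bias = {k: np.asarray(b, dtype=float).copy() for k, b in state.bias.items()}
    else:
        bias = {k: np.full(cfg.nuclei[k].n, cfg.nuclei[k].izh.i_ext) for k in cfg.nuclei}

    sw, dw = int(ip[K.IP_SW]), int(ip[K.IP_DW])
    sbuf = np.zeros((n_snc, sw), dtype=np.uint8)
    scnt = np.zeros(n_snc, dtype=np.int64)
    dbuf = np.zeros((n_snc, dw), dtype=np.uint8)
    dcnt = np.zeros(n_snc, dtype=np.int64)

    lesion_order = rng_therapy.permutation(n_stn).astype(np.int64)
    ip[K.IP_N_LESION] = int(cfg.therapy.lesion_pct * n_stn // 100)
    dbs = cfg.therapy.dbs.resolved()
    asf_mask = sample_failure_mask(n_stn, dbs.per_asf, rng_therapy).mask
    field_stn = dbs_spatial_field(bundle.layouts["stn"], dbs.contacts, dbs.sigma)
    field_gpe = dbs_spatial_field(bundle.layouts["gpe"], dbs.contacts, dbs.sigma_gpe)

    dur_s = plan.duration_s
    caps = {
        "stn": int(n_stn * spike_cap_hz * dur_s) + 1024,
        "gpe": int(n_gpe * spike_cap_hz * dur_s) + 1024,
        "snc": int(n_snc * spike_cap_hz * dur_s) + 64,
    }
    spk = {k: (np.empty(c, dtype=np.int64), np.empty(c, dtype=np.int64))
           for k, c in caps.items()}

    n_rec = n_steps // int(ip[K.IP_REC_EVERY]) + 1
    rec_da = np.zeros(n_rec)
    rec_da_eff = np.zeros(n_rec)
    rec_nsc = np.zeros(n_rec, dtype=np.int64)
    rec_q = np.zeros((n_rec, n_snc), dtype=np.float32)
    death_step = np.full(n_snc, -1, dtype=np.int64)

    status, trig_step, c_st, c_gp, c_sc, r_idx, da_f = K.run_loop(
        fp, ip,
        v_stn, u_stn, alive_stn, v_gpe, u_gpe, v_snc, u_snc, alive_snc,
        bias["stn"], bias["gpe"], bias["snc"],
        h_ampa, h_nmda, h_gg, h_sg,
        bundle.kernels["stn"].kernel1d, bundle.kernels["gpe"].kernel1d,
        bundle.kernels["snc"].kernel1d,
        bundle.stn_to_snc.sources,
        sbuf, scnt, q, dbuf, dcnt,
        lesion_order, asf_mask, field_stn, field_gpe,
        spk["stn"][0], spk["stn"][1], spk["gpe"][0], spk["gpe"][1],
        spk["snc"][0], spk["snc"][1],
        rec_da, rec_da_eff, rec_nsc, rec_q, death_step,
    )
    if status == K.STATUS_BLOWUP:
        raise RuntimeError(
            "numerical blow-up: |v| exceeded 1000 mV; check weights/dt")
    if status == K.STATUS_OVERFLOW:
        raise RuntimeError(
            "spike buffer overflow; raise spike_cap_hz for this configuration")

    duration_ms = plan.duration_s * 1000.0
    death_ms = {
        "snc": np.where(death_step >= 0, death_step * dt, np.inf),
        "stn": np.where(alive_stn > 0, np.inf,
                        (trig_step if trig_step >= 0 else 0) * dt),
    }
    rasters = {
        "stn": _split_raster(spk["stn"][0][:c_st], spk["stn"][1][:c_st],
                             n_stn, dt, duration_ms, death_ms["stn"], "stn"),
        "gpe": _split_raster(spk["gpe"][0][:c_gp], spk["gpe"][1][:c_gp],
                             n_gpe, dt, duration_ms, np.full(n_gpe, np.inf), "gpe"),
        "snc": _split_raster(spk["snc"][0][:c_sc], spk["snc"][1][:c_sc],
                             n_snc, dt, duration_ms, death_ms["snc"], "snc"),
    }
    rec_every = int(ip[K.IP_REC_EVERY])
    times_s = np.arange(r_idx) * rec_every * dt / 1000.0
    traces = pd.DataFrame({
        "time_s": times_s,
        "da": rec_da[:r_idx],
        "da_eff": rec_da_eff[:r_idx],
        "n_sc": rec_nsc[:r_idx],
    })
    final = NetworkState(
        v={"stn": v_stn, "gpe": v_gpe, "snc": v_snc},
        u={"stn": u_stn, "gpe": u_gpe, "snc": u_snc},
        gates={"stn_ampa": h_ampa, "stn_nmda": h_nmda,
               "gpe_gaba": h_gg, "snc_gaba": h_sg},
        alive={"stn": alive_stn.astype(bool), "snc": alive_snc.astype(bool)},
        stress=q, da=da_f, bias=bias,
    )
    return SimulationRecord(
        config=cfg, seed=seed, rasters=rasters, traces=traces,
        q_trace=rec_q[:r_idx],
        trigger_time_s=trig_step * dt / 1000.0 if trig_step >= 0 else np.nan,
        final_state=final, status=status,
    )


# ---------------------------------------------------------------------------
# Experiment harnesses
# ---------------------------------------------------------------------------


def run_sensitivity_sweep(
    axis: str,
    grid: Sequence[float],
    seeds: Sequence[int] = (0,),
    base_cfg: Optional[NetworkConfig] = None,
) -> pd.DataFrame:
    """Degeneration kinetics across a parameter grid.

    ``axis`` is ``"s_thres"`` (the late-phase stress threshold) or
    ``"w_stn_snc"``.  Each grid point is run with every seed on the
    scaled-down profile; the table reports t_1/2 and lambda per run.
    """
    if len(grid) < 1:
        raise ValueError("grid must be non-empty")
    rows = []
    for value in grid:
        for seed in seeds:
            cfg = base_cfg if base_cfg is not None else NetworkConfig.scaled_profile()
            cfg = dataclasses.replace(cfg)
            cfg = NetworkConfig.from_dict(cfg.to_dict())  # deep copy
            if axis == "s_thres":
                cfg.stress.threshold_late = float(value)
            elif axis == "w_stn_snc":
                cfg.plan.w_stn_snc_override = float(value)
            else:
                raise ValueError(f"unknown sweep axis {axis!r}")
            rec = run_network(cfg, seed=seed)
            kin = rec.kinetics()
            rows.append({
                "axis": axis, "value": float(value), "seed": seed,
                "t_half_s": kin.t_half_s, "lambda_per_s": kin.lam,
                "n_sc_end": int(rec.traces["n_sc"].iloc[-1]),
            })
    return pd.DataFrame(rows)


def run_therapy_grid(
    kind: str,
    stages: Sequence[float] = (25.0, 50.0, 75.0),
    doses: Sequence[float] = (10.0, 50.0, 90.0),
    seeds: Sequence[int] = (0,),
    base_cfg: Optional[NetworkConfig] = None,
    halt_grace_s: float = 1.0,
    thresholds: tuple[float, float] = (0.15, 0.85),
) -> pd.DataFrame:
    """Outcome matrix of one therapy over intervention stages and doses.

    Each run is classified by the end-of-run survival ratio against the
    untreated reference (same seed): ``forthwith`` (~0), ``delayed``
    (intermediate) or ``halted`` (~1).  A ``halted_plateau`` column applies
    the stricter plateau criterion (no loss from shortly after the trigger
    to the end of the run).
    """
    dose_field = {
        "glutamate_inhibition": "inhibition_pct",
        "dopamine_restoration": "restore_pct",
        "subthalamotomy": "lesion_pct",
        "dbs": "per_asf",
    }[kind]
    rows = []
    for seed in seeds:
        base = base_cfg if base_cfg is not None else NetworkConfig.scaled_profile()
        untreated_cfg = NetworkConfig.from_dict(base.to_dict())
        untreated_cfg.therapy = TherapyProtocol(kind="none")
        ref = run_network(untreated_cfg, seed=seed)
        t_ref, n_ref = ref.survival_course()
        for stage in stages:
            n_i = int(round(untreated_cfg.nuclei["snc"].n * (1 - stage / 100.0)))
            for dose in doses:
                cfg = NetworkConfig.from_dict(base.to_dict())
                cfg.therapy = TherapyProtocol(kind=kind, stage_pct=stage)
                if kind == "dbs":
                    cfg.therapy.dbs = dataclasses.replace(
                        cfg.therapy.dbs, per_asf=float(dose) / 100.0)
                else:
                    setattr(cfg.therapy, dose_field, float(dose))
                rec = run_network(cfg, seed=seed)
                t, n = rec.survival_course()
                ratio = survival_ratio(n[-1], n_ref[-1], n_i)
                trig = rec.trigger_time_s
                halted = (np.isfinite(trig)
                          and is_halted(t, n, trig, grace_s=halt_grace_s))
                lo, hi = thresholds
                if not np.isfinite(ratio):
                    label = "undefined"
                elif ratio <= lo:
                    label = "forthwith"
                elif ratio >= hi:
                    label = "halted"
                else:
                    label = "delayed"
                rows.append({
                    "kind": kind, "stage_pct": stage, "dose": dose,
                    "seed": seed, "trigger_time_s": trig,
                    "n_sc_end": int(n[-1]), "n_sc_end_untreated": int(n_ref[-1]),
                    "survival_ratio": ratio, "outcome": label,
                    "halted_plateau": bool(halted),
                })
    return pd.DataFrame(rows)
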