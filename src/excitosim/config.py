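"""Configuration objects for the basal-ganglia excitotoxicity simulator.

All tunable quantities of the model live here as plain dataclasses with the
published defaults: Izhikevich parameters, lattice geometry, receptor
kinetics, dopamine-coupling constants, the stress/apoptosis settings and the
therapy protocols.  Configurations round-trip through YAML so that every
simulation is fully described by a small text file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

# ---------------------------------------------------------------------------
# Neuron-level parameters
# ---------------------------------------------------------------------------

V_PEAK = 30.0  # spike cutoff (mV), common to all nuclei


@dataclass
class IzhikevichParams:
    """Two-variable Izhikevich neuron parameters for one nucleus.

    ``a`` (1/ms) sets the recovery time scale, ``b`` the recovery
    sensitivity, ``c`` (mV) the post-spike reset potential, ``d`` the
    recovery increment per spike, and ``i_ext`` the constant bias drive in
    nominal Izhikevich current units.
    """

    a: float
    b: float
    c: float
    d: float
    i_ext: float = 0.0
    v_peak: float = V_PEAK

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("recovery time scale a must be positive")
        if self.c >= self.v_peak:
            raise ValueError("reset potential c must lie below v_peak")


#: Published parameter rows for the three nuclei.
STN_PARAMS = IzhikevichParams(a=0.005, b=0.265, c=-65.0, d=1.5, i_ext=3.0)
SNC_PARAMS = IzhikevichParams(a=0.0025, b=0.2, c=-55.0, d=2.0, i_ext=9.0)
GPE_PARAMS = IzhikevichParams(a=0.1, b=0.2, c=-65.0, d=2.0, i_ext=4.25)

NEURON_PARAMS = {"stn": STN_PARAMS, "snc": SNC_PARAMS, "gpe": GPE_PARAMS}


@dataclass
class NucleusSpec:
    """Lattice geometry plus lateral-kernel parameters for one nucleus."""

    name: str
    rows: int
    cols: int
    izh: IzhikevichParams
    nlat: int       # side length of the square lateral neighborhood
    radius: float   # Gaussian radius R of the lateral kernel
    strength: float  # basal lateral strength A (== s_max at zero dopamine)
    bias_jitter: float = 0.0  # fractional cell-to-cell spread of i_ext

    @property
    def n(self) -> int:
        return self.rows * self.cols


def default_nuclei() -> dict[str, NucleusSpec]:
    """The 8x8 SNc / 32x32 STN / 32x32 GPe lattices with published laterals."""
    return {
        "stn": NucleusSpec("stn", 32, 32, STN_PARAMS, nlat=11, radius=1.4,
                           strength=1.3, bias_jitter=0.05),
        "snc": NucleusSpec("snc", 8, 8, SNC_PARAMS, nlat=5, radius=1.6,
                           strength=0.1, bias_jitter=0.08),
        "gpe": NucleusSpec("gpe", 32, 32, GPE_PARAMS, nlat=15, radius=1.6,
                           strength=0.1, bias_jitter=0.05),
    }


# ---------------------------------------------------------------------------
# Synapses
# ---------------------------------------------------------------------------


@dataclass
class SynapseConfig:
    """Receptor kinetics and the discrete spike-input convention.

    ``gate_jump_gaba``/``gate_jump_glu`` are the increments applied to a
    presynaptic gate when its neuron spikes; the gate then decays
    exponentially with the receptor time constant.  GABA gates use the
    standard unit-normalized convention.  The glutamatergic jump is the one
    calibrated scale constant of the synaptic model: it is chosen so that
    the published STN lateral strength places the dopamine-depleted STN at
    the edge of its synchronized-bursting regime while the dopamine-intact
    STN stays near its basal tonic rate.
    """

    tau_ampa: float = 6.0     # ms
    tau_nmda: float = 160.0   # ms
    tau_gaba: float = 4.0     # ms
    e_ampa: float = 0.0       # mV
    e_nmda: float = 0.0       # mV
    e_gaba: float = -60.0     # mV
    mg: float = 1.0           # magnesium concentration entering the NMDA block
    gate_jump_glu: float = 0.03
    gate_jump_gaba: float = 2.0


@dataclass
class ConnectivityConfig:
    """Base inter-nucleus weights W0.

    These are not published; the defaults were calibrated once so that the
    dopamine-intact network reproduces the basal population rates
    (~13 Hz STN, ~30 Hz GPe, SNc operating near the stress threshold).
    """

    w_stn_gpe: float = 0.5
    w_gpe_stn: float = 0.5
    w_stn_snc: float = 0.125


# ---------------------------------------------------------------------------
# Dopamine
# ---------------------------------------------------------------------------


@dataclass
class DopamineConfig:
    """Dopamine signal and its coupling to synaptic strengths.

    The instantaneous dopamine level is the SNc population rate (all lattice
    positions, dead cells counting zero) in a trailing ``window_ms`` window,
    divided by ``n_total * r_ref`` and clipped to [0, 1].  ``r_ref`` is the
    per-cell rate of the healthy network, so a fully intact SNc yields a
    dopamine level of ~1 and cell loss lowers it proportionally.
    """

    cd_stn: float = 2.2
    cd_gpe: float = 0.5
    cd_snc: float = 1.0
    cd2: float = 0.1
    r_ref: float = 12.0       # Hz, normalization of the SNc population rate
    window_ms: float = 100.0
    tau_da: float = 200.0     # ms, low-pass filter before modulation
    clamp: Optional[float] = None  # externally fixed DA level (sweeps)


# ---------------------------------------------------------------------------
# Stress / degeneration
# ---------------------------------------------------------------------------


@dataclass
class StressConfig:
    """Firing-history stress variable and the apoptosis threshold schedule.

    Each SNc neuron's stress Q relaxes toward its sliding-window firing rate
    with time constant ``tau_stress``; crossing the threshold kills the cell
    irreversibly.  ``threshold_initial`` applies from t=0, and
    ``threshold_late`` from ``switch_time_s`` onward (the energy-deficit
    phase of the three-phase experiment).
    """

    tau_stress: float = 1000.0    # ms
    window_ms: float = 1000.0     # rate window Delta-t
    threshold_initial: float = 11.3
    threshold_late: float = 10.8
    switch_time_s: float = 10.0


# ---------------------------------------------------------------------------
# Therapy
# ---------------------------------------------------------------------------

SCP_CONTACTS = ((16, 16),)
FCP_CONTACTS = ((8, 8), (8, 24), (24, 8), (24, 24))
DBS_SIGMA = {"scp": 5.0, "fcp": 2.0, "mcp": 0.0}


@dataclass
class DBSSettings:
    """Deep-brain-stimulation waveform, electrode geometry and side effects.

    Defaults follow the published stimulation table: 130 Hz pulses,
    monophasic amplitude 650 / biphasic 1000 (model current units), spatial
    spread sigma of 5 (single contact), 2 (four contacts) or uniform
    stimulation for the all-point configuration.  Pulse widths are 100 us
    (monophasic) and 200 us (biphasic), the clinical scale.
    """

    waveform: str = "biphasic"          # "monophasic" | "biphasic"
    configuration: str = "fcp"          # "scp" | "fcp" | "mcp"
    amplitude: Optional[float] = None   # defaults by waveform if None
    frequency_hz: float = 130.0
    pulse_width_ms: Optional[float] = None  # defaults by waveform if None
    sigma: Optional[float] = None           # defaults by configuration if None
    sigma_gpe: Optional[float] = None       # defaults to sigma if None
    contacts: Optional[Sequence[tuple[int, int]]] = None
    per_aa: float = 0.0    # antidromic fraction routed to GPe
    per_asf: float = 0.0   # fraction of STN efferents failing while DBS is on

    def resolved(self) -> "DBSSettings":
        """Fill waveform/configuration-dependent defaults."""
        out = dataclasses.replace(self)
        if out.amplitude is None:
            out.amplitude = 1000.0 if out.waveform == "biphasic" else 650.0
        if out.pulse_width_ms is None:
            out.pulse_width_ms = 0.2 if out.waveform == "biphasic" else 0.1
        if out.sigma is None:
            out.sigma = DBS_SIGMA[out.configuration]
        if out.sigma_gpe is None:
            out.sigma_gpe = out.sigma
        if out.contacts is None:
            if out.configuration == "scp":
                out.contacts = SCP_CONTACTS
            elif out.configuration == "fcp":
                out.contacts = FCP_CONTACTS
            else:
                out.contacts = ()  # uniform field, no discrete contacts
        return out


@dataclass
class TherapyProtocol:
    """Which intervention to apply and when.

    The intervention latches on the first time the surviving SNc count
    drops to ``stage_cells`` (25/50/75 % loss of 64 cells -> 48/32/16
    survivors) and stays active for the rest of the run.
    """

    kind: str = "none"  # none | glutamate_inhibition | dopamine_restoration | subthalamotomy | dbs
    stage_pct: float = 25.0      # percentage of SNc cell loss at intervention
    inhibition_pct: float = 0.0  # glutamate inhibition dose
    restore_pct: float = 0.0     # dopamine restoration dose
    lesion_pct: float = 0.0      # subthalamotomy lesion percentage
    dbs: DBSSettings = field(default_factory=DBSSettings)

    def stage_cells(self, n_total: int = 64) -> int:
        """Surviving-cell count at which the intervention triggers."""
        return int(round(n_total * (1.0 - self.stage_pct / 100.0)))


# ---------------------------------------------------------------------------
# Experiment plan / top-level config
# ---------------------------------------------------------------------------


@dataclass
class ExperimentPlan:
    """Duration, output cadence and sweep overrides for one simulation."""

    duration_s: float = 50.0
    dt_ms: float = 0.1
    record_every_ms: float = 10.0
    w_stn_snc_override: Optional[float] = None  # sensitivity-sweep axis


@dataclass
class NetworkConfig:
    """Complete description of one network simulation."""

    nuclei: dict[str, NucleusSpec] = field(default_factory=default_nuclei)
    synapse: SynapseConfig = field(default_factory=SynapseConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    dopamine: DopamineConfig = field(default_factory=DopamineConfig)
    stress: StressConfig = field(default_factory=StressConfig)
    therapy: TherapyProtocol = field(default_factory=TherapyProtocol)
    plan: ExperimentPlan = field(default_factory=ExperimentPlan)

    # -- profiles ----------------------------------------------------------

    @classmethod
    def full_profile(cls) -> "NetworkConfig":
        """The 50-s three-phase excitotoxicity experiment at full size."""
        return cls()

    @classmethod
    def scaled_profile(cls) -> "NetworkConfig":
        """A shorter degeneration run for sweeps and therapy grids.

        Same lattices and physics on a compressed disease course: the
        energy-deficit threshold drop comes at 2 s and is deeper, and the
        STN->SNc weight is raised so that the pathological drive holds every
        SNc cell above the lowered threshold.  The full degeneration course
        then fits in 14 s of simulated time while keeping the distinction
        between reducing the excitatory drive (which can arrest the loss)
        and restoring dopamine (which cannot).
        """
        cfg = cls()
        cfg.plan = ExperimentPlan(duration_s=14.0)
        cfg.connectivity.w_stn_snc = 0.25
        cfg.dopamine = DopamineConfig(r_ref=10.0)
        cfg.stress = StressConfig(
            threshold_initial=11.3,
            threshold_late=10.5,
            switch_time_s=2.0,
        )
        return cfg

    # -- YAML round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "NetworkConfig":
        def build(tp, payload):
            kwargs = {}
            for f in dataclasses.fields(tp):
                if f.name not in payload:
                    continue
                val = payload[f.name]
                sub = _NESTED.get((tp, f.name))
                if sub is not None and isinstance(val, dict):
                    val = build(sub, val)
                kwargs[f.name] = val
            return tp(**kwargs)

        _NESTED = {
            (NetworkConfig, "synapse"): SynapseConfig,
            (NetworkConfig, "connectivity"): ConnectivityConfig,
            (NetworkConfig, "dopamine"): DopamineConfig,
            (NetworkConfig, "stress"): StressConfig,
            (NetworkConfig, "therapy"): TherapyProtocol,
            (NetworkConfig, "plan"): ExperimentPlan,
            (TherapyProtocol, "dbs"): DBSSettings,
            (NucleusSpec, "izh"): IzhikevichParams,
        }
        data = dict(data)
        nuclei = {}
        for name, spec in data.pop("nuclei", {}).items():
            spec = dict(spec)
            izh = IzhikevichParams(**spec.pop("izh"))
            nuclei[name] = NucleusSpec(izh=izh, **spec)
        cfg = build(NetworkConfig, data)
        if nuclei:
            cfg.nuclei = nuclei
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
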