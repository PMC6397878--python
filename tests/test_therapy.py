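"""Intervention protocols: triggers, doses, DBS waveforms and failures."""

import numpy as np
import pytest

from excitosim import (
    apply_antidromic_split,
    apply_dopamine_restoration,
    apply_failure_mask,
    apply_glutamate_inhibition,
    apply_subthalamotomy,
    generate_pulse_train,
    sample_failure_mask,
)
from excitosim.config import DBSSettings, TherapyProtocol
from excitosim.connectivity import LatticeLayout
from excitosim.therapy import dbs_current_field, dbs_spatial_field, lesion_count


def test_stage_cell_counts():
    assert TherapyProtocol(stage_pct=25.0).stage_cells(64) == 48
    assert TherapyProtocol(stage_pct=50.0).stage_cells(64) == 32
    assert TherapyProtocol(stage_pct=75.0).stage_cells(64) == 16


# -- glutamate inhibition ----------------------------------------------------


def test_gi_inactive_before_trigger():
    assert apply_glutamate_inhibition(0.14, n_sc=50, n_i=48, inhibition_pct=90.0) == 0.14


@pytest.mark.parametrize("dose,residual", [(0.0, 1.0), (90.0, 0.1), (100.0, 0.0)])
def test_gi_residual_factor(dose, residual):
    w = apply_glutamate_inhibition(1.0, n_sc=40, n_i=48, inhibition_pct=dose)
    assert w == pytest.approx(residual)


# -- dopamine restoration ----------------------------------------------------


def test_dr_identity_and_addition():
    assert apply_dopamine_restoration(0.2, 50, 48, 50.0) == pytest.approx(0.2)
    assert apply_dopamine_restoration(0.2, 40, 48, 50.0) == pytest.approx(0.7)
    assert apply_dopamine_restoration(0.4, 40, 48, 100.0) == 1.0  # clipped
    assert apply_dopamine_restoration(0.2, 40, 48, 0.0) == pytest.approx(0.2)


# -- subthalamotomy ----------------------------------------------------------


def test_lesion_counts():
    assert lesion_count(5.0) == 51
    assert lesion_count(100.0) == 1024
    assert lesion_count(0.0) == 0


def test_subthalamotomy_trigger_and_size():
    rng = np.random.default_rng(0)
    alive = np.ones(1024, bool)
    before = apply_subthalamotomy(alive, n_sc=50, n_i=48, p_les=40.0, rng=rng)
    assert before.all()
    after = apply_subthalamotomy(alive, n_sc=48, n_i=48, p_les=40.0, rng=rng)
    assert (~after).sum() == 409  # floor(40 * 1024 / 100)


def test_subthalamotomy_seeded_reproducible():
    a = apply_subthalamotomy(np.ones(1024, bool), 40, 48, 20.0, np.random.default_rng(7))
    b = apply_subthalamotomy(np.ones(1024, bool), 40, 48, 20.0, np.random.default_rng(7))
    assert np.array_equal(a, b)


# -- DBS waveforms -----------------------------------------------------------


def test_pulse_onset_interval_at_130hz():
    s = DBSSettings(waveform="monophasic", configuration="scp")
    t = np.arange(0.0, 100.0, 0.01)
    p = generate_pulse_train(s, t)
    onsets = t[(p > 0) & (np.roll(p, 1) <= 0)]
    assert np.allclose(np.diff(onsets), 1000.0 / 130.0, atol=0.02)


def test_monophasic_zero_between_pulses():
    s = DBSSettings(waveform="monophasic").resolved()
    mid = 1000.0 / 130.0 / 2.0  # between onsets
    assert generate_pulse_train(s, mid) == 0.0
    assert generate_pulse_train(s, 0.05) == 650.0


def test_biphasic_charge_balance():
    s = DBSSettings(waveform="biphasic")
    dt = 1e-4
    t = np.arange(0.0, 1000.0 / 130.0, dt)  # one full period
    p = generate_pulse_train(s, t)
    assert abs(np.sum(p) * dt) < 1e-6 * 1000.0
    assert p.max() == 1000.0 and p.min() == -1000.0


def test_pulse_width_must_fit_period():
    s = DBSSettings(waveform="monophasic", pulse_width_ms=10.0)
    with pytest.raises(ValueError):
        generate_pulse_train(s, 0.0)


# -- DBS fields --------------------------------------------------------------


@pytest.fixture(scope="module")
def stn_layout():
    return LatticeLayout("stn", 32, 32)


def test_scp_field_at_contact_and_distance(stn_layout):
    field = dbs_spatial_field(stn_layout, [(16, 16)], sigma=5.0)
    at_contact = field[16 * 32 + 16]
    assert at_contact == pytest.approx(1.0)
    at_d5 = field[21 * 32 + 16]  # distance^2 = 25
    assert at_d5 == pytest.approx(np.exp(-1.0))


def test_fcp_center_receives_negligible_current(stn_layout):
    s = DBSSettings(waveform="monophasic", configuration="fcp").resolved()
    field = dbs_spatial_field(stn_layout, s.contacts, s.sigma)
    center = field[16 * 32 + 16]  # d^2 = 128 from each of the 4 contacts
    assert center == pytest.approx(4.0 * np.exp(-128.0 / 4.0), rel=1e-9)
    assert center < 1e-10


def test_mcp_field_is_uniform(stn_layout):
    s = DBSSettings(configuration="mcp").resolved()
    field = dbs_spatial_field(stn_layout, s.contacts, s.sigma)
    assert np.all(field == 1.0)


def test_field_validation(stn_layout):
    with pytest.raises(ValueError):
        dbs_spatial_field(stn_layout, [(40, 0)], sigma=5.0)
    with pytest.raises(ValueError):
        dbs_spatial_field(stn_layout, [(0, 0)], sigma=-1.0)


def test_dbs_current_field_is_pulse_times_field(stn_layout):
    s = DBSSettings(waveform="monophasic", configuration="scp")
    cur = dbs_current_field(s, stn_layout, t_ms=0.05)
    assert cur[16 * 32 + 16] == pytest.approx(650.0)


# -- antidromic split and failures -------------------------------------------


@pytest.mark.parametrize("per_aa,expect", [(0.0, (1000.0, 0.0)),
                                           (1.0, (0.0, 1000.0)),
                                           (0.25, (750.0, 250.0))])
def test_antidromic_split(per_aa, expect):
    s = DBSSettings(waveform="biphasic", per_aa=per_aa)
    assert apply_antidromic_split(s) == pytest.approx(expect)


def test_failure_mask_counts_and_application():
    rng = np.random.default_rng(3)
    mask = sample_failure_mask(1024, 0.5, rng)
    assert (mask.mask == 0).sum() == 512
    w = np.full(1024, 0.14)
    off = apply_failure_mask(w, mask, dbs_on=False)
    assert np.array_equal(off, w)
    on = apply_failure_mask(w, mask, dbs_on=True)
    assert (on == 0).sum() == 512
    assert np.allclose(on[mask.mask == 1], 0.14)


def test_failure_mask_extremes():
    rng = np.random.default_rng(0)
    assert (sample_failure_mask(1024, 0.0, rng).mask == 1).all()
    assert (sample_failure_mask(1024, 1.0, rng).mask == 0).all()
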