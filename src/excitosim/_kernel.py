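"""Compiled inner loop of the network simulation.

Everything here is numba-jitted and operates on flat arrays prepared by
:mod:`excitosim.engine`.  The physics per step, in order: dopamine signal
from the SNc spike-count window -> dopamine-modulated lateral strengths and
afferent scaling -> synaptic currents (separable Gaussian lateral
convolutions, one-to-one STN<->GPe maps, block-convergent STN->SNc map,
NMDA magnesium block) -> Izhikevich update with spike reset -> gate decay /
spike increments -> stress update and apoptosis -> therapy trigger check.

Scalar parameters are packed into ``fp`` (float) and ``ip`` (int) vectors;
the index constants below name the slots.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# float parameter slots
FP_DT = 0
FP_R_REF = 1
FP_TAU_DA = 2
FP_CD_STN = 3
FP_CD_GPE = 4
FP_CD_SNC = 5
FP_CD2 = 6
FP_SMAX_STN = 7
FP_SMAX_GPE = 8
FP_SMAX_SNC = 9
FP_W_STN_GPE = 10
FP_W_GPE_STN = 11
FP_W_STN_SNC = 12
FP_MG = 13
FP_TAU_AMPA = 14
FP_TAU_NMDA = 15
FP_TAU_GABA = 16
FP_JUMP_GLU = 17
FP_E_GABA = 18
FP_TAU_STRESS = 19
FP_TH1 = 20
FP_TH2 = 21
FP_GI_FRAC = 22
FP_DAA = 23
FP_DBS_AMP_STN = 24
FP_DBS_AMP_GPE = 25
FP_DBS_PERIOD = 26  # steps (float)
FP_DBS_PW = 27      # steps (float)
FP_DA_CLAMP = 28    # < 0 means endogenous dopamine
FP_A_STN = 29
FP_B_STN = 30
FP_C_STN = 31
FP_D_STN = 32
FP_I_STN = 33
FP_A_GPE = 34
FP_B_GPE = 35
FP_C_GPE = 36
FP_D_GPE = 37
FP_I_GPE = 38
FP_A_SNC = 39
FP_B_SNC = 40
FP_C_SNC = 41
FP_D_SNC = 42
FP_I_SNC = 43
FP_VPEAK = 44
FP_DA0 = 45  # initial filtered dopamine level
FP_JUMP_GABA = 46
N_FP = 47

# int parameter slots
IP_N_STEPS = 0
IP_STEP0 = 1        # absolute step offset (time origin)
IP_REC_EVERY = 2
IP_SW = 3           # stress window length, steps
IP_DW = 4           # dopamine window length, steps
IP_SWITCH_STEP = 5  # threshold switch, absolute step
IP_THERAPY = 6      # 0 none, 1 GI, 2 DR, 3 lesion, 4 DBS
IP_N_I = 7          # trigger stage (surviving cells)
IP_N_LESION = 8
IP_ROWS_STN = 9
IP_COLS_STN = 10
IP_ROWS_SNC = 11
IP_COLS_SNC = 12
IP_DBS_BIPHASIC = 13
N_IP = 14

STATUS_OK = 0
STATUS_BLOWUP = 1
STATUS_OVERFLOW = 2


@njit(cache=False, fastmath=True)
def _sepconv(field, k, out, tmp):
    """Separable windowed correlation with zero padding at the edges."""
    n1, n2 = field.shape
    m = k.size
    c = m // 2
    for i in range(n1):
        for j in range(n2):
            s = 0.0
            for d in range(m):
                jj = j + d - c
                if 0 <= jj < n2:
                    s += k[d] * field[i, jj]
            tmp[i, j] = s
    for i in range(n1):
        for j in range(n2):
            s = 0.0
            for d in range(m):
                ii = i + d - c
                if 0 <= ii < n1:
                    s += k[d] * tmp[ii, j]
            out[i, j] = s


@njit(cache=False, fastmath={'contract', 'reassoc', 'arcp'})
def run_loop(
    fp, ip,
    v_stn, u_stn, alive_stn,
    v_gpe, u_gpe,
    v_snc, u_snc, alive_snc,
    bias_stn, bias_gpe, bias_snc,
    h_ampa, h_nmda, h_gg, h_sg,
    k_stn, k_gpe, k_snc,
    snc_src,
    sbuf, scnt, q,
    dbuf, dcnt,
    lesion_order, asf_mask,
    field_stn, field_gpe,
    spk_t_stn, spk_i_stn, spk_t_gpe, spk_i_gpe, spk_t_snc, spk_i_snc,
    rec_da, rec_da_eff, rec_nsc, rec_q,
    death_step,
):
    dt = fp[FP_DT]
    n_steps = ip[IP_N_STEPS]
    step0 = ip[IP_STEP0]
    n_stn = v_stn.size
    n_gpe = v_gpe.size
    n_snc = v_snc.size
    rows_stn, cols_stn = ip[IP_ROWS_STN], ip[IP_COLS_STN]
    rows_snc, cols_snc = ip[IP_ROWS_SNC], ip[IP_COLS_SNC]
    sw, dw = ip[IP_SW], ip[IP_DW]

    tmp_stn = np.zeros((rows_stn, cols_stn))
    out_a = np.zeros((rows_stn, cols_stn))
    out_n = np.zeros((rows_stn, cols_stn))
    out_g = np.zeros((rows_stn, cols_stn))
    tmp_snc = np.zeros((rows_snc, cols_snc))
    out_s = np.zeros((rows_snc, cols_snc))

    i_stn = np.zeros(n_stn)
    i_gpe = np.zeros(n_gpe)
    i_snc = np.zeros(n_snc)
    spiked_stn = np.zeros(n_stn, dtype=np.uint8)
    spiked_gpe = np.zeros(n_gpe, dtype=np.uint8)
    spiked_snc = np.zeros(n_snc, dtype=np.uint8)

    mg = fp[FP_MG]
    e_gaba = fp[FP_E_GABA]
    da_f = fp[FP_DA0]

    dec_a = 1.0 - dt / fp[FP_TAU_AMPA]
    dec_n = 1.0 - dt / fp[FP_TAU_NMDA]
    dec_g = 1.0 - dt / fp[FP_TAU_GABA]
    jump_glu = fp[FP_JUMP_GLU]
    jump_gaba = fp[FP_JUMP_GABA]

    n_sc = 0
    for m in range(n_snc):
        if alive_snc[m]:
            n_sc += 1

    fa = h_ampa.reshape(rows_stn, cols_stn)
    fn = h_nmda.reshape(rows_stn, cols_stn)
    fg = h_gg.reshape(rows_stn, cols_stn)  # GPe lattice == STN lattice
    fs = h_sg.reshape(rows_snc, cols_snc)
    lat_a = out_a.reshape(n_stn)
    lat_n = out_n.reshape(n_stn)
    lat_g = out_g.reshape(n_gpe)
    lat_s = out_s.reshape(n_snc)

    triggered = False
    trig_step = np.int64(-1)
    dbs_on = False
    dbs_start = np.int64(0)
    therapy = ip[IP_THERAPY]

    c_st = 0
    c_gp = 0
    c_sc = 0
    r_idx = 0
    status = STATUS_OK

    for s in range(n_steps):
        step_abs = step0 + s

        # --- dopamine signal ------------------------------------------------
        tot = 0.0
        for m in range(n_snc):
            if alive_snc[m]:
                tot += dcnt[m]
        rate_pop = tot / (dw * dt / 1000.0) / n_snc  # Hz per lattice site
        da_raw = rate_pop / fp[FP_R_REF]
        if da_raw > 1.0:
            da_raw = 1.0
        da_f += (dt / fp[FP_TAU_DA]) * (da_raw - da_f)
        da_eff = da_f
        if fp[FP_DA_CLAMP] >= 0.0:
            da_eff = fp[FP_DA_CLAMP]
        if therapy == 2 and triggered:
            da_eff = min(da_eff + fp[FP_DAA], 1.0)

        a_stn_eff = fp[FP_SMAX_STN] * np.exp(-fp[FP_CD_STN] * da_eff)
        a_gpe_eff = fp[FP_SMAX_GPE] * np.exp(fp[FP_CD_GPE] * da_eff)
        a_snc_eff = fp[FP_SMAX_SNC] * np.exp(fp[FP_CD_SNC] * da_eff)
        wfac = 1.0 - fp[FP_CD2] * da_eff

        w_snc_eff = fp[FP_W_STN_SNC]
        if therapy == 1 and triggered:
            w_snc_eff *= fp[FP_GI_FRAC]

        # --- DBS pulse ------------------------------------------------------
        pulse_stn = 0.0
        pulse_gpe = 0.0
        if dbs_on:
            phase = (s - dbs_start) % fp[FP_DBS_PERIOD]
            pw = fp[FP_DBS_PW]
            val = 0.0
            if ip[IP_DBS_BIPHASIC] == 1:
                if phase < 0.5 * pw:
                    val = 1.0
                elif phase < pw:
                    val = -1.0
            else:
                if phase < pw:
                    val = 1.0
            pulse_stn = val * fp[FP_DBS_AMP_STN]
            pulse_gpe = val * fp[FP_DBS_AMP_GPE]

        # --- lateral sums ---------------------------------------------------
        _sepconv(fa, k_stn, out_a, tmp_stn)
        _sepconv(fn, k_stn, out_n, tmp_stn)
        _sepconv(fg, k_gpe, out_g, tmp_stn)
        _sepconv(fs, k_snc, out_s, tmp_snc)

        # --- currents + membrane update + spike recording ---------------------
        # (currents only read gates and each nucleus's own voltage, so the
        # per-nucleus fusion is exact; gate updates follow afterwards)
        half = 0.5 * dt
        w_gpe_stn = fp[FP_W_GPE_STN]
        w_stn_gpe = fp[FP_W_STN_GPE]
        for n in range(n_stn):
            spiked_stn[n] = 0
            if not alive_stn[n]:
                continue
            v = v_stn[n]
            b = 1.0 / (1.0 + (mg / 3.57) * np.exp(-0.062 * v))
            la = lat_a[n] - h_ampa[n]
            ln = lat_n[n] - h_nmda[n]
            cur = wfac * (
                a_stn_eff * (la + b * ln) * (0.0 - v)
                + w_gpe_stn * h_gg[n] * (e_gaba - v)
            )
            if dbs_on:
                cur += pulse_stn * field_stn[n]
            u = u_stn[n]
            drive = bias_stn[n] + cur
            v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + drive)
            v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + drive)
            u += dt * fp[FP_A_STN] * (fp[FP_B_STN] * v - u)
            if v >= fp[FP_VPEAK]:
                v = fp[FP_C_STN]
                u += fp[FP_D_STN]
                spiked_stn[n] = 1
                if c_st >= spk_t_stn.size:
                    status = STATUS_OVERFLOW
                else:
                    spk_t_stn[c_st] = step_abs + 1
                    spk_i_stn[c_st] = n
                    c_st += 1
            if not (-1e3 < v < 1e3):  # catches NaN as well
                status = STATUS_BLOWUP
            v_stn[n] = v
            u_stn[n] = u

        for n in range(n_gpe):
            spiked_gpe[n] = 0
            v = v_gpe[n]
            b = 1.0 / (1.0 + (mg / 3.57) * np.exp(-0.062 * v))
            lg = lat_g[n] - h_gg[n]
            ha = h_ampa[n]
            hn = h_nmda[n]
            if dbs_on:
                ha *= asf_mask[n]
                hn *= asf_mask[n]
            cur = wfac * (
                a_gpe_eff * lg * (e_gaba - v)
                + w_stn_gpe * (ha + b * hn) * (0.0 - v)
            )
            if dbs_on:
                cur += pulse_gpe * field_gpe[n]
            u = u_gpe[n]
            drive = bias_gpe[n] + cur
            v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + drive)
            v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + drive)
            u += dt * fp[FP_A_GPE] * (fp[FP_B_GPE] * v - u)
            if v >= fp[FP_VPEAK]:
                v = fp[FP_C_GPE]
                u += fp[FP_D_GPE]
                spiked_gpe[n] = 1
                if c_gp >= spk_t_gpe.size:
                    status = STATUS_OVERFLOW
                else:
                    spk_t_gpe[c_gp] = step_abs + 1
                    spk_i_gpe[c_gp] = n
                    c_gp += 1
            if not (-1e3 < v < 1e3):  # catches NaN as well
                status = STATUS_BLOWUP
            v_gpe[n] = v
            u_gpe[n] = u

        for m in range(n_snc):
            spiked_snc[m] = 0
            if not alive_snc[m]:
                continue
            v = v_snc[m]
            b = 1.0 / (1.0 + (mg / 3.57) * np.exp(-0.062 * v))
            suma = 0.0
            sumn = 0.0
            for kk in range(snc_src.shape[1]):
                j = snc_src[m, kk]
                if dbs_on:
                    suma += h_ampa[j] * asf_mask[j]
                    sumn += h_nmda[j] * asf_mask[j]
                else:
                    suma += h_ampa[j]
                    sumn += h_nmda[j]
            ls = lat_s[m] - h_sg[m]
            cur = wfac * (
                a_snc_eff * ls * (e_gaba - v)
                + w_snc_eff * (suma + b * sumn) * (0.0 - v)
            )
            u = u_snc[m]
            drive = bias_snc[m] + cur
            v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + drive)
            v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + drive)
            u += dt * fp[FP_A_SNC] * (fp[FP_B_SNC] * v - u)
            if v >= fp[FP_VPEAK]:
                v = fp[FP_C_SNC]
                u += fp[FP_D_SNC]
                spiked_snc[m] = 1
                if c_sc >= spk_t_snc.size:
                    status = STATUS_OVERFLOW
                else:
                    spk_t_snc[c_sc] = step_abs + 1
                    spk_i_snc[c_sc] = m
                    c_sc += 1
            if not (-1e3 < v < 1e3):  # catches NaN as well
                status = STATUS_BLOWUP
            v_snc[m] = v
            u_snc[m] = u

        if status != STATUS_OK:
            break

        # --- gate updates -----------------------------------------------------
        for n in range(n_stn):
            if alive_stn[n]:
                h_ampa[n] = h_ampa[n] * dec_a + jump_glu * spiked_stn[n]
                h_nmda[n] = h_nmda[n] * dec_n + jump_glu * spiked_stn[n]
            else:
                h_ampa[n] = 0.0
                h_nmda[n] = 0.0
        for n in range(n_gpe):
            h_gg[n] = h_gg[n] * dec_g + jump_gaba * spiked_gpe[n]
        for m in range(n_snc):
            if alive_snc[m]:
                h_sg[m] = h_sg[m] * dec_g + jump_gaba * spiked_snc[m]
            else:
                h_sg[m] = 0.0

        # --- stress and dopamine windows --------------------------------------
        pos_s = step_abs % sw
        pos_d = step_abs % dw
        inv_win_s = 1000.0 / (sw * dt)
        for m in range(n_snc):
            spk = spiked_snc[m]
            scnt[m] += spk - sbuf[m, pos_s]
            sbuf[m, pos_s] = spk
            dcnt[m] += spk - dbuf[m, pos_d]
            dbuf[m, pos_d] = spk
            if alive_snc[m]:
                r = scnt[m] * inv_win_s
                q[m] += (dt / fp[FP_TAU_STRESS]) * (r - q[m])

        # --- apoptosis --------------------------------------------------------
        th = fp[FP_TH1] if step_abs < ip[IP_SWITCH_STEP] else fp[FP_TH2]
        for m in range(n_snc):
            if alive_snc[m] and q[m] > th:
                alive_snc[m] = 0
                v_snc[m] = 0.0
                h_sg[m] = 0.0
                scnt[m] = 0
                dcnt[m] = 0
                for kk in range(sw):
                    sbuf[m, kk] = 0
                for kk in range(dw):
                    dbuf[m, kk] = 0
                death_step[m] = step_abs + 1
                n_sc -= 1

        # --- therapy trigger --------------------------------------------------
        if therapy > 0 and not triggered and n_sc <= ip[IP_N_I]:
            triggered = True
            trig_step = step_abs + 1
            if therapy == 3:
                for kk in range(ip[IP_N_LESION]):
                    idx = lesion_order[kk]
                    alive_stn[idx] = 0
                    v_stn[idx] = fp[FP_C_STN]
                    h_ampa[idx] = 0.0
                    h_nmda[idx] = 0.0
            elif therapy == 4:
                dbs_on = True
                dbs_start = s

        # --- recording --------------------------------------------------------
        if s % ip[IP_REC_EVERY] == 0:
            rec_da[r_idx] = da_raw
            rec_da_eff[r_idx] = da_eff
            rec_nsc[r_idx] = n_sc
            for m in range(n_snc):
                rec_q[r_idx, m] = q[m]
            r_idx += 1

    return status, trig_step, c_st, c_gp, c_sc, r_idx, da_f
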