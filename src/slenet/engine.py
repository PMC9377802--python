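"""Fixed-step integrator for the coupled membrane / ion / volume system.

One 0.05 ms step advances, in order: (1) gating variables by exponential
integration at the current voltage, (2) membrane potentials by a backward
(linearised-conductance) update — the soma-dendrite pair is solved as a
2x2 linear system, (3) synaptic conductance states and spike-triggered
event routing, (4) concentrations, glial buffer and volumes by a forward
update using start-of-step currents.  The fast membrane subsystem is the
stiff part and is treated implicitly; the slow accumulation variables are
kept explicit so that every flux is accounted for exactly once.

The whole loop is compiled with numba; identical inputs (state + seed)
give bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import constants as cn
from .biophysics import _ca_free, glia_k2
from .gating import gate_inf_tau
from .network import (CELL, IN_INDEX, KIND, NCOMP, PARTNER, PY_DENDRITES,
                      PY_SOMATA, NetworkModel, NetworkState, RunSpec, SOMATA)

# slow-record channels
(SL_CI_NA, SL_CI_K, SL_CI_CL, SL_CI_CA, SL_CI_A,
 SL_CO_NA, SL_CO_K, SL_CO_CL, SL_CO_CA, SL_CO_A,
 SL_VI, SL_VO, SL_B, SL_IPUMP, SL_IKCC2, SL_IGABA,
 SL_CAF, SL_GE, SL_GI) = range(19)
NSLOW = 19

_RTF = cn.RTF
_JFAC = cn.JFAC
_P = cn.P_HCO3
_EHCO3 = -_RTF * math.log(cn.HCO3_OUT / cn.HCO3_IN)  # z = -1

# indices into the conductance matrix (biophysics.CURRENTS order)
(IC_NA, IC_NAP, IC_KDR, IC_CAL, IC_KAHP, IC_KC, IC_KM,
 IC_LNA, IC_LK, IC_LCL) = range(10)


@njit(cache=True)
def _run(nsteps, dt, kind, partner, gcur, imax_pump, imax_capump, u_kcc2,
         gc_dens, surface, area_cm2, vi0, vo0, cabuf_total, ca_kd,
         ca_pump_km, km_k, km_na, b_max, k1_glia,
         long_pairs, long_s_in, long_s_out, long_dist,
         rad_pairs, rad_contact, rad_dist,
         bath_surface, bath_dr, bath_conc, diff_coef,
         w_exc, w_inh, syn_norm, tau1, tau2, e_exc,
         inj_dc, ramp_on, ramp_t0, ramp_dur, ramp_dens,
         probe_on, probe_period, probe_start, probe_w,
         ev_step, ev_comp, w_input, spike_thresh,
         flags, clamp_i, clamp_o,
         tr_side, tr_sp, tr_comp, tr_off, tr_t, tr_v,
         v, gates, ci, co, b_glia, vi, vo, syn, last_spike,
         fast_stride, slow_stride, v_rec, imem_rec, slow_rec,
         spike_t, spike_c):
    (f_syn, f_pump, f_kcc2, f_glia, f_bath, f_vol, f_ldiff, f_rdiff,
     f_gaba_flux, f_ion) = (flags[0], flags[1], flags[2], flags[3], flags[4],
                            flags[5], flags[6], flags[7], flags[8], flags[9])
    a_imp = cn.CM / (cn.VFAC * dt)
    dec1 = math.exp(-dt / tau1)
    dec2 = math.exp(-dt / tau2)
    ntraj = tr_side.shape[0]

    v_old = np.empty(NCOMP)
    ena = np.empty(NCOMP); ek = np.empty(NCOMP); ecl = np.empty(NCOMP)
    eca = np.empty(NCOMP); egaba = np.empty(NCOMP); caf = np.empty(NCOMP)
    g_tot = np.empty(NCOMP); drive = np.empty(NCOMP)
    i_na = np.empty(NCOMP); i_k = np.empty(NCOMP)
    i_cl = np.empty(NCOMP); i_ca = np.empty(NCOMP)
    i_hco3 = np.empty(NCOMP); i_pump_net = np.empty(NCOMP)
    ik_kcc2_arr = np.empty(NCOMP); gi_dens_arr = np.empty(NCOMP)
    ge_us_arr = np.empty(NCOMP); gi_us_arr = np.empty(NCOMP)
    dci = np.empty((NCOMP, 5)); dco = np.empty((NCOMP, 5))
    n_spk = 0
    ev_ptr = 0
    status = 0
    t_fail = -1.0

    for k in range(nsteps):
        t = k * dt
        # externally imposed concentration trajectories
        for j in range(ntraj):
            lo = tr_off[j]; hi = tr_off[j + 1]
            if t <= tr_t[lo]:
                val = tr_v[lo]
            elif t >= tr_t[hi - 1]:
                val = tr_v[hi - 1]
            else:
                idx = lo
                while tr_t[idx + 1] < t:
                    idx += 1
                f = (t - tr_t[idx]) / (tr_t[idx + 1] - tr_t[idx])
                val = tr_v[idx] + f * (tr_v[idx + 1] - tr_v[idx])
            if tr_side[j] == 0:
                ci[tr_comp[j], tr_sp[j]] = val
            else:
                co[tr_comp[j], tr_sp[j]] = val

        # ---- per-compartment membrane machinery -----------------------
        for c in range(NCOMP):
            kd = kind[c]
            vc = v[c]
            v_old[c] = vc
            btot = cabuf_total * vi0[c] / vi[c]
            cf = _ca_free(ci[c, 3], btot, ca_kd)
            caf[c] = cf
            ena[c] = _RTF * math.log(co[c, 0] / ci[c, 0])
            ek[c] = _RTF * math.log(co[c, 1] / ci[c, 1])
            ecl[c] = -_RTF * math.log(co[c, 2] / ci[c, 2])
            eca[c] = 0.5 * _RTF * math.log(co[c, 3] / cf)
            egaba[c] = (1.0 - _P) * ecl[c] + _P * _EHCO3

            # gating: exponential update at the current voltage
            for g in range(9):
                inf, tau = gate_inf_tau(kd, g, vc, cf)
                gates[c, g] = inf + (gates[c, g] - inf) * math.exp(-dt / tau)

            # open-channel conductances
            if kd == 1:
                g_na = gcur[c, IC_NA] * gates[c, 0] ** 2 * gates[c, 1]
                g_kdr = gcur[c, IC_KDR] * gates[c, 4] ** 2
            else:
                g_na = gcur[c, IC_NA] * gates[c, 0] ** 3 * gates[c, 1]
                g_kdr = gcur[c, IC_KDR] * gates[c, 4] ** 4
            g_nap = gcur[c, IC_NAP] * gates[c, 2] ** 2 * gates[c, 3]
            g_cal = gcur[c, IC_CAL] * gates[c, 5] ** 2
            g_kahp = gcur[c, IC_KAHP] * gates[c, 6]
            sat = cf / 250.0
            if sat > 1.0:
                sat = 1.0
            g_kc = gcur[c, IC_KC] * sat * gates[c, 7]
            g_km = gcur[c, IC_KM] * gates[c, 8]

            g_na_tot = g_na + g_nap + gcur[c, IC_LNA]
            g_k_tot = g_kdr + g_kahp + g_kc + g_km + gcur[c, IC_LK]
            g_cl_tot = gcur[c, IC_LCL]

            ge_us = syn_norm * (syn[1, c] - syn[0, c])
            gi_us = syn_norm * (syn[3, c] - syn[2, c])
            ge_us_arr[c] = ge_us
            gi_us_arr[c] = gi_us
            ge_d = ge_us * 1e-6 / area_cm2[c]
            gi_d = gi_us * 1e-6 / area_cm2[c]
            gi_dens_arr[c] = gi_d

            if f_pump:
                fp = ((1.0 + km_k / co[c, 1]) ** -2
                      * (1.0 + km_na / ci[c, 0]) ** -3)
            else:
                fp = 0.0
            ipump_na = 3.0 * imax_pump[c] * fp
            ipump_k = -2.0 * imax_pump[c] * fp
            i_pump_net[c] = imax_pump[c] * fp
            if f_kcc2:
                ikcc2 = u_kcc2[c] * math.log(
                    ci[c, 1] * ci[c, 2] / (co[c, 1] * co[c, 2]))
            else:
                ikcc2 = 0.0
            ik_kcc2_arr[c] = ikcc2
            icap = imax_capump[c] / (1.0 + ca_pump_km / cf)

            inj = inj_dc[c]
            if ramp_on and c == IN_INDEX and ramp_t0 <= t < ramp_t0 + ramp_dur:
                inj += ramp_dens * (1.0 - (t - ramp_t0) / ramp_dur)

            g_tot[c] = g_na_tot + g_k_tot + g_cl_tot + g_cal + ge_d + gi_d
            drive[c] = (g_na_tot * ena[c] + g_k_tot * ek[c]
                        + g_cl_tot * ecl[c] + g_cal * eca[c]
                        + ge_d * e_exc + gi_d * egaba[c]
                        - i_pump_net[c] - icap + inj)

            # start-of-step per-ion membrane currents (for the fluxes)
            i_na[c] = g_na_tot * (vc - ena[c]) + ipump_na
            i_k[c] = g_k_tot * (vc - ek[c]) + ipump_k + ikcc2
            i_cl[c] = g_cl_tot * (vc - ecl[c]) - ikcc2
            if f_gaba_flux:
                i_cl[c] += (1.0 - _P) * gi_d * (vc - ecl[c])
            i_ca[c] = g_cal * (vc - eca[c]) + icap
            i_hco3[c] = _P * gi_d * (vc - _EHCO3)

        # ---- implicit voltage update ---------------------------------
        for c in range(NCOMP):
            p = partner[c]
            if p < 0:
                v[c] = (a_imp * v[c] + drive[c]) / (a_imp + g_tot[c])
            elif p > c:  # handle each soma-dendrite pair once
                a11 = a_imp + g_tot[c] + gc_dens[c]
                a22 = a_imp + g_tot[p] + gc_dens[p]
                a12 = -gc_dens[c]
                a21 = -gc_dens[p]
                b1 = a_imp * v[c] + drive[c]
                b2 = a_imp * v[p] + drive[p]
                det = a11 * a22 - a12 * a21
                vs = (b1 * a22 - a12 * b2) / det
                vd = (a11 * b2 - a21 * b1) / det
                v[c] = vs
                v[p] = vd
            if v[c] != v[c] or abs(v[c]) > 200.0:
                status = 1
                t_fail = t

        if status:
            break

        # ---- synaptic decay, spikes and event routing -----------------
        for c in range(NCOMP):
            syn[0, c] *= dec1
            syn[1, c] *= dec2
            syn[2, c] *= dec1
            syn[3, c] *= dec2
        for si in range(SOMATA.shape[0]):
            c = SOMATA[si]
            # upward crossing of 0 mV with a 2 ms refractory period
            if (v[c] > spike_thresh and v_old[c] <= spike_thresh
                    and t - last_spike[c] >= 2.0
                    and n_spk < spike_c.shape[0]):
                spike_t[n_spk] = t
                spike_c[n_spk] = c
                n_spk += 1
                last_spike[c] = t
                if f_syn:
                    for d in range(NCOMP):
                        if w_exc[c, d] != 0.0:
                            syn[0, d] += w_exc[c, d]
                            syn[1, d] += w_exc[c, d]
                        if w_inh[c, d] != 0.0:
                            syn[2, d] += w_inh[c, d]
                            syn[3, d] += w_inh[c, d]
        while ev_ptr < ev_step.shape[0] and ev_step[ev_ptr] == k:
            d = ev_comp[ev_ptr]
            syn[0, d] += w_input
            syn[1, d] += w_input
            ev_ptr += 1
        if probe_on and k >= probe_start and (k - probe_start) % probe_period == 0:
            for si in range(PY_SOMATA.shape[0]):
                d = PY_SOMATA[si]
                syn[0, d] += probe_w
                syn[1, d] += probe_w

        # ---- ionic fluxes (start-of-step currents) --------------------
        if f_ion:
            for c in range(NCOMP):
                for s in range(5):
                    dci[c, s] = 0.0
                    dco[c, s] = 0.0
                base = i_na[c] * surface[c] * _JFAC
                dci[c, 0] -= base / vi[c]
                dco[c, 0] += base / vo[c]
                base = i_k[c] * surface[c] * _JFAC
                dci[c, 1] -= base / vi[c]
                dco[c, 1] += base / vo[c]
                base = i_cl[c] * surface[c] * _JFAC / -1.0
                dci[c, 2] -= base / vi[c]
                dco[c, 2] += base / vo[c]
                base = i_ca[c] * surface[c] * _JFAC / 2.0
                dci[c, 3] -= base / vi[c]
                dco[c, 3] += base / vo[c]
                if f_glia:
                    k2 = k1_glia / (1.0 + math.exp((co[c, 1] - 16.0) / -1.25))
                    db = -k2 * co[c, 1] * b_glia[c] + k1_glia * (b_max - b_glia[c])
                    dco[c, 1] += db
                    b_glia[c] += db * dt
                if f_bath:
                    for s in range(3):
                        dco[c, s] += (diff_coef[s] * (bath_conc[s] - co[c, s])
                                      * bath_surface[c]
                                      / (cn.BATH_SCALE * bath_dr[c] * vo[c]))
            if f_ldiff:
                for j in range(long_pairs.shape[0]):
                    ca_ = long_pairs[j, 0]
                    cb = long_pairs[j, 1]
                    for s in range(4):
                        if s == 3:
                            ga = caf[ca_]; gb = caf[cb]
                        else:
                            ga = ci[ca_, s]; gb = ci[cb, s]
                        dr_in = (diff_coef[s] * (gb - ga) * long_s_in[j]
                                 / long_dist[j])
                        dci[ca_, s] += dr_in / vi[ca_]
                        dci[cb, s] -= dr_in / vi[cb]
                        dr_out = (diff_coef[s] * (co[cb, s] - co[ca_, s])
                                  * long_s_out[j] / long_dist[j])
                        dco[ca_, s] += dr_out / vo[ca_]
                        dco[cb, s] -= dr_out / vo[cb]
            if f_rdiff:
                for j in range(rad_pairs.shape[0]):
                    ca_ = rad_pairs[j, 0]
                    cb = rad_pairs[j, 1]
                    for s in range(2):  # Na+ and K+ only
                        dr = (diff_coef[s] * (co[cb, s] - co[ca_, s])
                              * rad_contact[j] / rad_dist[j])
                        dco[ca_, s] += dr / vo[ca_]
                        dco[cb, s] -= dr / vo[cb]
            for c in range(NCOMP):
                for s in range(4):
                    if not clamp_i[c, s]:
                        ci[c, s] += dci[c, s] * dt
                    if not clamp_o[c, s]:
                        co[c, s] += dco[c, s] * dt

            # ---- osmotic volume dynamics ------------------------------
            if f_vol:
                for c in range(NCOMP):
                    pi_i = (ci[c, 0] + ci[c, 1] + ci[c, 2] + caf[c]
                            + ci[c, 4] + cn.HCO3_IN)
                    pi_o = (co[c, 0] + co[c, 1] + co[c, 2] + co[c, 3]
                            + co[c, 4] + cn.HCO3_OUT)
                    delta = cn.OSMO_C * (pi_i - pi_o) / cn.OSMO_TAU
                    vi_new = vi[c] + delta * dt
                    vo_new = vo[c] - delta * dt
                    if delta > 0.0 and vo_new < cn.ECS_FRACTION_MIN * vi_new:
                        continue
                    fi = vi[c] / vi_new
                    fo = vo[c] / vo_new
                    for s in range(5):
                        if not clamp_i[c, s]:
                            ci[c, s] *= fi
                        if not clamp_o[c, s]:
                            co[c, s] *= fo
                    vi[c] = vi_new
                    vo[c] = vo_new

        # ---- recording -------------------------------------------------
        if k % fast_stride == 0:
            idx = k // fast_stride
            for c in range(NCOMP):
                v_rec[idx, c] = v[c]
                imem_rec[idx, c] = (i_na[c] + i_k[c] + i_cl[c] + i_ca[c]
                                    + i_hco3[c])
        if k % slow_stride == 0:
            idx = k // slow_stride
            for c in range(NCOMP):
                for s in range(5):
                    slow_rec[idx, c, s] = ci[c, s]
                    slow_rec[idx, c, 5 + s] = co[c, s]
                slow_rec[idx, c, SL_VI] = vi[c]
                slow_rec[idx, c, SL_VO] = vo[c]
                slow_rec[idx, c, SL_B] = b_glia[c]
                slow_rec[idx, c, SL_IPUMP] = i_pump_net[c]
                slow_rec[idx, c, SL_IKCC2] = ik_kcc2_arr[c]
                slow_rec[idx, c, SL_IGABA] = gi_dens_arr[c] * (v[c] - egaba[c])
                slow_rec[idx, c, SL_CAF] = caf[c]
                slow_rec[idx, c, SL_GE] = ge_us_arr[c]
                slow_rec[idx, c, SL_GI] = gi_us_arr[c]
    return n_spk, status, t_fail


@dataclass
class TraceSet:
    """Recorded time series of one run (shared time bases, fixed strides)."""

    dt: float
    duration: float
    fast_dt: float
    slow_dt: float
    v: np.ndarray          # (nfast, 9) mV
    imem: np.ndarray       # (nfast, 9) mA/cm^2, total transmembrane density
    lfp: np.ndarray        # (nfast,) mV
    slow: np.ndarray       # (nslow, 9, NSLOW)
    spike_times: dict      # comp index -> ndarray of ms
    seed: int | None
    meta: dict = field(default_factory=dict)

    @property
    def t_fast(self) -> np.ndarray:
        return np.arange(self.v.shape[0]) * self.fast_dt

    @property
    def t_slow(self) -> np.ndarray:
        return np.arange(self.slow.shape[0]) * self.slow_dt

    def conc(self, side: str, species: int, comp: int) -> np.ndarray:
        ch = species if side == "in" else 5 + species
        return self.slow[:, comp, ch]

    def volumes(self, comp: int) -> tuple[np.ndarray, np.ndarray]:
        return self.slow[:, comp, SL_VI], self.slow[:, comp, SL_VO]

    def spikes(self, comps) -> np.ndarray:
        """Pooled, sorted spike times (ms) of the given compartments."""
        arrs = [self.spike_times.get(int(c), np.empty(0)) for c in np.atleast_1d(comps)]
        return np.sort(np.concatenate(arrs)) if arrs else np.empty(0)


def _poisson_events(spec: RunSpec, model: NetworkModel, nsteps: int, dt: float):
    """Independent Poisson input streams, one per pyramidal cell."""
    if not spec.poisson or spec.seed is None:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), [])
    rate = model.config.poisson_rate_hz * 1e-3  # 1/ms
    children = np.random.SeedSequence(spec.seed).spawn(len(PY_DENDRITES))
    steps, comps, seeds = [], [], []
    for child, dend in zip(children, PY_DENDRITES):
        rng = np.random.default_rng(child)
        seeds.append(child.entropy)
        n_exp = int(rate * nsteps * dt * 2 + 100)
        times = np.cumsum(rng.exponential(1.0 / rate, size=n_exp))
        while times[-1] < nsteps * dt:
            times = np.concatenate(
                [times, times[-1] + np.cumsum(rng.exponential(1.0 / rate, n_exp))])
        times = times[times < nsteps * dt]
        steps.append((times / dt).astype(np.int64))
        comps.append(np.full(times.size, dend, dtype=np.int64))
    step = np.concatenate(steps)
    comp = np.concatenate(comps)
    order = np.argsort(step, kind="stable")
    return step[order], comp[order], seeds


def _build_clamps(spec: RunSpec):
    clamp_i = np.zeros((NCOMP, 5), dtype=np.uint8)
    clamp_o = np.zeros((NCOMP, 5), dtype=np.uint8)
    if not spec.ion_dynamics:
        clamp_i[:, :] = 1
        clamp_o[:, :] = 1
    for side, species, comps in spec.clamps:
        target = clamp_i if side == "in" else clamp_o
        if comps is None:
            target[:, species] = 1
        else:
            for c in np.atleast_1d(comps):
                target[int(c), species] = 1
    for tr in spec.trajectories:
        target = clamp_i if tr.side == "in" else clamp_o
        for c in tr.comps:
            target[int(c), tr.species] = 1
    return clamp_i, clamp_o


def _flatten_trajectories(spec: RunSpec):
    sides, sps, comps, offs, ts, vs = [], [], [], [0], [], []
    for tr in spec.trajectories:
        times = np.asarray(tr.times, dtype=float)
        values = np.asarray(tr.values, dtype=float)
        for c in tr.comps:
            sides.append(0 if tr.side == "in" else 1)
            sps.append(int(tr.species))
            comps.append(int(c))
            ts.append(times)
            vs.append(values)
            offs.append(offs[-1] + times.size)
    if not sides:
        return (np.empty(0, np.int64), np.empty(0, np.int64),
                np.empty(0, np.int64), np.zeros(1, np.int64),
                np.empty(0), np.empty(0))
    return (np.array(sides, np.int64), np.array(sps, np.int64),
            np.array(comps, np.int64), np.array(offs, np.int64),
            np.concatenate(ts), np.concatenate(vs))


def integrate(model: NetworkModel, spec: RunSpec,
              state: NetworkState | None = None) -> tuple[TraceSet, NetworkState]:
    """Run the network for ``spec.duration`` ms; returns traces + end state.

    The supplied state is not modified.  Raises ``RuntimeError`` on
    numerical blow-up (|V| > 200 mV or NaN), reporting the failure time.
    """
    from .lfp import lfp_weights

    cfg = model.config
    dt = spec.dt if spec.dt is not None else cfg.dt
    nsteps = int(round(spec.duration / dt))
    st = (state or model.rest_state()).copy()

    ev_step, ev_comp, stream_seeds = _poisson_events(spec, model, nsteps, dt)
    clamp_i, clamp_o = _build_clamps(spec)
    trajs = _flatten_trajectories(spec)

    inj_dc = np.zeros(NCOMP)
    if spec.dc_comp:
        inj_dc[PY_DENDRITES] += (cfg.dc_comp_pa * 1e-9
                                 / model.area_cm2[PY_DENDRITES])
    if spec.extra_dc is not None:
        inj_dc += spec.extra_dc

    ramp_t0 = spec.ramp_onset if spec.ramp_onset is not None else cfg.ramp_onset_s * 1e3
    ramp_dur = (spec.ramp_duration if spec.ramp_duration is not None
                else cfg.ramp_duration_s * 1e3)
    ramp_amp = spec.ramp_amp if spec.ramp_amp is not None else cfg.ramp_amp_na
    ramp_dens = ramp_amp * 1e-6 / model.area_cm2[IN_INDEX]

    probe_period = (spec.probe_period if spec.probe_period is not None
                    else cfg.probe_period_s * 1e3)
    probe_period_steps = max(int(round(probe_period / dt)), 1)
    probe_start_steps = int(round(spec.probe_start / dt))

    flags = np.array([spec.synapses, spec.pump, spec.kcc2, spec.glia,
                      spec.bath, spec.volume, spec.long_diffusion,
                      spec.rad_diffusion, spec.gaba_cl_flux,
                      spec.ion_dynamics], dtype=np.uint8)

    nfast = (nsteps + spec.fast_stride - 1) // spec.fast_stride
    nslow = (nsteps + spec.slow_stride - 1) // spec.slow_stride
    v_rec = np.zeros((nfast, NCOMP))
    imem_rec = np.zeros((nfast, NCOMP))
    slow_rec = np.zeros((nslow, NCOMP, NSLOW))
    cap = max(int(nsteps * dt * 3), 1000)
    spike_t = np.zeros(cap)
    spike_c = np.zeros(cap, dtype=np.int64)

    n_spk, status, t_fail = _run(
        nsteps, dt, KIND, PARTNER, model.gcur, model.imax_pump,
        model.imax_capump, model.u_kcc2, model.gc_density, model.surface,
        model.area_cm2, model.v_in0, model.v_out0, cfg.ca_buffer_total,
        cfg.ca_kd, cfg.ca_pump_km, cfg.km_k, cfg.km_na, cfg.b_max,
        cfg.k1_glia, model.long_pairs, model.long_s_in, model.long_s_out,
        model.long_dist, model.rad_pairs, model.rad_contact, model.rad_dist,
        model.bath_surface, model.bath_dr, model.bath_conc, cn.DIFF_COEF,
        model.w_exc, model.w_inh, model.syn_norm, cfg.tau_rise,
        cfg.tau_decay, cfg.e_exc, inj_dc, np.uint8(spec.ramp), ramp_t0,
        ramp_dur, ramp_dens, np.uint8(spec.probe), probe_period_steps,
        probe_start_steps, spec.probe_weight, ev_step, ev_comp, cfg.w_input,
        spec.spike_threshold,
        flags, clamp_i, clamp_o, *trajs,
        st.v, st.gates, st.ci, st.co, st.b_glia, st.v_in, st.v_out, st.syn,
        st.last_spike, spec.fast_stride, spec.slow_stride, v_rec, imem_rec,
        slow_rec, spike_t, spike_c)

    if status:
        raise RuntimeError(
            f"integration blew up at t = {t_fail:.2f} ms "
            f"(|V| > 200 mV or NaN); state dump: V = {st.v}")

    spikes = {c: spike_t[:n_spk][spike_c[:n_spk] == c].copy()
              for c in range(NCOMP)}
    weights = lfp_weights(model)
    lfp = imem_rec @ weights
    traces = TraceSet(
        dt=dt, duration=nsteps * dt, fast_dt=dt * spec.fast_stride,
        slow_dt=dt * spec.slow_stride, v=v_rec, imem=imem_rec, lfp=lfp,
        slow=slow_rec, spike_times=spikes, seed=spec.seed,
        meta={"poisson_stream_seeds": stream_seeds,
              "probe_period_ms": probe_period if spec.probe else None,
              "probe_start_ms": spec.probe_start if spec.probe else None,
              "ramp_onset_ms": ramp_t0 if spec.ramp else None})
    return traces, st
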