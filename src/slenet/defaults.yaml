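# slenet model configuration: published defaults (value unit)
# Two entries are geometry-derived when left as 'derived':
#   gc_total_us      = 0.163698 uS (from R_a = 100 Ohm cm and the cylinder dimensions)
#   bath_distance_um = 4.021427 um (half the somatic shell radius, uniform for all shells)
# Na_leak conductances, u_kcc2, imax_pump and imax_capump are
# recomputed by the rest-state calibration when a network is built;
# the values below are the published ones.
b_max: 1100.0 mM
bath_cl: 135.0 mM
bath_distance_um: derived
bath_k: 3.5 mM
bath_na: 140.0 mM
ca_buffer_total: 1.562 mM
ca_kd: 0.008 mM
ca_pump_km: 0.0069 mM
dc_comp_pa: 1.85 pA
dt: 0.05 ms
e_exc: 0.0 mV
g_CaL.in_soma: 0.0 S/cm2
g_CaL.py_dend: 0.00015 S/cm2
g_CaL.py_soma: 0.00015 S/cm2
g_Cl_leak.in_soma: 1e-05 S/cm2
g_Cl_leak.py_dend: 1e-05 S/cm2
g_Cl_leak.py_soma: 1e-05 S/cm2
g_KAHP.in_soma: 0.0 S/cm2
g_KAHP.py_dend: 5e-05 S/cm2
g_KAHP.py_soma: 5e-05 S/cm2
g_KC.in_soma: 0.0 S/cm2
g_KC.py_dend: 196.0 S/cm2
g_KC.py_soma: 196.0 S/cm2
g_KM.in_soma: 0.0 S/cm2
g_KM.py_dend: 0.0 S/cm2
g_KM.py_soma: 0.006 S/cm2
g_K_leak.in_soma: 6e-05 S/cm2
g_K_leak.py_dend: 3e-05 S/cm2
g_K_leak.py_soma: 3e-05 S/cm2
g_Kdr.in_soma: 0.027 S/cm2
g_Kdr.py_dend: 0.0032 S/cm2
g_Kdr.py_soma: 0.032 S/cm2
g_Na.in_soma: 0.013 S/cm2
g_Na.py_dend: 0.0014 S/cm2
g_Na.py_soma: 0.014 S/cm2
g_NaP.in_soma: 0.0 S/cm2
g_NaP.py_dend: 0.0 S/cm2
g_NaP.py_soma: 0.0006 S/cm2
g_Na_leak.in_soma: 2.9e-05 S/cm2
g_Na_leak.py_dend: 1.1e-05 S/cm2
g_Na_leak.py_soma: 1.5e-05 S/cm2
gc_total_us: derived
imax_capump.in_soma: 0.0 mA/cm2
imax_capump.py_dend: 2.55 mA/cm2
imax_capump.py_soma: 2.55 mA/cm2
imax_pump.in_soma: 0.025 mA/cm2
imax_pump.py_dend: 0.009 mA/cm2
imax_pump.py_soma: 0.014 mA/cm2
k1_glia: 0.0008 1/ms
km_k: 2.0 mM
km_na: 10.0 mM
p_hco3: 0.18 1
poisson_rate_hz: 5.0 Hz
probe_period_s: 5.0 s
ramp_amp_na: 0.35 nA
ramp_duration_s: 40.0 s
ramp_onset_s: 60.0 s
tau_decay: 6.0 ms
tau_rise: 2.0 ms
temperature: 305.16 K
u_kcc2.in_soma: 0.002 mA/cm2
u_kcc2.py_dend: 0.002 mA/cm2
u_kcc2.py_soma: 0.002 mA/cm2
w_ee: 0.0002 uS
w_ei: 0.0017 uS
w_ie: 0.0005 uS
w_input: 0.0004 uS
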