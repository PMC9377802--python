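# slenet

A biophysical network model of focal seizure-like events (SLEs) organised
by the feedback between neural firing and ion concentration changes — for
computational neuroscientists studying seizure initiation, progression and
termination, and for anyone who needs a compact, fully ion-conserving
conductance-based network with homeostatic machinery.

The network is a chain of four two-compartment pyramidal cells (PY) and a
fast-spiking interneuron (IN). On top of Hodgkin–Huxley membrane dynamics
(I_Na, I_NaP, I_Kdr, I_CaL, I_KAHP, I_KC, I_KM and Na/K/Cl leaks), the
model tracks intra- and extracellular Na⁺, K⁺, Cl⁻ and Ca²⁺ per
compartment and evolves them by

  J_X = −ΣI_X·S/(zF·V)

together with a 3:2 Na⁺/K⁺ pump, I = I_max(1 + K_mK/[K⁺]ₒ)⁻²(1 + K_mNa/[Na⁺]ᵢ)⁻³,
electroneutral KCC2 cotransport, I_K = U·ln([K]ᵢ[Cl]ᵢ/[K]ₒ[Cl]ₒ), a glial
K⁺ buffer, Fickian longitudinal/radial/bath diffusion and osmotic volume
dynamics with exact mass conservation. GABAa currents are carried by Cl⁻
and HCO₃⁻ with E_GABAa = (1−P)E_Cl + P·E_HCO3. All reversal potentials are
Nernst potentials refreshed from the instantaneous concentrations. A brief
depolarising ramp into the interneuron is enough to ignite a
self-terminating SLE with low-voltage-fast onset, tonic and bursting
phases, exponential slowing of the inter-burst interval, ~27% shrinkage of
the extracellular space and a ~90 s postictal depression.

The scientific background, every equation, the numerical scheme and the
design decisions are documented in `docs/methods.md`.

## Worked example

```python
from slenet import build_network, verify_rest
from slenet.protocols import run_reference_sle, settled_state
from slenet.analysis import sle_phase_markers

model = build_network()        # closed-form rest-state calibration
report = verify_rest(model)
print(report.to_frame())
for kind, res in report.values.items():
    print(kind, f"U={res.u_kcc2:.6f} g_Na,leak={res.g_na_leak:.3e} "
                f"I_max={res.imax_pump:.4f}")
```

prints the per-compartment rest residuals (all zero to machine precision —
the calibrated rest state is an exact fixed point) and the calibrated
transporter strengths:

```
 compartment   net_current            Na             K  Cl  Ca
     PY soma  0.000000e+00  0.000000e+00  0.000000e+00 0.0 0.0
 PY dendrite -2.168404e-19  0.000000e+00 -2.168404e-19 0.0 0.0
          IN  0.000000e+00 -4.336809e-19  4.336809e-19 0.0 0.0
0 U=0.002095 g_Na,leak=1.514e-05 I_max=0.0143
1 U=0.002095 g_Na,leak=1.108e-05 I_max=0.0099
2 U=0.002095 g_Na,leak=2.938e-05 I_max=0.0252
```

`U` is the KCC2 strength (mA/cm²) that cancels the chloride leak at rest,
`g_Na,leak` (S/cm²) enforces the −3:2 Na:K current ratio and `I_max`
(mA/cm²) is the Na⁺/K⁺-pump strength that zeroes both fluxes — matching
the published 0.014 / 0.009 / 0.025 mA/cm² for PY soma / dendrite / IN.

```python
traces = run_reference_sle(model, seed=1)      # 240 s, ramp into IN at 60 s
pm = sle_phase_markers(traces)
print(f"tonic onset +{(pm.tonic_onset - 60e3)/1e3:.1f} s, "
      f"bursting +{(pm.bursting_onset - 60e3)/1e3:.1f} s, "
      f"termination at {pm.termination/1e3:.1f} s")
```

```
tonic onset +14.0 s, bursting +15.8 s, termination at 103.2 s
```

i.e. the interneuron discharge (≈150 Hz initially) silently elevates
somatic [K⁺]ₒ for ~14 s, the pyramidal cells then fire tonically, switch
to bursting, and the event self-terminates ~43 s later as Na⁺ loading
drives the hyperpolarising pump current up. `traces` holds Vm, the LFP,
all concentrations, volumes and spike times (`slenet.io.write_traces`
saves them as HDF5 or tidy CSV).

A command-line interface mirrors the library:
`slenet simulate`, `slenet calibrate`, `slenet probe`, `slenet sweep`,
`slenet ibi-fit`.

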