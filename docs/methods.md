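# Methods

`slenet` simulates a small cortical microcircuit — four two-compartment
pyramidal cells (PY) and one fast-spiking interneuron (IN) in a chain
PY–PY–IN–PY–PY — in which the intra- and extracellular concentrations of
Na⁺, K⁺, Cl⁻ and Ca²⁺ are dynamical variables coupled to the membrane
dynamics. The slow feedback between firing and ionic gradients produces
self-organised seizure-like events (SLEs): a brief depolarising ramp into
the interneuron raises interstitial K⁺, recruits the pyramidal cells into
tonic firing and then bursting, and the same homeostatic machinery
(Na⁺/K⁺-pump, diffusion, glial uptake) eventually terminates the event and
produces a postictal depression.

## Model

### Membrane dynamics

Each compartment follows a Hodgkin–Huxley current balance

C dV/dt = −ΣI_ionic − I_pump − I_CaPump − g_c(V − V_partner) − I_syn + I_inj

with C_m = 1 µF/cm², R_a = 100 Ω·cm. Pyramidal somata carry
I_Na (m³h), I_NaP (m²h), I_Kdr (n⁴), I_CaL (m²), I_KAHP (m), I_KC (m, with
the `min([Ca²⁺]ᵢ/250, 1)` saturation), I_KM (m) and Na/K/Cl leaks; the
dendrite carries the same set minus I_NaP and I_KM with reduced exponents
(m²h, n²); the interneuron carries only I_Na, I_Kdr and the leaks, with its
Na and Kdr *activation curves* shifted −3 and −19 mV (time constants
unshifted) to avoid depolarisation block under strong drive. All reversal
potentials are Nernst potentials recomputed from the instantaneous
concentrations at every step (T = 305.16 K).

The somato-dendritic coupling is derived from R_a and the cylinder
geometry (two half-cylinders in series), giving 0.164 µS total, i.e.
≈1.5 mS/cm² when normalised by total membrane area. A config override
(`gc_total_us`) exists.

The delayed-rectifier time constant is implemented as
τ_n = 1.6/(α_n + β_n), α_n = 0.016(V+64.9)/(1 − e^{−(V+64.9)/5}),
β_n = 0.0338338·e^{−V/40}; the companion constant −2.30599·10⁻⁶ in the
published rational form equals −e^{−64.9/5}, which fixes the otherwise
ambiguous grouping. Rational rate functions with removable singularities
are evaluated by a series expansion within 10⁻⁷ mV of the pole.

### Ion dynamics

Membrane currents convert to concentration fluxes as
J = ±ΣI·S/(zF·V) per compartment side. The tracked pools are
Na⁺ᵢ/ₒ, K⁺ᵢ/ₒ, Cl⁻ᵢ/ₒ, total Ca²⁺ᵢ, Ca²⁺ₒ and the impermeant anion A⁻ᵢ;
HCO₃⁻ and A⁻ₒ are static. Free calcium is recovered from total calcium
each step through the fast-buffer relation
Ca_tot = Ca(B + K_d + Ca)/(K_d + Ca) (B = 1.562·Vᵢ⁰/Vᵢ mM, K_d = 8 µM),
inverted in closed form (quadratic).

Transport and exchange:

* **Na⁺/K⁺-pump**: I_Na = 3·I_max·f, I_K = −2·I_max·f with
  f = (1 + K_mK/[K⁺]ₒ)⁻²(1 + K_mNa/[Na⁺]ᵢ)⁻³ (K_mK = 2, K_mNa = 10 mM).
* **KCC2**: I_K = U·ln([K]ᵢ[Cl]ᵢ/[K]ₒ[Cl]ₒ), I_Cl = −I_K (electroneutral;
  contributes mass flux but no net charge, so it is absent from the
  voltage equation).
* **Glial buffer** on every shell: d[B]/dt = −k₂[K⁺]ₒ[B] + k₁[KB],
  k₂ = k₁/(1 + e^{(Ko−16)/−1.25}), B_max = 1100 mM, k₁ = 8·10⁻⁴ ms⁻¹.
* **Ca²⁺ pump**: I = I_max/(1 + K_pump/[Ca²⁺]ᵢ), I_max = 2.55 mA/cm².
* **Longitudinal diffusion** (soma↔dendrite, both sides, Na/K/Cl/Ca) and
  **radial diffusion** (neighbouring shells along the chain, Na/K only,
  contact area 16% of the shell surface, 40 µm between shell centres;
  somatic with somatic, dendritic with dendritic — the two central
  dendritic shells exchange across the interneuron gap over 80 µm).
* **Bath exchange** (Na/K/Cl): J = (1/s)·D·([X]_bath − [X]ₒ)·S/(dr·V),
  s = 4.4·10⁴, bath composition fixed at the resting extracellular values
  so that rest is a fixed point.

**Bath distance.** The distance dr between a shell and the bath is the one
geometric constant the published description leaves under-determined
("half of the shell thickness" without defining which thickness). Taking
each shell's ~0.5 µm annulus wall gives clearance time constants of ≈3 s
(soma) and ≈0.7 s (dendrite): the dendritic shell would then clear
*faster* than the somatic one, dendritic K⁺ could never accumulate, and no
seizure-like event can ignite — contradicting the reference behaviour the
same description reports. We therefore read "thickness" as the shell's
outer radius and use a single dr = half the somatic shell radius
(4.02 µm) for every shell (τ ≈ 47 s soma, ≈10 s dendrite before pump and
glia act). With this one constant resolved, the full reference
phenomenology emerges without further adjustment, including the ≈27%
extracellular shrinkage and ≈4% cellular swelling. `bath_distance_um`
overrides it.

### Volume dynamics

dVᵢ/dt = c(πᵢ − πₒ)/τ with τ = 250 ms, c = 1 µm³/mM, osmolarities summing
all six species (free calcium on the intracellular side, which balances
πᵢ = πₒ = 305.5 mM exactly at rest). Total volume is conserved; shrinkage
of a shell stops at 4% of the cellular volume (the rate is zeroed, not
reflected). Volume changes rescale concentrations so per-species mass is
conserved to machine precision. The shell starts at 15% of the cellular
volume (ECS fraction α = 0.131).

### Synapses and inputs

Dual-exponential conductances (τ₁ = 2 ms, τ₂ = 6 ms, peak normalised to
the weight) implemented as two auxiliary linear states per channel —
exactly equivalent to the event sum under superposition. Wiring:
PY→PY w_ee = 0.2 nS onto mid-dendrite (all-to-all, no autapses), PY→IN
w_ei = 1.7 nS, IN→PY w_ie = 0.5 nS onto mid-soma. The GABAa current splits
into Cl⁻ (1−P) and HCO₃⁻ (P = 0.18) components; its chloride component
feeds the Cl⁻ pools. AMPA reversal 0 mV. Each PY receives an independent
5 Hz Poisson input (w = 0.4 nS); streams are spawned from one root seed
via `numpy.random.SeedSequence` and the child seeds are logged. The SLE
trigger is a 0.35 nA → 0 linear ramp over 40 s into the IN (default onset
60 s).

Presynaptic spikes are detected as upward crossings of −10 mV with a 2 ms
refractory period. −10 mV rather than a conventional 0 mV because the
converged pyramidal spike peak under the derived dendritic load is ≈−2 mV;
the threshold still clears the depolarised envelope of ictal bursts. It is
exposed as `RunSpec.spike_threshold`.

### LFP

Point-source sum φ = 1/(4πσ)·ΣIₙ/|r − rₙ| over all transmembrane currents
(ionic + pump + synaptic; injected stimuli excluded), σ = 0.3 S/m,
interneuron sources weighted 0.2. Sources sit at compartment midpoints;
for the LFP layout the four PY somata are placed 32 µm apart with the
electrode in the somatic layer midway between the two central somata
(16 µm from each) and the IN 29 µm off-axis. The LFP source layout is a
separate parameter set from the diffusion chain spacing.

## Numerics

Fixed step dt = 0.05 ms, operator splitting per step: (1) gating variables
by exponential integration at the current voltage, (2) membrane potentials
by a backward (linearised-conductance) update — each soma–dendrite pair as
a 2×2 linear solve, (3) synaptic-state decay and event routing,
(4) concentrations, buffers and volumes by forward Euler using
start-of-step currents, with the volume update applied multiplicatively so
mass is conserved exactly. The loop is numba-compiled; identical state and
seed give bit-identical trajectories. Integration aborts with a state dump
if |V| exceeds 200 mV or becomes non-finite.

## Calibration and the settled rest state

Closed-form, per compartment kind, at V = −61 mV with gates at steady
state: U_KCC2 cancels the chloride leak (→ 2.1·10⁻³ mA/cm²); g_Na,leak
puts the Na and K totals (including the KCC2 K⁺ flux) in the −3:2 pump
stoichiometry; I_max cancels both (→ 0.0143 / 0.0099 / 0.0252 mA/cm² for
PY soma / PY dendrite / IN, reproducing the published 0.014 / 0.009 /
0.025 and the published leak conductances to ≤2%). Because the chloride
leak equals the KCC2 K⁺ current at rest, the calibrated state carries zero
net membrane current and is an exact fixed point — except for calcium.

Calcium is deliberately not pinned at its nominal initial value: with the
published pump strength, free Ca²⁺ relaxes within tens of milliseconds
from 5·10⁻⁵ mM to the pump/I_CaL equilibrium (≈2·10⁻⁸ mM), which is then
stationary. Weakening the pump to hold 5·10⁻⁵ mM instead would slow
calcium clearance ~3000-fold and abolish the afterhyperpolarisation
dynamics that shape bursts. Every experiment therefore starts from a 5 s
input-free *settled state*; the I_KAHP activation threshold keeps its
nominal 5·10⁻⁵ mM reference.

## Experiment protocols

* **Reference SLE**: 240 s, Poisson background, IN ramp at 60 s. Phase
  markers are computed, not annotated: tonic onset = pooled PY rate
  ≥2 Hz/cell sustained 3 s (background is ~0.03 Hz/cell, ictal tonic
  ≥5 Hz, so any threshold in 1–5 Hz gives the same marker to ±2 s);
  bursting onset = first detected ictal burst; termination = offset of the
  last burst.
* **Burst definition** (detector parameters, exposed): spikes group at
  inter-spike gaps <200 ms; a group is an ictal burst if it has ≥2 spikes
  and lasts ≤2 s (the duration cap separates discrete bursts from
  sustained tonic runs). IBIs are onset-to-onset.
* **Noise-free runs** replace the background with 1.85 pA DC into every PY
  dendrite.
* **Clamped-ion (fast–slow) protocols** clamp Na/K/Cl/A on both sides and
  extracellular Ca²⁺, with glia/bath/volume/radial-diffusion off;
  intracellular free Ca²⁺ stays dynamic because it is part of the fast
  burst machinery (freezing it at the nominal initial value also leaves
  the strong Ca-pump current permanently unbalanced). PY chloride is set
  to 7 mM. Sweeps carry state between 5 s steps in both directions.
* **Excitability probe**: 5 s periodic EPSC at every PY soma, weight
  bisected to just-above-threshold (×1.05) on the interictal model; the
  postictal unresponsive span is the longest run of failed probes after
  the SLE offset.
* **IBI scaling fits**: linear, exponential (A + B·e^{Ct}), logarithmic
  and inverse-square-root laws; the λ predictor is t_end − t + 1 s with
  t_end defaulting to the last burst onset plus its extrapolated IBI. The
  exponential is profiled (A, B by least squares given C) and C optimised
  by Nelder–Mead from four deterministic starts. Two winners are
  reported: the raw-RMSE winner (the published contest) and a
  BIC-corrected winner. The BIC variant exists because the
  three-parameter exponential *nests* the linear law and shadows the
  other two-parameter laws on any smoothly accelerating sequence, so a
  raw-RMSE four-way contest can never return a linear verdict on noisy
  data; parameter-recovery tests use BIC.

## What the tests do and do not show

The acceptance-style tests exercise the model's own emergent behaviour
(reference event timing, volume changes, postictal span, clamped-regime
maps) and analytic identities — not real recordings. Synthetic burst
sequences used for the scaling-law recovery tests are generated directly
from the four laws with multiplicative noise; they emulate the shape of
terminal IBI slowing, not the detailed statistics of experimental seizure
data. Passing them shows internal consistency and faithful implementation
of the published machinery; it does not validate the biology beyond what
the original study argued.

Problem sizes used by the shipped tests and the acceptance script: one
240 s reference run per seed (five seeds for termination statistics), one
240 s noise-free run, one 300 s probe run, ramp experiments of 260–500 s,
and a sweep scaled to a 0.5 mM somatic-K⁺ step over three dendritic-K⁺
rows and three Na⁺ levels.

## Known limitations

* The carried-state (hysteresis) sweep is dominated by slow adaptation:
  with 5 s steps, accommodation (KM/Kdr activation, slow NaP inactivation,
  τ ≈ 5–7 s) keeps the network on a silent branch over much of the grid,
  and the active attractors themselves take 5–10 s to establish. The
  published sweep reports near-reversible transitions (≤1 step); here the
  forward/backward mismatch is far wider and is reported honestly.
  `bifurcation_sweep(carry_state=False)` therefore also provides a
  quasi-stationary map (each grid point simulated 10 s from the settled
  rest state), which cleanly resolves the regimes: rest → tonic along
  somatic K⁺ at resting dendritic K⁺, discrete bursting only in the
  elevated dendritic-K⁺ rows, and strong shrinkage of the active domains
  with Na⁺ loading. Note that well-separated (>300 ms quiescence) ictal
  bursts at the reference sodium level appear as dense doublet firing in
  the clamped map; the discrete bursting of the full event also involves
  the elevated Na⁺/pump current of the late SLE, exactly as the fast–slow
  replay shows.
* Under slow single-species ramps the terminal IBI sequences are best fit
  (raw RMSE) by the exponential law for all three species; the published
  assignment of logarithmic scaling to the Na⁺/Cl⁻ ramps sits within a
  few percent of RMSE ("often comparable", as the original analysis
  notes) and is not reproduced by the stronger optimiser used here.
* No electrodiffusion, no tortuosity beyond the printed constants, no
  astrocyte swelling, no temperature scaling, no stochastic channels.
* The LFP is a point-source approximation over nine sources; its absolute
  amplitude is an order of magnitude below experimental signals, as in
  the original report.
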