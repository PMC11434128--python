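# Methods

## Model overview

`somnotc` simulates a thalamocortical loop of four populations — cortical
pyramidal (PY) and inhibitory (INH) cells, thalamocortical relay (TC) and
thalamic reticular (RE) cells — through a scheduled sequence of vigilance
states (wake, N2, N3, REM).  State transitions are implemented purely as
changes in three neuromodulator levels (acetylcholine, histamine, GABA),
which scale a potassium leak conductance and synaptic weights.  The model
family is the conductance-based thalamocortical sleep literature: reduced
two-compartment cortical cells, single-compartment thalamic cells,
first-order kinetic synapses with use-dependent depression, a low-threshold
calcium current that enables rebound bursting, and a calcium-regulated
hyperpolarisation-activated current that paces spindle waxing and waning.

## Cells

**Cortical PY/INH** are two compartments (dendrite + axosomatic) coupled by
an axial conductance g_c = 0.1 µS, with area ratio ρ = A_dend/A_soma (165
for PY, 50 for INH; soma area 1e-6 cm²).  The axosomatic compartment
carries the fast spike-generating currents (I_Na 3000, I_K 200 mS/cm² as
legacy values); the dendrite carries I_Na (window), I_Nap, I_Km, I_KCa,
I_HVA, leak and K-leak.  In the default `capacitive` soma variant the
axosomatic compartment has the same specific capacitance as the dendrite
(0.75 µF/cm²) and **every axosomatic maximal conductance is rescaled by
3/4** relative to the legacy parameter set, which preserves the firing
phenotype of the original capacitance-free algebraic-soma formulation.  The
legacy solver itself is not implemented; the enum value only labels
parameter sets.  The 3/4 rescale is applied uniformly to PY and INH.

**Thalamic TC/RE** are single compartments (C_m = 1 µF/cm²) with Traub-type
I_Na/I_K, a T-type calcium current (TC and RE kinetic variants, m²h with
Boltzmann steady states and the standard biexponential time constants,
divided by Q10-derived φ = 3 at a nominal 36 °C), potassium leak, and — for
TC only — the calcium-regulated I_h: voltage gating C↔O
(half-activation −75 mV, slope −5.5), calcium binding P0↔P1 with forward
rate k1·[Ca]⁴, and a locking step O+P1↔OL whose locked-open state conducts
`ginc = 2` times more.  Probability is conserved by construction
(C = 1−O−OL, P0 = 1−P1).  E_Ca is a Nernst potential from a per-cell
calcium shell (thalamic: τ = 5 ms; cortical dendrite: τ = 150 ms so calcium
integrates over an Up state and I_KCa acts as a slow
activity-dependent brake).

All spiking currents share the Traub m³h/n⁴ rate functions (with a
per-type voltage shift) rather than bespoke per-population forms; removable
singularities in all rate functions are evaluated by series limit when the
denominator is within 1e-9 of zero.  Channel constants live in one shipped
table (`data/channels.tsv`) and can be overridden per key from the config's
`channels:` section; the shapes of the τ(V) expressions are fixed in code.

## Synapses

Receptors follow dO/dt = α·T·(1−O) − β·O with rectangular transmitter
pulses (0.5 mM for 0.3 ms) released at presynaptic spikes; pulses do not
stack (T is a concentration).  The exact exponential solution is used per
step.  AMPA (α = 1.1 mM⁻¹ms⁻¹, β = 0.19 ms⁻¹, E = 0), NMDA (0.072/0.0066,
E = 0) with the standard magnesium block 1/(1+exp(−0.062 V)·[Mg]/3.57),
GABA-A (5.0/0.18, E per projection: −70 mV cortical, −85 mV RE→TC), and a
second-messenger GABA-B cascade (K1 = 0.52, K2 = 0.0013, K3 = 0.098,
K4 = 0.033, K_d = 100) gating a potassium conductance through G⁴/(G⁴+K_d).

Cortical AMPA synapses depress: at each presynaptic spike the resource
updates to E ← 1 − (1 − E·(1−U))·exp(−Δt/τ_D) with U = 0.07, τ_D = 700 ms,
and the effective weight is w·E.  With U = 0 the model reduces exactly to
plain AMPA (trace equality to machine precision — tested).  This rundown of
recurrent excitation is the mechanism that terminates cortical Up states;
removing it (U = 0) turns the N3 slow oscillation into sustained firing.

**Miniature EPSPs.**  Spontaneous releases on the recurrent cortical AMPA
synapses are drawn per connection from a renewal process whose hazard
λ(s) = λ_max·(1 − e^(−s/τ_r)) is suppressed immediately after a presynaptic
spike and saturates at λ_max (per-connection λ_max = 35 Hz, τ_r = 1100 ms;
a mini opens the receptor pool by a fixed fraction equal to 0.5 of a full
pulse's increment).  Sampling is by thinning against λ_max with a
counter-based splitmix64 stream per connection, so runs are reproducible
for a given seed and insensitive to unrelated edits of the network.  These
three numbers are the main calibration of the slow oscillation: λ_max and
the mini amplitude set how quickly summating minis can ignite an Up state,
and τ_r sets the refractory depth of the Down state.  With the defaults the
N3 slab produces Up/Down alternation at ~0.7–0.9 Hz; the values were chosen
once as the package's study conditions and are fully exposed in the config.

## Network

Populations sit on 1-D index lines.  Presynaptic cell i of a projection
contacts every target j with |j − round(i·n_post/n_pre)| ≤ radius, clipped
at the array bounds (finite slab, no wraparound) — construction is
deterministic.  Per-target conductance is normalised by actual in-degree so
boundary cells receive the same total drive (switchable).  The projection
set is PY→PY (AMPA+NMDA, depressing, minis), PY→INH (same), INH→PY
(GABA-A), PY→TC, PY→RE, TC→PY, TC→INH, TC→RE (AMPA), RE→TC
(GABA-A + GABA-B), RE→RE (GABA-A).  Intracortical radii are narrower than
thalamocortical ones (defaults in the config).  Geometry: 20 µm pitch,
cortical dendrites 500 µm above the somata, giving each cortical cell a
vertical dipole.

## Neuromodulation

With wake as the reference (ach = ha = gaba = 1):

* g_KL,eff = g_KL·(1 + κ_ach·(1−ach) + κ_ha·(1−ha)), histamine acting on
  thalamic K-leak only (κ_ha = 0 for PY/INH);
* cortical AMPA weight w·(1 + λ·(1−ach)), λ = 0.6 (lower acetylcholine →
  stronger recurrent excitation);
* every GABA-A weight scales directly with the gaba level.

Stage levels (wake 1/1/1; N2 0.7/0.7/1.2; N3 0.3/0.3/1.3; REM
1.2/0.1/0.9) and gains (κ_ach: PY/INH 2, TC 5, RE 0.5; κ_ha: TC 1.5,
RE 0.5) are calibration constants, not literature measurements.  They were
chosen so that the four regimes separate cleanly: N2 leaves the cortex
near its activated state while putting TC cells at the spindle-permissive
K-leak (≈3× wake); N3 hyperpolarises the cortex into the slow-oscillation
regime (K-leak ≈2.4× wake) and parks TC cells below it; REM is
cortically activated with histamine withdrawn.  The schedule is
piecewise-constant with a linear ramp (default 5 s) centred on each
boundary; the five-stage headline protocol (wake, N2, N3, REM, N2) splits
the 360 s total equally, since only the sequence, not the split, is
specified by the source material.

Levels are validated to ach, ha ∈ [0, 2] and gaba ≥ 0: REM acetylcholine
deliberately exceeds the wake reference (1.2), reflecting cholinergic REM
tone.

## Integration

Fixed global step dt = 0.025 ms.  Per step: (1) neuromodulator levels and
effective scales; (2) synapse kinetics (exact exponential), depression
updates at new presynaptic spikes, minis due in (t, t+dt], conductance
accumulation; (3) gating variables by the exponential update
x ← x∞ + (x−x∞)e^(−dt/τ) (exact at frozen V, so fractions cannot leave
[0,1]); (4) calcium pools; (5) voltages semi-implicitly — all conductances
frozen at the start of the step make the membrane equation linear in V, and
the 2×2 per-cell system (cortex) or scalar equation (thalamus) is solved
exactly, which is unconditionally stable; (6) somatic spike detection
(upward crossing of 0 mV with a 2 ms refractory).  The raster event
criterion is a package decision; it only labels spikes, the dynamics are
continuous.

Correctness is defined by convergence, not bit-matching any earlier code:
halving dt changes a quiet cell's sampled trajectory by ≪ 0.1 mV, and the
spike times of a ten-cell circuit firing a stimulus-locked rebound volley
move by < 0.5 ms over a 5 s run (tested).  A per-spike bound only makes
sense for stimulus-locked firing: the scheme is first-order in dt, so a
*free-running* oscillation accumulates phase error linearly in time
(measured ≈ 7 ms of spike-time shift per second of tonic firing between
dt = 0.025 and 0.0125 ms, halving with dt) — a property of any fixed-step
integrator, not a defect of this one; rhythms, rates and regime boundaries
are unaffected.  Runs
are deterministic in (config, seed), and checkpoint/restore resumes
bit-identically (tested).  Hot loops are numba-compiled; the first call in
a fresh environment pays a one-time JIT cost.

## LFP forward models

* **Summed-voltage LFP**: the arithmetic mean (not raw sum, so the
  amplitude is population-size invariant) of PY dendritic voltages, in mV.
* **Biophysical LFP**: point-source volume conductor,
  φ = Σ_k R_k·I_k with R_k = 1/(4πσ·r_k), σ = 0.3 S/m.  I_k is the total
  transmembrane current of compartment k (ionic + synaptic + capacitive);
  by charge conservation this equals the axial current entering the
  compartment, so each two-compartment cell contributes
  g_c·(V_d−V_s)·(R_soma−R_dend) and single-compartment cells contribute
  nothing (no dipole) — the LFP is cortical by construction.  R is kept in
  ohms so φ = R·I holds in SI units (2652.6 Ω at 100 µm; 1 nA ↦ 2.65 µV).
  The default electrode sits 100 µm above the dendritic plane at the slab
  centre; a midplane electrode would null every dipole by symmetry and is
  rejected only if it violates the 10 µm minimum distance, so electrode
  placement is the user's responsibility when overridden.
* Point-source (not line-source) is used because cells have at most two
  compartments; σ and all geometry are configurable.

## Spectral analysis

Spectrograms use a single Hann taper (display default 2 s windows, 75 %
overlap).  Stage-wise band powers are medians over per-window band power
with a 4 s analysis window — the shortest resolving the slow-oscillation
band (0.1–1 Hz needs Δf ≤ 0.25 Hz).  Stage contrasts are measured on the
biophysical LFP: at desk scale the summed-voltage trace averages only ~50
cells, so its incoherent fluctuation power is large enough to mask the
spindle-band contrast on some seeds, whereas the transfer-resistance LFP
weights the coherent dipolar currents of the rhythms and separates the
stages reliably.  Default bands: slow oscillation
0.1–1 Hz, spindle 7–14 Hz, alpha 8–13 Hz.  Dominant frequency is the
argmax of a Welch PSD on a stated range.  Burst-mode vs relay-mode
thalamic firing is summarised by the fraction of inter-spike intervals
under 10 ms, which separates N2 spindling (≈0.2) from wake tonic firing
(≈0.1) independently of the mean rate — the wake RE–TC loop legitimately
carries an ~8 Hz alpha-like relay rhythm, so dominant frequency alone does
not discriminate the regimes.

## Desk-scale scenarios and what they do (and do not) show

The shipped full-scale configuration (500/100/100/100 cells, 360 s) is the
headline protocol; tests and the acceptance script run reduced scenarios:

* `single_tc_rebound`: one TC cell, 2 s of fully open K-leak (levels
  ach = ha = 0 with an enlarged TC gain so the cell rests near −83 mV,
  below the T-current activation range), then wake levels.  Probes the
  I_T/I_h rebound burst in isolation.
* `re_tc_spindle_pair`: 4+4 TC/RE cells, 10 s at one stage's levels.
  Sparse minis on TC→RE stand in for the cortical input that re-kindles
  spindles in the full loop.
* `cortical_slab_n3`: 40 PY + 10 INH (thalamic populations present at
  minimal size with zeroed conductances, satisfying the ≥1-cell
  invariant), 12 s at N3 levels.
* `full_reduced_cycle`: the whole network at 1/10 scale through the
  five-stage sequence at 1/10 duration (36 s, ramp 0.5 s).

These sizes keep every scenario within desk/CI timescales.  The reduced
scale inflates the fluctuation power of population averages (mean over 50
rather than 500 cells), which makes the stage band-power contrasts noisier
than the full model's; they remain qualitative orderings, not effect-size
estimates.  The synthetic protocol also omits features of real sleep —
stage-duration variability, gradual neuromodulator drift, noise sources
other than miniature release — so passing tests demonstrate the mechanisms
(rebound bursting, RE–TC spindling, depression-paced slow oscillation,
neuromodulator-driven stage separation), not quantitative agreement with
recordings.

## Numerical and design choices

* Semi-implicit voltage update chosen over fully explicit for robustness at
  dt = 0.025 ms given the stiff axosomatic conductances (up to
  2250 mS/cm²).
* Synaptic delays default to 0 ms (configurable per projection).
* Unknown config keys are hard errors; validation reports every violated
  invariant at once.
* The engine is serial; determinism and checkpointing are designed so a
  future parallel driver cannot change results.
* Degenerate inputs: zero-duration runs return the initial sample and an
  empty raster; a non-finite voltage aborts with the population, cell and
  time, flushing partial results with a failure marker.

## Known limitations

* Norepinephrine, orexin and serotonin are not modelled.
* No spike-timing-dependent or long-term plasticity.
* No event-level spindle/slow-wave detectors — analyses are band-power
  based.
* The legacy algebraic (capacitance-free) soma solver is a documented
  non-goal; only its parameter convention survives via the 3/4 rescale.
* One-compartment thalamic cells contribute nothing to the biophysical
  LFP by construction (no dipole); thalamic analyses use membrane
  voltages directly.
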