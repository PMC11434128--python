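# somnotc

A self-contained, conductance-based simulator of a thalamocortical network
model of sleep.  It reproduces the characteristic rhythms of the main
vigilance states — activated wake/REM dynamics, 7–14 Hz sleep spindles in
N2, and the < 1 Hz slow oscillation of N3 — purely by scheduling three
neuromodulator levels (acetylcholine, histamine, GABA) that scale a
potassium leak conductance and synaptic weights.  It is aimed at
computational neuroscientists who want a hackable, deterministic,
pure-Python/numba implementation of this model family for studying sleep
rhythms, neuromodulation, and thalamocortical interactions.

## The model in brief

Four populations form a thalamocortical loop (defaults: 500 cortical
pyramidal PY, 100 cortical inhibitory INH, 100 thalamocortical relay TC,
100 thalamic reticular RE cells; topographic, radius-based connectivity).
PY/INH cells are two-compartment (dendrite + axosomatic; the axosomatic
compartment is capacitive, with every axosomatic conductance rescaled by
3/4 relative to its legacy value).  TC/RE cells are single-compartment with
the low-threshold calcium current I_T and, for TC, a calcium-regulated
hyperpolarisation-activated current I_h.  Synapses are kinetic
(AMPA/NMDA/GABA-A and second-messenger GABA-B); recurrent cortical AMPA
depresses with use fraction U and recovery τ_D,

    E ← 1 − (1 − E·(1 − U))·exp(−Δt/τ_D),   I = g·E·O·(V − E_rev),

and carries spontaneous miniature EPSPs.  Neuromodulators act as

    g_KL_eff = g_KL·(1 + κ_ach(1 − ach) + κ_ha(1 − ha)),
    w_AMPA_eff = w·(1 + λ(1 − ach))  (cortical),   w_GABA-A_eff = w·gaba,

so the wake reference (ach = ha = gaba = 1) leaves everything at base
values.  Two LFP forward models are provided: the mean PY dendritic
voltage, and the biophysical point-source potential
φ = Σ_k I_k/(4πσ·r_k) over all cortical compartment currents.  See
`docs/methods.md` for the full account.

## Worked example

Run the spindle-pacemaker circuit (4 TC + 4 RE cells) for 10 s at N2
levels and at wake levels, and compare the regimes:

```python
import numpy as np
from somnotc import FixtureSpec, make_fixture, run
from somnotc.lfp import burst_isi_fraction, dominant_frequency, summed_voltage_lfp

for stage in ("N2", "wake"):
    cfg = make_fixture(FixtureSpec("re_tc_spindle_pair", seed=1), stage=stage)
    res = run(cfg)
    v = np.column_stack([res.voltage_traces[f"TC:{i}"] for i in range(4)])
    lfp = summed_voltage_lfp(v[res.t_ms >= 500])
    print(stage,
          f"dominant {dominant_frequency(lfp, res.fs_hz, 1, 30):.2f} Hz,",
          f"burst-ISI fraction {burst_isi_fraction(res, 'TC', min_t_ms=500):.2f}")
```

prints

```
N2 dominant 7.50 Hz, burst-ISI fraction 0.19
wake dominant 1.25 Hz, burst-ISI fraction 0.09
```

i.e. at N2 levels the pair oscillates in the spindle band with burst-mode
TC firing (a quarter of inter-spike intervals are within-burst, < 10 ms),
while at wake levels the same circuit relays tonically — the
hyperpolarisation that de-inactivates I_T and enables rebound bursts is
missing.

The same machinery runs from the shell:

```bash
somnotc fixture cortical_slab_n3 --seed 1 --out slab.yaml
somnotc run --config slab.yaml --out slab.h5
somnotc analyze slab.h5 --bands --spectrogram --report slab.json
```

The slab run shows the N3 slow oscillation: network-wide active periods
alternating with silence at a dominant frequency of ~0.75 Hz, which
collapses into sustained tonic firing when AMPA depression is disabled
(`synapses: {depression_U: 0.0}` in the config).

## Layout

| Module | Contents |
| --- | --- |
| `somnotc.config` | parameter tree, YAML dialect, stage schedule |
| `somnotc.channels` | intrinsic current kinetics, calcium, constants table |
| `somnotc.cells` | two-/one-compartment cell assembly, soma variant |
| `somnotc.synapses` | kinetic receptors, depression, GABA-B, minis |
| `somnotc.network` | populations, topographic projections, geometry |
| `somnotc.neuromodulation` | level → effective-parameter mapping |
| `somnotc.engine` | fixed-step integrator, checkpoints, HDF5 output |
| `somnotc.lfp` | LFP forward models, spectrogram/band analysis |
| `somnotc.fixtures` | desk-scale scenario configurations |
| `somnotc.cli` | `somnotc run / analyze / fixture` |
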