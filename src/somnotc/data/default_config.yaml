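populations:
  PY: 500
  INH: 100
  TC: 100
  RE: 100
soma_variant: capacitive
cells:
  PY:
    cm: 0.75
    rho: 165.0
    soma_area_cm2: 1.0e-06
    g_c_uS: 0.1
    vtraub: -55.0
    v_init: -68.0
    e_na: 50.0
    e_k: -95.0
    soma:
      g_na: 3000.0
      g_k: 200.0
      g_nap: 0.0
      g_km: 0.0
      g_kca: 0.0
      g_hva: 0.0
      g_leak: 0.0
      e_leak: -70.0
      g_kl: 0.0
    dend:
      g_na: 1.5
      g_k: 0.0
      g_nap: 0.02
      g_km: 0.1
      g_kca: 0.3
      g_hva: 0.012
      g_leak: 0.033
      e_leak: -68.0
      g_kl: 0.002
  INH:
    cm: 0.75
    rho: 50.0
    soma_area_cm2: 1.0e-06
    g_c_uS: 0.1
    vtraub: -55.0
    v_init: -68.0
    e_na: 50.0
    e_k: -95.0
    soma:
      g_na: 2500.0
      g_k: 200.0
      g_nap: 0.0
      g_km: 0.0
      g_kca: 0.0
      g_hva: 0.0
      g_leak: 0.0
      e_leak: -70.0
      g_kl: 0.0
    dend:
      g_na: 1.5
      g_k: 0.0
      g_nap: 0.0
      g_km: 0.05
      g_kca: 0.3
      g_hva: 0.012
      g_leak: 0.033
      e_leak: -68.0
      g_kl: 0.002
  TC:
    cm: 1.0
    area_cm2: 0.00029
    vtraub: -52.0
    v_init: -68.0
    e_na: 50.0
    e_k: -95.0
    g_na: 90.0
    g_k: 10.0
    g_t: 2.2
    g_h: 0.017
    g_leak: 0.01
    e_leak: -70.0
    g_kl: 0.005
  RE:
    cm: 1.0
    area_cm2: 0.000143
    vtraub: -52.0
    v_init: -70.0
    e_na: 50.0
    e_k: -95.0
    g_na: 100.0
    g_k: 10.0
    g_t: 2.3
    g_h: 0.0
    g_leak: 0.05
    e_leak: -77.0
    g_kl: 0.003
connectivity:
  normalize_by_indegree: true
  projections:
    PY_PY:
      radius: 5
      g_ampa: 0.3
      g_nmda: 0.02
      g_gabaa: 0.0
      g_gabab: 0.0
      e_gabaa: -70.0
      depressing: true
      minis: true
      allow_self: false
      delay_ms: 0.0
    PY_INH:
      radius: 1
      g_ampa: 0.05
      g_nmda: 0.008
      g_gabaa: 0.0
      g_gabab: 0.0
      e_gabaa: -70.0
      depressing: true
      minis: true
      allow_self: false
      delay_ms: 0.0
    INH_PY:
      radius: 5
      g_ampa: 0.0
      g_nmda: 0.0
      g_gabaa: 0.05
      g_gabab: 0.0
      e_gabaa: -70.0
      depressing: false
      minis: false
      allow_self: false
      delay_ms: 0.0
    PY_TC:
      radius: 10
      g_ampa: 0.025
      g_nmda: 0.0
      g_gabaa: 0.0
      g_gabab: 0.0
      e_gabaa: -70.0
      depressing: false
      minis: false
      allow_self: false
      delay_ms: 0.0
    PY_RE:
      radius: 8
      g_ampa: 0.05
      g_nmda: 0.0
      g_gabaa: 0.0
      g_gabab: 0.0
      e_gabaa: -70.0
      depressing: false
      minis: false
      allow_self: false
      delay_ms: 0.0
    TC_PY:
      radius: 10
      g_ampa: 0.1
      g_nmda: 0.0
      g_gabaa: 0.0
      g_gabab: 0.0
      e_gabaa: -70.0
      depressing: false
      minis: false
      allow_self: false
      delay_ms: 0.0
    TC_INH:
      radius: 2
      g_ampa: 0.1
      g_nmda: 0.0
      g_gabaa: 0.0
      g_gabab: 0.0
      e_gabaa: -70.0
      depressing: false
      minis: false
      allow_self: false
      delay_ms: 0.0
    TC_RE:
      radius: 8
      g_ampa: 0.05
      g_nmda: 0.0
      g_gabaa: 0.0
      g_gabab: 0.0
      e_gabaa: -70.0
      depressing: false
      minis: false
      allow_self: false
      delay_ms: 0.0
    RE_TC:
      radius: 8
      g_ampa: 0.0
      g_nmda: 0.0
      g_gabaa: 0.03
      g_gabab: 0.004
      e_gabaa: -85.0
      depressing: false
      minis: false
      allow_self: false
      delay_ms: 0.0
    RE_RE:
      radius: 5
      g_ampa: 0.0
      g_nmda: 0.0
      g_gabaa: 0.07
      g_gabab: 0.0
      e_gabaa: -70.0
      depressing: false
      minis: false
      allow_self: false
      delay_ms: 0.0
synapses:
  ampa_alpha: 1.1
  ampa_beta: 0.19
  ampa_e_rev: 0.0
  nmda_alpha: 0.072
  nmda_beta: 0.0066
  nmda_e_rev: 0.0
  nmda_mg_mM: 1.0
  gabaa_alpha: 5.0
  gabaa_beta: 0.18
  gabab_k1: 0.52
  gabab_k2: 0.0013
  gabab_k3: 0.098
  gabab_k4: 0.033
  gabab_kd: 100.0
  gabab_e_rev: -95.0
  pulse_amp_mM: 0.5
  pulse_dur_ms: 0.3
  depression_U: 0.07
  depression_tau_ms: 700.0
  mini_amp_fraction: 0.5
  mini_rate_max_hz: 35.0
  mini_tau_recover_ms: 1100.0
modulation:
  kl_ach:
    PY: 2.0
    INH: 2.0
    TC: 5.0
    RE: 0.5
  kl_ha:
    PY: 0.0
    INH: 0.0
    TC: 2.5
    RE: 0.5
  ampa_ach_gain: 0.6
schedule:
  stages:
  - stage: wake
    duration_ms: 72000.0
  - stage: N2
    duration_ms: 72000.0
  - stage: N3
    duration_ms: 72000.0
  - stage: REM
    duration_ms: 72000.0
  - stage: N2
    duration_ms: 72000.0
  levels:
    wake:
      ach: 1.0
      ha: 1.0
      gaba: 1.0
    N2:
      ach: 0.7
      ha: 0.7
      gaba: 1.2
    N3:
      ach: 0.3
      ha: 0.3
      gaba: 1.3
    REM:
      ach: 1.2
      ha: 0.1
      gaba: 0.9
  ramp_ms: 5000.0
integration:
  dt_ms: 0.025
  seed: 0
  record_dt_ms: 1.0
  settle_ms: 500.0
  refractory_ms: 2.0
  spike_threshold_mV: 0.0
lfp:
  sigma_S_per_m: 0.3
  pitch_um: 20.0
  dend_offset_um: 500.0
  electrode_um: null
  min_distance_um: 10.0
outputs:
  record_cortex_voltages: false
  voltage_traces: {}
channels: {}
schema: 1
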