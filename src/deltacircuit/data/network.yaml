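# Layer-V network configuration.
#
# Base pairwise connection probabilities (p) and synapses per connection are
# config defaults from the digital-microcircuit literature lineage for the
# seven nonzero layer-V classes; they are scaled by probability_scale at
# build time (clipping at 1 is logged).  Conductance symbols tie LBC and NGC
# outputs across their two target classes.
#
# Background drive: free calibration constants, NOT literature values; they
# were tuned (and frozen here) so the default healthy-control network hits
# the 3.0 Hz pyramidal-rate target with a delta-band-dominant spectrum.
# Gap-junction parameters are likewise config defaults unconstrained by the
# delta-power data.
populations: {PC: 120, LBC: 30, NGC: 30}
probability_scale: 6.0
connections:
  - {pre: PC,  post: PC,  p: 0.072, synapses: 5,  symbol: g_EE, receptors: [AMPA, NMDA]}
  - {pre: PC,  post: LBC, p: 0.057, synapses: 12, symbol: g_EI, receptors: [AMPA, NMDA]}
  - {pre: PC,  post: NGC, p: 0.04,  synapses: 4,  symbol: g_EN, receptors: [AMPA, NMDA]}
  - {pre: LBC, post: PC,  p: 0.084, synapses: 12, symbol: g_I,  receptors: [GABA_A]}
  - {pre: LBC, post: LBC, p: 0.083, synapses: 11, symbol: g_I,  receptors: [GABA_A]}
  - {pre: NGC, post: LBC, p: 0.035, synapses: 9,  symbol: g_N,  receptors: [GABA_B]}
  - {pre: NGC, post: PC,  p: 0.026, synapses: 9,  symbol: g_N,  receptors: [GABA_B]}
conductances: {g_EE: 0.2, g_EI: 0.7, g_EN: 1.2, g_I: 0.5, g_N: 0.6}
gap_junctions: {probability: 0.5, conductance_nS: 0.2}
background:
  targets_per_cell: 3
  receptors:
    AMPA: {rate_hz: 2000.0, weight_uS: 0.001}
    NMDA: {rate_hz: 2000.0, weight_uS: 0.001}
    GABA: {rate_hz: 800.0, weight_uS: 0.001}
nmda_ratio: 2.0
synaptic_delay_ms: 1.0
dt_ms: 0.05
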