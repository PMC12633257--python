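# Receptor kinetics for the four synapse classes.
# tau_rise / tau_decay in ms, reversal in mV, peak_conductance in uS
# (per-synapse baseline; connection-class weights scale it).
# GABA_B: rise 30 ms, decay 200 ms (slow neurogliaform-type inhibition).
# AMPA/GABA_A pairs follow the fast-kinetics lineage of the antecedent
# delta-oscillation model; NMDA carries the sigmoidal Mg-block.
receptors:
  - {receptor: AMPA,   tau_rise: 0.3,  tau_decay: 3.0,   reversal: 0.0,   peak_conductance: 0.000667}
  - {receptor: NMDA,   tau_rise: 2.0,  tau_decay: 65.0,  reversal: 0.0,   peak_conductance: 0.000667,
     mg_block: true, mg_conc: 1.0, mg_eta: 0.2801, mg_gamma: 0.062}
  - {receptor: GABA_A, tau_rise: 0.5,  tau_decay: 8.0,   reversal: -80.0, peak_conductance: 0.000333}
  - {receptor: GABA_B, tau_rise: 30.0, tau_decay: 200.0, reversal: -95.0, peak_conductance: 0.0067}
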