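# High-voltage-activated calcium channel (CACNA1C/CACNA1D-encoded, L-type like).
# Ohmic approximation with fixed calcium reversal; current feeds the
# intracellular calcium pool that drives SK.
name: Ca_HVA
ion: ca
reversal: 120.0
q10: 1.0
q10_ref_temp: 34.0
gates:
  - var: m
    power: 2
    form: alpha_beta
    alpha: {form: efun, A: 0.055, Vh: -27.0, k: 3.8}       # 0.055*(v+27)/(1-exp(-(v+27)/3.8))
    beta:  {form: expl, A: 0.94, Vh: -75.0, k: -17.0}
  - var: h
    power: 1
    form: alpha_beta
    alpha: {form: expl, A: 0.000457, Vh: -13.0, k: -50.0}
    beta:  {form: sigm, A: 0.0065, Vh: -15.0, k: 28.0}
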