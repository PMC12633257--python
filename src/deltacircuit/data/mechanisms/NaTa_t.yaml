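# Fast transient sodium channel (action-potential upstroke).
# Rates in 1/ms at 21 C; voltages in mV; density in S/cm2.
name: NaTa_t
ion: na
reversal: 50.0
q10: 2.3
q10_ref_temp: 21.0
gates:
  - var: m
    power: 3
    form: alpha_beta
    alpha: {form: efun, A: 0.182, Vh: -38.0, k: 6.0}      # 0.182*(v+38)/(1-exp(-(v+38)/6))
    beta:  {form: efun, A: -0.124, Vh: -38.0, k: -6.0}    # 0.124*(-(v+38))/(1-exp((v+38)/6))
  - var: h
    power: 1
    form: alpha_beta
    alpha: {form: efun, A: -0.015, Vh: -66.0, k: -6.0}    # -0.015*(v+66)/(1-exp((v+66)/6))
    beta:  {form: efun, A: 0.015, Vh: -66.0, k: 6.0}
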