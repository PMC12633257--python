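# Muscarinic-sensitive slow potassium channel (M-type, KCNQ3-like).
name: Im
ion: k
reversal: -85.0
q10: 2.3
q10_ref_temp: 21.0
gates:
  - var: m
    power: 1
    form: alpha_beta
    alpha: {form: expl, A: 0.0033, Vh: -35.0, k: 10.0}
    beta:  {form: expl, A: 0.0033, Vh: -35.0, k: -10.0}
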