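# Slow persistent potassium channel (KCNB1 / Kv2-like).
name: K_Pst
ion: k
reversal: -85.0
q10: 2.3
q10_ref_temp: 21.0
gates:
  - var: m
    power: 2
    form: inf_tau
    inf: {Vh: -11.0, k: 12.0}
    tau: {form: bell, t0: 1.25, amp: 175.0, v1: -50.0, k1: 23.0, v2: -76.0, k2: 12.0}
  - var: h
    power: 1
    form: inf_tau
    inf: {Vh: -64.0, k: -11.0}
    tau: {form: sigmoid, t0: 360.0, amp: 1010.0, Vh: -75.0, k: -48.0}
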