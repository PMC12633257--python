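# Fast delayed-rectifier potassium channel (spike repolarisation).
name: SKv3_1
ion: k
reversal: -85.0
q10: 1.0
q10_ref_temp: 34.0
gates:
  - var: m
    power: 1
    form: inf_tau
    inf: {Vh: 18.7, k: 9.7}
    tau: {form: sigmoid, t0: 0.05, amp: 4.0, Vh: -46.56, k: 44.14}
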