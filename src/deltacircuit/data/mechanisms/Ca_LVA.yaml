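# Low-voltage-activated calcium channel (CACNA1I-encoded, T-type like).
name: Ca_LVA
ion: ca
reversal: 120.0
q10: 2.3
q10_ref_temp: 21.0
gates:
  - var: m
    power: 2
    form: inf_tau
    inf: {Vh: -40.0, k: 6.0}
    tau: {form: sigmoid, t0: 5.0, amp: 20.0, Vh: -35.0, k: -5.0}
  - var: h
    power: 1
    form: inf_tau
    inf: {Vh: -90.0, k: -6.4}
    tau: {form: sigmoid, t0: 20.0, amp: 50.0, Vh: -50.0, k: -7.0}
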