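# Small-conductance calcium-activated potassium channel (SK; AHP current).
# Gated by intracellular calcium via a Hill function, not voltage.
name: SK_E2
ion: k
reversal: -85.0
q10: 1.0
q10_ref_temp: 34.0
gates:
  - var: z
    power: 1
    form: ca_hill
    Kd: 0.00043   # mM
    n: 4.8
    tau: 1.0      # ms
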