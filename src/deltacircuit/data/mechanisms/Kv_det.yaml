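# Deterministic replacement of the stochastic slow-inactivating Kv channel
# used by the interneuron models; identical mean-field HH kinetics with no
# random channel gating, so trajectories are bit-identical across runs.
name: Kv_det
ion: k
reversal: -85.0
deterministic: true
q10: 2.3
q10_ref_temp: 23.0
gates:
  - var: n
    power: 1
    form: inf_tau
    inf: {Vh: -36.0, k: 9.0}
    tau: {form: sigmoid, t0: 1.0, amp: 10.0, Vh: -46.0, k: -12.0}
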