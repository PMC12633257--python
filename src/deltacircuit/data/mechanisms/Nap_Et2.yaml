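# Persistent (non-inactivating on network timescales) sodium channel.
name: Nap_Et2
ion: na
reversal: 50.0
q10: 2.3
q10_ref_temp: 21.0
gates:
  - var: m
    power: 3
    form: inf_tau
    inf: {Vh: -52.6, k: 4.6}
    tau: {form: const, value: 6.0}
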