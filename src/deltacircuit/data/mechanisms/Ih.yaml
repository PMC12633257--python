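# Hyperpolarisation-activated mixed cation current (HCN1-like).
# Mixed Na/K current with depolarised reversal; activation gate opens on
# hyperpolarisation.
name: Ih
ion: nonspecific
reversal: -45.0
q10: 1.0
q10_ref_temp: 34.0
gates:
  - var: m
    power: 1
    form: alpha_beta
    alpha: {form: efun, A: -0.00643, Vh: -154.9, k: -11.9}  # 6.43e-3*(v+154.9)/(exp((v+154.9)/11.9)-1)
    beta:  {form: expl, A: 0.193, Vh: 0.0, k: 33.1}
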