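# Large basket cell, ball-and-stick reduction: soma + 2 dendrites of 301 um
# (1 segment each); stuttering e-type via the deterministic slow Kv.
cell_class: LBC
v_init: -72.0
sections:
- name: soma
  length: 20
  diameter: 15
  nseg: 1
  ra: 100
  cm: 1.0
  g_pas: 9.0e-05
  e_pas: -75.0
- name: dend1
  parent: soma
  length: 301
  diameter: 2.1
  nseg: 1
  ra: 100
  cm: 1.0
  g_pas: 9.0e-05
  e_pas: -75.0
- name: dend2
  parent: soma
  length: 301
  diameter: 2.1
  nseg: 1
  ra: 100
  cm: 1.0
  g_pas: 9.0e-05
  e_pas: -75.0
calcium:
  decay: 80.0
  gamma: 0.0008
  depth: 0.1
  ca_min: 0.0001
  sections:
  - soma
channels:
  soma:
    NaTa_t: 1.5
    SKv3_1: 0.6
    Kv_det: 0.008
    K_Pst: 0.004
    Im: 0.0002
    Ih: 8.0e-05
    Ca_HVA: 0.0003
    SK_E2: 0.02
  dend1:
    NaTa_t: 0.012
    SKv3_1: 0.004
    Ih: 8.0e-05
  dend2:
    NaTa_t: 0.012
    SKv3_1: 0.004
    Ih: 8.0e-05
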