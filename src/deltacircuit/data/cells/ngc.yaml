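# Neurogliaform cell, ball-and-stick reduction: soma + 2 dendrites of 245 um
# (5 segments each); burst-non-accommodating e-type.
cell_class: NGC
v_init: -72.0
sections:
- name: soma
  length: 15
  diameter: 15
  nseg: 1
  ra: 100
  cm: 1.0
  g_pas: 0.0001
  e_pas: -72.0
- name: dend1
  parent: soma
  length: 245
  diameter: 1.95
  nseg: 5
  ra: 100
  cm: 1.0
  g_pas: 0.0001
  e_pas: -72.0
- name: dend2
  parent: soma
  length: 245
  diameter: 1.95
  nseg: 5
  ra: 100
  cm: 1.0
  g_pas: 0.0001
  e_pas: -72.0
channels:
  soma:
    NaTa_t: 2.0
    SKv3_1: 0.35
    Kv_det: 0.002
    Ca_LVA: 0.001
    Im: 0.0001
    Ih: 0.0001
  dend1:
    NaTa_t: 0.01
    SKv3_1: 0.003
  dend2:
    NaTa_t: 0.01
    SKv3_1: 0.003
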