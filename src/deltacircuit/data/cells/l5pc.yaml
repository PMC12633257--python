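# Simplified thick-tufted layer-5 pyramidal cell: soma + basal + apical trunk
# + tuft, with Hay-lineage conductance complement (densities in S/cm2).
cell_class: PC
v_init: -75.0
sections:
  - {name: soma,   length: 25,  diameter: 25,  nseg: 1, ra: 100, cm: 1.0, g_pas: 3.38e-5, e_pas: -90}
  - {name: basal,  parent: soma,   length: 250, diameter: 3.0, nseg: 3, ra: 100, cm: 2.0, g_pas: 4.67e-5, e_pas: -90}
  - {name: apical, parent: soma,   length: 500, diameter: 4.0, nseg: 5, ra: 100, cm: 2.0, g_pas: 5.89e-5, e_pas: -90}
  - {name: tuft,   parent: apical, length: 300, diameter: 2.5, nseg: 3, ra: 100, cm: 2.0, g_pas: 5.89e-5, e_pas: -90}
calcium: {decay: 60.0, gamma: 0.016, depth: 0.1, ca_min: 1.0e-4, sections: [soma, apical]}
channels:
  soma:
    NaTa_t: 2.04
    SKv3_1: 0.693
    Nap_Et2: 0.00172
    K_Pst: 0.0223
    Ca_HVA: 0.000992
    Ca_LVA: 0.00343
    SK_E2: 0.0441
    Ih: 0.0002
    Im: 0.0001
  basal:
    Ih: 0.0002
  apical:
    NaTa_t: 0.0213
    SKv3_1: 0.000261
    Ca_HVA: 0.000555
    Ca_LVA: 0.0187
    SK_E2: 0.0012
    Im: 0.0000675
    Ih: 0.002
  tuft:
    NaTa_t: 0.0106
    SKv3_1: 0.000131
    Ca_HVA: 0.000278
    Ca_LVA: 0.00936
    Im: 0.0000675
    Ih: 0.004
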