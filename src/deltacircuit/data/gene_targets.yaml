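# Schizophrenia-risk genes encoding model channels: target SCZ/HC expression
# ratios per region, minimal GWAS SNP p-values, and generator defaults for
# healthy-control mean expression (DESeq2-normalized scale) and dispersion.
genes:
  CACNA1C: {channel: Ca_HVA, acc_ratio: 1.171, pfc_ratio: 1.139, min_p: 1.279e-21, hc_mean: 1800.0}
  CACNA1D: {channel: Ca_HVA, acc_ratio: 1.158, pfc_ratio: 1.135, min_p: 3.277e-9,  hc_mean: 1200.0}
  CACNA1I: {channel: Ca_LVA, acc_ratio: 1.173, pfc_ratio: 1.144, min_p: 1.171e-13, hc_mean: 600.0}
  HCN1:    {channel: Ih,     acc_ratio: 1.034, pfc_ratio: 1.117, min_p: 2.873e-14, hc_mean: 2500.0}
  KCNB1:   {channel: K_Pst,  acc_ratio: 1.123, pfc_ratio: 1.150, min_p: 2.197e-10, hc_mean: 1500.0}
  KCNQ3:   {channel: Im,     acc_ratio: 1.056, pfc_ratio: 1.034, min_p: 2.128e-6,  hc_mean: 900.0}
  GABBR2:  {channel: GABA_B, acc_ratio: 1.084, pfc_ratio: 1.095, min_p: 9.334e-9,  hc_mean: 3200.0}
cohorts:
  ACC: {SCZ: 230, HC: 251}
  PFC: {SCZ: 263, HC: 295}
dispersion: 0.2
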