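# Synthetic stand-in reference f-I table for the LBC reduction.
# Generated from this package's own 19-segment ball-and-stick LBC
# model at dendrite length 301.0 um (area-preserving diameter
# 2.1000 um, total dendritic area 3971.6 um2), 1 s stimuli.
# amplitude_nA frequency_Hz
0.000 0.0000
0.100 0.0000
0.200 0.0000
0.300 53.0000
0.400 71.0000
0.500 83.0000
0.600 92.0000
0.700 101.0000
0.800 108.0000
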