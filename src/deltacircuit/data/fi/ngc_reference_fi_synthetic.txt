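# Synthetic stand-in reference f-I table for the NGC reduction.
# Generated from this package's own 19-segment ball-and-stick NGC
# model at dendrite length 245.0 um (area-preserving diameter
# 1.9500 um, total dendritic area 3001.8 um2), 1 s stimuli.
# amplitude_nA frequency_Hz
0.000 0.0000
0.025 0.0000
0.050 0.0000
0.075 32.0000
0.100 51.0000
0.125 63.0000
0.150 72.0000
0.175 80.0000
0.200 87.0000
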