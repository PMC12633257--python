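"""Ball-and-stick reduction demo.

Recovers the dendrite length of the LBC reduction from its reference f-I
table (shipped synthetic stand-in generated at 301 um): a coarse 50-um grid
search locates the minimum of the summed absolute f-I error, then a fine
1-um search pins it down while the dendrite diameter is adjusted at every
length so total dendritic area is conserved.  A second search then finds the
smallest odd sub-compartment count matching the 19-segment model.
A narrow fine window and a 5-amplitude protocol keep the demo to a few
minutes; the full-width search behaves identically.
"""
from importlib import resources

from deltacircuit.cells import CurrentClampProtocol, FICurve, cell_registry
from deltacircuit.reduction import (ReductionSearchConfig, area_preserving_diameter,
                                    segment_count_search, two_stage_length_search)

template = cell_registry()["LBC"]
ref = FICurve.load(str(resources.files("deltacircuit") / "data" / "fi"
                       / "lbc_reference_fi_synthetic.txt"))
keep = slice(4, 9)
ref_small = FICurve(ref.amplitudes[keep], ref.frequencies[keep])
protocol = CurrentClampProtocol(tuple(ref_small.amplitudes), stimulus_duration=1000.0)
cfg = ReductionSearchConfig(reference_fi=ref_small,
                            total_dendritic_area=template.total_dendritic_area(),
                            fine_halfwidth=25.0)
res = two_stage_length_search(template, cfg, protocol)
print(f"coarse best: {res.coarse_lengths[res.coarse_errors.argmin()]:.0f} um, "
      f"fine best: {res.best_length:.0f} um (error {res.best_error:.1f} Hz)")
best = template.with_dendrite_geometry(
    res.best_length, area_preserving_diameter(cfg.total_dendritic_area, res.best_length))
segs = segment_count_search(best, cfg, protocol)
print(f"segment search: errors vs 19-segment model {dict(zip(segs.candidates, segs.errors))}")
print(f"-> {segs.best_nseg} segment(s) per dendrite suffice "
      f"(threshold {segs.threshold:.0f} Hz)")
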