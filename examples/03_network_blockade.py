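"""Receptor-blockade calibration of the layer-V network (desk scale).

Simulates the control network and the two pharmacological blockade
conditions (GABA_A: basket->pyramidal weights zeroed; GABA_B: all
neurogliaform-origin weights zeroed) with paired noise seeds, and prints
delta-band (0.5-5 Hz) power of the pyramidal population rate as a percentage
of control.  GABA_B blockade collapses the slow rhythm (far below 100%),
GABA_A blockade does not reduce it — the qualitative pattern of the slice
pharmacology the model is calibrated against.
"""
import numpy as np

from deltacircuit.network import (BlockadeState, NetworkSpec, apply_blockade,
                                  build_network, simulate_network)
from deltacircuit.spectral import (SpectralConfig, band_power, firing_rate,
                                   population_rate_signal, power_spectrum)

spec = NetworkSpec.default(n_PC=40, n_LBC=10, n_NGC=10)
spectral = SpectralConfig(segment_ms=2048.0)
ratios = {"blockA": [], "blockB": []}
for seed in (2, 3, 4):
    deltas = {}
    for cond in ("control", "blockA", "blockB"):
        net = build_network(spec, seed=1)
        if cond == "blockA":
            apply_blockade(net, BlockadeState(gabaA_blocked=True))
        if cond == "blockB":
            apply_blockade(net, BlockadeState(gabaB_blocked=True))
        sts = simulate_network(net, 10000.0, seed=seed)
        ps = power_spectrum(population_rate_signal(sts), spectral)
        deltas[cond] = band_power(ps, "delta")
        if cond == "control" and seed == 2:
            print(f"control rates: PC {firing_rate(sts, 'PC'):.2f} Hz, "
                  f"LBC {firing_rate(sts, 'LBC'):.2f} Hz, "
                  f"NGC {firing_rate(sts, 'NGC'):.2f} Hz")
    for c in ratios:
        ratios[c].append(100.0 * deltas[c] / deltas["control"])
print(f"GABA_A blockade: {np.mean(ratios['blockA']):.0f}% of control delta power")
print(f"GABA_B blockade: {np.mean(ratios['blockB']):.0f}% of control delta power")
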