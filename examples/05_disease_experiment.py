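"""Population-averaged disease experiment (desk scale).

Compares delta power between the healthy-control network and a network whose
channel densities are multiplied by the ACC expression coefficients (HVA and
LVA calcium, Ih, persistent and M-type potassium, and the GABA_B synaptic
weight), using the same seed list in both arms and a two-sided Mann-Whitney
U test across seeds.  A negative percent change means the disease variant
loses delta power.
"""
from deltacircuit.experiments import ExperimentConfig, run_population_averaged

cfg = ExperimentConfig.preset("desk", n_seeds=5)
res = run_population_averaged("ACC", cfg)
s = res.summary()
print(f"delta-power change (SCZ vs HC): {s['percent_change_delta']:+.1f}%")
print(f"PC rate: HC {s['hc_rate_mean']:.2f} Hz -> SCZ {s['scz_rate_mean']:.2f} Hz")
print(f"Mann-Whitney U = {s['U']:.0f}, p = {s['p']:.3f} "
      f"(n = {s['n_hc']} seeds per arm, raw p-value)")
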