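# deltacircuit

Biophysical modelling of how schizophrenia-associated changes in ion-channel
gene expression alter cortical delta oscillations.

Delta-band (0.5–5 Hz) power is reproducibly altered in schizophrenia, and
layer-V pyramidal cells are central to cortically generated delta rhythms.
`deltacircuit` implements a minimal layer-V network of conductance-based
multicompartment neurons — 120 thick-tufted pyramidal cells (PC), 30 large
basket cells (LBC, GABA_A-kinetic output) and 30 neurogliaform cells (NGC,
slow GABA_B-kinetic output, τ_rise/τ_decay = 30/200 ms) — driven by
stochastic background input to the PCs.  The network is calibrated against
slice pharmacology (GABA_A blockade raises delta power to ~109% of control;
GABA_B blockade collapses it to ~17%), and disease variants are built by
multiplying channel conductances with SCZ/HC expression ratios of
GWAS-supported risk genes:

| gene | target conductance | ACC | PFC |
|---|---|---|---|
| CACNA1C, CACNA1D | HVA Ca²⁺ (averaged) | 1.164 | 1.137 |
| CACNA1I | LVA Ca²⁺ | 1.173 | 1.144 |
| HCN1 | Ih | 1.034 | 1.117 |
| KCNB1 | persistent K⁺ | 1.123 | 1.150 |
| KCNQ3 | M-type K⁺ | 1.056 | 1.034 |
| GABBR2 | GABA_B synaptic weight | 1.084 | 1.095 |

The spectral readout is the Welch power spectrum of the binned,
mean-subtracted PC population spike-count signal; experiments compare
delta-band power between arms with a two-sided Mann–Whitney U test.

The package is used from Python.  It covers, module by module:

* `mechanisms` — Hodgkin–Huxley channel kinetics and dual-exponential
  receptor models (AMPA, NMDA with Mg-block, GABA_A, GABA_B), defined by
  per-mechanism YAML configs;
* `cells` — the PC/LBC/NGC parameter sets, current-clamp protocols and f-I
  curves;
* `engine` — a fixed-step implicit compartmental integrator (backward-Euler
  Hines solve, exact exponential gating updates, numba-compiled);
* `reduction` — the two-stage ball-and-stick reduction (area-conserving
  dendrite-length search, then minimal sub-compartment count) against
  reference f-I tables;
* `network` — wiring, gap junctions, background drive, receptor blockades
  and coefficient application;
* `spectral` — population-rate signals, Welch spectra, band powers, LOESS
  smoothing;
* `expression` / `synthetic_data` — GWAS filtering, expression-ratio
  coefficients (population-averaged and subject-wise), and a synthetic
  cohort generator at the published cohort sizes;
* `fit_conductances` / `experiments` — the conductance grid search and the
  four disease experiments with their statistics.

A thin CLI (`delta-circuit synth|reduce|fit|blockade|run`) wraps the same
functions; the `examples/` directory holds one narrative script per
capability.

## Worked example

`examples/03_network_blockade.py` simulates the scaled-down (40/10/10)
control network and both receptor blockades with paired noise seeds:

```text
control rates: PC 1.14 Hz, LBC 3.19 Hz, NGC 25.56 Hz
GABA_A blockade: 101% of control delta power
GABA_B blockade: 20% of control delta power
```

Silencing the neurogliaform (GABA_B) pathway collapses delta power to 20%
of control — the slow rhythm is paced by 200 ms GABA_B inhibition — while
silencing the basket-cell (GABA_A) input to PCs leaves it intact, matching
the qualitative pattern of the slice pharmacology the model is calibrated
against.  `examples/05_disease_experiment.py` then applies the ACC
coefficient set to all populations:

```text
delta-power change (SCZ vs HC): -1.8%
PC rate: HC 1.71 Hz -> SCZ 1.62 Hz
Mann-Whitney U = 13, p = 1.000 (n = 5 seeds per arm, raw p-value)
```

The disease variant loses delta power and pyramidal firing.  At this desk
scale and seed count the effect is directional rather than significant —
per-seed variance in delta power is large, and the unpaired five-seed
comparison has little power (the full-scale layout uses 30 seeds and 30 s
runs; paired per-seed ratios, as used in the acceptance script, give a
steadier estimate).  See `docs/methods.md` for the model, its calibration,
and known limitations.

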