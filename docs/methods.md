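# Methods

`deltacircuit` models cortically generated delta oscillations (~0.5–5 Hz) in
a minimal layer-V network and asks how schizophrenia-associated changes in
ion-channel gene expression alter them.  This note documents the model, its
numerics, the calibration, and what the shipped defaults do and do not claim.

## Cell models

Three conductance-based multicompartment cell classes are shipped as YAML
parameter sets (`data/cells/`):

* **PC** — a simplified thick-tufted layer-5 pyramidal cell: cylindrical
  soma, basal dendrite, apical trunk and tuft (12 compartments).  Conductance
  complement: fast transient Na (NaTa_t), persistent Na (Nap_Et2), fast
  delayed-rectifier K (SKv3_1), slow persistent K (K_Pst), M-type K (Im),
  hyperpolarization-activated mixed cation current (Ih, strongest in the
  tuft), high- and low-voltage-activated Ca (Ca_HVA, Ca_LVA) and
  Ca-activated SK, coupled through a single-pool submembrane calcium model
  (decay 60 ms, fractional influx gamma = 0.016, shell depth 0.1 µm,
  resting 0.1 µM).
* **LBC** — a large basket cell reduced to a ball-and-stick: soma plus two
  301 µm dendrites of 1 sub-compartment each; fast-spiking complement with a
  deterministic slow Kv current producing mild stuttering near rheobase.
* **NGC** — a neurogliaform cell: soma plus two 245 µm dendrites of 5
  sub-compartments each; burst-non-accommodating complement including a
  small T-type Ca conductance.

Gating kinetics follow the Hodgkin–Huxley formalism with rate laws described
declaratively (one YAML per mechanism) using a small library of forms
(exponential, sigmoid, linoid, and inf/tau pairs; a calcium Hill gate for
SK).  The parameter values are authored from the published equation lineage
of the detailed layer-V models this package descends from; the exact
original parameter files are not redistributed here, so the shipped cells
are calibrated surrogates, not copies.  Each cell's f-I curve was tuned to
its class phenotype over the published current ranges (LBC: 0–0.8 nA,
rheobase 0.3 nA, 110 Hz at 0.8 nA; NGC: 0–0.2 nA, rheobase 0.075 nA, 87 Hz
at 0.2 nA); currents beyond these ranges drive unrealistically fast firing.

The stochastic Kv channel of the source interneuron models is replaced by a
deterministic mean-field variant (`Kv_det`): no random channel gating exists
anywhere in the package, so trajectories are bit-identical given the seed.

## Numerical integration

The engine (`engine.py`) flattens all cells into structure-of-arrays form
and advances them with a fixed-step implicit scheme:

* voltage by backward Euler with an exact per-step Hines solve of the
  branched-cable system (compartments ordered parent-before-child);
* gating variables by exact exponential relaxation
  `x ← x_inf + (x − x_inf)·exp(−dt·q_T/τ)`, which is the analytic solution
  for frozen voltage; steady states and decay factors are linearly
  interpolated from 0.05 mV-resolution tables (log-spaced for the calcium
  gate), built once per (dt, temperature);
* synapses as difference-of-exponential conductances aggregated per
  (compartment, receptor): the kinetics are linear, so one state pair per
  target replaces per-synapse state; presynaptic events add the
  peak-normalised weight after a 1 ms conduction delay;
* NMDA carries the standard sigmoidal Mg-block factor, evaluated at the
  previous-step voltage;
* gap junctions (LBC–LBC somatic, 0.2 nS) explicitly at previous-step
  voltages — adequate for this weak coupling;
* background drive as per-step Poisson event counts per (target
  compartment, receptor), drawn inside the kernel from the run seed.

Default dt is 25 µs for single-cell work and 50 µs for network runs; the
kernel is compiled with numba.  A fixed-step implicit integrator was chosen
over an adaptive one: with the stochastic channel determinised,
reproducibility is exact at any fixed step, and halving dt changes network
spike counts at the ≤1-spike-per-trace level.  Integration aborts with a
diagnostic if |V| exceeds 200 mV.

All kinetics are evaluated at 34 °C via per-mechanism q10 factors.
Temperature, thresholds (spike detection −10 mV, 1 ms refractory) and the
1000 ms analysis transient are configurable.

## Morphology reduction

The ball-and-stick reductions are produced by a two-stage search
(`reduction.py`): dendrite lengths over 50–750 µm in 50 µm steps, then
±75 µm in 1 µm steps around the coarse minimum, with the dendrite diameter
set at every candidate length to `d = A/(2πL)` so the two cylinders carry
the full model's total dendritic area (conserved to better than 1e−9
relative).  Candidates are scored by the summed absolute f-I difference
against a reference curve; ties break toward the smaller length.  A second
search then returns the smallest odd sub-compartment count per dendrite
whose f-I error against the 19-segment model stays below 1 Hz per amplitude
point (the matching requirement is qualitative; this default makes it
concrete).  The error metric is a sum over amplitudes — a mean would change
tables by a constant factor but not the argmin — and the choice is recorded
in every report file.

Reference f-I curves are consumed as two-column text tables.  The shipped
tables (`data/fi/*_synthetic.txt`) are synthetic stand-ins generated from
this package's own 19-segment models at the literature lengths (301 µm LBC,
245 µm NGC), because the original full-morphology models cannot be
redistributed; with user-supplied tables from the real full models the same
machinery applies unchanged.  Note that simulated f-I curves quantize
frequency at 1/duration, so the zero-error set of the length search is a
short plateau rather than a single point.

## Network

Default composition is 120 PC / 30 LBC / 30 NGC (one third inhibitory).
Seven connection classes carry synapses (PC→PC, PC→LBC, PC→NGC, LBC→PC,
LBC→LBC, NGC→LBC, NGC→PC); classes reported with zero probability in the
reference microcircuit carry none.  Base pairwise probabilities (config,
`data/network.yaml`) are scaled by 6 to compensate for the small size, and
clipped at 1 with a warning.  Synapses per connection are class defaults;
placement is uniform over postsynaptic dendritic sub-compartments.
Excitatory synapses carry paired AMPA + NMDA components (NMDA weight ratio
2); basket output is GABA_A-kinetic (τ 0.5/8 ms, −80 mV), neurogliaform
output GABA_B-kinetic (τ 30/200 ms, reversal −95 mV, a K⁺-like value since
the effector is a K channel; configurable).  Five dimensionless class
weights (g_EE, g_EI, g_EN, g_I, g_N) scale the class peak conductances, with
the two ties g_I: LBC→PC = LBC→LBC and g_N: NGC→PC = NGC→LBC (the tying
convention is the one that keeps g_EI and g_EN distinct).

Synaptic weights are multiplied by `n_pre_reference / n_pre` (reference
composition 120/30/30), so scaled-down networks keep the mean recurrent
input per cell.

Background drive — independent Poisson streams into AMPA, NMDA and GABA_A
receptors at three sites per PC (soma + two dendritic), PCs only — is a free
calibration constant, not a literature value: rates and weights were tuned
and frozen in config (see Calibration).  Whether the GABA component of the
drive is GABA_A- or mixed-kinetic is unspecified upstream; GABA_A is
assumed and configurable.

**Blockades** zero class conductances and never delete synapses, so they are
exactly reversible: GABA_A blockade zeroes LBC→PC (the literal scope of the
experiment being emulated; a `block_all_gabaA` flag extends it to LBC→LBC
for pharmacological realism), GABA_B blockade zeroes both NGC-origin
classes.

**Coefficient application** multiplies channel densities in the targeted
populations wherever the channel exists; the GABBR2 coefficient multiplies
GABA_B synaptic weights selected by postsynaptic population.  Applications
compose multiplicatively and invert exactly.

## Calibration and the delta rhythm

The healthy-control network was calibrated at desk scale (40/10/10, see
below) against the pharmacological targets: GABA_A blockade should raise
delta power slightly (≈109% of control), GABA_B blockade should collapse it
(≈17%).  In the shipped regime the slow rhythm is a GABA_B-paced population
oscillation: pyramidal bursts recruit NGCs, whose slow inhibition silences
the PCs for a few hundred milliseconds; SK-mediated adaptation (calcium
decay 60 ms) shapes burst termination but is deliberately too fast to pace a
delta rhythm on its own — with GABA_B removed, the network settles into
faster (~8–10 Hz), weakly coordinated firing whose delta-band power is a
small fraction of control.  Measured at desk scale (4 paired seeds, 10 s):
GABA_B-blocked delta ≈ 10–25% of control, GABA_A-blocked ≈ 95–115%,
control PC rate ≈ 1.1 Hz, LBC ≈ 3.2 Hz.

The five class weights default to g_EE=0.2, g_I=0.5, g_EI=0.7, g_EN=1.2,
g_N=0.6; the grid-search module (`fit_conductances.py`) reproduces the
calibration protocol around these values (a full factorial of 3 values per
weight, 243 candidates; 3 screening seeds, rate-window rejection with PC ∈ [2.5, 3.5] Hz
and LBC ∈ [3, 12] Hz, 5 confirmation seeds).  The final-model score is the
summed absolute deviation of the two blockade ratios from their targets;
the sentence defining the published selection admits a second reading
(the difference between the two alterations), which is provided as an
alternative scoring and labelled in the output.

## Expression mapping and the synthetic cohort

Seven risk genes map to model parameters (CACNA1C, CACNA1D → HVA Ca;
CACNA1I → LVA Ca; HCN1 → Ih; KCNB1 → persistent K; KCNQ3 → M-type K;
GABBR2 → GABA_B synaptic weight).  The map is closed-world: glutamatergic
and GABA_A receptor genes are deliberately excluded because their expression
is likely confounded by antipsychotic use.  Population-averaged coefficients
are ratios of group means (SCZ/HC) per region — the most direct reading of
an "average difference between populations" — with the two HVA genes
averaged (ACC 1.164, PFC 1.137).  Subject-wise coefficients divide each
subject's expression by the healthy-control mean of their region (HC
subjects included); subjects missing any mapped gene are dropped with a
logged count.

The synthetic cohort generator draws `x = µ · Gamma(1/d, d)` per gene and
subject (multiplicative gamma noise, a continuous gamma–Poisson
approximation suited to non-integer normalized counts; dispersion d = 0.2,
i.e. ~45% between-subject CV), with µ the gene's healthy-control mean and
`ratio·µ` for SCZ subjects, at the published cohort sizes (ACC 230/251,
PFC 263/295).  d = 0 degenerates to exact group means.  The generator
emulates group-mean structure only: no covariates (age, sex, post-mortem
interval), batch effects, or co-expression — so passing tests demonstrate
correct pipeline arithmetic and unbiased ratio recovery, not robustness to
real-data confounding.  The delta-method SE of a recovered ratio,
`r·sqrt(d/n_SCZ + d/n_HC)` (~4% per draw at these sizes), is exposed for
test calibration.

## Spectral analysis and statistics

Spectral estimates are based on pyramidal spiking only: spike trains are
binned at 1 ms into a mean-subtracted population count series (after a 1 s
transient), and Welch's method (Hann window, 50% overlap; 8192 ms segments
by default, 2048 ms in the desk preset) yields the power spectrum.  Band
powers are means over in-band frequencies — a summed reduction is also
provided; ratios and rank tests are invariant to the choice on a shared
grid, which the tests assert.  Delta is 0.5–5 Hz; beta defaults to
12–30 Hz with a 13–30 Hz preset matching the alternative convention.
LOESS smoothing (statsmodels lowess, no robustness iterations) is available
for presentation and never feeds statistics.  Group comparisons use the
two-sided Mann–Whitney U test with tie correction; p-values are reported
raw, without multiple-testing correction, and flagged as such.

## Scale presets and problem sizes

* `full`: 120/30/30 cells, 30 seeds, 30 s runs — the full experiment
  layout, suitable for long unattended runs.
* `desk`: 40/10/10 cells, 5 seeds, 10 s runs, 2048 ms Welch segments — the
  calibrated, tested object; all tests and the acceptance script use it.

## Known limitations

* The control PC rate at desk scale is ~1.1 Hz, below the 2.5–3.5 Hz
  acceptance window used in the published calibration; within this model
  family, backgrounds strong enough to push PCs to 3 Hz weaken the
  GABA_B-paced rhythm and degrade the blockade contrast, and the blockade
  contrast was prioritised.  The rate windows remain the defaults of the
  fitting module.
* The desk-scale calibration does not transfer quantitatively to the
  120/30/30 network: 1/N weight scaling preserves mean input but not the
  input fluctuations that seed population bursts, so the full-scale network
  runs slower (PC ≈ 0.5 Hz) and needs its own background calibration.
  Blockade directions persist at full scale; full-scale effect magnitudes
  are not claimed.
* The disease-coefficient effect on delta power at desk scale is a few
  percent to ~−13% depending on seeds — directionally stable under paired
  comparison but small relative to per-seed variance; claims are therefore
  directional, not quantitative.
* Channel kinetics are authored from the published equation lineage, not
  extracted from the original model files; single-cell behaviour is
  class-typical but not a parameter-for-parameter reproduction.
* Spectra are rate-based; no LFP/EEG forward model is included.
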