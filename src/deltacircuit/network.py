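"""The 180-cell layer-V network: construction, blockade, coefficient scaling
and simulation.

The default composition is 120 pyramidal cells (PC), 30 large basket cells
(LBC) and 30 neurogliaform cells (NGC).  Only seven connection classes carry
synapses (PC→PC, PC→LBC, PC→NGC, LBC→PC, LBC→LBC, NGC→LBC, NGC→PC); base
pairwise probabilities from the microcircuit literature are scaled by 6 (the
network is much smaller than the reference circuit) and clipped at 1.
Basket-cell output is GABA_A-kinetic, neurogliaform output GABA_B-kinetic;
excitatory connections carry paired AMPA + NMDA components.  LBCs are
additionally coupled by somatic gap junctions.  Stochastic background drive
(independent Poisson streams into AMPA, NMDA and GABA receptors) reaches the
PC population only.

Receptor blockades act by zeroing the relevant class conductances — GABA_A
blockade zeroes LBC→PC, GABA_B blockade zeroes both NGC-origin classes —
and never delete synapses, so they are exactly reversible.  Expression-derived
coefficient sets multiply channel densities (and GABA_B synaptic weights,
selected by the postsynaptic cell) in the targeted populations and compose
multiplicatively.

Wiring is fully determined by the spec seed; run-to-run stochasticity enters
only through the seeded background drive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .cells import cell_registry, realize
from .engine import Simulation
from .exceptions import MappingError, ValidationError
from .mechanisms import mechanism_registry, synapse_registry

__all__ = [
    "ConnectionClass",
    "SynapticConductanceSet",
    "BackgroundDrive",
    "BlockadeState",
    "NetworkSpec",
    "SpikeTrainSet",
    "RealizedNetwork",
    "build_network",
    "apply_blockade",
    "apply_coefficients",
    "simulate_network",
]

POPULATIONS = ("PC", "LBC", "NGC")

#: channel keys a coefficient set may address (plus the GABA_B synaptic weight)
CHANNEL_KEYS = ("Ca_HVA", "Ca_LVA", "Ih", "K_Pst", "Im", "GABA_B")


@dataclass(frozen=True)
class ConnectionClass:
    pre: str
    post: str
    p_base: float  # literature pairwise probability, before x6 scaling
    synapses_per_connection: int
    symbol: str  # which SynapticConductanceSet weight applies
    receptors: tuple[str, ...]  # synapse kinds instantiated per synapse


@dataclass(frozen=True)
class SynapticConductanceSet:
    """Dimensionless class weights; the LBC and NGC outputs are tied by construction."""

    g_EE: float = 0.2  # PC->PC
    g_EI: float = 0.7  # PC->LBC
    g_EN: float = 1.2  # PC->NGC
    g_I: float = 0.5  # LBC->PC and LBC->LBC (tied)
    g_N: float = 0.6  # NGC->PC and NGC->LBC (tied)

    def __post_init__(self) -> None:
        for name in ("g_EE", "g_EI", "g_EN", "g_I", "g_N"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def weight(self, symbol: str) -> float:
        return getattr(self, symbol)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("g_EE", "g_EI", "g_EN", "g_I", "g_N")}


@dataclass(frozen=True)
class BackgroundDrive:
    """Independent Poisson drive per receptor, PC compartments only."""

    rates_hz: dict = field(default_factory=dict)  # receptor -> events/s per target site
    weights_uS: dict = field(default_factory=dict)
    targets_per_cell: int = 3  # soma plus dendritic sites

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rates_hz.values()):
            raise ValidationError("background rates must be >= 0")


@dataclass
class BlockadeState:
    gabaA_blocked: bool = False
    gabaB_blocked: bool = False
    block_all_gabaA: bool = False  # extend GABA_A blockade to LBC->LBC


@dataclass(frozen=True)
class NetworkSpec:
    n_PC: int = 120
    n_LBC: int = 30
    n_NGC: int = 30
    connections: tuple[ConnectionClass, ...] = ()
    conductances: SynapticConductanceSet = field(default_factory=SynapticConductanceSet)
    background: BackgroundDrive = field(default_factory=BackgroundDrive)
    probability_scale: float = 6.0
    #: composition the class weights were calibrated at; synaptic weights are
    #: scaled by n_pre_reference / n_pre so the per-cell recurrent input is
    #: preserved when the network is scaled down (standard 1/N scaling)
    reference_populations: tuple = (120, 30, 30)
    gap_junction_probability: float = 0.5
    gap_junction_conductance_nS: float = 0.2
    nmda_ratio: float = 1.0  # NMDA weight relative to AMPA on excitatory synapses
    synaptic_delay_ms: float = 1.0
    dt_ms: float = 0.05
    temperature: float = 34.0

    @classmethod
    def default(cls, **overrides) -> "NetworkSpec":
        """The shipped network configuration (data/network.yaml)."""
        cfg = yaml.safe_load(
            (resources.files("deltacircuit") / "data" / "network.yaml").read_text()
        )
        conns = tuple(
            ConnectionClass(
                pre=c["pre"], post=c["post"], p_base=float(c["p"]),
                synapses_per_connection=int(c["synapses"]), symbol=c["symbol"],
                receptors=tuple(c["receptors"]),
            )
            for c in cfg["connections"]
        )
        bg = cfg["background"]
        spec = cls(
            n_PC=int(cfg["populations"]["PC"]),
            n_LBC=int(cfg["populations"]["LBC"]),
            n_NGC=int(cfg["populations"]["NGC"]),
            connections=conns,
            conductances=SynapticConductanceSet(**cfg["conductances"]),
            background=BackgroundDrive(
                rates_hz={k: float(v["rate_hz"]) for k, v in bg["receptors"].items()},
                weights_uS={k: float(v["weight_uS"]) for k, v in bg["receptors"].items()},
                targets_per_cell=int(bg.get("targets_per_cell", 3)),
            ),
            probability_scale=float(cfg.get("probability_scale", 6.0)),
            gap_junction_probability=float(cfg["gap_junctions"]["probability"]),
            gap_junction_conductance_nS=float(cfg["gap_junctions"]["conductance_nS"]),
            nmda_ratio=float(cfg.get("nmda_ratio", 1.0)),
            synaptic_delay_ms=float(cfg.get("synaptic_delay_ms", 1.0)),
            dt_ms=float(cfg.get("dt_ms", 0.05)),
        )
        return replace(spec, **overrides) if overrides else spec

    def validate(self) -> None:
        if min(self.n_PC, self.n_LBC, self.n_NGC) < 1:
            raise ValidationError("all populations must be non-empty")
        allowed = {("PC", "PC"), ("PC", "LBC"), ("PC", "NGC"), ("LBC", "PC"),
                   ("LBC", "LBC"), ("NGC", "LBC"), ("NGC", "PC")}
        for c in self.connections:
            if (c.pre, c.post) not in allowed:
                raise ValidationError(
                    f"{c.pre}->{c.post} is a zero-probability class and may carry no synapses"
                )


@dataclass
class SpikeTrainSet:
    """Per-neuron spike times with population labels."""

    spike_times: list  # list of np.ndarray, ms, sorted
    populations: list  # population label per neuron
    duration: float  # ms
    transient: float = 1000.0  # ms discarded by analysis

    def population_indices(self, population: str) -> list[int]:
        return [i for i, p in enumerate(self.populations) if p == population]

    def save(self, path, sidecar=None) -> None:
        """Two-column text (neuron_id, time_ms) plus a population-map sidecar."""
        rows = [
            (i, t) for i, st in enumerate(self.spike_times) for t in st
        ]
        with open(path, "w") as fh:
            fh.write(f"# duration_ms={self.duration} transient_ms={self.transient}\n")
            fh.write("# neuron_id time_ms\n")
            for i, t in rows:
                fh.write(f"{i} {t:.3f}\n")
        side = sidecar or (str(path) + ".populations")
        with open(side, "w") as fh:
            fh.write("# neuron_id population\n")
            for i, p in enumerate(self.populations):
                fh.write(f"{i} {p}\n")

    @classmethod
    def load(cls, path, sidecar=None) -> "SpikeTrainSet":
        meta = {}
        with open(path) as fh:
            first = fh.readline()
            for tok in first.lstrip("#").split():
                if "=" in tok:
                    k, v = tok.split("=")
                    meta[k] = float(v)
        side = sidecar or (str(path) + ".populations")
        pops = []
        with open(side) as fh:
            for line in fh:
                if not line.startswith("#") and line.strip():
                    pops.append(line.split()[1])
        data = np.loadtxt(path, comments="#", ndmin=2)
        trains = [np.sort(data[data[:, 0] == i, 1]) if data.size else np.empty(0)
                  for i in range(len(pops))]
        return cls(trains, pops, duration=meta.get("duration_ms", 0.0),
                   transient=meta.get("transient_ms", 1000.0))


class RealizedNetwork:
    """A wired network: cells, synapse table, gap junctions, mutable scalings.

    The underlying engine arrays are re-synchronised from the base synapse
    table and the current blockade / coefficient multipliers before every run,
    which makes blockade exactly reversible and coefficient application
    exactly invertible.
    """

    def __init__(self, spec: NetworkSpec, seed: int):
        spec.validate()
        self.spec = spec
        self.seed = int(seed)
        self.blockade = BlockadeState()
        # population-level channel-density multipliers (coefficients)
        self.channel_multipliers = {p: {} for p in POPULATIONS}
        self.gabab_weight_multipliers = {p: 1.0 for p in POPULATIONS}

        mechs = mechanism_registry()
        cellspecs = cell_registry()
        # independent streams so e.g. zeroing connection probabilities leaves
        # the gap-junction realization untouched
        rng = np.random.default_rng([self.seed, 0])
        rng_gj = np.random.default_rng([self.seed, 1])

        self.populations: list[str] = (
            ["PC"] * spec.n_PC + ["LBC"] * spec.n_LBC + ["NGC"] * spec.n_NGC
        )
        cells = [realize(cellspecs[p], mechs) for p in self.populations]
        syn_kinds = synapse_registry()
        self.sim = Simulation(
            cells, mechs,
            [syn_kinds[r] for r in ("AMPA", "NMDA", "GABA_A", "GABA_B")],
            dt=spec.dt_ms, temperature=spec.temperature,
            delay_ms=spec.synaptic_delay_ms,
        )
        self._base_ch_g = self.sim.ch_g.copy()

        pop_idx = {p: [i for i, q in enumerate(self.populations) if q == p]
                   for p in POPULATIONS}
        dend_comps = {
            i: [self.sim.cell_offsets[i] + c for c in cells[i].dendritic_compartments()]
            for i in range(len(cells))
        }

        # --- synapse table ---------------------------------------------------
        # rows: (pre_cell, post_cell, post_comp, receptor, base_w_uS, class)
        self.synapses: list[tuple[int, int, int, str, float, ConnectionClass]] = []
        self.realized_connections: dict[tuple[str, str], int] = {}
        clipped = []
        for cc in spec.connections:
            p_eff = spec.probability_scale * cc.p_base
            if p_eff > 1.0:
                clipped.append((cc.pre, cc.post, p_eff))
                p_eff = 1.0
            n_conn = 0
            w_class = syn_kinds[cc.receptors[0]].peak_conductance
            for pre in pop_idx[cc.pre]:
                for post in pop_idx[cc.post]:
                    if pre == post:
                        continue
                    if rng.random() >= p_eff:
                        continue
                    n_conn += 1
                    targets = rng.choice(dend_comps[post], size=cc.synapses_per_connection)
                    for comp in targets:
                        for r in cc.receptors:
                            base = syn_kinds[r].peak_conductance
                            if r == "NMDA":
                                base *= spec.nmda_ratio
                            self.synapses.append(
                                (pre, post, int(comp), r, base, cc)
                            )
            self.realized_connections[(cc.pre, cc.post)] = n_conn
        if clipped:
            warnings.warn(
                "connection probabilities clipped at 1 after scaling: "
                + ", ".join(f"{a}->{b} ({p:.2f})" for a, b, p in clipped)
            )

        # --- gap junctions (LBC-LBC only) ------------------------------------
        self.n_gap_junctions = 0
        lbc = pop_idx["LBC"]
        for ii, a in enumerate(lbc):
            for b in lbc[ii + 1:]:
                if rng_gj.random() < spec.gap_junction_probability:
                    self.sim.add_gap_junction(
                        self.sim.soma_index(a), self.sim.soma_index(b),
                        spec.gap_junction_conductance_nS * 1e-3,
                    )
                    self.n_gap_junctions += 1

        # --- background drive into PCs ---------------------------------------
        for i in pop_idx["PC"]:
            cell = cells[i]
            sites = [self.sim.soma_index(i)]
            dend = dend_comps[i]
            n_extra = max(0, spec.background.targets_per_cell - 1)
            if n_extra and dend:
                picks = np.linspace(0, len(dend) - 1, n_extra).astype(int)
                sites.extend(dend[k] for k in picks)
            for receptor, rate in spec.background.rates_hz.items():
                kin = "GABA_A" if receptor == "GABA" else receptor
                w = spec.background.weights_uS[receptor]
                for s in sites:
                    self.sim.add_background(s, kin, rate, w)

        self._dirty = True
        self._sync()

    # -- state synchronisation ------------------------------------------------

    def _size_factor(self, pre_pop: str) -> float:
        ref = dict(zip(POPULATIONS, self.spec.reference_populations))
        n = {"PC": self.spec.n_PC, "LBC": self.spec.n_LBC, "NGC": self.spec.n_NGC}
        return ref[pre_pop] / n[pre_pop]

    def _class_factor(self, cc: ConnectionClass, post_pop: str) -> float:
        b = self.blockade
        if b.gabaA_blocked and cc.pre == "LBC":
            if cc.post == "PC" or (b.block_all_gabaA and cc.post == "LBC"):
                return 0.0
        if b.gabaB_blocked and cc.pre == "NGC":
            return 0.0
        return 1.0

    def _sync(self) -> None:
        """Rewrite engine weights/densities from base values and multipliers."""
        sim = self.sim
        sim._conn = [[] for _ in sim.cells]
        sim._conn_final = None
        g = self.spec.conductances
        for pre, post, comp, receptor, base_w, cc in self.synapses:
            w = (base_w * g.weight(cc.symbol) * self._size_factor(cc.pre)
                 * self._class_factor(cc, self.populations[post]))
            if receptor == "GABA_B":
                w *= self.gabab_weight_multipliers[self.populations[post]]
            sim.add_connection(pre, comp, receptor, w)
        sim.ch_g[:] = self._base_ch_g
        for ci, pop in enumerate(self.populations):
            mult = self.channel_multipliers[pop]
            if not mult:
                continue
            rows = sim.channel_rows[ci]
            for mech, c in mult.items():
                if mech in rows:
                    sim.ch_g[rows[mech]] *= c
        self._dirty = False

    # -- queries ---------------------------------------------------------------

    def class_weights(self, pre: str, post: str) -> np.ndarray:
        """Current effective synaptic weights (uS) of one connection class."""
        if self._dirty:
            self._sync()
        g = self.spec.conductances
        out = []
        for pre_c, post_c, comp, receptor, base_w, cc in self.synapses:
            if cc.pre == pre and cc.post == post:
                w = (base_w * g.weight(cc.symbol) * self._size_factor(cc.pre)
                     * self._class_factor(cc, post))
                if receptor == "GABA_B":
                    w *= self.gabab_weight_multipliers[self.populations[post_c]]
                out.append(w)
        return np.asarray(out)

    def channel_density_vector(self) -> np.ndarray:
        """Current absolute channel conductances (uS), post-multipliers."""
        if self._dirty:
            self._sync()
        return self.sim.ch_g.copy()

    def edge_list(self) -> list[tuple[int, int, int, str]]:
        """(pre_cell, post_cell, post_comp, receptor) rows; wiring fingerprint."""
        return [(a, b, c, r) for a, b, c, r, _, _ in self.synapses]

    def inhibitory_fraction(self) -> float:
        n = len(self.populations)
        return sum(1 for p in self.populations if p != "PC") / n

    # -- simulation -------------------------------------------------------------

    def run(self, duration_ms: float, seed: int, transient_ms: float = 1000.0,
            record_exemplars: bool = False) -> SpikeTrainSet | tuple:
        if self._dirty:
            self._sync()
        rec = []
        labels = []
        if record_exemplars:
            for pop in POPULATIONS:
                i = self.populations.index(pop)
                rec.append(self.sim.soma_index(i))
                labels.append(pop)
        res = self.sim.run(duration_ms, seed=seed, record_comps=rec,
                           record_stride=20)
        sts = SpikeTrainSet(
            spike_times=res.spike_times,
            populations=list(self.populations),
            duration=res.duration,
            transient=transient_ms,
        )
        if record_exemplars:
            return sts, (res.t_record, res.v_record, labels)
        return sts


def build_network(spec: NetworkSpec, seed: int = 0) -> RealizedNetwork:
    """Realize the random wiring of ``spec`` under ``seed`` (fully deterministic)."""
    return RealizedNetwork(spec, seed)


def apply_blockade(network: RealizedNetwork, state: BlockadeState) -> RealizedNetwork:
    """Set the receptor-blockade flags (conductances zeroed, synapses kept)."""
    network.blockade = replace(state)
    network._dirty = True
    return network


def apply_coefficients(network: RealizedNetwork, coefficients,
                       target_populations=POPULATIONS) -> RealizedNetwork:
    """Multiply channel densities (and GABA_B weights) in the targeted populations.

    ``coefficients`` maps channel keys (``Ca_HVA``, ``Ca_LVA``, ``Ih``,
    ``K_Pst``, ``Im``) to multiplicative factors; the ``GABA_B`` key scales
    GABA_B synaptic peak conductances whose postsynaptic cell lies in a
    targeted population.  Application composes multiplicatively, so applying
    ``c`` then ``1/c`` restores the network exactly.
    """
    items = coefficients.items() if hasattr(coefficients, "items") else coefficients
    items = dict(items)
    for key in items:
        if key not in CHANNEL_KEYS:
            raise MappingError(
                f"coefficient key {key!r} maps to no channel or synaptic target"
            )
    for pop in target_populations:
        if pop not in POPULATIONS:
            raise MappingError(f"unknown population {pop!r}")
        for key, c in items.items():
            if c <= 0:
                raise ValidationError(f"coefficient {key} must be > 0")
            if key == "GABA_B":
                network.gabab_weight_multipliers[pop] *= c
            else:
                cur = network.channel_multipliers[pop].get(key, 1.0)
                network.channel_multipliers[pop][key] = cur * c
    network._dirty = True
    return network


def simulate_network(network: RealizedNetwork, duration_ms: float, seed: int,
                     transient_ms: float = 1000.0,
                     record_exemplars: bool = False):
    """Run the realized network; identical (network, seed) gives identical output."""
    return network.run(duration_ms, seed, transient_ms=transient_ms,
                       record_exemplars=record_exemplars)
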