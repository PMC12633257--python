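"""Compartmental cell models and current-clamp protocols.

Three cell classes are shipped as structured configs (``data/cells``):

* ``PC``  — simplified thick-tufted layer-5 pyramidal cell (soma, basal
  dendrite, apical trunk, tuft) with the full complement of somatic and
  dendritic conductances including HVA/LVA calcium, SK, Ih, persistent and
  M-type potassium;
* ``LBC`` — large basket cell reduced to a ball-and-stick with two dendrites;
* ``NGC`` — neurogliaform cell, same topology with more dendritic segments.

A :class:`CellSpec` is a pure description; :func:`realize` discretizes it into
the flat arrays the engine consumes (each section split into ``nseg``
sub-compartments, child sections attached to the distal end of their parent,
or to the soma).  Units follow the package convention (um, ohm*cm, uF/cm2,
S/cm2, mV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .engine import Simulation
from .exceptions import ValidationError
from .mechanisms import ChannelMechanism, mechanism_registry

__all__ = [
    "SectionSpec",
    "CalciumDynamics",
    "CellSpec",
    "CurrentClampProtocol",
    "FICurve",
    "load_cell",
    "cell_registry",
    "realize",
    "simulate_current_clamp",
    "compute_fi_curve",
    "swc_total_dendritic_area",
    "protocol_presets",
]

FARADAY = 96485.332  # C/mol


@dataclass(frozen=True)
class SectionSpec:
    """One cable section (the soma is a single cylindrical section)."""

    name: str
    length: float  # um
    diameter: float  # um
    nseg: int = 1
    ra: float = 100.0  # ohm*cm
    cm: float = 1.0  # uF/cm2
    g_pas: float = 3e-5  # S/cm2
    e_pas: float = -75.0  # mV
    parent: str | None = None

    def area(self) -> float:
        """Lateral membrane area, um2."""
        return math.pi * self.diameter * self.length


@dataclass(frozen=True)
class CalciumDynamics:
    """Single-pool submembrane calcium accumulation with linear extrusion."""

    decay: float = 80.0  # ms
    gamma: float = 0.02  # fraction of Ca current reaching the pool
    depth: float = 0.1  # um, shell depth
    ca_min: float = 1e-4  # mM, resting concentration
    sections: tuple[str, ...] = ()  # empty = every section with a Ca channel


@dataclass(frozen=True)
class CellSpec:
    cell_class: str  # PC | LBC | NGC
    sections: tuple[SectionSpec, ...]
    channel_densities: Mapping[str, Mapping[str, float]]  # section -> mech -> S/cm2
    calcium: CalciumDynamics | None = None
    v_init: float = -72.0

    def section(self, name: str) -> SectionSpec:
        for s in self.sections:
            if s.name == name:
                return s
        raise KeyError(name)

    def total_dendritic_area(self) -> float:
        """Summed lateral area of all non-soma sections, um2."""
        return sum(s.area() for s in self.sections if s.name != "soma")

    def validate(self, mechanisms: Mapping[str, ChannelMechanism] | None = None) -> None:
        mechanisms = mechanisms or mechanism_registry()
        names = [s.name for s in self.sections]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate section names")
        for s in self.sections:
            if s.length <= 0 or s.diameter <= 0 or s.nseg <= 0:
                raise ValidationError(f"section {s.name}: non-positive geometry")
            if s.nseg % 2 != 1:
                raise ValidationError(f"section {s.name}: nseg must be odd")
            if s.parent is not None and s.parent not in names:
                raise ValidationError(f"section {s.name}: unknown parent {s.parent}")
        for sec, mechs in self.channel_densities.items():
            if sec not in names:
                raise ValidationError(f"channel table references unknown section {sec}")
            for m in mechs:
                if m not in mechanisms:
                    raise ValidationError(f"unknown mechanism {m!r} in section {sec}")

    def with_dendrite_geometry(
        self, length: float, diameter: float, nseg: int | None = None,
        dendrite_names: Sequence[str] | None = None,
    ) -> "CellSpec":
        """Return a copy with all (or the named) dendrites re-sized; used by reduction."""
        targets = set(dendrite_names) if dendrite_names else {
            s.name for s in self.sections if s.name != "soma"
        }
        new_secs = tuple(
            replace(s, length=length, diameter=diameter,
                    nseg=s.nseg if nseg is None else nseg)
            if s.name in targets else s
            for s in self.sections
        )
        return replace(self, sections=new_secs)


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

class CompartmentalCell:
    """A CellSpec realized into flat per-compartment arrays (engine input)."""

    def __init__(self, spec: CellSpec, mechanisms: Mapping[str, ChannelMechanism] | None = None):
        mechanisms = mechanisms or mechanism_registry()
        spec.validate(mechanisms)
        self.spec = spec
        self.cell_class = spec.cell_class
        self.v_init = spec.v_init

        parent: list[int] = []
        area: list[float] = []
        ga: list[float] = []
        labels: list[str] = []
        sec_first: dict[str, int] = {}
        sec_last: dict[str, int] = {}
        half_r: list[float] = []  # axial half-resistance of each compartment, MOhm

        for s in self.spec.sections:
            seg_len = s.length / s.nseg
            cross_um2 = math.pi * s.diameter ** 2 / 4.0
            # R(MOhm) of a half-segment: Ra[ohm*cm] * (L/2)[cm] / A[cm2] * 1e-6
            hr = s.ra * (seg_len / 2.0 * 1e-4) / (cross_um2 * 1e-8) * 1e-6
            for i in range(s.nseg):
                idx = len(parent)
                if i == 0:
                    if s.parent is None:
                        p = -1
                        g = 0.0
                    else:
                        p = sec_last[s.parent]
                        g = 1.0 / (hr + half_r[p])
                else:
                    p = idx - 1
                    g = 1.0 / (hr + half_r[p])
                parent.append(p)
                ga.append(g)
                area.append(math.pi * s.diameter * seg_len)
                labels.append(s.name)
                half_r.append(hr)
                sec_last[s.name] = idx
                if i == 0:
                    sec_first[s.name] = idx

        self.n_comp = len(parent)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.area_um2 = np.asarray(area)
        self.ga_uS = np.asarray(ga)
        self.labels = labels
        self.soma_comp = sec_first.get("soma", 0)
        cm = np.asarray([self.spec.section(l).cm for l in labels])
        gp = np.asarray([self.spec.section(l).g_pas for l in labels])
        ep = np.asarray([self.spec.section(l).e_pas for l in labels])
        self.cm_nF = cm * self.area_um2 * 1e-5
        self.g_pas_uS = gp * self.area_um2 * 1e-2
        self.e_pas = ep

        # channels: one instance per (mechanism, compartment)
        self.channels: list[tuple[str, int, float]] = []
        comps_of = {name: [i for i, l in enumerate(labels) if l == name] for name in sec_first}
        ca_secs: set[str] = set()
        for sec_name, mechs in self.spec.channel_densities.items():
            for mech_name, dens in sorted(mechs.items()):
                if dens <= 0.0:
                    continue
                for c in comps_of[sec_name]:
                    self.channels.append((mech_name, c, dens * self.area_um2[c] * 1e-2))
                if mechanisms[mech_name].ion == "ca":
                    ca_secs.add(sec_name)

        # calcium pools
        cad = self.spec.calcium
        self.ca_has = np.zeros(self.n_comp, dtype=np.uint8)
        self.ca_decay = np.full(self.n_comp, 80.0)
        self.ca_gain = np.zeros(self.n_comp)
        self.ca_min = np.full(self.n_comp, 1e-4)
        if cad is not None:
            pool_secs = set(cad.sections) if cad.sections else ca_secs
            for i, l in enumerate(labels):
                if l in pool_secs:
                    self.ca_has[i] = 1
                    self.ca_decay[i] = cad.decay
                    self.ca_gain[i] = cad.gamma * 1e6 / (
                        2.0 * FARADAY * self.area_um2[i] * cad.depth
                    )
                    self.ca_min[i] = cad.ca_min

    def compartments_of(self, section: str) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == section]

    def dendritic_compartments(self) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l != "soma"]


def realize(spec: CellSpec, mechanisms=None) -> CompartmentalCell:
    return CompartmentalCell(spec, mechanisms)


# ---------------------------------------------------------------------------
# protocols and f-I curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurrentClampProtocol:
    """Somatic square-pulse family for f-I measurement."""

    amplitudes: tuple[float, ...]  # nA, non-decreasing
    stimulus_duration: float = 2000.0  # ms
    onset_delay: float = 200.0  # ms
    spike_threshold: float = -10.0  # mV

    def __post_init__(self) -> None:
        if self.onset_delay < 0 or self.stimulus_duration <= 0:
            raise ValidationError("need onset_delay >= 0 and stimulus_duration > 0")
        if any(b < a for a, b in zip(self.amplitudes, self.amplitudes[1:])):
            raise ValidationError("amplitudes must be non-decreasing")


def protocol_presets(stimulus_duration: float = 2000.0) -> dict[str, CurrentClampProtocol]:
    """Shipped protocol families.

    ``lbc``/``ngc`` use the published amplitude grids (0-0.8 nA step 0.1;
    0-0.2 nA step 0.025).  ``*_brief`` (20 ms) and ``*_long`` (20 s) presets
    carry the two published stimulus durations; the package default of 2 s is
    long enough to resolve rates down to 0.5 Hz at a fraction of the cost.
    """
    lbc_amps = tuple(np.round(np.arange(0.0, 0.8001, 0.1), 10))
    ngc_amps = tuple(np.round(np.arange(0.0, 0.2001, 0.025), 10))
    out = {
        "lbc": CurrentClampProtocol(lbc_amps, stimulus_duration),
        "ngc": CurrentClampProtocol(ngc_amps, stimulus_duration),
        "lbc_brief": CurrentClampProtocol(lbc_amps, 20.0),
        "ngc_brief": CurrentClampProtocol(ngc_amps, 20.0),
        "lbc_long": CurrentClampProtocol(lbc_amps, 20000.0),
        "ngc_long": CurrentClampProtocol(ngc_amps, 20000.0),
    }
    return out


@dataclass
class FICurve:
    """Firing frequency (spike count / stimulus duration) per amplitude."""

    amplitudes: np.ndarray  # nA
    frequencies: np.ndarray  # Hz

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.amplitudes.shape != self.frequencies.shape:
            raise ValidationError("amplitude/frequency arrays differ in length")
        if np.any(self.frequencies < 0):
            raise ValidationError("negative firing frequency")

    def save(self, path) -> None:
        np.savetxt(path, np.column_stack([self.amplitudes, self.frequencies]),
                   header="amplitude_nA frequency_Hz")

    @classmethod
    def load(cls, path) -> "FICurve":
        arr = np.atleast_2d(np.loadtxt(path, comments="#", delimiter=None))
        return cls(arr[:, 0], arr[:, 1])


@dataclass
class ClampResult:
    amplitude: float
    t: np.ndarray
    v_soma: np.ndarray
    spike_times: np.ndarray


def simulate_current_clamp(
    cell: CellSpec | CompartmentalCell,
    protocol: CurrentClampProtocol,
    dt: float = 0.025,
    temperature: float = 34.0,
    record_stride: int = 40,
) -> list[ClampResult]:
    """Run the protocol's amplitude family on a single cell.

    Spikes are positive-going crossings of the protocol threshold at the soma
    (1 ms detection refractory); each trace starts with ``onset_delay`` ms of
    unstimulated equilibration.
    """
    comp = cell if isinstance(cell, CompartmentalCell) else realize(cell)
    mechs = mechanism_registry()
    sim = Simulation([comp], mechs, [], dt=dt, temperature=temperature,
                     spike_threshold=protocol.spike_threshold)
    soma = sim.soma_index(0)
    out = []
    total = protocol.onset_delay + protocol.stimulus_duration
    for amp in protocol.amplitudes:
        sim.set_step(soma, amp, protocol.onset_delay, protocol.stimulus_duration)
        try:
            res = sim.run(total, seed=0, record_comps=[soma], record_stride=record_stride)
        except Exception as exc:  # annotate which amplitude failed
            raise type(exc)(f"{exc} (amplitude {amp} nA)") from exc
        out.append(ClampResult(
            amplitude=float(amp),
            t=res.t_record,
            v_soma=res.v_record[0],
            spike_times=res.spike_times[0],
        ))
    return out


def compute_fi_curve(
    cell: CellSpec | CompartmentalCell,
    protocol: CurrentClampProtocol,
    dt: float = 0.025,
    temperature: float = 34.0,
) -> FICurve:
    """f-I curve: spikes within the stimulus window divided by its duration."""
    traces = simulate_current_clamp(cell, protocol, dt=dt, temperature=temperature,
                                    record_stride=10 ** 9)
    t0 = protocol.onset_delay
    t1 = t0 + protocol.stimulus_duration
    freqs = [
        np.sum((r.spike_times >= t0) & (r.spike_times < t1)) /
        (protocol.stimulus_duration / 1000.0)
        for r in traces
    ]
    return FICurve(np.asarray(protocol.amplitudes), np.asarray(freqs))


# ---------------------------------------------------------------------------
# config IO and SWC helper
# ---------------------------------------------------------------------------

def load_cell(text_or_mapping) -> CellSpec:
    cfg = (
        yaml.safe_load(text_or_mapping)
        if isinstance(text_or_mapping, str)
        else dict(text_or_mapping)
    )
    secs = tuple(
        SectionSpec(
            name=s["name"], length=float(s["length"]), diameter=float(s["diameter"]),
            nseg=int(s.get("nseg", 1)), ra=float(s.get("ra", 100.0)),
            cm=float(s.get("cm", 1.0)), g_pas=float(s.get("g_pas", 3e-5)),
            e_pas=float(s.get("e_pas", -75.0)), parent=s.get("parent"),
        )
        for s in cfg["sections"]
    )
    cad = None
    if "calcium" in cfg and cfg["calcium"]:
        c = cfg["calcium"]
        cad = CalciumDynamics(
            decay=float(c.get("decay", 80.0)), gamma=float(c.get("gamma", 0.02)),
            depth=float(c.get("depth", 0.1)), ca_min=float(c.get("ca_min", 1e-4)),
            sections=tuple(c.get("sections", ())),
        )
    spec = CellSpec(
        cell_class=cfg["cell_class"],
        sections=secs,
        channel_densities={k: dict(v) for k, v in cfg.get("channels", {}).items()},
        calcium=cad,
        v_init=float(cfg.get("v_init", -72.0)),
    )
    spec.validate()
    return spec


_CELL_CACHE: dict[str, CellSpec] | None = None


def cell_registry() -> dict[str, CellSpec]:
    """Shipped cell parameter sets keyed by class (PC, LBC, NGC)."""
    global _CELL_CACHE
    if _CELL_CACHE is None:
        reg = {}
        base = resources.files("deltacircuit") / "data" / "cells"
        for entry in sorted(base.iterdir(), key=lambda p: p.name):
            if entry.name.endswith(".yaml"):
                spec = load_cell(entry.read_text())
                reg[spec.cell_class] = spec
        _CELL_CACHE = reg
    return _CELL_CACHE


def swc_total_dendritic_area(path) -> float:
    """Total dendritic membrane area (um2) of an SWC morphology.

    Sums frustum lateral areas of basal (type 3) and apical (type 4)
    segments; used only to supply ``total_dendritic_area`` to the reduction.
    """
    nodes: dict[int, tuple[int, float, float, float, float, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p = line.split()
            nodes[int(p[0])] = (int(p[1]), float(p[2]), float(p[3]), float(p[4]),
                                float(p[5]), int(p[6]))
    total = 0.0
    for t, x, y, z, r, par in nodes.values():
        if t in (3, 4) and par in nodes:
            _, xp, yp, zp, rp, _ = nodes[par]
            L = math.dist((x, y, z), (xp, yp, zp))
            slant = math.hypot(L, r - rp)
            total += math.pi * (r + rp) * slant
    return total
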