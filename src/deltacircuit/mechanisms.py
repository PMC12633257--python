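"""Voltage-gated channel and synaptic-receptor kinetics.

This module is the single place where membrane currents are defined.  Channel
gating follows the Hodgkin–Huxley formalism: each gating variable ``x`` relaxes
toward a voltage- (or calcium-) dependent steady state ``x_inf`` with time
constant ``tau_x``,

    dx/dt = (x_inf(v) - x) / tau_x(v),

and a channel passes the ohmic current

    i = gbar * prod_j x_j^p_j * (v - E_rev)        [outward positive]

Kinetic laws are described declaratively (YAML, one file per mechanism) using a
small library of rate forms, so that the same definition drives the scalar
evaluators used in tests and the table-based fast path used by the simulator
engine.  Rate constants are in 1/ms at the mechanism's reference temperature;
time constants are divided by a q10-derived factor at the simulation
temperature.

Synaptic receptors (AMPA, NMDA, GABA_A, GABA_B) are difference-of-exponential
conductances normalised so the peak equals ``peak_conductance``.  GABA_B uses
the slow kinetics (rise 30 ms, decay 200 ms) characteristic of neurogliaform
transmission; NMDA carries the standard sigmoidal magnesium-block factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .exceptions import InvalidKineticsError, InvalidStateError, ValidationError

__all__ = [
    "GateSpec",
    "ChannelMechanism",
    "DeterministicKv",
    "SynapseKinetics",
    "dual_exponential_conductance",
    "dual_exp_peak_time",
    "channel_current",
    "mg_block",
    "load_mechanism",
    "mechanism_registry",
    "synapse_registry",
]

# Voltage range over which kinetics must be well behaved (mV).
V_RANGE = (-120.0, 60.0)


# ---------------------------------------------------------------------------
# rate-form library
# ---------------------------------------------------------------------------

def _expl(p: Mapping[str, float], v: np.ndarray) -> np.ndarray:
    """A * exp((v - Vh) / k)."""
    return p["A"] * np.exp((v - p["Vh"]) / p["k"])


def _sigm(p: Mapping[str, float], v: np.ndarray) -> np.ndarray:
    """A / (1 + exp(-(v - Vh) / k))."""
    return p["A"] / (1.0 + np.exp(-(v - p["Vh"]) / p["k"]))


def _efun(p: Mapping[str, float], v: np.ndarray) -> np.ndarray:
    """A * (v - Vh) / (1 - exp(-(v - Vh)/k)), linoid with removable singularity."""
    u = (np.asarray(v, dtype=float) - p["Vh"]) / p["k"]
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.where(
            np.abs(u) < 1e-6,
            p["A"] * p["k"] * (1.0 + 0.5 * u),
            p["A"] * p["k"] * u / (1.0 - np.exp(-u)),
        )
    return out


_RATE_FORMS = {"expl": _expl, "sigm": _sigm, "efun": _efun}


def _tau_const(p: Mapping[str, float], v: np.ndarray) -> np.ndarray:
    return np.full_like(np.asarray(v, dtype=float), p["value"])


def _tau_sigmoid(p: Mapping[str, float], v: np.ndarray) -> np.ndarray:
    """t0 + amp / (1 + exp(-(v - Vh)/k))."""
    return p["t0"] + p["amp"] / (1.0 + np.exp(-(v - p["Vh"]) / p["k"]))


def _tau_bell(p: Mapping[str, float], v: np.ndarray) -> np.ndarray:
    """t0 + amp / (exp((v - v1)/k1) + exp(-(v - v2)/k2))."""
    return p["t0"] + p["amp"] / (
        np.exp((v - p["v1"]) / p["k1"]) + np.exp(-(v - p["v2"]) / p["k2"])
    )


_TAU_FORMS = {"const": _tau_const, "sigmoid": _tau_sigmoid, "bell": _tau_bell}


# ---------------------------------------------------------------------------
# gates and channels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateSpec:
    """One activation/inactivation variable of a channel.

    ``form`` is either ``alpha_beta`` (inf = a/(a+b), tau = 1/(a+b)), ``inf_tau``
    (independent sigmoidal steady state and tau law), or ``ca_hill`` (calcium-
    dependent steady state 1/(1+(Kd/ca)^n), constant tau).
    """

    var: str
    power: int = 1
    form: str = "alpha_beta"
    params: Mapping[str, object] = field(default_factory=dict)

    @property
    def ca_dependent(self) -> bool:
        return self.form == "ca_hill"

    def inf(self, x: np.ndarray | float) -> np.ndarray:
        """Steady state as a function of voltage (mV) or calcium (mM)."""
        x = np.asarray(x, dtype=float)
        if self.form == "alpha_beta":
            a = _RATE_FORMS[self.params["alpha"]["form"]](self.params["alpha"], x)
            b = _RATE_FORMS[self.params["beta"]["form"]](self.params["beta"], x)
            return a / (a + b)
        if self.form == "inf_tau":
            p = self.params["inf"]
            return 1.0 / (1.0 + np.exp(-(x - p["Vh"]) / p["k"]))
        if self.form == "ca_hill":
            ca = np.maximum(x, 1e-9)
            return 1.0 / (1.0 + (self.params["Kd"] / ca) ** self.params["n"])
        raise InvalidKineticsError(f"unknown gate form {self.form!r}")

    def tau(self, x: np.ndarray | float, qt: float = 1.0) -> np.ndarray:
        """Time constant (ms); divided by the temperature factor ``qt``."""
        x = np.asarray(x, dtype=float)
        if self.form == "alpha_beta":
            a = _RATE_FORMS[self.params["alpha"]["form"]](self.params["alpha"], x)
            b = _RATE_FORMS[self.params["beta"]["form"]](self.params["beta"], x)
            return 1.0 / (a + b) / qt
        if self.form == "inf_tau":
            p = self.params["tau"]
            return _TAU_FORMS[p["form"]](p, x) / qt
        if self.form == "ca_hill":
            return np.full_like(x, self.params.get("tau", 1.0)) / qt
        raise InvalidKineticsError(f"unknown gate form {self.form!r}")


@dataclass(frozen=True)
class ChannelMechanism:
    """A voltage-gated (or Ca-dependent K) membrane conductance.

    ``max_conductance_density`` is a nominal default in S/cm2; the density
    actually inserted is set per cell section.  ``ion == "ca"`` flags channels
    whose current feeds the intracellular calcium pool.
    """

    name: str
    gates: Sequence[GateSpec]
    reversal: float  # mV
    max_conductance_density: float = 0.0  # S/cm2
    ion: str = "k"
    q10: float = 2.3
    q10_ref_temp: float = 21.0  # Celsius
    deterministic: bool = False

    def qt(self, temperature: float = 34.0) -> float:
        return self.q10 ** ((temperature - self.q10_ref_temp) / 10.0)

    def steady_states(self, v: float, ca_i: float = 1e-4) -> dict[str, float]:
        return {
            g.var: float(g.inf(ca_i if g.ca_dependent else v)) for g in self.gates
        }

    def open_fraction(self, state: Mapping[str, float]) -> float:
        out = 1.0
        for g in self.gates:
            x = state[g.var]
            if not (0.0 <= x <= 1.0):
                raise InvalidStateError(
                    f"{self.name}.{g.var} = {x} outside [0, 1]"
                )
            out *= x ** g.power
        return out

    def validate(self) -> None:
        v = np.linspace(V_RANGE[0], V_RANGE[1], 721)
        for g in self.gates:
            x = np.logspace(-6, -1, 101) if g.ca_dependent else v
            inf, tau = g.inf(x), g.tau(x)
            if not (np.all(inf >= 0.0) and np.all(inf <= 1.0)):
                raise ValidationError(f"{self.name}.{g.var}: steady state outside [0,1]")
            if not np.all(tau > 0.0):
                raise ValidationError(f"{self.name}.{g.var}: non-positive time constant")


class DeterministicKv(ChannelMechanism):
    """Deterministic replacement of the stochastic slow-inactivating Kv channel.

    Identical HH structure; flagged so that run-to-run trajectories are
    bit-identical by construction (no random channel gating anywhere).
    """


def channel_current(
    v: float,
    state: Mapping[str, float],
    ca_i: float,
    mech: ChannelMechanism,
    density: float | None = None,
) -> float:
    """Ohmic current density (mA/cm2, outward positive) at a clamped voltage.

    ``density`` overrides the mechanism's nominal max conductance (S/cm2).
    Deliberately a straightforward scalar evaluation of g * prod(x^p) * (v - E).
    """
    g = mech.max_conductance_density if density is None else density
    if g == 0.0:
        # still validate the state so misuse is caught
        mech.open_fraction(state)
        return 0.0
    return g * mech.open_fraction(state) * (v - mech.reversal)


# ---------------------------------------------------------------------------
# synapses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapseKinetics:
    """Dual-exponential receptor kinetics for one receptor class."""

    receptor: str  # AMPA | NMDA | GABA_A | GABA_B
    tau_rise: float  # ms
    tau_decay: float  # ms
    reversal: float  # mV
    peak_conductance: float = 1e-3  # uS
    mg_block: bool = False
    mg_conc: float = 1.0  # mM
    mg_eta: float = 1.0 / 3.57  # 1/mM
    mg_gamma: float = 0.062  # 1/mV

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0.0):
            raise InvalidKineticsError(
                f"{self.receptor}: need tau_decay > tau_rise > 0, "
                f"got ({self.tau_rise}, {self.tau_decay}) ms"
            )

    def with_peak(self, peak: float) -> "SynapseKinetics":
        return replace(self, peak_conductance=peak)


def dual_exp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time to peak of the difference of exponentials (closed form, ms)."""
    return (
        tau_rise * tau_decay / (tau_decay - tau_rise)
        * math.log(tau_decay / tau_rise)
    )


def dual_exp_norm(tau_rise: float, tau_decay: float) -> float:
    """Factor scaling (e^{-t/tau_d} - e^{-t/tau_r}) so its maximum is 1."""
    tp = dual_exp_peak_time(tau_rise, tau_decay)
    return 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))


def dual_exponential_conductance(
    t_since_event: np.ndarray | float, kin: SynapseKinetics
) -> np.ndarray | float:
    """Conductance (uS) at ``t_since_event`` ms after a presynaptic event.

    Zero at t = 0, peaks at ``peak_conductance`` at the closed-form peak time.
    """
    t = np.asarray(t_since_event, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("t_since_event must be >= 0")
    norm = dual_exp_norm(kin.tau_rise, kin.tau_decay)
    g = kin.peak_conductance * norm * (
        np.exp(-t / kin.tau_decay) - np.exp(-t / kin.tau_rise)
    )
    return float(g) if np.isscalar(t_since_event) else g


def mg_block(v: np.ndarray | float, kin: SynapseKinetics) -> np.ndarray | float:
    """Sigmoidal magnesium-block factor for NMDA; 1.0 for other receptors."""
    if not kin.mg_block:
        return np.ones_like(np.asarray(v, dtype=float)) if not np.isscalar(v) else 1.0
    return 1.0 / (1.0 + kin.mg_eta * kin.mg_conc * np.exp(-kin.mg_gamma * np.asarray(v, dtype=float)))


# ---------------------------------------------------------------------------
# config loading / registry
# ---------------------------------------------------------------------------

def _gate_from_config(cfg: Mapping[str, object]) -> GateSpec:
    return GateSpec(
        var=cfg["var"],
        power=int(cfg.get("power", 1)),
        form=cfg.get("form", "alpha_beta"),
        params={k: v for k, v in cfg.items() if k not in ("var", "power", "form")},
    )


_REQUIRED_CHANNEL_KEYS = {"name", "reversal", "gates"}


def load_mechanism(text_or_mapping) -> ChannelMechanism:
    """Build a ChannelMechanism from YAML text or a parsed mapping."""
    cfg = (
        yaml.safe_load(text_or_mapping)
        if isinstance(text_or_mapping, str)
        else dict(text_or_mapping)
    )
    missing = _REQUIRED_CHANNEL_KEYS - set(cfg)
    if missing:
        raise ValidationError(f"mechanism config missing fields: {sorted(missing)}")
    cls = DeterministicKv if cfg.get("deterministic", False) else ChannelMechanism
    mech = cls(
        name=cfg["name"],
        gates=tuple(_gate_from_config(g) for g in cfg["gates"]),
        reversal=float(cfg["reversal"]),
        max_conductance_density=float(cfg.get("max_conductance_density", 0.0)),
        ion=cfg.get("ion", "k"),
        q10=float(cfg.get("q10", 2.3)),
        q10_ref_temp=float(cfg.get("q10_ref_temp", 21.0)),
        deterministic=bool(cfg.get("deterministic", False)),
    )
    mech.validate()
    return mech


def _data_dir():
    return resources.files("deltacircuit") / "data"


_MECH_CACHE: dict[str, ChannelMechanism] | None = None
_SYN_CACHE: dict[str, SynapseKinetics] | None = None


def mechanism_registry() -> dict[str, ChannelMechanism]:
    """All shipped channel mechanisms, keyed by name (loaded once)."""
    global _MECH_CACHE
    if _MECH_CACHE is None:
        reg: dict[str, ChannelMechanism] = {}
        for entry in sorted(
            (_data_dir() / "mechanisms").iterdir(), key=lambda p: p.name
        ):
            if entry.name.endswith(".yaml") and entry.name != "synapses.yaml":
                mech = load_mechanism(entry.read_text())
                reg[mech.name] = mech
        _MECH_CACHE = reg
    return _MECH_CACHE


def synapse_registry() -> dict[str, SynapseKinetics]:
    """Shipped receptor kinetics (AMPA, NMDA, GABA_A, GABA_B), keyed by receptor."""
    global _SYN_CACHE
    if _SYN_CACHE is None:
        cfg = yaml.safe_load((_data_dir() / "mechanisms" / "synapses.yaml").read_text())
        reg = {}
        for item in cfg["receptors"]:
            reg[item["receptor"]] = SynapseKinetics(
                receptor=item["receptor"],
                tau_rise=float(item["tau_rise"]),
                tau_decay=float(item["tau_decay"]),
                reversal=float(item["reversal"]),
                peak_conductance=float(item.get("peak_conductance", 1e-3)),
                mg_block=bool(item.get("mg_block", False)),
                mg_conc=float(item.get("mg_conc", 1.0)),
                mg_eta=float(item.get("mg_eta", 1.0 / 3.57)),
                mg_gamma=float(item.get("mg_gamma", 0.062)),
            )
        _SYN_CACHE = reg
    return _SYN_CACHE
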