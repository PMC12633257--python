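"""Compartmental-network integration engine.

The engine flattens a set of compartmental cells into structure-of-arrays form
and integrates the cable equation with a fixed-step implicit scheme:

* voltage: backward Euler; the branched-tree linear system is solved exactly
  per step with a Hines-ordered elimination (compartments are numbered so that
  every parent precedes its children);
* gating variables: exact exponential relaxation toward the voltage-dependent
  steady state over each step (the update ``x <- x_inf + (x - x_inf) e^{-dt/tau}``
  is the analytic solution for frozen voltage), with steady states and decay
  factors linearly interpolated from precomputed tables;
* synapses: difference-of-exponential receptor conductances aggregated per
  (compartment, receptor) pair — linearity of the kinetics makes per-synapse
  state redundant; presynaptic events add the normalised weight to both state
  variables after a fixed conduction delay;
* background drive: independent Poisson event streams per targeted
  compartment and receptor, drawn inside the kernel from the run seed;
* gap junctions: ohmic coupling treated explicitly (previous-step voltages),
  adequate for the weak LBC–LBC coupling used here.

All dynamics are deterministic given (model, seed): the only stochasticity is
the seeded background Poisson drive, so identical seeds give bit-identical
trajectories.

Units: mV, ms, nA, uS, nF, mM; channel densities enter in S/cm2 and are
converted to absolute conductances per compartment at assembly time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .exceptions import IntegrationError
from .mechanisms import (
    ChannelMechanism,
    SynapseKinetics,
    dual_exp_norm,
)

__all__ = ["GateTableSet", "Simulation", "SimResult", "V_TABLE_RANGE"]

V_TABLE_RANGE = (-120.0, 60.0)
_N_TAB = 3601  # 0.05 mV / fine log10-Ca resolution
_LOGCA_RANGE = (-6.0, -1.0)


class GateTableSet:
    """Interpolation tables for gating steady states and per-step decay factors.

    One table row per (mechanism, gate variable).  ``tab_f`` holds
    ``exp(-dt * qt / tau)`` so the inner loop performs no transcendental calls.
    """

    def __init__(self, mechanisms: dict[str, ChannelMechanism], dt: float, temperature: float):
        self.ids: dict[tuple[str, str], int] = {}
        v = np.linspace(V_TABLE_RANGE[0], V_TABLE_RANGE[1], _N_TAB)
        logca = np.linspace(_LOGCA_RANGE[0], _LOGCA_RANGE[1], _N_TAB)
        ca = 10.0 ** logca
        rows_inf, rows_f, isca = [], [], []
        for name in sorted(mechanisms):
            mech = mechanisms[name]
            qt = mech.qt(temperature)
            for gate in mech.gates:
                x = ca if gate.ca_dependent else v
                rows_inf.append(gate.inf(x))
                rows_f.append(np.exp(-dt * qt / gate.tau(x)))
                isca.append(1 if gate.ca_dependent else 0)
                self.ids[(name, gate.var)] = len(rows_inf) - 1
        self.tab_inf = np.ascontiguousarray(rows_inf, dtype=np.float64)
        self.tab_f = np.ascontiguousarray(rows_f, dtype=np.float64)
        self.tab_isca = np.asarray(isca, dtype=np.uint8)
        self.vmin = V_TABLE_RANGE[0]
        self.inv_dv = (_N_TAB - 1) / (V_TABLE_RANGE[1] - V_TABLE_RANGE[0])
        self.lcmin = _LOGCA_RANGE[0]
        self.inv_dlc = (_N_TAB - 1) / (_LOGCA_RANGE[1] - _LOGCA_RANGE[0])


@dataclass
class SimResult:
    """Outcome of one integration run."""

    spike_times: list[np.ndarray]  # ms, one array per cell
    duration: float  # ms
    dt: float
    t_record: np.ndarray | None = None
    v_record: np.ndarray | None = None  # (n_recorded, n_samples)
    record_labels: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _integrate(
    dt, n_steps,
    parent, cm_dt, ga, g_pas, e_pas, v,
    ch_comp, ch_g, ch_e, ch_isca, ch_t1, ch_p1, ch_t2, ch_p2, g1, g2,
    tab_inf, tab_f, tab_isca, vmin, inv_dv, lcmin, inv_dlc,
    ca, ca_has, ca_f, ca_gain, ca_min_arr,
    synA, synB, kin_fA, kin_fB, kin_e, kin_mg, mg_eta, mg_gamma,
    ring, delay_steps,
    out_ptr, out_comp, out_kind, out_inc,
    bg_comp, bg_kind, bg_lam, bg_inc,
    gj_a, gj_b, gj_g,
    i_const, i_step, step_on, step_off,
    det_comp, thr, refr_steps, spk_cell, spk_step, max_spikes,
    rec_comp, rec_stride, rec_buf,
    seed,
):
    np.random.seed(seed)
    n_comp = v.shape[0]
    n_ch = ch_comp.shape[0]
    n_kind = synA.shape[0]
    n_cells = det_comp.shape[0]
    D = ring.shape[0]
    n_x = tab_inf.shape[1]

    g_sum = np.empty(n_comp)
    ge_sum = np.empty(n_comp)
    dvec = np.empty(n_comp)
    rhs = np.empty(n_comp)
    ica = np.empty(n_comp)
    gk_arr = np.empty(n_ch)

    last_spk = np.full(n_cells, -2147483647, dtype=np.int64)
    above = np.zeros(n_cells, dtype=np.uint8)
    for i in range(n_cells):
        if v[det_comp[i]] >= thr:
            above[i] = 1
    n_spk = 0
    rec_ptr = 0

    for s in range(n_steps):
        # --- recording (state at the start of step s, i.e. t = s*dt) --------
        if rec_comp.shape[0] > 0 and s % rec_stride == 0:
            for i in range(rec_comp.shape[0]):
                rec_buf[i, rec_ptr] = v[rec_comp[i]]
            rec_ptr += 1
        # --- deliver due synaptic events -----------------------------------
        slot = s % D
        for k in range(n_kind):
            for c in range(n_comp):
                inc = ring[slot, k, c]
                if inc != 0.0:
                    synA[k, c] += inc
                    synB[k, c] += inc
                    ring[slot, k, c] = 0.0
        # --- background Poisson drive --------------------------------------
        for b in range(bg_comp.shape[0]):
            lam = bg_lam[b]
            if lam > 0.0:
                nev = np.random.poisson(lam)
                if nev > 0:
                    w = bg_inc[b] * nev
                    synA[bg_kind[b], bg_comp[b]] += w
                    synB[bg_kind[b], bg_comp[b]] += w
        # --- passive terms and stimuli -------------------------------------
        for c in range(n_comp):
            g_sum[c] = g_pas[c]
            ge_sum[c] = g_pas[c] * e_pas[c] + i_const[c]
            ica[c] = 0.0
        if (s >= step_on) and (s < step_off):
            for c in range(n_comp):
                ge_sum[c] += i_step[c]
        # --- gating update and channel conductances ------------------------
        for j in range(n_ch):
            c = ch_comp[j]
            t1 = ch_t1[j]
            if tab_isca[t1] == 1:
                x = (np.log10(ca[c]) - lcmin) * inv_dlc
            else:
                x = (v[c] - vmin) * inv_dv
            xi = int(x)
            if xi < 0:
                xi = 0
                fr = 0.0
            elif xi >= n_x - 1:
                xi = n_x - 2
                fr = 1.0
            else:
                fr = x - xi
            inf1 = tab_inf[t1, xi] * (1.0 - fr) + tab_inf[t1, xi + 1] * fr
            f1 = tab_f[t1, xi] * (1.0 - fr) + tab_f[t1, xi + 1] * fr
            m = inf1 + (g1[j] - inf1) * f1
            g1[j] = m
            gk = ch_g[j]
            for _ in range(ch_p1[j]):
                gk *= m
            t2 = ch_t2[j]
            if t2 >= 0:
                if tab_isca[t2] == 1:
                    x2 = (np.log10(ca[c]) - lcmin) * inv_dlc
                else:
                    x2 = (v[c] - vmin) * inv_dv
                xi2 = int(x2)
                if xi2 < 0:
                    xi2 = 0
                    fr2 = 0.0
                elif xi2 >= n_x - 1:
                    xi2 = n_x - 2
                    fr2 = 1.0
                else:
                    fr2 = x2 - xi2
                inf2 = tab_inf[t2, xi2] * (1.0 - fr2) + tab_inf[t2, xi2 + 1] * fr2
                f2 = tab_f[t2, xi2] * (1.0 - fr2) + tab_f[t2, xi2 + 1] * fr2
                h = inf2 + (g2[j] - inf2) * f2
                g2[j] = h
                for _ in range(ch_p2[j]):
                    gk *= h
            gk_arr[j] = gk
            g_sum[c] += gk
            ge_sum[c] += gk * ch_e[j]
        # --- synaptic conductances ------------------------------------------
        for k in range(n_kind):
            fA = kin_fA[k]
            fB = kin_fB[k]
            e = kin_e[k]
            ismg = kin_mg[k]
            for c in range(n_comp):
                a = synA[k, c] * fA
                b2 = synB[k, c] * fB
                synA[k, c] = a
                synB[k, c] = b2
                gsyn = b2 - a
                if gsyn > 1e-12:
                    if ismg == 1:
                        gsyn *= 1.0 / (1.0 + mg_eta * np.exp(-mg_gamma * v[c]))
                    g_sum[c] += gsyn
                    ge_sum[c] += gsyn * e
        # --- gap junctions (explicit) ---------------------------------------
        for j in range(gj_a.shape[0]):
            a_ = gj_a[j]
            b_ = gj_b[j]
            g = gj_g[j]
            ge_sum[a_] += g * (v[b_] - v[a_])
            ge_sum[b_] += g * (v[a_] - v[b_])
        # --- implicit solve (Hines elimination on the tree) -----------------
        for c in range(n_comp):
            dvec[c] = cm_dt[c] + g_sum[c]
            rhs[c] = cm_dt[c] * v[c] + ge_sum[c]
        for c in range(n_comp):
            p = parent[c]
            if p >= 0:
                dvec[c] += ga[c]
                dvec[p] += ga[c]
        for c in range(n_comp - 1, 0, -1):
            p = parent[c]
            if p >= 0:
                f = ga[c] / dvec[c]
                dvec[p] -= f * ga[c]
                rhs[p] += f * rhs[c]
        for c in range(n_comp):
            p = parent[c]
            if p < 0:
                v[c] = rhs[c] / dvec[c]
            else:
                v[c] = (rhs[c] + ga[c] * v[p]) / dvec[c]
        # --- calcium pools ---------------------------------------------------
        for j in range(n_ch):
            if ch_isca[j] == 1:
                c = ch_comp[j]
                ica[c] += gk_arr[j] * (v[c] - ch_e[j])
        for c in range(n_comp):
            if ca_has[c] == 1:
                camin = ca_min_arr[c]
                canew = camin + (ca[c] - camin) * ca_f[c] - ca_gain[c] * ica[c] * dt
                if canew < 1e-6:
                    canew = 1e-6
                ca[c] = canew
        # --- spike detection and event scheduling ---------------------------
        for i in range(n_cells):
            vc = v[det_comp[i]]
            if above[i] == 0:
                if vc >= thr and (s - last_spk[i]) > refr_steps:
                    above[i] = 1
                    last_spk[i] = s
                    if n_spk < max_spikes:
                        spk_cell[n_spk] = i
                        spk_step[n_spk] = s
                        n_spk += 1
                    slot2 = (s + delay_steps) % D
                    for j in range(out_ptr[i], out_ptr[i + 1]):
                        ring[slot2, out_kind[j], out_comp[j]] += out_inc[j]
            elif vc < thr:
                above[i] = 0
        # --- divergence guard ------------------------------------------------
        if s % 50 == 0:
            for c in range(n_comp):
                if not (-200.0 < v[c] < 200.0):
                    return 1, n_spk, s, c
    return 0, n_spk, -1, -1


# ---------------------------------------------------------------------------
# python-side model container
# ---------------------------------------------------------------------------

_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_F = np.empty(0, dtype=np.float64)


class Simulation:
    """A flattened, runnable compartmental network.

    Built once from realized cells; synaptic weights, channel conductances and
    stimuli remain mutable between runs (the network module edits them for
    blockade and coefficient application).  Each :meth:`run` starts from the
    same initial state, so results depend only on (model arrays, seed).
    """

    def __init__(
        self,
        cells,  # list[CompartmentalCell] (see cells.py)
        mechanisms: dict[str, ChannelMechanism],
        synapse_kinds: list[SynapseKinetics],
        dt: float = 0.025,
        temperature: float = 34.0,
        delay_ms: float = 1.0,
        spike_threshold: float = -10.0,
        refractory_ms: float = 1.0,
    ):
        self.dt = float(dt)
        self.temperature = float(temperature)
        self.spike_threshold = float(spike_threshold)
        self.refractory_ms = float(refractory_ms)
        self.delay_steps = max(1, int(round(delay_ms / dt)))
        self.tables = GateTableSet(mechanisms, self.dt, temperature)
        self.kinds = list(synapse_kinds)
        self.kind_index = {k.receptor: i for i, k in enumerate(self.kinds)}
        self.cells = list(cells)

        # --- compartments ---------------------------------------------------
        parents, cmdt, ga, gpas, epas, vinit = [], [], [], [], [], []
        ca_has, ca_f, ca_gain, ca_min = [], [], [], []
        self.cell_offsets: list[int] = []
        off = 0
        for cell in self.cells:
            self.cell_offsets.append(off)
            n = cell.n_comp
            parents.extend(p + off if p >= 0 else -1 for p in cell.parent)
            cmdt.extend(cell.cm_nF / self.dt)
            ga.extend(cell.ga_uS)
            gpas.extend(cell.g_pas_uS)
            epas.extend(cell.e_pas)
            vinit.extend(np.full(n, cell.v_init))
            ca_has.extend(cell.ca_has)
            ca_f.extend(np.exp(-self.dt / np.maximum(cell.ca_decay, 1e-6)))
            ca_gain.extend(cell.ca_gain)
            ca_min.extend(cell.ca_min)
            off += n
        self.n_comp = off
        self.parent = np.asarray(parents, dtype=np.int64)
        self.cm_dt = np.asarray(cmdt, dtype=np.float64)
        self.ga = np.asarray(ga, dtype=np.float64)
        self.g_pas = np.asarray(gpas, dtype=np.float64)
        self.e_pas = np.asarray(epas, dtype=np.float64)
        self.v_init = np.asarray(vinit, dtype=np.float64)
        self.ca_has = np.asarray(ca_has, dtype=np.uint8)
        self.ca_f = np.asarray(ca_f, dtype=np.float64)
        self.ca_gain = np.asarray(ca_gain, dtype=np.float64)
        self.ca_min = np.asarray(ca_min, dtype=np.float64)

        # --- channels ---------------------------------------------------------
        ch_comp, ch_g, ch_e, ch_isca = [], [], [], []
        ch_t1, ch_p1, ch_t2, ch_p2 = [], [], [], []
        # per-cell index of channel rows by mechanism name, for coefficient edits
        self.channel_rows: list[dict[str, np.ndarray]] = []
        for ci, cell in enumerate(self.cells):
            offc = self.cell_offsets[ci]
            rows: dict[str, list[int]] = {}
            for mech_name, comp_local, g_uS in cell.channels:
                mech = mechanisms[mech_name]
                rows.setdefault(mech_name, []).append(len(ch_comp))
                ch_comp.append(offc + comp_local)
                ch_g.append(g_uS)
                ch_e.append(mech.reversal)
                ch_isca.append(1 if mech.ion == "ca" else 0)
                gates = list(mech.gates)
                ch_t1.append(self.tables.ids[(mech_name, gates[0].var)])
                ch_p1.append(gates[0].power)
                if len(gates) > 1:
                    ch_t2.append(self.tables.ids[(mech_name, gates[1].var)])
                    ch_p2.append(gates[1].power)
                else:
                    ch_t2.append(-1)
                    ch_p2.append(0)
            self.channel_rows.append(
                {k: np.asarray(idx, dtype=np.int64) for k, idx in rows.items()}
            )
        self.ch_comp = np.asarray(ch_comp, dtype=np.int64)
        self.ch_g = np.asarray(ch_g, dtype=np.float64)
        self.ch_e = np.asarray(ch_e, dtype=np.float64)
        self.ch_isca = np.asarray(ch_isca, dtype=np.uint8)
        self.ch_t1 = np.asarray(ch_t1, dtype=np.int64)
        self.ch_p1 = np.asarray(ch_p1, dtype=np.int64)
        self.ch_t2 = np.asarray(ch_t2, dtype=np.int64)
        self.ch_p2 = np.asarray(ch_p2, dtype=np.int64)

        # --- synapse kind constants ------------------------------------------
        nk = len(self.kinds)
        self.kin_fA = np.asarray([np.exp(-self.dt / k.tau_rise) for k in self.kinds])
        self.kin_fB = np.asarray([np.exp(-self.dt / k.tau_decay) for k in self.kinds])
        self.kin_e = np.asarray([k.reversal for k in self.kinds])
        self.kin_mg = np.asarray([1 if k.mg_block else 0 for k in self.kinds], dtype=np.uint8)
        self.kin_norm = np.asarray([dual_exp_norm(k.tau_rise, k.tau_decay) for k in self.kinds])
        mg = [k for k in self.kinds if k.mg_block]
        self.mg_eta = mg[0].mg_eta * mg[0].mg_conc if mg else 0.0
        self.mg_gamma = mg[0].mg_gamma if mg else 0.062
        self.n_kind = nk

        # --- mutable wiring ---------------------------------------------------
        self._conn: list[list[tuple[int, int, float]]] = [[] for _ in self.cells]
        self._conn_final = None
        self.bg_comp: list[int] = []
        self.bg_kind: list[int] = []
        self.bg_rate_hz: list[float] = []
        self.bg_w: list[float] = []
        self.gj_a: list[int] = []
        self.gj_b: list[int] = []
        self.gj_g: list[float] = []
        self.i_const = np.zeros(self.n_comp)
        self.i_step = np.zeros(self.n_comp)
        self.step_window = (0.0, 0.0)  # ms

    # -- construction helpers ------------------------------------------------

    def soma_index(self, cell_idx: int) -> int:
        return self.cell_offsets[cell_idx] + self.cells[cell_idx].soma_comp

    def add_connection(self, pre_cell: int, post_comp: int, receptor: str, weight_uS: float) -> int:
        """Register one synapse instance; returns its index within the pre-cell list."""
        k = self.kind_index[receptor]
        self._conn[pre_cell].append((post_comp, k, weight_uS))
        self._conn_final = None
        return len(self._conn[pre_cell]) - 1

    def add_background(self, comp: int, receptor: str, rate_hz: float, weight_uS: float) -> None:
        self.bg_comp.append(comp)
        self.bg_kind.append(self.kind_index[receptor])
        self.bg_rate_hz.append(rate_hz)
        self.bg_w.append(weight_uS)

    def add_gap_junction(self, comp_a: int, comp_b: int, g_uS: float) -> None:
        self.gj_a.append(comp_a)
        self.gj_b.append(comp_b)
        self.gj_g.append(g_uS)

    def set_step(self, comp: int | None, amp_nA: float, onset_ms: float, dur_ms: float) -> None:
        """Configure the single square-pulse current stimulus."""
        self.i_step[:] = 0.0
        if comp is not None:
            self.i_step[comp] = amp_nA
        self.step_window = (onset_ms, onset_ms + dur_ms)

    def _finalize_connections(self):
        if self._conn_final is None:
            ptr = [0]
            comp, kind, inc = [], [], []
            self.conn_weight_view: list[np.ndarray] = []
            for pre in range(len(self.cells)):
                rows = self._conn[pre]
                idx0 = len(comp)
                for post_comp, k, w in rows:
                    comp.append(post_comp)
                    kind.append(k)
                    inc.append(w * self.kin_norm[k])
                ptr.append(len(comp))
                self.conn_weight_view.append(np.arange(idx0, len(comp)))
            self._conn_final = (
                np.asarray(ptr, dtype=np.int64),
                np.asarray(comp, dtype=np.int64) if comp else _EMPTY_I,
                np.asarray(kind, dtype=np.int64) if kind else _EMPTY_I,
                np.asarray(inc, dtype=np.float64) if inc else _EMPTY_F,
            )
        return self._conn_final

    def scale_connection_inc(self, pre_cell: int, local_idx: int, factor: float) -> None:
        """Multiply one registered synapse's weight in place (post-finalization safe)."""
        ptr, comp, kind, inc = self._finalize_connections()
        inc[ptr[pre_cell] + local_idx] *= factor

    # -- running ---------------------------------------------------------------

    def run(self, duration_ms: float, seed: int = 0, record_comps=(), record_stride: int = 40,
            max_rate_hz: float = 400.0) -> SimResult:
        dt = self.dt
        n_steps = int(round(duration_ms / dt))
        ptr, ccomp, ckind, cinc = self._finalize_connections()
        v = self.v_init.copy()
        # gate states at steady state for v_init / resting calcium
        g1 = np.empty(self.ch_comp.shape[0])
        g2 = np.zeros(self.ch_comp.shape[0])
        for j in range(self.ch_comp.shape[0]):
            c = self.ch_comp[j]
            g1[j] = self._table_inf(self.ch_t1[j], v[c], self.ca_min[c])
            if self.ch_t2[j] >= 0:
                g2[j] = self._table_inf(self.ch_t2[j], v[c], self.ca_min[c])
        ca = np.where(self.ca_has == 1, self.ca_min, 1e-4).astype(np.float64)
        synA = np.zeros((self.n_kind, self.n_comp))
        synB = np.zeros((self.n_kind, self.n_comp))
        ring = np.zeros((self.delay_steps + 1, self.n_kind, self.n_comp))
        bg_comp = np.asarray(self.bg_comp, dtype=np.int64) if self.bg_comp else _EMPTY_I
        bg_kind = np.asarray(self.bg_kind, dtype=np.int64) if self.bg_kind else _EMPTY_I
        bg_lam = (
            np.asarray(self.bg_rate_hz) * dt / 1000.0 if self.bg_rate_hz else _EMPTY_F
        )
        bg_inc = (
            np.asarray(
                [w * self.kin_norm[k] for w, k in zip(self.bg_w, self.bg_kind)]
            )
            if self.bg_w
            else _EMPTY_F
        )
        gj_a = np.asarray(self.gj_a, dtype=np.int64) if self.gj_a else _EMPTY_I
        gj_b = np.asarray(self.gj_b, dtype=np.int64) if self.gj_b else _EMPTY_I
        gj_g = np.asarray(self.gj_g, dtype=np.float64) if self.gj_g else _EMPTY_F
        det = np.asarray([self.soma_index(i) for i in range(len(self.cells))], dtype=np.int64)
        max_spikes = int(len(self.cells) * duration_ms / 1000.0 * max_rate_hz) + 1024
        spk_cell = np.empty(max_spikes, dtype=np.int64)
        spk_step = np.empty(max_spikes, dtype=np.int64)
        rec_comp = np.asarray(record_comps, dtype=np.int64) if len(record_comps) else _EMPTY_I
        n_rec_samples = (
            (n_steps + record_stride - 1) // record_stride if len(record_comps) else 1
        )
        rec_buf = np.zeros((max(len(record_comps), 0), n_rec_samples))
        step_on = int(round(self.step_window[0] / dt))
        step_off = int(round(self.step_window[1] / dt))

        status, n_spk, bad_step, bad_comp = _integrate(
            dt, n_steps,
            self.parent, self.cm_dt, self.ga, self.g_pas, self.e_pas, v,
            self.ch_comp, self.ch_g, self.ch_e, self.ch_isca,
            self.ch_t1, self.ch_p1, self.ch_t2, self.ch_p2, g1, g2,
            self.tables.tab_inf, self.tables.tab_f, self.tables.tab_isca,
            self.tables.vmin, self.tables.inv_dv, self.tables.lcmin, self.tables.inv_dlc,
            ca, self.ca_has, self.ca_f, self.ca_gain, self.ca_min,
            synA, synB, self.kin_fA, self.kin_fB, self.kin_e, self.kin_mg,
            self.mg_eta, self.mg_gamma,
            ring, self.delay_steps,
            ptr, ccomp, ckind, cinc,
            bg_comp, bg_kind, bg_lam, bg_inc,
            gj_a, gj_b, gj_g,
            self.i_const, self.i_step, step_on, step_off,
            det, self.spike_threshold, int(round(self.refractory_ms / dt)),
            spk_cell, spk_step, max_spikes,
            rec_comp, record_stride, rec_buf,
            int(seed),
        )
        if status != 0:
            raise IntegrationError(
                f"voltage diverged (|v| > 200 mV) at t = {bad_step * dt:.3f} ms "
                f"in compartment {bad_comp}"
            )
        spikes: list[list[float]] = [[] for _ in self.cells]
        for i in range(n_spk):
            spikes[spk_cell[i]].append(spk_step[i] * dt)
        result = SimResult(
            spike_times=[np.asarray(s) for s in spikes],
            duration=n_steps * dt,
            dt=dt,
        )
        if len(record_comps):
            result.t_record = np.arange(n_rec_samples) * dt * record_stride
            result.v_record = rec_buf
        return result

    def _table_inf(self, tab_id: int, v: float, ca: float) -> float:
        t = self.tables
        if t.tab_isca[tab_id] == 1:
            x = (np.log10(max(ca, 1e-6)) - t.lcmin) * t.inv_dlc
        else:
            x = (v - t.vmin) * t.inv_dv
        xi = int(np.clip(x, 0, _N_TAB - 2))
        fr = np.clip(x - xi, 0.0, 1.0)
        return float(t.tab_inf[tab_id, xi] * (1 - fr) + t.tab_inf[tab_id, xi + 1] * fr)
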