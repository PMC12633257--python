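"""Network construction, blockade, coefficient application, simulation."""

import numpy as np
import pytest

from deltacircuit.exceptions import MappingError
from deltacircuit.network import (
    BlockadeState,
    NetworkSpec,
    SpikeTrainSet,
    SynapticConductanceSet,
    apply_blockade,
    apply_coefficients,
    build_network,
    simulate_network,
)
from deltacircuit.spectral import firing_rate


def tiny_spec(**overrides) -> NetworkSpec:
    return NetworkSpec.default(n_PC=12, n_LBC=4, n_NGC=4, **overrides)


@pytest.fixture(scope="module")
def tiny_net():
    return build_network(tiny_spec(), seed=3)


class TestBuild:
    def test_composition_is_one_third_inhibitory(self):
        spec = NetworkSpec.default()
        assert (spec.n_PC, spec.n_LBC, spec.n_NGC) == (120, 30, 30)
        net = build_network(tiny_spec(), seed=0)
        assert net.inhibitory_fraction() == pytest.approx(8 / 20)
        full = spec.n_LBC + spec.n_NGC
        assert full / (spec.n_PC + full) == pytest.approx(1 / 3)

    def test_only_seven_connection_classes(self, tiny_net):
        assert set(tiny_net.realized_connections) == {
            ("PC", "PC"), ("PC", "LBC"), ("PC", "NGC"), ("LBC", "PC"),
            ("LBC", "LBC"), ("NGC", "LBC"), ("NGC", "PC"),
        }

    def test_zero_probability_scale_gives_no_synapses(self):
        net = build_network(tiny_spec(probability_scale=0.0), seed=0)
        assert len(net.synapses) == 0
        # gap junctions are drawn independently of chemical connectivity
        net_ref = build_network(tiny_spec(), seed=0)
        assert net.n_gap_junctions == net_ref.n_gap_junctions

    def test_same_seed_same_edge_list(self):
        a = build_network(tiny_spec(), seed=11)
        b = build_network(tiny_spec(), seed=11)
        assert a.edge_list() == b.edge_list()
        c = build_network(tiny_spec(), seed=12)
        assert a.edge_list() != c.edge_list()

    def test_connection_counts_match_binomial_oracle(self):
        """Realized counts vs Binomial(n_pairs, min(1, 6 p)) over 20 seeds."""
        spec = tiny_spec()
        counts = {cc: [] for cc in [("PC", "PC"), ("PC", "LBC"), ("NGC", "PC")]}
        for seed in range(20):
            net = build_network(spec, seed=seed)
            for cc in counts:
                counts[cc].append(net.realized_connections[cc])
        pops = {"PC": spec.n_PC, "LBC": spec.n_LBC, "NGC": spec.n_NGC}
        table = {(c.pre, c.post): c for c in spec.connections}
        for (pre, post), vals in counts.items():
            p = min(1.0, spec.probability_scale * table[(pre, post)].p_base)
            n_pairs = pops[pre] * pops[post] - (pops[pre] if pre == post else 0)
            mean_expected = n_pairs * p
            sd = np.sqrt(20 * n_pairs * p * (1 - p)) / 20 + 1e-9
            assert abs(np.mean(vals) - mean_expected) < 3 * sd + 1e-9, (pre, post)

    def test_gabab_weight_tied_across_targets(self, tiny_net):
        g = tiny_net.spec.conductances
        w_pc = tiny_net.class_weights("NGC", "PC")
        w_lbc = tiny_net.class_weights("NGC", "LBC")
        assert np.allclose(w_pc, w_pc[0]) and np.allclose(w_lbc, w_lbc[0])
        assert w_pc[0] == pytest.approx(w_lbc[0])  # both scaled by g_N

    def test_negative_weight_rejected(self):
        with pytest.raises(Exception):
            SynapticConductanceSet(g_EE=-0.1)


class TestBlockade:
    def test_gabab_blockade_zeroes_all_ngc_origin_weights(self):
        net = build_network(tiny_spec(), seed=5)
        apply_blockade(net, BlockadeState(gabaB_blocked=True))
        assert np.all(net.class_weights("NGC", "PC") == 0.0)
        assert np.all(net.class_weights("NGC", "LBC") == 0.0)
        assert np.all(net.class_weights("LBC", "PC") > 0.0)

    def test_gabaa_blockade_literal_text_scope(self):
        """Default GABA_A blockade zeroes LBC->PC only; LBC->LBC persists
        unless the block_all flag extends it."""
        net = build_network(tiny_spec(), seed=5)
        apply_blockade(net, BlockadeState(gabaA_blocked=True))
        assert np.all(net.class_weights("LBC", "PC") == 0.0)
        assert np.all(net.class_weights("LBC", "LBC") > 0.0)
        apply_blockade(net, BlockadeState(gabaA_blocked=True, block_all_gabaA=True))
        assert np.all(net.class_weights("LBC", "LBC") == 0.0)

    def test_blockade_roundtrip_restores_exactly(self):
        net = build_network(tiny_spec(), seed=5)
        before = {k: net.class_weights(*k) for k in net.realized_connections}
        apply_blockade(net, BlockadeState(gabaA_blocked=True, gabaB_blocked=True))
        apply_blockade(net, BlockadeState())
        after = {k: net.class_weights(*k) for k in net.realized_connections}
        for k in before:
            assert np.array_equal(before[k], after[k])

    def test_blockade_keeps_synapse_count(self):
        net = build_network(tiny_spec(), seed=5)
        n = len(net.synapses)
        apply_blockade(net, BlockadeState(gabaB_blocked=True))
        assert len(net.synapses) == n  # zeroed, never deleted


class TestCoefficients:
    def test_identity_coefficients_change_nothing(self):
        net = build_network(tiny_spec(), seed=7)
        before = net.channel_density_vector()
        apply_coefficients(net, {k: 1.0 for k in ("Ca_HVA", "Ih", "GABA_B")})
        assert np.array_equal(net.channel_density_vector(), before)

    def test_inverse_roundtrip_to_1e12(self):
        net = build_network(tiny_spec(), seed=7)
        before = net.channel_density_vector()
        w_before = net.class_weights("NGC", "PC")
        coeffs = {"Ca_HVA": 1.164, "Ca_LVA": 1.173, "Ih": 1.034, "GABA_B": 1.084}
        apply_coefficients(net, coeffs)
        apply_coefficients(net, {k: 1.0 / v for k, v in coeffs.items()})
        after = net.channel_density_vector()
        assert np.allclose(after, before, rtol=1e-12)
        assert np.allclose(net.class_weights("NGC", "PC"), w_before, rtol=1e-12)

    def test_scaling_targets_only_named_populations(self):
        net = build_network(tiny_spec(), seed=7)
        before = net.channel_density_vector()
        apply_coefficients(net, {"Ih": 2.0}, target_populations=("NGC",))
        after = net.channel_density_vector()
        changed = np.flatnonzero(~np.isclose(before, after))
        ngc_cells = [i for i, p in enumerate(net.populations) if p == "NGC"]
        allowed = set()
        for ci in ngc_cells:
            allowed.update(net.sim.channel_rows[ci].get("Ih", []))
        assert set(changed) <= allowed and len(changed) > 0

    def test_gabab_coefficient_selects_postsynaptic_population(self):
        net = build_network(tiny_spec(), seed=7)
        w_pc_before = net.class_weights("NGC", "PC")
        w_lbc_before = net.class_weights("NGC", "LBC")
        apply_coefficients(net, {"GABA_B": 1.5}, target_populations=("PC",))
        assert np.allclose(net.class_weights("NGC", "PC"), 1.5 * w_pc_before)
        assert np.allclose(net.class_weights("NGC", "LBC"), w_lbc_before)

    def test_unknown_key_raises_mapping_error(self):
        net = build_network(tiny_spec(), seed=7)
        with pytest.raises(MappingError):
            apply_coefficients(net, {"NaV9000": 1.1})

    def test_coefficients_compose_multiplicatively(self):
        net = build_network(tiny_spec(), seed=7)
        apply_coefficients(net, {"Im": 1.2})
        apply_coefficients(net, {"Im": 1.5})
        net2 = build_network(tiny_spec(), seed=7)
        apply_coefficients(net2, {"Im": 1.8})
        assert np.allclose(net.channel_density_vector(),
                           net2.channel_density_vector(), rtol=1e-12)


class TestSimulation:
    def test_determinism_bit_identical(self):
        net = build_network(tiny_spec(), seed=2)
        a = simulate_network(net, 1500.0, seed=9)
        b = simulate_network(net, 1500.0, seed=9)
        for ta, tb in zip(a.spike_times, b.spike_times):
            assert np.array_equal(ta, tb)

    def test_different_noise_seed_changes_output(self):
        net = build_network(tiny_spec(), seed=2)
        a = simulate_network(net, 1500.0, seed=9)
        b = simulate_network(net, 1500.0, seed=10)
        assert any(not np.array_equal(x, y)
                   for x, y in zip(a.spike_times, b.spike_times))

    def test_silent_without_drive_and_weights(self):
        spec = tiny_spec(probability_scale=0.0)
        spec.background.rates_hz.update({k: 0.0 for k in spec.background.rates_hz})
        net = build_network(spec, seed=2)
        sts = simulate_network(net, 1000.0, seed=1)
        assert all(t.size == 0 for t in sts.spike_times)

    def test_doubling_duration_roughly_doubles_counts(self):
        spec = tiny_spec()
        totals = {1: [], 2: []}
        for seed in range(5):
            net = build_network(spec, seed=seed)
            s1 = simulate_network(net, 3000.0, seed=seed)
            s2 = simulate_network(net, 6000.0, seed=seed)
            totals[1].append(sum(t.size for t in s1.spike_times))
            totals[2].append(sum(t.size for t in s2.spike_times))
        m1, m2 = np.mean(totals[1]), np.mean(totals[2])
        sd = np.std(totals[2], ddof=1) + 1e-9
        assert abs(m2 - 2 * m1) < 2 * sd + 0.2 * m1

    def test_removing_gabaa_does_not_decrease_pc_rate(self):
        """Monotone sanity: zeroing LBC->PC inhibition cannot lower PC firing
        (averaged over seeds at reduced scale)."""
        spec = tiny_spec()
        base, blocked = [], []
        for seed in range(5):
            net = build_network(spec, seed=seed)
            base.append(firing_rate(simulate_network(net, 2500.0, seed=seed,
                                                     transient_ms=500.0), "PC"))
            apply_blockade(net, BlockadeState(gabaA_blocked=True,
                                              block_all_gabaA=False))
            blocked.append(firing_rate(simulate_network(net, 2500.0, seed=seed,
                                                        transient_ms=500.0), "PC"))
        assert np.mean(blocked) >= np.mean(base) - 0.05


def test_spiketrainset_roundtrip(tmp_path):
    sts = SpikeTrainSet(
        [np.array([1001.5, 2002.25]), np.array([]), np.array([1500.0])],
        ["PC", "PC", "LBC"], duration=3000.0, transient=1000.0)
    path = tmp_path / "spikes.txt"
    sts.save(path)
    back = SpikeTrainSet.load(path)
    assert back.populations == sts.populations
    assert back.duration == sts.duration
    for a, b in zip(back.spike_times, sts.spike_times):
        assert np.allclose(a, b, atol=1e-3)
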