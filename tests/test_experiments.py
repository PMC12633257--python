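"""Experiment orchestration and statistics on stub simulators."""

import itertools

import numpy as np
import pytest

from deltacircuit.experiments import (
    ComparisonResult,
    ExperimentConfig,
    mann_whitney,
    region_coefficients,
    run_per_population,
    run_population_averaged,
    run_single_channel,
)
from deltacircuit.expression import ConductanceCoefficientSet
from deltacircuit.network import POPULATIONS


class StubSimulator:
    """Analytic delta-power model: each coefficient above 1 applied to the PC
    population multiplies delta power by a known factor; seeded noise on top."""

    def __init__(self, effect: float = 0.3, noise: float = 0.05):
        self.effect = effect
        self.noise = noise

    def run(self, coefficients=None, target_populations=POPULATIONS,
            seed: int = 0, blockade=None) -> dict:
        rng = np.random.default_rng(seed + (0 if coefficients is None else 10000))
        depression = 0.0
        if coefficients is not None and "PC" in target_populations:
            for k, c in coefficients.items():
                depression += self.effect * max(0.0, c - 1.0)
        delta = 1.0 * (1.0 - depression) * np.exp(self.noise * rng.normal())
        bands = {b: delta for b in ("delta", "theta", "alpha", "beta", "gamma")}
        return {"delta": delta, "bands": bands,
                "rate_PC": 3.0 * (1.0 - 0.5 * depression)}


@pytest.fixture
def cfg():
    return ExperimentConfig.preset("desk", n_seeds=10)


class TestMannWhitney:
    def test_identical_samples_nonsignificant(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        u, p = mann_whitney(a, a)
        assert p > 0.5

    def test_fully_separated_matches_exhaustive_permutation(self):
        """U for disjoint 5-vs-5 samples is 0/25 and the exact two-sided p
        equals the value from enumerating all C(10,5) label assignments."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a + 10.0
        u, p = mann_whitney(a, b)
        assert u in (0.0, 25.0)
        pooled = np.concatenate([a, b])
        observed = 0.0
        for ia in itertools.combinations(range(10), 5):
            xa = pooled[list(ia)]
            xb = pooled[[i for i in range(10) if i not in ia]]
            ua = sum((x > y) + 0.5 * (x == y) for x in xa for y in xb)
            observed += 1 if min(ua, 25 - ua) <= min(u, 25 - u) else 0
        p_exact = observed / 252.0  # C(10,5) assignments, two-sided
        assert p == pytest.approx(p_exact, rel=1e-9)

    def test_handles_ties(self):
        u, p = mann_whitney([1, 1, 2, 2], [1, 2, 2, 3])
        assert 0.0 < p <= 1.0


class TestConfig:
    def test_presets(self):
        desk = ExperimentConfig.preset("desk")
        full = ExperimentConfig.preset("full")
        assert desk.n_seeds == 5 and full.n_seeds == 30
        assert full.duration_ms > desk.duration_ms
        d_spec = desk.network_spec()
        p_spec = full.network_spec()
        assert (d_spec.n_PC, d_spec.n_LBC, d_spec.n_NGC) == (40, 10, 10)
        assert (p_spec.n_PC, p_spec.n_LBC, p_spec.n_NGC) == (120, 30, 30)

    def test_requires_two_seeds(self):
        with pytest.raises(ValueError):
            ExperimentConfig(n_seeds=1)

    def test_config_hash_stable(self, cfg):
        assert cfg.config_hash() == cfg.config_hash()
        other = ExperimentConfig.preset("desk", n_seeds=11)
        assert cfg.config_hash() != other.config_hash()


class TestRegionCoefficients:
    def test_hva_is_mean_of_the_two_calcium_genes(self):
        acc = region_coefficients("ACC")
        assert acc["Ca_HVA"] == pytest.approx((1.171 + 1.158) / 2.0)
        pfc = region_coefficients("PFC")
        assert pfc["Ca_HVA"] == pytest.approx((1.139 + 1.135) / 2.0)

    def test_covers_all_channel_keys(self):
        acc = region_coefficients("ACC")
        assert sorted(acc.coefficients) == sorted(
            ["Ca_HVA", "Ca_LVA", "Ih", "K_Pst", "Im", "GABA_B"])


class TestPopulationAveraged:
    def test_identity_coefficients_null_calibration(self, cfg):
        """With identity coefficients the type-I error at alpha = 0.05 stays
        within [0.01, 0.12] over 100 stub runs."""
        rejections = 0
        n_runs = 100
        for i in range(n_runs):
            sim = StubSimulator(noise=0.05)
            c = ExperimentConfig.preset("desk", n_seeds=10, base_seed=37 * i)
            res = run_population_averaged(
                "ACC", c, coefficients=ConductanceCoefficientSet.identity(),
                simulator=sim)
            rejections += res.p_value < 0.05
        assert 0.01 <= rejections / n_runs <= 0.12

    def test_injected_effect_detected_with_correct_sign(self, cfg):
        res = run_population_averaged("ACC", cfg, simulator=StubSimulator(0.5, 0.02))
        assert res.percent_change < 0
        assert res.p_value < 0.01
        assert res.metadata["region"] == "ACC"

    def test_halving_seeds_inflates_p_but_keeps_sign(self):
        sim = StubSimulator(0.12, 0.1)
        big = run_population_averaged("ACC", ExperimentConfig.preset("desk", n_seeds=24),
                                      simulator=sim)
        small = run_population_averaged("ACC", ExperimentConfig.preset("desk", n_seeds=6),
                                        simulator=sim)
        assert big.percent_change < 0 and small.percent_change < 0
        assert small.p_value >= big.p_value

    def test_band_table_has_both_arms(self, cfg):
        res = run_population_averaged("ACC", cfg, simulator=StubSimulator())
        assert set(res.band_powers["arm"]) == {"HC", "SCZ"}
        assert "gamma" in res.band_powers.columns


class TestSingleChannelAndPerPopulation:
    def test_forced_identity_channel_gives_null(self, cfg):
        sim = StubSimulator(0.5, 0.02)
        out = run_single_channel("ACC", cfg, simulator=sim, channels=["Ih"])
        res_forced = run_population_averaged(
            "ACC", cfg, coefficients=ConductanceCoefficientSet({"Ih": 1.0}),
            simulator=sim)
        assert res_forced.p_value > 0.05
        # the real Ih coefficient is > 1, so the single-channel run moves
        assert out["Ih"].percent_change <= 0.0

    def test_per_population_only_pc_targets_move_on_stub(self, cfg):
        out = run_per_population("ACC", cfg, simulator=StubSimulator(0.5, 0.02))
        assert out["PC"].percent_change < -5.0
        assert abs(out["NGC"].percent_change) < 5.0
        assert out["PC"].p_value < 0.05 < out["NGC"].p_value

    def test_empty_target_set_is_null(self, cfg):
        sim = StubSimulator(0.5, 0.02)
        out = run_per_population("ACC", cfg, simulator=sim, populations=())
        assert out == {}

    def test_sequential_all_population_application_matches_averaged_arm(self):
        """Applying the full set to all three populations equals the
        population-averaged SCZ arm configuration (structural equality of the
        modified network)."""
        from deltacircuit.network import NetworkSpec, apply_coefficients, build_network

        spec = NetworkSpec.default(n_PC=8, n_LBC=3, n_NGC=3)
        coeffs = region_coefficients("ACC")
        a = build_network(spec, seed=4)
        apply_coefficients(a, coeffs, POPULATIONS)
        b = build_network(spec, seed=4)
        for pop in POPULATIONS:
            apply_coefficients(b, coeffs, (pop,))
        assert np.allclose(a.channel_density_vector(), b.channel_density_vector(),
                           rtol=1e-14)
        for k in a.realized_connections:
            assert np.allclose(a.class_weights(*k), b.class_weights(*k), rtol=1e-14)


class TestComparisonResult:
    def test_percent_change_definition(self):
        res = ComparisonResult(
            label="x", hc_delta=np.array([1.0, 1.2]), scz_delta=np.array([0.9, 0.9]),
            hc_rate=np.array([3.0]), scz_rate=np.array([2.9]),
            u_statistic=1.0, p_value=0.5)
        expected = 100.0 * (0.9 - 1.1) / 1.1
        assert res.percent_change == pytest.approx(expected)


class TestSubjectWise:
    def _dataset(self, n_per_group=6, dispersion=0.25, seed=0):
        from deltacircuit.synthetic_data import GeneratorConfig, generate_expression

        cfg = GeneratorConfig.default(seed=seed, n_decoys=0, dispersion=dispersion)
        cfg.cohort_sizes = {"ACC": {"SCZ": n_per_group, "HC": n_per_group}}
        return generate_expression(cfg)

    def test_scz_arm_loses_delta_on_stub(self):
        from deltacircuit.experiments import run_subject_wise

        ds = self._dataset()
        cfg = ExperimentConfig.preset("desk", n_seeds=6)
        res = run_subject_wise("ACC", ds, cfg, simulator=StubSimulator(0.5, 0.02))
        assert res.percent_change < 0
        assert res.metadata["n_subjects"] == {"HC": 6, "SCZ": 6}

    def test_all_subjects_at_hc_mean_is_null(self):
        from deltacircuit.experiments import run_subject_wise

        ds = self._dataset(dispersion=0.0)  # every subject exactly at group mean
        # force SCZ means equal to HC means so every coefficient is 1
        ds.counts.loc[:, ds.subjects("ACC", "SCZ")] = (
            ds.counts[ds.subjects("ACC", "HC")].mean(axis=1).values[:, None])
        cfg = ExperimentConfig.preset("desk", n_seeds=6)
        res = run_subject_wise("ACC", ds, cfg, simulator=StubSimulator(0.5, 0.0))
        assert res.percent_change == pytest.approx(0.0, abs=1e-9)

    def test_subject_wise_spread_exceeds_population_averaged(self):
        """Between-subject expression variability adds delta-power variance on
        top of seed noise, so the subject-wise arm SD exceeds the
        population-averaged arm SD on the same stub."""
        from deltacircuit.experiments import run_subject_wise

        sim = StubSimulator(0.6, 0.02)
        ds = self._dataset(n_per_group=12, dispersion=0.3, seed=3)
        cfg = ExperimentConfig.preset("desk", n_seeds=12)
        sw = run_subject_wise("ACC", ds, cfg, simulator=sim)
        pa = run_population_averaged("ACC", cfg, simulator=sim)
        assert np.std(sw.scz_delta) > np.std(pa.scz_delta)

    def test_subject_cap_respected(self):
        from deltacircuit.experiments import run_subject_wise

        ds = self._dataset(n_per_group=8)
        cfg = ExperimentConfig.preset("desk", n_seeds=4)
        res = run_subject_wise("ACC", ds, cfg, simulator=StubSimulator(),
                               max_subjects_per_group=4)
        assert res.hc_delta.size == 4 and res.scz_delta.size == 4
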