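"""Expression-to-coefficient mapping and the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest

from deltacircuit.exceptions import UndefinedRatioError, ValidationError
from deltacircuit.expression import (
    GENE_CHANNEL_MAP,
    GWAS_THRESHOLD,
    ConductanceCoefficientSet,
    ExpressionDataset,
    build_population_coefficients,
    build_subject_coefficients,
    group_ratio,
    gwas_filter,
    population_coefficients_from_dataset,
    subject_coefficient_table,
)
from deltacircuit.synthetic_data import (
    GeneratorConfig,
    analytic_ratio_se,
    gene_targets,
    generate_expression,
    generate_gwas_table,
)


def toy_dataset(values: dict, diagnosis: list, region: list) -> ExpressionDataset:
    subjects = [f"S{i}" for i in range(len(diagnosis))]
    counts = pd.DataFrame(values)  # columns: subjects, index: genes
    counts = counts[subjects]
    meta = pd.DataFrame({"diagnosis": diagnosis, "region": region},
                        index=pd.Index(subjects, name="subject_id"))
    return ExpressionDataset(counts, meta)


@pytest.fixture
def six_subject_ds():
    # 3 SCZ + 3 HC, one region
    return toy_dataset(
        {"S0": {"CACNA1C": 12.0, "HCN1": 8.0}, "S1": {"CACNA1C": 10.0, "HCN1": 9.0},
         "S2": {"CACNA1C": 14.0, "HCN1": 10.0}, "S3": {"CACNA1C": 10.0, "HCN1": 10.0},
         "S4": {"CACNA1C": 9.0, "HCN1": 11.0}, "S5": {"CACNA1C": 11.0, "HCN1": 9.0}},
        ["SCZ", "SCZ", "SCZ", "HC", "HC", "HC"],
        ["ACC"] * 6,
    )


class TestGwasFilter:
    def test_zero_threshold_empty(self):
        table = {g: 1e-20 for g in GENE_CHANNEL_MAP}
        assert gwas_filter(GENE_CHANNEL_MAP, table, threshold=0.0) == []

    def test_all_seven_mapped_genes_pass_at_default(self):
        table = generate_gwas_table(sorted(GENE_CHANNEL_MAP))
        kept = gwas_filter(sorted(GENE_CHANNEL_MAP), table)
        assert sorted(kept) == sorted(GENE_CHANNEL_MAP)
        # the largest shipped p-value (KCNQ3) is still below 5e-6
        assert max(dict(zip(table.gene, table.min_p)).values()) < GWAS_THRESHOLD

    def test_matches_brute_force_on_toy_table(self):
        genes = list(GENE_CHANNEL_MAP) + [f"G{i}" for i in range(3)]
        rng = np.random.default_rng(0)
        pvals = {g: float(p) for g, p in zip(genes, rng.uniform(1e-9, 1e-3, len(genes)))}
        expected = [g for g in genes
                    if pvals[g] < GWAS_THRESHOLD and g in GENE_CHANNEL_MAP]
        assert gwas_filter(genes, pvals) == expected

    def test_invalid_pvalue_rejected(self):
        with pytest.raises(ValidationError):
            gwas_filter(["CACNA1C"], {"CACNA1C": 0.0})


class TestGroupRatio:
    def test_identical_means_give_unity(self):
        ds = toy_dataset(
            {"S0": {"HCN1": 5.0}, "S1": {"HCN1": 7.0},
             "S2": {"HCN1": 5.0}, "S3": {"HCN1": 7.0}},
            ["SCZ", "SCZ", "HC", "HC"], ["PFC"] * 4)
        assert group_ratio(ds, "HCN1", "PFC") == pytest.approx(1.0)

    def test_matches_explicit_loop(self, six_subject_ds):
        ds = six_subject_ds
        scz_vals, hc_vals = [], []
        for s in ds.counts.columns:
            v = float(ds.counts.loc["CACNA1C", s])
            (scz_vals if ds.metadata.loc[s, "diagnosis"] == "SCZ" else hc_vals).append(v)
        expected = (sum(scz_vals) / len(scz_vals)) / (sum(hc_vals) / len(hc_vals))
        assert group_ratio(ds, "CACNA1C", "ACC") == pytest.approx(expected)

    def test_zero_hc_mean_raises(self):
        ds = toy_dataset({"S0": {"HCN1": 5.0}, "S1": {"HCN1": 0.0}},
                         ["SCZ", "HC"], ["ACC"] * 2)
        with pytest.raises(UndefinedRatioError):
            group_ratio(ds, "HCN1", "ACC")

    def test_scale_invariance(self, six_subject_ds):
        r1 = group_ratio(six_subject_ds, "CACNA1C", "ACC")
        scaled = ExpressionDataset(six_subject_ds.counts * 37.5,
                                   six_subject_ds.metadata)
        assert group_ratio(scaled, "CACNA1C", "ACC") == pytest.approx(r1)


class TestPopulationCoefficients:
    def test_identity_ratios_give_identity_set(self):
        ratios = {g: 1.0 for g in GENE_CHANNEL_MAP}
        cs = build_population_coefficients(ratios)
        assert all(v == 1.0 for v in cs.coefficients.values())

    def test_hva_averaging_matches_printed_values(self):
        """mean(CACNA1C, CACNA1D) = 1.164 (ACC) and 1.137 (PFC) at printed
        rounding."""
        t = gene_targets()["genes"]
        acc = build_population_coefficients(
            {g: t[g]["acc_ratio"] for g in GENE_CHANNEL_MAP}, "ACC")
        pfc = build_population_coefficients(
            {g: t[g]["pfc_ratio"] for g in GENE_CHANNEL_MAP}, "PFC")
        assert round(acc["Ca_HVA"], 3) == 1.164
        assert round(pfc["Ca_HVA"], 3) == 1.137

    def test_gene_order_irrelevant(self):
        t = gene_targets()["genes"]
        ratios = {g: t[g]["acc_ratio"] for g in GENE_CHANNEL_MAP}
        a = build_population_coefficients(dict(sorted(ratios.items())))
        b = build_population_coefficients(dict(sorted(ratios.items(), reverse=True)))
        assert a.coefficients == b.coefficients

    def test_nonpositive_coefficient_rejected(self):
        with pytest.raises(ValidationError):
            ConductanceCoefficientSet({"Ih": 0.0})


class TestSubjectCoefficients:
    def test_subject_at_hc_mean_gets_identity(self):
        ds = toy_dataset(
            {"S0": {"CACNA1C": 10.0, "CACNA1D": 20.0}, "S1": {"CACNA1C": 10.0, "CACNA1D": 20.0},
             "S2": {"CACNA1C": 10.0, "CACNA1D": 20.0}},
            ["SCZ", "HC", "HC"], ["ACC"] * 3)
        cs = build_subject_coefficients(ds, "S0", genes=["CACNA1C", "CACNA1D"])
        assert cs["Ca_HVA"] == pytest.approx(1.0)

    def test_mean_subject_coefficient_equals_population_ratio(self):
        """Shared HC-mean denominators make the SCZ-mean of subject-wise
        coefficients equal the population ratio exactly."""
        cfg = GeneratorConfig.default(seed=3)
        cfg.cohort_sizes = {"ACC": {"SCZ": 40, "HC": 50}}
        ds = generate_expression(cfg)
        genes = ["HCN1"]
        subj = [build_subject_coefficients(ds, s, genes=genes)["Ih"]
                for s in ds.subjects("ACC", "SCZ")]
        pop = group_ratio(ds, "HCN1", "ACC")
        assert np.mean(subj) == pytest.approx(pop, rel=1e-12)

    def test_missing_gene_names_subject(self):
        ds = toy_dataset({"S0": {"CACNA1C": 10.0}, "S1": {"CACNA1C": 10.0}},
                         ["SCZ", "HC"], ["ACC"] * 2)
        with pytest.raises(ValidationError, match="HCN1.*S0"):
            build_subject_coefficients(ds, "S0", genes=["HCN1"])

    def test_applies_to_hc_subjects_too(self):
        cfg = GeneratorConfig.default(seed=4)
        cfg.cohort_sizes = {"ACC": {"SCZ": 5, "HC": 5}}
        ds = generate_expression(cfg)
        table = subject_coefficient_table(ds, "ACC")
        assert set(table["diagnosis"]) == {"SCZ", "HC"}
        assert len(table) == 10

    def test_inverse_roundtrip(self):
        cs = ConductanceCoefficientSet({"Ih": 1.25, "Ca_HVA": 0.8})
        inv = cs.inverse()
        for k in cs.coefficients:
            assert cs[k] * inv[k] == pytest.approx(1.0)


class TestGenerator:
    def test_zero_dispersion_recovers_targets_exactly(self):
        cfg = GeneratorConfig.default(seed=0, dispersion=0.0)
        ds = generate_expression(cfg)
        t = gene_targets()["genes"]
        for g in GENE_CHANNEL_MAP:
            assert group_ratio(ds, g, "ACC") == pytest.approx(t[g]["acc_ratio"], rel=1e-12)
            assert group_ratio(ds, g, "PFC") == pytest.approx(t[g]["pfc_ratio"], rel=1e-12)

    def test_default_ratios_within_sampling_tolerance(self):
        cfg = GeneratorConfig.default(seed=8)
        ds = generate_expression(cfg)
        r = group_ratio(ds, "CACNA1C", "ACC")
        se = analytic_ratio_se(cfg, "CACNA1C", "ACC")
        assert abs(r - 1.171) < 4.0 * se

    def test_doubling_means_leaves_ratios_unchanged(self):
        cfg1 = GeneratorConfig.default(seed=5)
        cfg2 = GeneratorConfig.default(seed=5)
        cfg2.hc_means = {g: 2.0 * m for g, m in cfg2.hc_means.items()}
        r1 = group_ratio(generate_expression(cfg1), "KCNB1", "ACC")
        r2 = group_ratio(generate_expression(cfg2), "KCNB1", "ACC")
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_reproducible_under_seed(self):
        a = generate_expression(GeneratorConfig.default(seed=9)).counts
        b = generate_expression(GeneratorConfig.default(seed=9)).counts
        pd.testing.assert_frame_equal(a, b)

    def test_gwas_table_end_to_end_filter(self):
        cfg = GeneratorConfig.default(seed=2, n_decoys=8)
        ds = generate_expression(cfg)
        table = generate_gwas_table(list(ds.counts.index), cfg)
        kept = gwas_filter(list(ds.counts.index), table)
        assert sorted(kept) == sorted(GENE_CHANNEL_MAP)

    def test_empty_decoy_set(self):
        table = generate_gwas_table(sorted(GENE_CHANNEL_MAP))
        assert len(table) == len(GENE_CHANNEL_MAP)

    def test_parameter_recovery_against_analytic_se(self):
        """Over 50 seeds at default cohort sizes the mean recovered ratio is
        within 1% of target and the empirical SE matches the count model's
        analytic SE within 25%."""
        gene, region = "KCNQ3", "ACC"
        target = gene_targets()["genes"][gene]["acc_ratio"]
        cfg0 = GeneratorConfig.default()
        cfg0.cohort_sizes = {region: cfg0.cohort_sizes[region]}
        ratios = []
        for seed in range(50):
            cfg = GeneratorConfig.default(seed=seed)
            cfg.cohort_sizes = {region: cfg.cohort_sizes[region]}
            cfg.n_decoys = 0
            ds = generate_expression(cfg)
            ratios.append(group_ratio(ds, gene, region))
        assert np.mean(ratios) == pytest.approx(target, rel=0.01)
        se_emp = np.std(ratios, ddof=1)
        se_ana = analytic_ratio_se(cfg0, gene, region)
        assert se_emp == pytest.approx(se_ana, rel=0.25)

    def test_files_roundtrip(self, tmp_path):
        cfg = GeneratorConfig.default(seed=1)
        cfg.cohort_sizes = {"ACC": {"SCZ": 4, "HC": 4}}
        ds = generate_expression(cfg)
        ds.to_files(tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = ExpressionDataset.from_files(tmp_path / "c.tsv", tmp_path / "m.tsv")
        assert np.allclose(back.counts.values, ds.counts.values)
        assert list(back.metadata["diagnosis"]) == list(ds.metadata["diagnosis"])
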