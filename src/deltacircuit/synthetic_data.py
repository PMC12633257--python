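"""Synthetic post-mortem expression datasets and GWAS tables.

Stands in for the restricted-access CommonMind-style cohort so every
downstream stage is testable without any download.  Per-gene expression is
drawn from a multiplicative gamma noise model (a continuous gamma-Poisson
approximation appropriate for DESeq2-normalized, non-integer counts):

    x = mu * Gamma(shape = 1/d, scale = d)      (mean mu, variance mu^2 d)

with mu the healthy-control mean for HC subjects and ``ratio * mu`` for SCZ
subjects, so the recovered group-mean ratio is unbiased for the target and
dispersion d = 0 degenerates to exact group means.  Default cohort sizes
(ACC: 230 SCZ / 251 HC; PFC: 263 SCZ / 295 HC), target ratios and GWAS
minimal p-values are the shipped per-gene table; decoy genes carry ratio 1
and clearly non-significant p-values.

The generator emulates group-mean structure only — no covariates (sex, age,
post-mortem interval), batch effects or gene-gene co-expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .expression import ExpressionDataset, GENE_CHANNEL_MAP, GWAS_THRESHOLD

__all__ = ["GeneratorConfig", "generate_expression", "generate_gwas_table",
           "gene_targets", "analytic_ratio_se"]


def gene_targets() -> dict:
    """The shipped per-gene target table (ratios, p-values, generator defaults)."""
    return yaml.safe_load(
        (resources.files("deltacircuit") / "data" / "gene_targets.yaml").read_text()
    )


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic cohort."""

    cohort_sizes: dict = field(default_factory=dict)  # region -> {SCZ: n, HC: n}
    hc_means: dict = field(default_factory=dict)  # gene -> mu
    ratios: dict = field(default_factory=dict)  # region -> gene -> SCZ/HC ratio
    dispersion: float = 0.2
    n_decoys: int = 5
    decoy_mean: float = 500.0
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        t = gene_targets()
        cfg = cls(
            cohort_sizes={r: dict(v) for r, v in t["cohorts"].items()},
            hc_means={g: float(v["hc_mean"]) for g, v in t["genes"].items()},
            ratios={
                "ACC": {g: float(v["acc_ratio"]) for g, v in t["genes"].items()},
                "PFC": {g: float(v["pfc_ratio"]) for g, v in t["genes"].items()},
            },
            dispersion=float(t["dispersion"]),
            seed=seed,
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    def validate(self) -> None:
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        for region, groups in self.cohort_sizes.items():
            if any(n < 1 for n in groups.values()):
                raise ValidationError(f"{region}: cohort sizes must be >= 1")
        if any(m <= 0 for m in self.hc_means.values()):
            raise ValidationError("HC means must be > 0")
        for region, rr in self.ratios.items():
            if any(r <= 0 for r in rr.values()):
                raise ValidationError(f"{region}: ratios must be > 0")


def _draw(rng: np.random.Generator, mu: float, d: float, n: int) -> np.ndarray:
    if d == 0.0:
        return np.full(n, mu)
    return mu * rng.gamma(shape=1.0 / d, scale=d, size=n)


def generate_expression(cfg: GeneratorConfig) -> ExpressionDataset:
    """Draw a gene x subject dataset with the configured group-mean structure."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = sorted(cfg.hc_means)
    decoys = [f"DECOY{i:03d}" for i in range(cfg.n_decoys)]
    subjects, diagnosis, region_col = [], [], []
    columns = {}
    for region in sorted(cfg.cohort_sizes):
        for dx in ("SCZ", "HC"):
            n = cfg.cohort_sizes[region][dx]
            for i in range(n):
                sid = f"{region}_{dx}_{i:04d}"
                subjects.append(sid)
                diagnosis.append(dx)
                region_col.append(region)
    mat = np.empty((len(genes) + len(decoys), len(subjects)))
    col = 0
    for region in sorted(cfg.cohort_sizes):
        for dx in ("SCZ", "HC"):
            n = cfg.cohort_sizes[region][dx]
            block = np.empty((mat.shape[0], n))
            for gi, g in enumerate(genes):
                mu = cfg.hc_means[g]
                if dx == "SCZ":
                    mu *= cfg.ratios[region][g]
                block[gi] = _draw(rng, mu, cfg.dispersion, n)
            for di in range(len(decoys)):
                block[len(genes) + di] = _draw(rng, cfg.decoy_mean, cfg.dispersion, n)
            mat[:, col:col + n] = block
            col += n
    counts = pd.DataFrame(mat, index=genes + decoys, columns=subjects)
    meta = pd.DataFrame(
        {"diagnosis": diagnosis, "region": region_col}, index=pd.Index(subjects, name="subject_id")
    )
    return ExpressionDataset(counts, meta, provenance=f"synthetic (seed={cfg.seed})")


def generate_gwas_table(genes, cfg: GeneratorConfig | None = None,
                        seed: int | None = None) -> pd.DataFrame:
    """Per-gene minimal SNP p-values: shipped values for mapped genes, uniform
    clearly-non-significant values for decoys."""
    cfg = cfg or GeneratorConfig.default()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    shipped = {g: float(v["min_p"]) for g, v in gene_targets()["genes"].items()}
    rows = []
    for g in genes:
        if g in GENE_CHANNEL_MAP:
            rows.append((g, shipped[g]))
        else:
            rows.append((g, float(rng.uniform(100 * GWAS_THRESHOLD, 1.0))))
    return pd.DataFrame(rows, columns=["gene", "min_p"])


def analytic_ratio_se(cfg: GeneratorConfig, gene: str, region: str) -> float:
    """Delta-method standard error of the recovered SCZ/HC mean ratio.

    Under the gamma model the coefficient of variation of each draw is
    sqrt(d), so SE(r) = r * sqrt(d/n_SCZ + d/n_HC).
    """
    d = cfg.dispersion
    r = cfg.ratios[region][gene]
    n_s = cfg.cohort_sizes[region]["SCZ"]
    n_h = cfg.cohort_sizes[region]["HC"]
    return r * np.sqrt(d / n_s + d / n_h)
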