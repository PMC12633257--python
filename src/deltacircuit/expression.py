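"""Gene-expression-to-conductance mapping.

Turns a gene x subject matrix of DESeq2-normalized RNA-seq counts (plus
subject metadata and a per-gene minimal GWAS SNP p-value table) into
multiplicative conductance coefficients:

* GWAS filter: keep genes whose minimal single-SNP p-value is below 5e-6 and
  that encode a channel represented in the model;
* population-averaged coefficients: the ratio of SCZ to HC mean expression
  per gene and region, mapped to channel keys — CACNA1C and CACNA1D both
  target the HVA Ca channel, so their ratios are averaged;
* subject-wise coefficients: each subject's expression divided by the
  healthy-control mean of their region (computed for HC subjects too).

Glutamatergic and GABA_A receptor genes are deliberately absent from the map
(their expression is likely confounded by antipsychotic use); the map is
closed-world.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import UndefinedRatioError, ValidationError

__all__ = [
    "GENE_CHANNEL_MAP",
    "GWAS_THRESHOLD",
    "ExpressionDataset",
    "ConductanceCoefficientSet",
    "gwas_filter",
    "group_ratio",
    "build_population_coefficients",
    "build_subject_coefficients",
]

logger = logging.getLogger(__name__)

#: gene -> model channel key; CACNA1C/CACNA1D share the HVA Ca target.
GENE_CHANNEL_MAP: dict[str, str] = {
    "CACNA1C": "Ca_HVA",
    "CACNA1D": "Ca_HVA",
    "CACNA1I": "Ca_LVA",
    "HCN1": "Ih",
    "KCNB1": "K_Pst",
    "KCNQ3": "Im",
    "GABBR2": "GABA_B",
}

GWAS_THRESHOLD = 5e-6

DIAGNOSES = ("SCZ", "HC")
REGIONS = ("ACC", "PFC")


@dataclass
class ExpressionDataset:
    """DESeq2-normalized counts (genes x subjects) with subject metadata."""

    counts: pd.DataFrame  # index: gene, columns: subject id
    metadata: pd.DataFrame  # index: subject id; columns: diagnosis, region
    provenance: str = ""

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("negative expression counts")
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate gene names")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValidationError(f"subjects without metadata: {sorted(missing)[:5]} ...")
        bad_dx = set(self.metadata["diagnosis"]) - set(DIAGNOSES)
        bad_rg = set(self.metadata["region"]) - set(REGIONS)
        if bad_dx or bad_rg:
            raise ValidationError(f"unknown diagnosis/region labels: {bad_dx | bad_rg}")

    def subjects(self, region: str, diagnosis: str | None = None) -> list[str]:
        m = self.metadata["region"] == region
        if diagnosis is not None:
            m &= self.metadata["diagnosis"] == diagnosis
        return [s for s in self.metadata.index[m] if s in self.counts.columns]

    @classmethod
    def from_files(cls, counts_path, metadata_path, provenance: str = "") -> "ExpressionDataset":
        counts = pd.read_csv(counts_path, sep=None, engine="python", index_col=0)
        meta = pd.read_csv(metadata_path, sep=None, engine="python", index_col=0)
        return cls(counts, meta, provenance)

    def to_files(self, counts_path, metadata_path) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        self.metadata.to_csv(metadata_path, sep="\t")


@dataclass
class ConductanceCoefficientSet:
    """Channel key -> multiplicative coefficient, with scope and region tags."""

    coefficients: dict[str, float]
    scope: str = "population-averaged"  # or a subject id
    region: str = "ACC"

    def __post_init__(self) -> None:
        for k, v in self.coefficients.items():
            if v <= 0:
                raise ValidationError(f"coefficient {k} must be > 0, got {v}")

    def items(self):
        return self.coefficients.items()

    def __getitem__(self, key: str) -> float:
        return self.coefficients[key]

    def inverse(self) -> "ConductanceCoefficientSet":
        return ConductanceCoefficientSet(
            {k: 1.0 / v for k, v in self.coefficients.items()},
            scope=f"inverse({self.scope})", region=self.region,
        )

    @classmethod
    def identity(cls, region: str = "ACC") -> "ConductanceCoefficientSet":
        keys = sorted(set(GENE_CHANNEL_MAP.values()))
        return cls({k: 1.0 for k in keys}, scope="identity", region=region)


def gwas_filter(genes, pvalue_table: pd.DataFrame | dict,
                threshold: float = GWAS_THRESHOLD) -> list[str]:
    """Genes with minimal SNP p-value below ``threshold`` AND a channel mapping.

    ``pvalue_table``: mapping gene -> min p, or a DataFrame with columns
    (gene, min_p).
    """
    if isinstance(pvalue_table, pd.DataFrame):
        table = dict(zip(pvalue_table.iloc[:, 0], pvalue_table.iloc[:, 1]))
    else:
        table = dict(pvalue_table)
    for g, p in table.items():
        if not 0.0 < p <= 1.0:
            raise ValidationError(f"p-value for {g} outside (0, 1]: {p}")
    return [
        g for g in genes
        if g in GENE_CHANNEL_MAP and table.get(g, 1.0) < threshold
    ]


def group_ratio(ds: ExpressionDataset, gene: str, region: str) -> float:
    """SCZ/HC ratio of group mean expression for one gene in one region."""
    scz = ds.subjects(region, "SCZ")
    hc = ds.subjects(region, "HC")
    if not scz or not hc:
        raise ValidationError(f"region {region}: empty SCZ or HC group")
    row = ds.counts.loc[gene]
    hc_mean = float(row[hc].mean())
    if hc_mean == 0.0:
        raise UndefinedRatioError(f"{gene} ({region}): zero HC mean expression")
    return float(row[scz].mean()) / hc_mean


def _map_ratios_to_channels(ratios: dict[str, float]) -> dict[str, float]:
    """Apply the gene->channel map; the two HVA genes are averaged."""
    out: dict[str, list[float]] = {}
    for gene, r in ratios.items():
        if gene not in GENE_CHANNEL_MAP:
            raise ValidationError(f"gene {gene!r} not in the channel map")
        out.setdefault(GENE_CHANNEL_MAP[gene], []).append(r)
    return {ch: float(np.mean(vals)) for ch, vals in out.items()}


def build_population_coefficients(
    ratios: dict[str, float], region: str = "ACC"
) -> ConductanceCoefficientSet:
    """Channel coefficients from per-gene SCZ/HC expression ratios."""
    return ConductanceCoefficientSet(
        _map_ratios_to_channels(ratios), scope="population-averaged", region=region
    )


def population_coefficients_from_dataset(
    ds: ExpressionDataset, region: str, genes=None
) -> ConductanceCoefficientSet:
    genes = list(genes) if genes is not None else sorted(GENE_CHANNEL_MAP)
    ratios = {g: group_ratio(ds, g, region) for g in genes}
    return build_population_coefficients(ratios, region)


def build_subject_coefficients(
    ds: ExpressionDataset, subject: str, genes=None
) -> ConductanceCoefficientSet:
    """Coefficients for one subject: expression / HC-region mean, per gene."""
    if subject not in ds.counts.columns:
        raise ValidationError(f"unknown subject {subject!r}")
    region = ds.metadata.loc[subject, "region"]
    hc = ds.subjects(region, "HC")
    genes = list(genes) if genes is not None else sorted(GENE_CHANNEL_MAP)
    ratios = {}
    for g in genes:
        if g not in ds.counts.index or pd.isna(ds.counts.loc[g, subject]):
            raise ValidationError(f"missing expression for gene {g} in subject {subject}")
        hc_mean = float(ds.counts.loc[g, hc].mean())
        if hc_mean == 0.0:
            raise UndefinedRatioError(f"{g} ({region}): zero HC mean expression")
        ratios[g] = float(ds.counts.loc[g, subject]) / hc_mean
    return ConductanceCoefficientSet(
        _map_ratios_to_channels(ratios), scope=subject, region=region
    )


def subject_coefficient_table(ds: ExpressionDataset, region: str) -> pd.DataFrame:
    """All subjects' coefficient sets for a region (rows: subject).

    Subjects with any missing mapped gene are dropped with a logged count.
    """
    rows = {}
    dropped = 0
    for s in ds.subjects(region):
        try:
            cs = build_subject_coefficients(ds, s)
        except ValidationError:
            dropped += 1
            continue
        rows[s] = dict(cs.coefficients)
    if dropped:
        logger.warning("dropped %d subjects with missing mapped genes (%s)", dropped, region)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["diagnosis"] = ds.metadata.loc[df.index, "diagnosis"]
    return df
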