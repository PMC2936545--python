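"""Core in-memory containers shared across the pipeline.

All matrices are pandas DataFrames so that probe/sample/SNP labels travel
with the values. Expression is stored probes x samples on the log2 scale;
genotypes are stored samples x SNPs as minor-allele dosages (0/1/2, NaN for
missing); traits are stored samples x columns with covariates alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GenotypeDataset",
    "TraitTable",
]


@dataclass
class ExpressionDataset:
    """Probes x samples log2 intensity matrix with per-probe annotations.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample.
    annotations
        DataFrame indexed by probe id. Recognised columns: ``chromosome``
        (str), ``position`` (1-based probe midpoint, int), ``globin``
        (bool), ``n_mappings`` (int, genomic mapping count).
    replicates
        Optional mapping ``sample_id -> ReplicatePair`` holding raw
        (linear-scale) technical replicates with bead counts.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame | None = None
    replicates: dict | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if self.annotations is not None:
            missing = self.values.index.difference(self.annotations.index)
            if len(missing):
                raise ValueError(
                    f"{len(missing)} probes lack annotations (e.g. {missing[0]!r})"
                )
            self.annotations = self.annotations.loc[self.values.index]

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_probes(self, probes) -> "ExpressionDataset":
        ann = self.annotations.loc[probes] if self.annotations is not None else None
        return ExpressionDataset(self.values.loc[probes], ann, self.replicates)

    def subset_samples(self, samples) -> "ExpressionDataset":
        reps = None
        if self.replicates is not None:
            reps = {s: self.replicates[s] for s in samples if s in self.replicates}
        return ExpressionDataset(self.values[list(samples)], self.annotations, reps)


@dataclass
class GenotypeDataset:
    """Samples x SNPs minor-allele dosage matrix with SNP coordinates.

    ``dosages`` holds 0/1/2 (floats; NaN = missing). ``snps`` is indexed by
    SNP id with columns ``chromosome`` (str) and ``position`` (1-based int).
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.columns.has_duplicates:
            raise ValueError("duplicate SNP ids")
        if not self.dosages.columns.equals(self.snps.index):
            self.snps = self.snps.loc[self.dosages.columns]
        vals = self.dosages.to_numpy(dtype=float)
        bad = vals[~np.isnan(vals)]
        if bad.size and not np.isin(bad, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0/1/2 or missing")

    @property
    def samples(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    def subset_samples(self, samples) -> "GenotypeDataset":
        return GenotypeDataset(self.dosages.loc[list(samples)], self.snps)

    def subset_snps(self, snp_ids) -> "GenotypeDataset":
        return GenotypeDataset(self.dosages[list(snp_ids)], self.snps.loc[list(snp_ids)])


@dataclass
class TraitTable:
    """Per-sample trait values and covariates.

    ``traits`` lists the trait columns (raw scale); ``covariates`` lists
    covariate columns (age, sex, medications, alcohol). ``zscores`` is an
    optional samples x traits layer of gender-stratified standard scores
    filled in by :func:`llnet.preprocess.transform_trait`.
    """

    data: pd.DataFrame
    traits: list[str]
    covariates: list[str] = field(default_factory=list)
    zscores: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for c in list(self.traits) + list(self.covariates):
            if c not in self.data.columns:
                raise ValueError(f"column {c!r} missing from trait table")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    def trait_values(self, name: str, standardized: bool = True) -> pd.Series:
        """Return a trait column, preferring the Z-score layer when present."""
        if standardized and self.zscores is not None and name in self.zscores.columns:
            return self.zscores[name]
        return self.data[name]
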