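"""Subject-level case-control cohort container.

A :class:`Cohort` holds one row per subject: binary ischemic-stroke status
(``outcome``), the natural-log telomere length (``exposure``, ln kb),
covariates, and per-SNP genotypes coded as alternate-allele counts
(0/1/2, ``NaN`` = missing).  It is the unit every pipeline stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

RESERVED_PHENOTYPE_COLUMNS = ("outcome", "exposure")


@dataclass(frozen=True)
class SNPRecord:
    """Per-variant metadata (identifier, locus label, alleles)."""

    snp_id: str
    chromosome: str = "1"
    gene: Optional[str] = None
    ref_allele: str = "A"
    alt_allele: str = "G"
    position: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles must differ")


@dataclass
class Cohort:
    """Case-control cohort: phenotypes plus a genotype matrix.

    Parameters
    ----------
    phenotypes
        DataFrame indexed by subject id with columns ``outcome`` (0/1),
        ``exposure`` (ln kb) and any covariates.
    genotypes
        DataFrame indexed by subject id, one column per SNP, values in
        {0, 1, 2} counting alternate alleles, ``NaN`` for missing calls.
    snps
        Optional per-SNP metadata keyed by SNP id.
    meta
        Free-form provenance (seed, source paths, simulation config...).
    """

    phenotypes: pd.DataFrame
    genotypes: pd.DataFrame
    snps: dict[str, SNPRecord] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in RESERVED_PHENOTYPE_COLUMNS:
            if col not in self.phenotypes.columns:
                raise ValueError(f"phenotype table lacks required column {col!r}")
        if self.phenotypes.index.has_duplicates:
            dup = self.phenotypes.index[self.phenotypes.index.duplicated()][0]
            raise ValueError(f"duplicate subject id {dup!r}")
        out = self.phenotypes["outcome"]
        if not set(pd.unique(out.dropna())) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")
        if out.sum() < 1 or (1 - out).sum() < 1:
            raise ValueError("cohort needs at least one case and one control")
        expo = self.phenotypes["exposure"]
        if not np.all(np.isfinite(expo.dropna().to_numpy(dtype=float))):
            raise ValueError("exposure contains non-finite values")
        if not self.genotypes.index.equals(self.phenotypes.index):
            self.genotypes = self.genotypes.reindex(self.phenotypes.index)
        g = self.genotypes.to_numpy(dtype=float)
        valid = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotypes must be in {0,1,2} or missing")

    # -- convenience accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.phenotypes)

    @property
    def n_cases(self) -> int:
        return int(self.phenotypes["outcome"].sum())

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    @property
    def snp_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.phenotypes.columns if c not in RESERVED_PHENOTYPE_COLUMNS]

    @property
    def outcome(self) -> pd.Series:
        return self.phenotypes["outcome"]

    @property
    def exposure(self) -> pd.Series:
        return self.phenotypes["exposure"]

    def is_control(self) -> pd.Series:
        return self.phenotypes["outcome"] == 0

    def controls(self) -> "Cohort":
        """The control subset (instrument-exposure associations are estimated here)."""
        return self.subset(self.is_control())

    def cases(self) -> "Cohort":
        return self.subset(self.phenotypes["outcome"] == 1)

    def subset(self, mask) -> "Cohort":
        sub = Cohort.__new__(Cohort)  # skip validation: subsets may be single-class
        sub.phenotypes = self.phenotypes.loc[mask]
        sub.genotypes = self.genotypes.loc[mask]
        sub.snps = self.snps
        sub.meta = dict(self.meta)
        return sub

    def genotype(self, snp_id: str) -> pd.Series:
        if snp_id not in self.genotypes.columns:
            raise KeyError(f"unknown SNP {snp_id!r}")
        return self.genotypes[snp_id]
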