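"""Core containers for genotype/phenotype data and study design.

Genotypes are stored as a dense subject x SNP matrix of additive dosages
(0/1/2 counts of the counted allele).  SNP metadata lives in a pandas
DataFrame with one row per column of the matrix.  For simulated data the
per-subject true disease probability eta(x) is carried along for oracle
checks; fitting code must never read it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SNP_COLUMNS = ["snp_id", "chrom", "position", "allele_a", "allele_b", "counted_allele"]


class InvalidConfigError(ValueError):
    """Raised when a simulation or experiment configuration is inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the prospective disease model and the genotype simulator.

    Attributes
    ----------
    n_snps : number of biallelic SNPs to simulate.
    maf_range : interval in (0, 0.5] from which each SNP's minor allele
        frequency is drawn uniformly.
    ld_rho : first-order autoregressive correlation in [0, 1) between the
        latent haplotype states of adjacent SNPs (0 = linkage equilibrium).
    causal_effects : map SNP index -> per-allele log odds ratio beta_j of the
        prospective logistic disease model.
    baseline_log_odds : intercept alpha of the prospective logistic model;
        logit of disease probability for a subject with dosage 0 at every
        causal SNP.
    cohort_size : number of subjects in the prospective cohort.
    seed : integer seed; identical configs produce bit-identical data.
    """

    n_snps: int
    cohort_size: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    causal_effects: Mapping[int, float] = field(default_factory=dict)
    baseline_log_odds: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0:
            raise InvalidConfigError("n_snps must be positive")
        if self.cohort_size <= 0:
            raise InvalidConfigError("cohort_size must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise InvalidConfigError("ld_rho must be in [0, 1)")
        for j in self.causal_effects:
            if not (0 <= int(j) < self.n_snps):
                raise InvalidConfigError(f"causal SNP index {j} out of range")


@dataclass(frozen=True)
class SamplingDesign:
    """Case-control sampling fractions relative to the source cohort.

    pi1 (pi0) is the fraction of the cohort's cases (controls) drawn into the
    retrospective sample; knowing them allows mapping retrospectively fitted
    probabilities back to the prospective scale.
    """

    pi1: float
    pi0: float
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if not (0.0 < self.pi1 <= 1.0 and 0.0 < self.pi0 <= 1.0):
            raise InvalidConfigError("sampling fractions must lie in (0, 1]")
        if self.n_cases < 1 or self.n_controls < 1:
            raise InvalidConfigError("sampled counts must be >= 1")


@dataclass
class GenotypeDataset:
    """Subject x SNP additive dosage matrix with metadata and phenotype."""

    genotypes: np.ndarray
    snps: pd.DataFrame
    phenotype: Optional[np.ndarray] = None
    subject_ids: Optional[np.ndarray] = None
    design: Optional[SamplingDesign] = None
    true_prob: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-d matrix")
        if self.subject_ids is None:
            self.subject_ids = np.array(
                [f"S{i:07d}" for i in range(self.genotypes.shape[0])], dtype=object
            )
        self.subject_ids = np.asarray(self.subject_ids)
        self.validate()

    # -- basic views ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp_id"].to_numpy()

    def validate(self) -> None:
        if len(self.snps) != self.genotypes.shape[1]:
            raise ValueError("SNP metadata length must equal genotype column count")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("snp_id values must be unique")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype)
            if len(self.phenotype) != self.genotypes.shape[0]:
                raise ValueError("phenotype length must equal subject count")
            if not np.isin(self.phenotype, [0, 1]).all():
                raise ValueError("phenotype must be binary 0/1")
        if len(self.subject_ids) != self.genotypes.shape[0]:
            raise ValueError("subject_ids length must equal subject count")
        if self.genotypes.size and not np.isin(self.genotypes, [0, 1, 2]).all():
            raise ValueError("dosages must be 0, 1 or 2")

    # -- subsetting ----------------------------------------------------
    def subset_subjects(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            genotypes=self.genotypes[index],
            snps=self.snps.reset_index(drop=True),
            phenotype=None if self.phenotype is None else self.phenotype[index],
            subject_ids=self.subject_ids[index],
            design=self.design,
            true_prob=None if self.true_prob is None else self.true_prob[index],
        )

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeDataset":
        wanted = list(snp_ids)
        lookup = {s: i for i, s in enumerate(self.snps["snp_id"])}
        missing = [s for s in wanted if s not in lookup]
        if missing:
            raise KeyError(f"unknown SNP id(s): {missing[:5]}")
        cols = np.array([lookup[s] for s in wanted], dtype=int)
        return GenotypeDataset(
            genotypes=self.genotypes[:, cols],
            snps=self.snps.iloc[cols].reset_index(drop=True),
            phenotype=self.phenotype,
            subject_ids=self.subject_ids,
            design=self.design,
            true_prob=self.true_prob,
        )

    def dosages_for(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Dosage sub-matrix for the given SNP ids, in the given order."""
        lookup = {s: i for i, s in enumerate(self.snps["snp_id"])}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown SNP id(s): {missing[:5]}")
        cols = np.array([lookup[s] for s in snp_ids], dtype=int)
        return self.genotypes[:, cols]

    def with_design(self, design: SamplingDesign) -> "GenotypeDataset":
        new = replace_dataset(self)
        new.design = design
        return new


def replace_dataset(ds: GenotypeDataset) -> GenotypeDataset:
    return GenotypeDataset(
        genotypes=ds.genotypes,
        snps=ds.snps,
        phenotype=ds.phenotype,
        subject_ids=ds.subject_ids,
        design=ds.design,
        true_prob=ds.true_prob,
    )
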