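"""Synthetic genome-wide association data.

The simulator produces a prospective cohort first: biallelic SNPs in
Hardy-Weinberg proportions (two independent haplotypes per subject), an
optional first-order Gaussian-copula autoregression between adjacent SNPs to
mimic local linkage disequilibrium, and a sparse logistic disease model
P(y=1 | g) = expit(alpha + sum_j beta_j g_j).  Retrospective case-control
samples are then drawn from the cohort with recorded sampling fractions, and
a stratified train/test split prepares rule construction and evaluation.

The per-subject true probability eta(x) is retained on simulated datasets so
that probability estimates can be checked against the truth; fitting code
never sees it.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from .datatypes import (
    GenotypeDataset,
    InvalidConfigError,
    SamplingDesign,
    SimulationConfig,
    SNP_COLUMNS,
)

_NUCLEOTIDES = np.array(list("ACGT"))
_CHUNK = 4096  # subjects per haplotype-simulation block


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit stage seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def _snp_table(n_snps: int, rng: np.random.Generator) -> pd.DataFrame:
    chrom = 1 + (np.arange(n_snps) * 22) // max(n_snps, 1)
    position = 1000 * (1 + np.arange(n_snps))
    ref = rng.integers(0, 4, size=n_snps)
    alt = (ref + rng.integers(1, 4, size=n_snps)) % 4
    tab = pd.DataFrame(
        {
            "snp_id": [f"rs{j + 1:06d}" for j in range(n_snps)],
            "chrom": chrom.astype(int),
            "position": position.astype(int),
            "allele_a": _NUCLEOTIDES[ref],
            "allele_b": _NUCLEOTIDES[alt],
        }
    )
    # the counted (dosage) allele is the designated minor allele b
    tab["counted_allele"] = tab["allele_b"]
    return tab[SNP_COLUMNS]


def _haplotype_block(
    rng: np.random.Generator, n_hap: int, thresholds: np.ndarray, rho: float
) -> np.ndarray:
    """n_hap haplotypes over p SNPs: AR(1) latent normals thresholded at
    Phi^{-1}(MAF_j), so each SNP is Bernoulli(MAF_j) marginally."""
    p = thresholds.shape[0]
    eps = rng.standard_normal((n_hap, p))
    if rho > 0.0:
        scaled = eps * np.sqrt(1.0 - rho**2)
        scaled[:, 0] = eps[:, 0]
        z = lfilter([1.0], [1.0, -rho], scaled, axis=1)
    else:
        z = eps
    return (z < thresholds).astype(np.int8)


def simulate_genotypes(config: SimulationConfig) -> GenotypeDataset:
    """Simulate the genotype matrix of a prospective cohort (phenotype unset).

    Each SNP j draws MAF_j ~ Uniform(maf_range); each subject receives two
    independent haplotypes, so dosages follow Hardy-Weinberg proportions
    (MAF^2, 2 MAF(1-MAF), (1-MAF)^2 for 2/1/0 copies of the minor allele).
    With ld_rho > 0 the latent haplotype states of adjacent SNPs follow a
    first-order autoregression with that coefficient.
    """
    rng = np.random.default_rng(config.seed)
    snps = _snp_table(config.n_snps, rng)
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=config.n_snps)
    from scipy.stats import norm

    thresholds = norm.ppf(maf)
    blocks = []
    done = 0
    while done < config.cohort_size:
        n_blk = min(_CHUNK, config.cohort_size - done)
        h1 = _haplotype_block(rng, n_blk, thresholds, config.ld_rho)
        h2 = _haplotype_block(rng, n_blk, thresholds, config.ld_rho)
        blocks.append(h1 + h2)
        done += n_blk
    genotypes = np.vstack(blocks).astype(np.int8)
    return GenotypeDataset(genotypes=genotypes, snps=snps)


def true_probabilities(
    genotypes: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """eta(x_i) = expit(alpha + sum_j beta_j g_ij) for every subject."""
    eta_lin = np.full(genotypes.shape[0], float(config.baseline_log_odds))
    for j, beta in config.causal_effects.items():
        j = int(j)
        if not (0 <= j < genotypes.shape[1]):
            raise InvalidConfigError(f"causal SNP index {j} out of range")
        eta_lin = eta_lin + float(beta) * genotypes[:, j]
    return expit(eta_lin)


def assign_phenotypes(
    dataset: GenotypeDataset, config: SimulationConfig
) -> GenotypeDataset:
    """Draw prospective labels y_i ~ Bernoulli(eta(x_i)).

    The true probability vector is stored on the returned dataset for oracle
    checks; it is not an input to any fitting routine.
    """
    # a distinct stream from the genotype rng, still fully determined by seed
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x9E3779B9)))
    eta = true_probabilities(dataset.genotypes, config)
    y = (rng.random(dataset.n_subjects) < eta).astype(np.int8)
    return GenotypeDataset(
        genotypes=dataset.genotypes,
        snps=dataset.snps,
        phenotype=y,
        subject_ids=dataset.subject_ids,
        design=dataset.design,
        true_prob=eta,
    )


def sample_case_control(
    cohort: GenotypeDataset, n_cases: int, n_controls: int, seed: int
) -> GenotypeDataset:
    """Retrospective sample: simple random draws within each phenotype class.

    The returned dataset records the sampling fractions pi1 = n_cases /
    (cohort cases) and pi0 = n_controls / (cohort controls) needed to map
    fitted probabilities back to the prospective scale.
    """
    if cohort.phenotype is None:
        raise ValueError("cohort has no phenotype; run assign_phenotypes first")
    y = cohort.phenotype
    case_idx = np.flatnonzero(y == 1)
    control_idx = np.flatnonzero(y == 0)
    if n_cases > case_idx.size:
        raise ValueError(
            f"requested {n_cases} cases but cohort has only {case_idx.size}"
        )
    if n_controls > control_idx.size:
        raise ValueError(
            f"requested {n_controls} controls but cohort has only {control_idx.size}"
        )
    rng = np.random.default_rng(seed)
    take = np.concatenate(
        [
            rng.choice(case_idx, size=n_cases, replace=False),
            rng.choice(control_idx, size=n_controls, replace=False),
        ]
    )
    take = rng.permutation(take)
    out = cohort.subset_subjects(take)
    out.design = SamplingDesign(
        pi1=n_cases / case_idx.size,
        pi0=n_controls / control_idx.size,
        n_cases=n_cases,
        n_controls=n_controls,
    )
    return out


def split_train_test(
    dataset: GenotypeDataset,
    train_counts_per_class: tuple[int, int],
    seed: int,
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Stratified split into (train, test); together they partition the input.

    train_counts_per_class is (cases, controls) for the training set; all
    remaining subjects form the test set.
    """
    if dataset.phenotype is None:
        raise ValueError("dataset has no phenotype")
    n_tr_cases, n_tr_controls = train_counts_per_class
    y = dataset.phenotype
    case_idx = np.flatnonzero(y == 1)
    control_idx = np.flatnonzero(y == 0)
    if n_tr_cases > case_idx.size or n_tr_controls > control_idx.size:
        raise ValueError(
            f"requested train counts {train_counts_per_class} exceed available "
            f"({case_idx.size} cases, {control_idx.size} controls)"
        )
    rng = np.random.default_rng(seed)
    case_perm = rng.permutation(case_idx)
    control_perm = rng.permutation(control_idx)
    train_idx = np.sort(
        np.concatenate([case_perm[:n_tr_cases], control_perm[:n_tr_controls]])
    )
    test_idx = np.sort(
        np.concatenate([case_perm[n_tr_cases:], control_perm[n_tr_controls:]])
    )
    return dataset.subset_subjects(train_idx), dataset.subset_subjects(test_idx)
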