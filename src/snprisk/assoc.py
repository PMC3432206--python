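"""Quality control and single-SNP association.

The stage between raw genotypes and rule construction: exclusion of
monomorphic SNPs and SNPs out of Hardy-Weinberg equilibrium in controls,
the Cochran-Armitage trend test per SNP, allelic odds ratios with risk-allele
orientation, the genomic inflation factor lambda, and significance-threshold
SNP selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .datatypes import GenotypeDataset

#: Median of the chi-square distribution with 1 df, fixed at 4 decimals.
CHI2_1_MEDIAN = 0.4549

#: Default HWE exclusion threshold.
HWE_THRESHOLD = 1e-4

#: lambda above this triggers a stratification warning.
LAMBDA_WARN = 1.10


@dataclass
class AssocSummary:
    """Per-SNP association results plus the genomic inflation factor.

    ``results`` has one row per SNP with columns snp_id, maf, hwe_p,
    trend_stat, trend_p, odds_ratio, log_or, risk_is_counted, chrom, position.
    """

    results: pd.DataFrame
    lambda_gc: float
    n_selected: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lambda_gc <= 0:
            raise ValueError("lambda_gc must be positive")


# ----------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ----------------------------------------------------------------------

def hwe_test(counts: Sequence[int]) -> float:
    """Chi-square (1 df) goodness-of-fit p-value against HWE proportions.

    ``counts`` is the (dosage 2, dosage 1, dosage 0) genotype count triple.
    Expected counts come from the observed allele frequency.  Monomorphic
    input returns p = 1 by convention.
    """
    n2, n1, n0 = (int(c) for c in counts)
    if min(n2, n1, n0) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n2 + n1 + n0
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n2 + n1) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n2, n1, n0], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return float(chi2.sf(stat, df=1))


def _hwe_p_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Vectorized HWE p-values, one per SNP column."""
    n2 = (genotypes == 2).sum(axis=0).astype(float)
    n1 = (genotypes == 1).sum(axis=0).astype(float)
    n0 = (genotypes == 0).sum(axis=0).astype(float)
    n = n2 + n1 + n0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n2 + n1) / (2 * n)
        q = 1.0 - p
        e2, e1, e0 = n * p * p, 2 * n * p * q, n * q * q
        stat = (n2 - e2) ** 2 / e2 + (n1 - e1) ** 2 / e1 + (n0 - e0) ** 2 / e0
    pvals = chi2.sf(stat, df=1)
    pvals = np.where((p <= 0.0) | (p >= 1.0), 1.0, pvals)
    return np.asarray(pvals, dtype=float)


# ----------------------------------------------------------------------
# Filtering
# ----------------------------------------------------------------------

def filter_snps(
    dataset: GenotypeDataset,
    hwe_threshold: float = HWE_THRESHOLD,
    hwe_in_controls: bool = True,
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Remove monomorphic SNPs and SNPs violating HWE at ``hwe_threshold``.

    HWE is tested in controls only by default (standard GWAS practice).
    Returns the filtered dataset and a removal log with one row per removed
    SNP (columns snp_id, reason, hwe_p).
    """
    g = dataset.genotypes
    monomorphic = np.array([np.unique(g[:, j]).size <= 1 for j in range(g.shape[1])])
    if hwe_in_controls and dataset.phenotype is not None:
        g_hwe = g[dataset.phenotype == 0]
    else:
        g_hwe = g
    hwe_p = _hwe_p_matrix(g_hwe) if g_hwe.shape[0] else np.ones(g.shape[1])
    hwe_fail = (hwe_p < hwe_threshold) & ~monomorphic
    drop = monomorphic | hwe_fail
    log = pd.DataFrame(
        {
            "snp_id": dataset.snp_ids[drop],
            "reason": np.where(monomorphic[drop], "monomorphic", "hwe"),
            "hwe_p": hwe_p[drop],
        }
    )
    keep_ids = dataset.snp_ids[~drop]
    if keep_ids.size == 0:
        warnings.warn("all SNPs removed by QC filters")
    return dataset.subset_snps(keep_ids), log


# ----------------------------------------------------------------------
# Cochran-Armitage trend test
# ----------------------------------------------------------------------

def _trend_from_counts(
    n_k: np.ndarray, r_k: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """CA trend statistic from per-dosage totals n_k and case counts r_k.

    Scores x = (0, 1, 2); statistic T^2 / Var with
    T = N * sum x r  -  R * sum x n  and
    Var = (R S / N) * (sum x^2 n - (sum x n)^2 / N)   (unconditional form).
    """
    x = np.array([0.0, 1.0, 2.0])
    n = n_k.sum(axis=-1)
    r = r_k.sum(axis=-1)
    s = n - r
    sxn = n_k @ x
    sx2n = n_k @ (x**2)
    sxr = r_k @ x
    t = n * sxr - r * sxn
    var = (r * s) * (sx2n - sxn**2 / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(var > 0, t**2 / var, 0.0)
    pval = np.where(var > 0, chi2.sf(stat, df=1), 1.0)
    return stat, pval


def trend_test(g: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Cochran-Armitage trend test of a dosage vector against binary labels.

    Scores (0, 1, 2), unconditional variance; returns (chi-square statistic
    with 1 df, p-value).
    """
    g = np.asarray(g)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both phenotype classes must be present")
    n_k = np.array([(g == k).sum() for k in (0, 1, 2)], dtype=float)
    r_k = np.array([((g == k) & (y == 1)).sum() for k in (0, 1, 2)], dtype=float)
    stat, pval = _trend_from_counts(n_k, r_k)
    return float(stat), float(pval)


def trend_test_matrix(
    genotypes: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized trend test over all SNP columns of a dosage matrix."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("both phenotype classes must be present")
    cases = genotypes[y == 1]
    n_k = np.stack(
        [(genotypes == k).sum(axis=0) for k in (0, 1, 2)], axis=1
    ).astype(float)
    r_k = np.stack([(cases == k).sum(axis=0) for k in (0, 1, 2)], axis=1).astype(
        float
    )
    return _trend_from_counts(n_k, r_k)


# ----------------------------------------------------------------------
# Allelic odds ratio
# ----------------------------------------------------------------------

def estimate_or(
    g: np.ndarray, y: np.ndarray, method: str = "allelic"
) -> tuple[float, float, bool]:
    """Single-SNP odds ratio, risk-oriented.

    ``method="allelic"`` (default) uses the 2x2 allele-count table (each
    subject contributes two alleles) with a Haldane-Anscombe +0.5 added to
    every cell when any cell is zero.  ``method="logistic"`` instead fits a
    univariate additive-dosage logistic model and exponentiates its slope.
    Either way the OR is reported for the risk allele (the orientation with
    OR >= 1), so log_or >= 0 always.  Returns (odds_ratio, log_or,
    risk_is_counted): whether the risk allele is the counted allele.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("both phenotype classes must be present")
    if method == "logistic":
        import statsmodels.api as sm

        X = sm.add_constant(g[:, None], has_constant="add")
        beta = float(sm.Logit(y.astype(float), X).fit(disp=False).params[1])
        risk_is_counted = beta >= 0
        log_or = abs(beta)
        return float(np.exp(log_or)), log_or, bool(risk_is_counted)
    if method != "allelic":
        raise ValueError(f"unknown OR method: {method}")
    n_cases = int((y == 1).sum())
    n_controls = int((y == 0).sum())
    a = float(g[y == 1].sum())            # counted allele in cases
    b = 2.0 * n_cases - a                 # other allele in cases
    c = float(g[y == 0].sum())            # counted allele in controls
    d = 2.0 * n_controls - c
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    risk_is_counted = odds_ratio >= 1.0
    if not risk_is_counted:
        odds_ratio = 1.0 / odds_ratio
    return float(odds_ratio), float(np.log(odds_ratio)), bool(risk_is_counted)


def estimate_or_matrix(
    genotypes: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized risk-oriented allelic OR for every SNP column."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("both phenotype classes must be present")
    n_cases = int((y == 1).sum())
    n_controls = int((y == 0).sum())
    a = genotypes[y == 1].sum(axis=0).astype(float)
    c = genotypes[y == 0].sum(axis=0).astype(float)
    b = 2.0 * n_cases - a
    d = 2.0 * n_controls - c
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a, b, c, d = (np.where(zero, v + 0.5, v) for v in (a, b, c, d))
    odds_ratio = (a * d) / (b * c)
    risk_is_counted = odds_ratio >= 1.0
    odds_ratio = np.where(risk_is_counted, odds_ratio, 1.0 / odds_ratio)
    return odds_ratio, np.log(odds_ratio), risk_is_counted


# ----------------------------------------------------------------------
# Inflation factor, selection, full summary
# ----------------------------------------------------------------------

def inflation_factor(trend_stats: Sequence[float]) -> float:
    """Genomic inflation lambda = median(chi-square stats) / 0.4549."""
    stats = np.asarray(trend_stats, dtype=float)
    if stats.size == 0:
        raise ValueError("need at least one statistic")
    return float(np.median(stats) / CHI2_1_MEDIAN)


def associate(
    dataset: GenotypeDataset,
    lambda_warn: float = LAMBDA_WARN,
) -> AssocSummary:
    """Single-SNP association over the whole dataset.

    Computes per-SNP MAF, control-HWE p, trend test, risk-oriented allelic
    OR, and the genomic inflation factor from the trend statistics.
    """
    if dataset.phenotype is None:
        raise ValueError("dataset has no phenotype")
    g = dataset.genotypes
    y = dataset.phenotype
    stat, pval = trend_test_matrix(g, y)
    odds_ratio, log_or, risk_is_counted = estimate_or_matrix(g, y)
    controls = g[y == 0]
    hwe_p = _hwe_p_matrix(controls) if controls.shape[0] else np.ones(g.shape[1])
    freq = g.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    lam = inflation_factor(stat)
    if lam > lambda_warn:
        warnings.warn(
            f"genomic inflation lambda = {lam:.3f} exceeds {lambda_warn:.2f}; "
            "possible confounding/stratification"
        )
    results = pd.DataFrame(
        {
            "snp_id": dataset.snp_ids,
            "chrom": dataset.snps["chrom"].to_numpy(),
            "position": dataset.snps["position"].to_numpy(),
            "maf": maf,
            "hwe_p": hwe_p,
            "trend_stat": stat,
            "trend_p": pval,
            "odds_ratio": odds_ratio,
            "log_or": log_or,
            "risk_is_counted": risk_is_counted,
        }
    )
    return AssocSummary(results=results, lambda_gc=lam)


def select_snps(summary: AssocSummary, threshold: float) -> list[str]:
    """SNPs with trend p below ``threshold``, ordered by ascending p.

    Ties are broken by genomic position, then snp_id.  Sets
    ``summary.n_selected`` as a side record.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    res = summary.results
    hits = res[res["trend_p"] < threshold]
    hits = hits.sort_values(["trend_p", "position", "snp_id"], kind="mergesort")
    summary.n_selected = len(hits)
    return hits["snp_id"].tolist()
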