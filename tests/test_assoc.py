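"""QC and single-SNP association: HWE test, filtering, Cochran-Armitage
trend test, allelic odds ratios and the genomic inflation factor."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

import snprisk
from snprisk import (
    GenotypeDataset,
    estimate_or,
    filter_snps,
    hwe_test,
    inflation_factor,
    select_snps,
    trend_test,
)
from snprisk.assoc import AssocSummary, trend_test_matrix
from snprisk.datatypes import SNP_COLUMNS
from conftest import make_case_control


def _dataset(genotypes, phenotype=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    p = genotypes.shape[1]
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(p)],
            "chrom": 1,
            "position": np.arange(p),
            "allele_a": "A",
            "allele_b": "C",
            "counted_allele": "C",
        }
    )[SNP_COLUMNS]
    return GenotypeDataset(genotypes=genotypes, snps=snps, phenotype=phenotype)


# ----------------------------------------------------------------- HWE

def test_hwe_exact_proportions_give_p_one():
    assert hwe_test((25, 50, 25)) == pytest.approx(1.0)


def test_hwe_monomorphic_convention():
    assert hwe_test((100, 0, 0)) == 1.0
    assert hwe_test((0, 0, 77)) == 1.0


def test_hwe_matches_direct_formula():
    """(10, 10, 10): expected counts from allele frequency 0.5 are
    (7.5, 15, 7.5); chi-square computed by hand."""
    expected = np.array([7.5, 15.0, 7.5])
    observed = np.array([10.0, 10.0, 10.0])
    stat = ((observed - expected) ** 2 / expected).sum()
    assert hwe_test((10, 10, 10)) == pytest.approx(float(chi2.sf(stat, 1)))


def test_hwe_rejects_bad_input():
    with pytest.raises(ValueError):
        hwe_test((0, 0, 0))
    with pytest.raises(ValueError):
        hwe_test((-1, 2, 3))


# ------------------------------------------------------------- filtering

def test_filter_removes_constant_column():
    rng = np.random.default_rng(0)
    g = rng.binomial(2, 0.4, size=(200, 5))  # HWE by construction
    g[:, 2] = 1
    ds = _dataset(g)
    out, log = filter_snps(ds, hwe_in_controls=False)
    assert out.n_snps == 4
    assert log.iloc[0]["snp_id"] == "s2"
    assert log.iloc[0]["reason"] == "monomorphic"


def test_filter_keeps_perfect_hwe():
    block = np.repeat([2, 1, 0], [25, 50, 25])
    g = np.tile(block[:, None], (1, 4))
    out, log = filter_snps(_dataset(g), hwe_in_controls=False)
    assert out.n_snps == 4 and log.empty


def test_filter_removes_planted_hwe_violation():
    """200 subjects all heterozygous: hwe_test p is far below 1e-4."""
    rng = np.random.default_rng(1)
    g = rng.binomial(2, 0.4, size=(200, 3))
    g[:, 1] = 1  # all heterozygotes would be monomorphic; perturb two
    g[0, 1] = 0
    g[1, 1] = 2
    assert hwe_test(((g[:, 1] == 2).sum(), (g[:, 1] == 1).sum(), (g[:, 1] == 0).sum())) < 1e-10
    out, log = filter_snps(_dataset(g), hwe_in_controls=False)
    assert "s1" in set(log["snp_id"])
    assert set(log.loc[log.snp_id == "s1", "reason"]) == {"hwe"}


def test_filter_uses_controls_only():
    """A SNP violating HWE in cases only survives control-based filtering."""
    y = np.repeat([1, 0], 200)
    rng = np.random.default_rng(3)
    g = rng.binomial(2, 0.4, size=(400, 2))
    g[:200, 0] = 1  # cases all heterozygous
    ds = _dataset(g, phenotype=y)
    out, log = filter_snps(ds, hwe_in_controls=True)
    assert "s0" not in set(log["snp_id"])


# ------------------------------------------------------------ trend test

def test_trend_zero_when_distributions_identical():
    g = np.repeat([0, 1, 2, 0, 1, 2], [3, 4, 3, 3, 4, 3])
    y = np.repeat([1, 0], 10)
    stat, p = trend_test(g, y)
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_trend_label_swap_symmetry(signal_sample):
    _, _, sample = signal_sample
    g = sample.genotypes[:, 5]
    y = sample.phenotype
    s1, _ = trend_test(g, y)
    s2, _ = trend_test(g, 1 - y)
    assert s1 == pytest.approx(s2)


def test_trend_matches_published_formula():
    """Cases (1,2,7) vs controls (7,2,1) against a brute-force evaluation of
    the Cochran-Armitage statistic, and the N r^2 identity."""
    g = np.repeat([0, 1, 2, 0, 1, 2], [1, 2, 7, 7, 2, 1])
    y = np.repeat([1, 0], 10)
    stat, p = trend_test(g, y)
    # direct formula with scores x = (0, 1, 2)
    r_k = np.array([1.0, 2.0, 7.0])
    s_k = np.array([7.0, 2.0, 1.0])
    n_k = r_k + s_k
    x = np.array([0.0, 1.0, 2.0])
    N, R, S = n_k.sum(), r_k.sum(), s_k.sum()
    t = (x * (S * r_k - R * s_k)).sum()
    var = (R * S / N) * ((x**2 * n_k).sum() - (x * n_k).sum() ** 2 / N)
    assert stat == pytest.approx(t**2 / (N * var))
    r = np.corrcoef(g, y)[0, 1]
    assert stat == pytest.approx(len(g) * r**2)


def test_trend_requires_both_classes():
    with pytest.raises(ValueError):
        trend_test(np.array([0, 1, 2]), np.array([1, 1, 1]))


def test_trend_reduces_to_proportion_test_with_two_dosages():
    """With only dosages 0 and 2 present, the trend statistic equals the
    squared two-sample score test for proportions."""
    rng = np.random.default_rng(5)
    g = 2 * rng.binomial(1, 0.4, size=300)
    y = rng.binomial(1, 0.5, size=300)
    stat, _ = trend_test(g, y)
    x = (g / 2).astype(float)
    p1, p0 = x[y == 1].mean(), x[y == 0].mean()
    n1, n0 = (y == 1).sum(), (y == 0).sum()
    pbar = x.mean()
    z = (p1 - p0) / np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n0))
    assert stat == pytest.approx(z**2)


def test_trend_matrix_agrees_with_scalar(signal_sample):
    _, _, sample = signal_sample
    stats, ps = trend_test_matrix(sample.genotypes, sample.phenotype)
    for j in [0, 5, 35]:
        s, p = trend_test(sample.genotypes[:, j], sample.phenotype)
        assert stats[j] == pytest.approx(s)
        assert ps[j] == pytest.approx(p)


# ----------------------------------------------------------- odds ratio

def _geno_from_allele_counts(a, b, c, d):
    """Subjects carrying 1 copy each: a/b counted/other alleles in cases,
    c/d in controls (2 alleles per subject -> dosage patterns)."""
    # construct cases with given counted-allele count a out of 2*(a+b)/2 ... use
    # one-allele-at-a-time subjects is not possible; use dosage 2/0 subjects.
    g_cases = np.array([2] * (a // 2) + [1] * (a % 2) + [0] * (b // 2))
    g_controls = np.array([2] * (c // 2) + [1] * (c % 2) + [0] * (d // 2))
    g = np.concatenate([g_cases, g_controls])
    y = np.concatenate([np.ones_like(g_cases), np.zeros_like(g_controls)])
    return g, y


def test_or_cross_product():
    g, y = _geno_from_allele_counts(30, 10, 10, 30)
    odds_ratio, log_or, risk_is_counted = estimate_or(g, y)
    assert odds_ratio == pytest.approx(9.0)
    assert log_or == pytest.approx(np.log(9.0))
    assert risk_is_counted


def test_or_equal_frequencies():
    g, y = _geno_from_allele_counts(20, 20, 20, 20)
    odds_ratio, log_or, _ = estimate_or(g, y)
    assert odds_ratio == pytest.approx(1.0)
    assert log_or == pytest.approx(0.0)


def test_or_haldane_correction():
    """Allele table (10,0;5,5) -> (10.5 * 5.5)/(0.5 * 5.5) = 21."""
    g, y = _geno_from_allele_counts(10, 0, 5, 5)
    odds_ratio, _, _ = estimate_or(g, y)
    assert odds_ratio == pytest.approx(21.0)


def test_or_orientation_invariance(signal_sample):
    """log_or >= 0 always; relabelling alleles (dosage g -> 2 - g) gives the
    identical oriented OR."""
    _, _, sample = signal_sample
    y = sample.phenotype
    for j in range(0, 60, 7):
        g = sample.genotypes[:, j]
        or1, lo1, risk1 = estimate_or(g, y)
        or2, lo2, risk2 = estimate_or(2 - g, y)
        assert lo1 >= 0
        assert or1 == pytest.approx(or2)
        assert risk1 == (not risk2)


# ------------------------------------------------- inflation + selection

def test_inflation_reference_median():
    assert inflation_factor([0.4549] * 11) == pytest.approx(1.0)


def test_inflation_scale_equivariance():
    rng = np.random.default_rng(0)
    stats = rng.chisquare(1, size=501)
    assert inflation_factor(2 * stats) == pytest.approx(2 * inflation_factor(stats))


def test_inflation_simulation_oracle():
    rng = np.random.default_rng(42)
    stats = rng.chisquare(1, size=100_000)
    assert inflation_factor(stats) == pytest.approx(1.0, abs=0.02)


def test_inflation_empty_errors():
    with pytest.raises(ValueError):
        inflation_factor([])


def _summary(trend_p, positions=None):
    n = len(trend_p)
    res = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(n)],
            "chrom": 1,
            "position": positions if positions is not None else np.arange(n),
            "trend_p": trend_p,
        }
    )
    return AssocSummary(results=res, lambda_gc=1.0)


def test_select_threshold_one_returns_all():
    summ = _summary([0.5, 0.01, 0.2])
    assert set(select_snps(summ, 0.999999)) == {"s0", "s1", "s2"}
    assert summ.n_selected == 3


def test_select_below_minimum_empty():
    summ = _summary([0.5, 0.01, 0.2])
    assert select_snps(summ, 1e-6) == []


def test_select_order_and_ties():
    summ = _summary([0.01, 0.01, 0.001], positions=[20, 10, 5])
    assert select_snps(summ, 0.05) == ["s2", "s1", "s0"]


def test_select_null_type_one_error():
    """Null simulation: the fraction selected at threshold 0.05 is ~0.05."""
    cfg = snprisk.SimulationConfig(n_snps=10_000, cohort_size=400, seed=77)
    ds = snprisk.assign_phenotypes(snprisk.simulate_genotypes(cfg), cfg)
    summ = snprisk.associate(ds)
    selected = select_snps(summ, 0.05)
    frac = len(selected) / cfg.n_snps
    half = 2.576 * np.sqrt(0.05 * 0.95 / cfg.n_snps)
    assert abs(frac - 0.05) < half


def test_associate_lambda_near_one_under_null(null_sample):
    _, _, sample = null_sample
    summ = snprisk.associate(sample)
    assert 0.7 < summ.lambda_gc < 1.4


def test_logistic_or_flag_agrees_with_allelic(signal_sample):
    """The per-allele logistic OR tracks the allelic OR in sign and size."""
    _, _, sample = signal_sample
    y = sample.phenotype
    g = sample.genotypes[:, 50]  # planted strong SNP
    or_a, lo_a, risk_a = estimate_or(g, y)
    or_l, lo_l, risk_l = estimate_or(g, y, method="logistic")
    assert risk_a == risk_l
    assert lo_l == pytest.approx(lo_a, abs=0.15)
    with pytest.raises(ValueError):
        estimate_or(g, y, method="nope")
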