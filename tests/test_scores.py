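"""Risk-score construction: counting scores, logistic and lasso fits,
Youden thresholding, and the retrospective-to-prospective correction."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import snprisk
from snprisk import (
    SamplingDesign,
    SeparationError,
    allele_count_score,
    fit_lasso,
    fit_logreg,
    logor_score,
    prospective_intercept,
    to_prospective_probability,
    youden_threshold,
)
from snprisk.metrics import roc_auc
from snprisk.scores import _l1_path, _standardize, lasso_penalty_grid
from conftest import make_case_control
from test_assoc import _dataset


# ------------------------------------------------------ counting scores

def test_allele_count_oriented_dosages():
    ds = _dataset([[0, 1, 2]])
    assert allele_count_score(ds, ["s0", "s1", "s2"], [True, True, True])[0] == 3


def test_allele_count_flips_protective_allele():
    """A SNP whose counted allele has OR < 1 contributes 2 - g."""
    ds = _dataset([[0]])
    assert allele_count_score(ds, ["s0"], [False])[0] == 2


def test_counting_scores_match_enumeration():
    rng = np.random.default_rng(4)
    g = rng.integers(0, 3, size=(4, 5))
    ds = _dataset(g)
    risk = np.array([True, False, True, False, True])
    w = rng.uniform(0.1, 1.0, size=5)
    expected_count = np.zeros(4)
    expected_logor = np.zeros(4)
    for i in range(4):
        for j in range(5):
            r = g[i, j] if risk[j] else 2 - g[i, j]
            expected_count[i] += r
            expected_logor[i] += w[j] * r
    ids = [f"s{j}" for j in range(5)]
    assert allele_count_score(ds, ids, risk) == pytest.approx(expected_count)
    assert logor_score(ds, ids, w, risk) == pytest.approx(expected_logor)


def test_logor_single_snp():
    ds = _dataset([[2]])
    assert logor_score(ds, ["s0"], [np.log(2)], [True])[0] == pytest.approx(2 * np.log(2))


def test_logor_proportional_to_count_with_equal_weights():
    rng = np.random.default_rng(7)
    ds = _dataset(rng.integers(0, 3, size=(20, 6)))
    ids = [f"s{j}" for j in range(6)]
    risk = [True, False] * 3
    count = allele_count_score(ds, ids, risk)
    weighted = logor_score(ds, ids, [0.7] * 6, risk)
    assert weighted == pytest.approx(0.7 * count)


def test_logor_misaligned_lengths_error():
    ds = _dataset([[0, 1]])
    with pytest.raises(ValueError):
        logor_score(ds, ["s0", "s1"], [0.5], [True, True])


def test_unknown_snp_id_errors():
    ds = _dataset([[0, 1]])
    with pytest.raises(KeyError):
        allele_count_score(ds, ["nope"], [True])


# ------------------------------------------------------------- logistic

def test_logreg_null_coefficients_near_zero(null_sample):
    _, _, sample = null_sample
    ids = list(sample.snp_ids[:6])
    model = fit_logreg(sample, ids)
    se = model.extra["bse"][1:]
    assert np.all(np.abs(model.weights) < 3 * se)
    train_scores = model.score(sample)
    _, auc, _ = roc_auc(train_scores, sample.phenotype)
    assert 0.4 < auc < 0.6


def test_logreg_score_equation(signal_sample):
    """Fitted probabilities average to the observed case fraction."""
    _, _, sample = signal_sample
    model = fit_logreg(sample, list(sample.snp_ids[:8]))
    assert model.score(sample).mean() == pytest.approx(sample.phenotype.mean(), abs=1e-6)


def test_logreg_recovers_three_snp_model():
    """Coefficients of the generating 3-SNP logistic model are recovered
    within 3 standard errors at n = 5,000 (prospective fit)."""
    causal = {1: 0.5, 3: -0.4, 5: 0.6}
    cfg = snprisk.SimulationConfig(
        n_snps=8, cohort_size=5_000, causal_effects=causal,
        baseline_log_odds=-0.8, maf_range=(0.2, 0.4), seed=31,
    )
    cohort = snprisk.assign_phenotypes(snprisk.simulate_genotypes(cfg), cfg)
    ids = [cohort.snp_ids[j] for j in causal]
    model = fit_logreg(cohort, ids)
    betas = np.array(list(causal.values()))
    se = model.extra["bse"][1:]
    assert np.all(np.abs(model.weights - betas) < 3 * se)
    assert abs(model.intercept - cfg.baseline_log_odds) < 3 * model.extra["bse"][0]


def test_logreg_guard_rejects_wide_sets(signal_sample):
    _, _, sample = signal_sample
    wide = list(sample.snp_ids) * 4
    with pytest.raises(ValueError, match="n/5"):
        fit_logreg(sample, list(sample.snp_ids) + [f"x{i}" for i in range(200)])


def test_logreg_separation_raises():
    rng = np.random.default_rng(0)
    g = rng.integers(0, 3, size=(60, 1))
    y = (g[:, 0] > 0).astype(int)  # perfectly separable
    ds = _dataset(g, phenotype=y)
    with pytest.raises(SeparationError, match="lasso"):
        fit_logreg(ds, ["s0"])


# ---------------------------------------------------------------- lasso

def test_lasso_grid_end_is_null_model(null_sample):
    """At the largest penalty every SNP coefficient is 0 and the intercept
    is the log-odds of the case fraction."""
    _, _, sample = null_sample
    X = sample.genotypes[:, :20].astype(float)
    y = np.asarray(sample.phenotype, dtype=int)
    pens = lasso_penalty_grid(X, y)
    Xs, _, _ = _standardize(X)
    coefs, icepts = _l1_path(Xs, y, pens[:1])
    assert np.count_nonzero(coefs[0]) == 0
    assert icepts[0] == pytest.approx(float(logit(y.mean())), abs=0.01)


def test_lasso_support_monotone_in_penalty(signal_sample):
    _, _, sample = signal_sample
    model = fit_lasso(sample, list(sample.snp_ids[:30]), n_folds=5, seed=2)
    X = sample.genotypes[:, :30].astype(float)
    y = np.asarray(sample.phenotype, dtype=int)
    Xs, _, _ = _standardize(X)
    pens = model.extra["penalty_grid"][::10]
    coefs, _ = _l1_path(Xs, y, pens)
    support = (coefs != 0).sum(axis=1)
    # descending penalties -> support sizes non-decreasing
    assert np.all(np.diff(support) >= 0)


def test_lasso_deterministic_given_seed(signal_sample):
    _, _, sample = signal_sample
    ids = list(sample.snp_ids[:25])
    a = fit_lasso(sample, ids, n_folds=5, seed=9)
    b = fit_lasso(sample, ids, n_folds=5, seed=9)
    assert a.extra["penalty"] == b.extra["penalty"]
    assert np.array_equal(a.weights, b.weights)
    assert a.intercept == b.intercept


# ---------------------------------------------------------------- Youden

def test_youden_perfect_separation():
    scores = np.array([1, 2, 3, 10, 11, 12], dtype=float)
    labels = np.array([0, 0, 0, 1, 1, 1])
    thr, j = youden_threshold(scores, labels)
    assert j == pytest.approx(1.0)
    assert 3 < thr <= 10


def test_youden_uninformative_scores():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=4000)
    labels = rng.binomial(1, 0.5, size=4000)
    _, j = youden_threshold(scores, labels)
    assert j < 0.08


def test_youden_constant_scores_warns():
    with pytest.warns(UserWarning, match="constant"):
        thr, j = youden_threshold(np.ones(10), np.repeat([0, 1], 5))
    assert j == 0.0


def _brute_force_youden(scores, labels):
    uniq = np.unique(scores)
    cuts = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
    best = (None, -np.inf)
    for t in cuts:
        pred = scores >= t
        sens = pred[labels == 1].mean()
        spec = (~pred[labels == 0]).mean()
        j = sens + spec - 1
        if j > best[1]:
            best = (t, j)
    return best


def test_youden_equals_exhaustive_scan():
    rng = np.random.default_rng(123)
    for _ in range(100):
        n = rng.integers(6, 30)
        scores = rng.integers(0, 6, size=n).astype(float)  # many ties
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if labels.min() == labels.max():
            continue
        thr, j = youden_threshold(scores, labels)
        bf_thr, bf_j = _brute_force_youden(scores, labels)
        assert j == pytest.approx(bf_j)
        assert thr == pytest.approx(bf_thr)


# -------------------------------------------- prospective correction

def test_intercept_unchanged_with_equal_fractions():
    d = SamplingDesign(pi1=0.3, pi0=0.3, n_cases=10, n_controls=10)
    assert prospective_intercept(-1.5, d) == pytest.approx(-1.5)


def test_intercept_shift_magnitude():
    """Oversampling cases by a factor e lowers the corrected intercept by 1."""
    d = SamplingDesign(pi1=float(np.exp(-1)) * np.e, pi0=float(np.exp(-1)), n_cases=10, n_controls=10)
    assert prospective_intercept(0.0, d) == pytest.approx(-1.0)


def test_probability_shift_matches_intercept_shift():
    d = SamplingDesign(pi1=0.5, pi0=0.1, n_cases=10, n_controls=10)
    p = np.array([0.2, 0.5, 0.9])
    out = to_prospective_probability(p, d)
    assert out == pytest.approx(expit(logit(p) + np.log(0.1 / 0.5)))


def test_retrospective_fit_recovers_prospective_intercept():
    """Case-control fit + intercept correction recovers the cohort's alpha
    and the corrected mean probability matches the cohort prevalence."""
    causal = {1: 0.5, 4: -0.4}
    cfg, cohort, sample = make_case_control(
        n_snps=6, cohort=25_000, causal=causal, alpha=-1.6, seed=71,
        n_cases=800, n_controls=800, maf_range=(0.2, 0.4),
    )
    ids = [cohort.snp_ids[j] for j in causal]
    model = fit_logreg(sample, ids)
    alpha_hat = prospective_intercept(model.intercept, sample.design)
    assert abs(alpha_hat - cfg.baseline_log_odds) < 3 * model.extra["bse"][0]
    corrected = to_prospective_probability(model.score(sample), sample.design)
    # corrected mean over the sample reweights imperfectly; compare on cohort
    corrected_cohort = to_prospective_probability(model.score(cohort), sample.design)
    assert corrected_cohort.mean() == pytest.approx(cohort.phenotype.mean(), abs=0.02)


# ------------------------------------------------------------ invariants

def test_auc_invariant_under_weight_scaling(signal_sample):
    _, _, sample = signal_sample
    ids = list(sample.snp_ids[:10])
    risk = [True] * 10
    w = np.arange(1, 11) / 8.0  # dyadic: scaling by 4 is exact
    s1 = logor_score(sample, ids, w, risk)
    s2 = logor_score(sample, ids, 4.0 * w, risk)
    _, a1, _ = roc_auc(s1, sample.phenotype)
    _, a2, _ = roc_auc(s2, sample.phenotype)
    assert a1 == pytest.approx(a2)


def test_allele_count_equals_unit_weight_logor(signal_sample):
    _, _, sample = signal_sample
    ids = list(sample.snp_ids[:12])
    risk = [True, False] * 6
    assert allele_count_score(sample, ids, risk) == pytest.approx(
        logor_score(sample, ids, np.ones(12), risk)
    )
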