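"""Construction of non-forest risk rules.

Four score constructions over a selected SNP set: the unweighted risk-allele
count, the log-odds-ratio-weighted count, the multivariate logistic
regression fit, and the L1-penalized (lasso) logistic fit with its penalty
chosen by cross-validated classification accuracy.  A Youden-index scan
turns any continuous score into a binary classifier, and the retrospective
intercept correction maps case-control probabilities back to the prospective
scale when the sampling fractions are known.

All construction functions accept only the training split; weights,
thresholds and penalties never see test data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .datatypes import GenotypeDataset, SamplingDesign

#: methods whose score is a probability in [0, 1]
PROBABILITY_METHODS = frozenset({"log_reg", "lasso", "rf_reg"})

LASSO_N_PENALTIES = 100
LASSO_DECADES = 4.0  # penalty grid spans lambda_max down 4 decades


class SeparationError(RuntimeError):
    """Perfect separation: the logistic likelihood has no maximum.

    Use the lasso instead; the L1 penalty keeps the optimum finite.
    """


@dataclass
class RiskScoreModel:
    """A fitted risk rule.

    ``weights`` apply to risk-oriented dosages r_j (r = g if the counted
    allele is the risk allele for SNP j, else 2 - g, as given by ``flip``)
    for the counting scores, and to raw dosages for the regression scores
    (``flip`` all False there).  ``threshold`` classifies score >= threshold
    as case once set by the Youden scan.  Forest rules carry the fitted
    forest in ``model`` instead of weights.
    """

    method: str
    snp_ids: list[str]
    weights: Optional[np.ndarray] = None
    flip: Optional[np.ndarray] = None
    intercept: float = 0.0
    threshold: Optional[float] = None
    model: object = None
    extra: dict = field(default_factory=dict)

    @property
    def is_probability(self) -> bool:
        return self.method in PROBABILITY_METHODS

    def __post_init__(self) -> None:
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.snp_ids):
                raise ValueError("weights length must equal snp_ids length")
        if self.flip is None and self.weights is not None:
            self.flip = np.zeros(len(self.snp_ids), dtype=bool)

    def score(self, dataset: GenotypeDataset) -> np.ndarray:
        """Per-subject score on any dataset containing the rule's SNPs."""
        if self.method in {"rf_reg", "rf_class"}:
            from .forest import predict_forest

            return predict_forest(self.model, dataset)
        g = dataset.dosages_for(self.snp_ids).astype(float)
        r = np.where(self.flip, 2.0 - g, g)
        lin = r @ self.weights + self.intercept
        if self.is_probability:
            return expit(lin)
        return lin

    def classify(self, dataset: GenotypeDataset) -> np.ndarray:
        """Binary prediction with the rule score >= threshold => case."""
        if self.method == "rf_class":
            from .forest import predict_forest

            return predict_forest(self.model, dataset).astype(int)
        if self.threshold is None:
            raise ValueError("threshold not set; run youden_threshold first")
        return (self.score(dataset) >= self.threshold).astype(int)


# ----------------------------------------------------------------------
# Counting scores
# ----------------------------------------------------------------------

def _risk_dosages(
    dataset: GenotypeDataset, snp_ids: Sequence[str], risk_is_counted: Sequence[bool]
) -> np.ndarray:
    g = dataset.dosages_for(snp_ids).astype(float)
    flip = ~np.asarray(risk_is_counted, dtype=bool)
    return np.where(flip, 2.0 - g, g)


def allele_count_score(
    dataset: GenotypeDataset,
    snp_ids: Sequence[str],
    risk_is_counted: Sequence[bool],
) -> np.ndarray:
    """Number of risk alleles each subject carries over the included SNPs.

    Integer-valued in [0, 2 * |snps|].
    """
    return _risk_dosages(dataset, snp_ids, risk_is_counted).sum(axis=1)


def logor_score(
    dataset: GenotypeDataset,
    snp_ids: Sequence[str],
    log_ors: Sequence[float],
    risk_is_counted: Sequence[bool],
) -> np.ndarray:
    """Risk-allele count weighted by the per-SNP log odds ratio."""
    log_ors = np.asarray(log_ors, dtype=float)
    if len(log_ors) != len(list(snp_ids)):
        raise ValueError("log_ors must align with snp_ids")
    return _risk_dosages(dataset, snp_ids, risk_is_counted) @ log_ors


def make_count_model(
    method: str,
    snp_ids: Sequence[str],
    risk_is_counted: Sequence[bool],
    log_ors: Optional[Sequence[float]] = None,
) -> RiskScoreModel:
    """Package an allele-count or logOR rule as a RiskScoreModel."""
    snp_ids = list(snp_ids)
    flip = ~np.asarray(risk_is_counted, dtype=bool)
    if method == "allele_count":
        weights = np.ones(len(snp_ids))
    elif method == "log_or":
        weights = np.asarray(log_ors, dtype=float)
    else:
        raise ValueError(f"not a counting method: {method}")
    return RiskScoreModel(method=method, snp_ids=snp_ids, weights=weights, flip=flip)


# ----------------------------------------------------------------------
# Logistic regression
# ----------------------------------------------------------------------

def fit_logreg(train: GenotypeDataset, snp_ids: Sequence[str]) -> RiskScoreModel:
    """Maximum-likelihood additive-dosage logistic model over the SNP set.

    Guarded to small SNP sets (|snps| < n/5): the unpenalized fit is meant
    for the smallest set of the cascade.  Raises SeparationError when the
    likelihood has no maximum.
    """
    snp_ids = list(snp_ids)
    y = train.phenotype
    if y is None or np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    if len(snp_ids) >= train.n_subjects / 5:
        raise ValueError(
            f"{len(snp_ids)} SNPs is too many for an unpenalized logistic fit "
            f"on {train.n_subjects} subjects (guard: |snps| < n/5); use the lasso"
        )
    X = sm.add_constant(train.dosages_for(snp_ids).astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            fit = sm.Logit(np.asarray(y, dtype=float), X).fit(disp=False, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        raise SeparationError(
            "logistic likelihood appears unbounded (separation); use fit_lasso"
        ) from exc
    params = np.asarray(fit.params, dtype=float)
    if not fit.mle_retvals.get("converged", True) or np.abs(params).max() > 1e3:
        raise SeparationError(
            "logistic fit did not converge (likely separation); use fit_lasso"
        )
    model = RiskScoreModel(
        method="log_reg",
        snp_ids=snp_ids,
        weights=params[1:],
        intercept=float(params[0]),
    )
    model.extra["bse"] = np.asarray(fit.bse, dtype=float)
    return model


# ----------------------------------------------------------------------
# Lasso
# ----------------------------------------------------------------------

def lasso_penalty_grid(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Descending log-spaced penalty grid from the smallest lambda that
    zeroes every coefficient (on standardized dosages) down 4 decades."""
    Xs, _, _ = _standardize(X)
    ybar = y.mean()
    lam_max = np.abs(Xs.T @ (y - ybar)).max() / len(y)
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * 10.0**-LASSO_DECADES, LASSO_N_PENALTIES)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def _l1_path(
    Xs: np.ndarray, y: np.ndarray, penalties: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and intercepts along a descending penalty path.

    liblinear coordinate descent; intercept_scaling keeps the intercept
    effectively unpenalized.  Returns (coefs[k, p], intercepts[k]) on the
    standardized scale.
    """
    n = len(y)
    est = LogisticRegression(
        l1_ratio=1.0,
        solver="liblinear",
        intercept_scaling=100.0,
        tol=1e-4,
        C=1.0,
        random_state=0,
    )
    coefs = np.empty((len(penalties), Xs.shape[1]))
    icepts = np.empty(len(penalties))
    for k, lam in enumerate(penalties):
        est.C = 1.0 / (n * lam)
        est.fit(Xs, y)
        coefs[k] = est.coef_[0]
        icepts[k] = est.intercept_[0]
    return coefs, icepts


def fit_lasso(
    train: GenotypeDataset,
    snp_ids: Sequence[str],
    n_folds: int = 10,
    seed: int = 0,
) -> RiskScoreModel:
    """L1-penalized logistic model with CV-chosen shrinkage.

    The penalty grid is log-spaced over 4 decades from the smallest penalty
    zeroing all coefficients.  Tenfold class-stratified cross-validation
    scores each penalty by classification accuracy at the 0.5 probability
    cut-off; ties go to the larger penalty (the sparser model).  The chosen
    penalty is refit on the full training data.
    """
    snp_ids = list(snp_ids)
    y = np.asarray(train.phenotype, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    X = train.dosages_for(snp_ids).astype(float)
    penalties = lasso_penalty_grid(X, y)
    Xs, mu, sd = _standardize(X)

    folds = None
    for attempt in range(3):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        candidate = list(skf.split(Xs, y))
        if all(np.unique(y[tr]).size == 2 for tr, _ in candidate):
            folds = candidate
            break
    if folds is None:
        raise RuntimeError(
            "could not build folds with both classes present after 3 attempts"
        )

    correct = np.zeros(len(penalties))
    for tr, va in folds:
        coefs, icepts = _l1_path(Xs[tr], y[tr], penalties)
        proba = expit(Xs[va] @ coefs.T + icepts)  # (n_va, n_pen)
        pred = (proba >= 0.5).astype(int)
        correct += (pred == y[va][:, None]).sum(axis=0)
    accuracy = correct / len(y)
    best = int(np.argmax(accuracy))  # grid descends from largest penalty:
    # argmax takes the first maximum, i.e. the largest penalty on ties

    coefs, icepts = _l1_path(Xs, y, penalties[: best + 1])
    beta_s = coefs[best]
    b0_s = icepts[best]
    weights = beta_s / sd
    intercept = float(b0_s - (beta_s * mu / sd).sum())
    model = RiskScoreModel(
        method="lasso", snp_ids=snp_ids, weights=weights, intercept=intercept
    )
    model.extra.update(
        penalty=float(penalties[best]),
        penalty_grid=penalties,
        cv_accuracy=accuracy,
    )
    return model


# ----------------------------------------------------------------------
# Youden threshold
# ----------------------------------------------------------------------

def youden_threshold(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidate cuts are the midpoints between adjacent distinct sorted scores
    plus one cut below the minimum and one above the maximum, under the rule
    score >= threshold => case.  Ties on J resolve to the smallest
    threshold.  Constant scores return (threshold above the value, J = 0)
    with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    if uniq.size == 1:
        warnings.warn("constant scores: Youden index is 0")
        return float(uniq[0] + 1.0), 0.0
    # cuts: below min, midpoints, above max
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cuts = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    n_cases = (labels == 1).sum()
    n_controls = (labels == 0).sum()
    # sensitivity at cut t: P(score >= t | case); via sorted cumulative counts
    case_scores = np.sort(scores[labels == 1])
    control_scores = np.sort(scores[labels == 0])
    sens = 1.0 - np.searchsorted(case_scores, cuts, side="left") / n_cases
    spec = np.searchsorted(control_scores, cuts, side="left") / n_controls
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first maximum = smallest threshold
    return float(cuts[best]), float(j[best])


# ----------------------------------------------------------------------
# Retrospective -> prospective correction
# ----------------------------------------------------------------------

def prospective_intercept(alpha_retro: float, design: SamplingDesign) -> float:
    """Prospective intercept from a retrospectively fitted one.

    Case-control sampling with case fraction pi1 and control fraction pi0
    shifts the logistic intercept by ln(pi1/pi0) (slopes are unchanged);
    undoing it gives alpha = alpha* + ln(pi0/pi1).
    """
    if design.pi1 <= 0 or design.pi0 <= 0:
        raise ValueError("sampling fractions must be positive")
    return float(alpha_retro + np.log(design.pi0 / design.pi1))


def to_prospective_probability(
    probs: np.ndarray, design: SamplingDesign
) -> np.ndarray:
    """Rescale retrospective probability estimates to the prospective scale
    by the same logit shift as ``prospective_intercept``."""
    if design.pi1 <= 0 or design.pi0 <= 0:
        raise ValueError("sampling fractions must be positive")
    probs = np.asarray(probs, dtype=float)
    eps = np.finfo(float).tiny
    shifted = logit(np.clip(probs, eps, 1 - 1e-16)) + np.log(design.pi0 / design.pi1)
    return expit(shifted)
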