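"""Orchestration of the full experiment.

simulate -> case-control sample -> stratified split -> QC -> single-SNP
association -> backstep SNP-set cascade -> fit every rule on the training
split -> evaluate on train and held-out test -> tabular reports.

Leakage guards are structural: QC, association, weighting, penalty and
threshold selection, and the importance cascade all consume the training
split only; the test split is touched exclusively by evaluation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import warnings
from dataclasses import dataclass, field
from math import log
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .assoc import AssocSummary, associate, filter_snps, select_snps
from .datagen import (
    assign_phenotypes,
    sample_case_control,
    simulate_genotypes,
    spawn_seeds,
    split_train_test,
)
from .datatypes import GenotypeDataset, SimulationConfig
from .forest import backstep_select, fit_forest, forest_to_json, predict_forest
from .metrics import (
    ComparisonResult,
    EvalReport,
    brier_score,
    compare_correct,
    delong_compare,
    roc_auc,
    sens_spec_wilson,
)
from .scores import RiskScoreModel, fit_lasso, fit_logreg, make_count_model, youden_threshold

ALL_METHODS = ("allele_count", "log_or", "log_reg", "lasso", "rf_reg", "rf_class")
#: methods yielding a continuous (or probability) score, hence an AUC
SCORE_METHODS = ("allele_count", "log_or", "log_reg", "lasso", "rf_reg")
#: methods allowed on the largest cascade set
LARGEST_SET_METHODS = ("log_or", "rf_reg", "rf_class")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one full run."""

    simulation: SimulationConfig
    n_cases: int = 700
    n_controls: int = 750
    train_cases: int = 476
    train_controls: int = 487
    signif_threshold: float = 1e-4
    hwe_threshold: float = 1e-4
    lambda_warn: float = 1.10
    target_set_sizes: tuple = (16, 63, 250, 1000)
    methods: tuple = ALL_METHODS
    n_trees: int = 300
    backstep_n_trees: int = 150
    backstep_mode: str = "classification"
    rf_reg_min_terminal: int = 5
    lasso_folds: int = 10
    master_seed: int = 1

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d["simulation"]["causal_effects"] = {
            str(k): float(v) for k, v in sorted(d["simulation"]["causal_effects"].items())
        }
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_config(master_seed: int = 1) -> ExperimentConfig:
    """Desk-scale defaults: 2,000 SNPs, cohort of 20,000, 10 causal SNPs
    with per-allele |log OR| between ln 1.2 and ln 1.6 and mild local LD,
    sampled down to 700 cases / 750 controls and split 476/487 vs rest."""
    seeds = spawn_seeds(master_seed, 1)
    n_causal = 10
    idx = np.linspace(100, 1900, n_causal).astype(int)
    mag = np.linspace(log(1.2), log(1.6), n_causal)
    sign = np.where(np.arange(n_causal) % 3 == 2, -1.0, 1.0)  # a few protective
    causal = {int(j): float(s * m) for j, m, s in zip(idx, mag, sign)}
    sim = SimulationConfig(
        n_snps=2000,
        cohort_size=20000,
        maf_range=(0.05, 0.5),
        ld_rho=0.15,
        causal_effects=causal,
        baseline_log_odds=-2.2,
        seed=seeds[0],
    )
    return ExperimentConfig(simulation=sim, master_seed=master_seed)


@dataclass
class ResultsBundle:
    """All outputs of one experiment run."""

    metrics: pd.DataFrame
    comparisons: pd.DataFrame
    skips: pd.DataFrame
    removal_log: pd.DataFrame
    assoc: AssocSummary
    snp_sets: dict
    models: dict
    provenance: dict


# ----------------------------------------------------------------------
# Stages
# ----------------------------------------------------------------------

def prepare_data(
    config: ExperimentConfig,
) -> tuple[GenotypeDataset, GenotypeDataset, GenotypeDataset]:
    """Simulate the cohort, draw the case-control sample, split it."""
    seeds = spawn_seeds(config.master_seed, 4)
    cohort = assign_phenotypes(simulate_genotypes(config.simulation), config.simulation)
    sample = sample_case_control(cohort, config.n_cases, config.n_controls, seeds[1])
    train, test = split_train_test(
        sample, (config.train_cases, config.train_controls), seeds[2]
    )
    return cohort, train, test


def construct_rules(
    train: GenotypeDataset, config: ExperimentConfig
) -> tuple[GenotypeDataset, AssocSummary, pd.DataFrame, dict, dict, list[dict]]:
    """QC, association, cascade and model fitting — training data only.

    Returns (qc'd train, association summary, removal log, snp_sets,
    models keyed (method, set_size), skip records).
    """
    seeds = spawn_seeds(config.master_seed ^ 0x5EED, 4)
    train_qc, removal_log = filter_snps(train, config.hwe_threshold)
    assoc = associate(train_qc, lambda_warn=config.lambda_warn)
    select_snps(assoc, config.signif_threshold)  # records n_selected
    trend_p = assoc.results.set_index("snp_id")["trend_p"]

    sets = backstep_select(
        train_qc,
        list(train_qc.snp_ids),
        keep_fraction=0.5,
        target_sizes=config.target_set_sizes,
        trend_p=trend_p,
        n_trees=config.backstep_n_trees,
        mode=config.backstep_mode,
        seed=seeds[0],
    )
    snp_sets = {len(s): s for s in sets}
    sizes = sorted(snp_sets)
    largest = sizes[-1] if len(sizes) > 1 else None
    smallest = sizes[0]

    res = assoc.results.set_index("snp_id")
    models: dict = {}
    skips: list[dict] = []
    for size in sizes:
        ids = snp_sets[size]
        risk = res.loc[ids, "risk_is_counted"].to_numpy()
        log_ors = res.loc[ids, "log_or"].to_numpy()
        for method in config.methods:
            if size == largest and method not in LARGEST_SET_METHODS:
                skips.append(
                    {"method": method, "set_size": size,
                     "reason": "largest set restricted to logOR and forest methods"}
                )
                continue
            if method == "log_reg" and size != smallest:
                skips.append(
                    {"method": method, "set_size": size,
                     "reason": "logistic regression runs on the smallest set only"}
                )
                continue
            if method in {"allele_count", "log_or"}:
                model = make_count_model(method, ids, risk, log_ors)
            elif method == "log_reg":
                model = fit_logreg(train_qc, ids)
            elif method == "lasso":
                model = fit_lasso(
                    train_qc, ids, n_folds=config.lasso_folds, seed=seeds[1]
                )
            elif method == "rf_reg":
                forest = fit_forest(
                    train_qc, ids,
                    n_trees=config.n_trees,
                    mode="regression",
                    min_terminal=config.rf_reg_min_terminal,
                    seed=seeds[2] + size,
                )
                model = RiskScoreModel(method="rf_reg", snp_ids=list(ids), model=forest)
            elif method == "rf_class":
                forest = fit_forest(
                    train_qc, ids,
                    n_trees=config.n_trees,
                    mode="classification",
                    min_terminal=1,
                    seed=seeds[3] + size,
                )
                model = RiskScoreModel(method="rf_class", snp_ids=list(ids), model=forest)
            else:
                raise ValueError(f"unknown method {method}")
            if method in SCORE_METHODS:
                thr, j = youden_threshold(model.score(train_qc), train_qc.phenotype)
                model.threshold = thr
                model.extra["youden_j_train"] = j
            models[(method, size)] = model
    return train_qc, assoc, removal_log, snp_sets, models, skips


def evaluate_rules(
    models: dict, train: GenotypeDataset, test: GenotypeDataset
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-rule evaluation on both splits and pairwise test-set comparisons."""
    rows = []
    test_scores: dict = {}
    test_preds: dict = {}
    for (method, size), model in sorted(models.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        for split_name, ds in (("train", train), ("test", test)):
            y = ds.phenotype
            n_cases = int((y == 1).sum())
            n_controls = int((y == 0).sum())
            if method in SCORE_METHODS:
                scores = model.score(ds)
                _, auc, auc_ci = roc_auc(scores, y)
                rows.append(
                    dict(method=method, set_size=size, split=split_name,
                         metric="auc", estimate=auc,
                         ci_low=auc_ci[0], ci_high=auc_ci[1])
                )
                pred = (scores >= model.threshold).astype(int)
                if model.is_probability:
                    bs, bs_ci = brier_score(scores, y)
                    rows.append(
                        dict(method=method, set_size=size, split=split_name,
                             metric="brier", estimate=bs,
                             ci_low=bs_ci[0], ci_high=bs_ci[1])
                    )
                if split_name == "test":
                    test_scores[(method, size)] = scores
            else:  # rf_class votes directly
                pred = model.classify(ds)
            (sens, sens_ci), (spec, spec_ci) = sens_spec_wilson(pred, y)
            rows.append(
                dict(method=method, set_size=size, split=split_name,
                     metric="sensitivity", estimate=sens,
                     ci_low=sens_ci[0], ci_high=sens_ci[1])
            )
            rows.append(
                dict(method=method, set_size=size, split=split_name,
                     metric="specificity", estimate=spec,
                     ci_low=spec_ci[0], ci_high=spec_ci[1])
            )
            if split_name == "test":
                test_preds[(method, size)] = pred
    metrics = pd.DataFrame(rows)

    y_test = test.phenotype
    comp_rows = []

    def _compare(key_a, key_b, kind):
        rec = dict(
            kind=kind,
            method_a=key_a[0], set_size_a=key_a[1],
            method_b=key_b[0], set_size_b=key_b[1],
        )
        if key_a in test_scores and key_b in test_scores:
            c = delong_compare(test_scores[key_a], test_scores[key_b], y_test)
            rec.update(delta_auc=c.delta_auc, delta_auc_p=c.delta_auc_p)
        else:
            rec.update(delta_auc=np.nan, delta_auc_p=np.nan)
        c = compare_correct(test_preds[key_a], test_preds[key_b], y_test)
        rec.update(
            delta_correct=c.delta_correct,
            delta_correct_ci_low=c.delta_correct_ci[0],
            delta_correct_ci_high=c.delta_correct_ci[1],
        )
        comp_rows.append(rec)

    keys = sorted(test_preds, key=lambda k: (k[1], k[0]))
    sizes = sorted({k[1] for k in keys})
    for size in sizes:  # across methods within one SNP set
        in_set = [k for k in keys if k[1] == size]
        for i in range(len(in_set)):
            for j in range(i + 1, len(in_set)):
                _compare(in_set[i], in_set[j], "within_set")
    methods = sorted({k[0] for k in keys})
    for method in methods:  # across SNP sets within one method
        of_method = [k for k in keys if k[0] == method]
        for i in range(len(of_method)):
            for j in range(i + 1, len(of_method)):
                _compare(of_method[i], of_method[j], "within_method")
    comparisons = pd.DataFrame(comp_rows)
    return metrics, comparisons


def run_experiment(
    config: ExperimentConfig, out_dir: Optional[str] = None
) -> ResultsBundle:
    """Execute all stages in order; deterministic given the master seed."""
    _, train, test = prepare_data(config)
    train_qc, assoc, removal_log, snp_sets, models, skips = construct_rules(
        train, config
    )
    test_qc = test.subset_snps(train_qc.snp_ids)
    metrics, comparisons = evaluate_rules(models, train_qc, test_qc)
    provenance = {
        "config_hash": config.hash(),
        "master_seed": config.master_seed,
        "snprisk_version": __version__,
        "python": platform.python_version(),
        "lambda_gc": assoc.lambda_gc,
        "n_selected": assoc.n_selected,
        "n_snps_after_qc": train_qc.n_snps,
        "set_sizes": sorted(snp_sets),
    }
    metrics.insert(0, "config_hash", config.hash())
    bundle = ResultsBundle(
        metrics=metrics,
        comparisons=comparisons,
        skips=pd.DataFrame(skips, columns=["method", "set_size", "reason"]),
        removal_log=removal_log,
        assoc=assoc,
        snp_sets=snp_sets,
        models=models,
        provenance=provenance,
    )
    if out_dir is not None:
        write_reports(bundle, out_dir)
    return bundle


# ----------------------------------------------------------------------
# Reports
# ----------------------------------------------------------------------

_FLOAT_FMT = "%.6g"


def write_reports(bundle: ResultsBundle, out_dir: str) -> list[str]:
    """Write UTF-8 CSV reports and the provenance record; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        paths.append(str(path))

    _write(bundle.metrics, "metrics.csv")
    _write(bundle.comparisons, "comparisons.csv")
    _write(bundle.skips, "skips.csv")
    _write(bundle.removal_log, "qc_removals.csv")
    rules = pd.DataFrame(
        [
            {
                "method": method,
                "set_size": size,
                "n_snps": len(m.snp_ids),
                "threshold": np.nan if m.threshold is None else m.threshold,
                "n_nonzero_weights": (
                    np.nan if m.weights is None else int(np.count_nonzero(m.weights))
                ),
            }
            for (method, size), m in sorted(bundle.models.items())
        ]
    )
    _write(rules, "rules.csv")
    top = bundle.assoc.results.nsmallest(50, "trend_p")
    _write(top, "assoc_top.csv")
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(bundle.provenance, indent=2, sort_keys=True))
    paths.append(str(prov_path))
    return paths


def model_fingerprint(model: RiskScoreModel) -> str:
    """Stable hash of a fitted rule, for reproducibility/leakage checks."""
    h = hashlib.sha256()
    h.update(model.method.encode())
    h.update(",".join(model.snp_ids).encode())
    if model.weights is not None:
        h.update(np.ascontiguousarray(model.weights, dtype=float).tobytes())
        h.update(np.float64(model.intercept).tobytes())
    if model.threshold is not None:
        h.update(np.float64(model.threshold).tobytes())
    if model.model is not None:
        h.update(forest_to_json(model.model).encode())
    return h.hexdigest()
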