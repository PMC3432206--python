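"""Probability-estimation forests on additive genotype data.

Bagged CART trees over 0/1/2 dosages in two modes:

* classification — trees grown to purity (minimum terminal node size 1,
  no pruning); each tree votes with its leaf majority and the forest takes
  the majority of votes, ties resolving to "case".
* regression/probability — trees stopped at a minimum terminal node size
  (default 5, keeping some impurity in the leaves so that averaged leaf
  relative frequencies behave as probability estimates); the forest output
  is the mean of per-tree leaf case frequencies, a value in [0, 1].

On dosage data the only informative binary splits are the cuts {0.5, 1.5},
which is exactly what a Gini CART splitter produces here.  Each tree is
grown by sklearn's DecisionTreeClassifier on its own bootstrap sample; the
bagging loop, out-of-bag bookkeeping, permutation importance ("Liaw score":
mean decrease in OOB accuracy, or OOB MSE increase in regression mode) and
the 50% backstep elimination cascade live here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import ceil, floor, sqrt
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .datatypes import GenotypeDataset

DEFAULT_N_TREES = 500
REGRESSION_MIN_TERMINAL = 5


def default_mtry(n_features: int, mode: str) -> int:
    """floor(sqrt(p)) for classification, floor(p/3) for regression."""
    if mode == "classification":
        return max(1, floor(sqrt(n_features)))
    return max(1, floor(n_features / 3))


@dataclass
class ProbabilityForest:
    """A fitted bagged-tree ensemble with per-tree bootstrap records."""

    trees: list
    inbag_indices: list
    oob_indices: list
    n_trees: int
    mtry: int
    min_terminal: int
    mode: str
    seed: int
    snp_ids: list[str]
    classes_present: tuple = (0, 1)


def _as_matrix(
    data: Union[GenotypeDataset, np.ndarray], snp_ids: Optional[Sequence[str]]
) -> tuple[np.ndarray, Optional[np.ndarray], list[str]]:
    if isinstance(data, GenotypeDataset):
        ids = list(snp_ids) if snp_ids is not None else list(data.snp_ids)
        X = data.dosages_for(ids)
        y = data.phenotype
        return np.asarray(X), None if y is None else np.asarray(y), ids
    X = np.asarray(data)
    ids = list(snp_ids) if snp_ids is not None else [f"x{j}" for j in range(X.shape[1])]
    return X, None, ids


def _tree_case_prob(est: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
    """Leaf relative case frequency per subject, robust to one-class trees."""
    proba = est.predict_proba(X)
    classes = list(est.classes_)
    if 1 in classes:
        return proba[:, classes.index(1)]
    return np.zeros(X.shape[0])


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    mtry: int,
    min_terminal: int,
    seed: int = 0,
) -> DecisionTreeClassifier:
    """Grow one Gini CART tree on dosage data.

    At each node ``mtry`` SNPs are sampled without replacement and the best
    {<=0, <=1} cut by Gini impurity decrease is taken; growth stops when a
    node is pure, no positive-gain split exists, or a child would fall below
    ``min_terminal`` samples.  Leaves store the relative case frequency.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if X.size == 0 or len(y) == 0:
        raise ValueError("empty training data")
    est = DecisionTreeClassifier(
        criterion="gini",
        max_features=min(mtry, X.shape[1]),
        min_samples_leaf=min_terminal,
        random_state=int(seed),
    )
    est.fit(X, y)
    return est


def fit_forest(
    train: Union[GenotypeDataset, np.ndarray],
    snp_ids: Optional[Sequence[str]] = None,
    n_trees: int = DEFAULT_N_TREES,
    mtry: Optional[int] = None,
    min_terminal: Optional[int] = None,
    mode: str = "regression",
    seed: int = 0,
    y: Optional[np.ndarray] = None,
) -> ProbabilityForest:
    """Fit a bagged ensemble of ``n_trees`` trees, each on its own bootstrap
    sample (n draws with replacement), recording out-of-bag subjects.

    Regression mode defaults to a minimum terminal node size of 5 (some leaf
    impurity is needed for averaged leaf frequencies to estimate
    probabilities); classification mode splits to purity (min_terminal 1).
    """
    if mode not in {"classification", "regression"}:
        raise ValueError(f"unknown mode: {mode}")
    X, y_ds, ids = _as_matrix(train, snp_ids)
    if y is None:
        y = y_ds
    if y is None:
        raise ValueError("no phenotype available")
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    p = X.shape[1]
    if mtry is None:
        mtry = default_mtry(p, mode)
    if mtry > p:
        warnings.warn(f"mtry={mtry} exceeds {p} SNPs; clipped to {p}")
        mtry = p
    if min_terminal is None:
        min_terminal = REGRESSION_MIN_TERMINAL if mode == "regression" else 1
    n = X.shape[0]
    ss = np.random.SeedSequence(seed)
    tree_seeds = ss.generate_state(2 * n_trees, dtype=np.uint64)
    trees, inbag, oob = [], [], []
    for t in range(n_trees):
        rng = np.random.default_rng(int(tree_seeds[2 * t]))
        draw = rng.integers(0, n, size=n)
        oob_t = np.setdiff1d(np.arange(n), draw)
        est = grow_tree(
            X[draw], y[draw], mtry, min_terminal, seed=int(tree_seeds[2 * t + 1] % (2**31))
        )
        trees.append(est)
        inbag.append(draw)
        oob.append(oob_t)
    return ProbabilityForest(
        trees=trees,
        inbag_indices=inbag,
        oob_indices=oob,
        n_trees=n_trees,
        mtry=mtry,
        min_terminal=min_terminal,
        mode=mode,
        seed=seed,
        snp_ids=ids,
    )


def tree_case_probabilities(
    forest: ProbabilityForest, X: np.ndarray
) -> np.ndarray:
    """(n_trees, n_subjects) matrix of per-tree leaf case frequencies."""
    return np.stack([_tree_case_prob(est, X) for est in forest.trees])


def predict_forest(
    forest: ProbabilityForest, data: Union[GenotypeDataset, np.ndarray]
) -> np.ndarray:
    """Forest output per subject.

    Regression mode: arithmetic mean of per-tree leaf case frequencies (a
    probability estimate in [0, 1]).  Classification mode: majority vote of
    per-tree leaf-majority classes; a leaf tie and a vote tie both resolve
    to "case" (deterministic, documented).
    """
    if isinstance(data, GenotypeDataset):
        X = data.dosages_for(forest.snp_ids)
    else:
        X = np.asarray(data)
        if X.shape[1] != len(forest.snp_ids):
            raise KeyError(
                f"expected {len(forest.snp_ids)} SNP columns, got {X.shape[1]}"
            )
    per_tree = tree_case_probabilities(forest, X)
    if forest.mode == "regression":
        return per_tree.mean(axis=0)
    votes = (per_tree >= 0.5).mean(axis=0)  # leaf tie -> case
    return (votes >= 0.5).astype(np.int8)  # vote tie -> case


# ----------------------------------------------------------------------
# Liaw permutation importance
# ----------------------------------------------------------------------

def importance_liaw(
    forest: ProbabilityForest,
    train: Union[GenotypeDataset, np.ndarray],
    y: Optional[np.ndarray] = None,
    seed: int = 0,
    measure: str = "permutation",
) -> pd.DataFrame:
    """Permutation importance from out-of-bag data.

    For every SNP and tree, the SNP's OOB values are permuted and the drop
    in OOB accuracy (classification) or rise in OOB mean squared error
    (regression) is recorded; importance is the mean decrease across trees.
    SNPs a tree never splits on contribute exactly zero for that tree.
    ``measure="gini"`` returns mean Gini impurity-decrease importance
    instead.  Returns a DataFrame (snp_id, importance, rank), rank 1 =
    most important.
    """
    X, y_ds, ids = _as_matrix(train, forest.snp_ids)
    if measure == "gini":
        imp = np.mean([est.feature_importances_ for est in forest.trees], axis=0)
        order = np.lexsort((np.asarray(ids, dtype=object), -imp))
        rank = np.empty(len(ids), dtype=int)
        rank[order] = np.arange(1, len(ids) + 1)
        return pd.DataFrame({"snp_id": ids, "importance": imp, "rank": rank})
    if measure != "permutation":
        raise ValueError(f"unknown importance measure: {measure}")
    if y is None:
        y = y_ds
    if y is None:
        raise ValueError("no phenotype available")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    totals = np.zeros(p)
    used_trees = 0
    for est, oob_t in zip(forest.trees, forest.oob_indices):
        if oob_t.size == 0:
            warnings.warn("tree with no out-of-bag subjects skipped")
            continue
        used_trees += 1
        Xo = X[oob_t]
        yo = y[oob_t]
        prob = _tree_case_prob(est, Xo)
        if forest.mode == "classification":
            base = ((prob >= 0.5).astype(int) == yo).mean()
        else:
            base = ((prob - yo) ** 2).mean()
        used = np.unique(est.tree_.feature[est.tree_.feature >= 0])
        for f in used:
            Xp = Xo.copy()
            Xp[:, f] = Xp[rng.permutation(Xo.shape[0]), f]
            prob_p = _tree_case_prob(est, Xp)
            if forest.mode == "classification":
                perm = ((prob_p >= 0.5).astype(int) == yo).mean()
                totals[f] += base - perm
            else:
                perm = ((prob_p - yo) ** 2).mean()
                totals[f] += perm - base
    if used_trees == 0:
        raise ValueError("no tree had out-of-bag subjects")
    imp = totals / used_trees
    order = np.lexsort((np.asarray(ids, dtype=object), -imp))
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    return pd.DataFrame({"snp_id": ids, "importance": imp, "rank": rank})


# ----------------------------------------------------------------------
# Backstep elimination cascade
# ----------------------------------------------------------------------

def backstep_select(
    train: GenotypeDataset,
    snp_ids: Sequence[str],
    keep_fraction: float = 0.5,
    target_sizes: Optional[Sequence[int]] = None,
    trend_p: Optional[pd.Series] = None,
    n_trees: int = 200,
    mode: str = "classification",
    mtry: Optional[int] = None,
    min_terminal: Optional[int] = None,
    seed: int = 0,
) -> list[list[str]]:
    """Iterative importance-driven elimination producing nested SNP sets.

    Each round fits a forest on the current set, computes the Liaw
    importance, and keeps the ceil(keep_fraction * p) most important SNPs
    (importance ties broken by the better single-SNP trend p, then snp_id).
    Every intermediate set is recorded, starting with the input set;
    iteration stops once fewer than 2 SNPs would remain.  When
    ``target_sizes`` is given, only the recorded sets closest to each target
    are returned (still nested, de-duplicated).
    """
    snp_ids = list(snp_ids)
    if not snp_ids:
        raise ValueError("empty starting SNP set")
    if not (0.0 < keep_fraction < 1.0):
        raise ValueError("keep_fraction must be in (0, 1)")
    if trend_p is not None:
        trend_p = pd.Series(trend_p)
    ss = np.random.SeedSequence(seed)
    sets = [snp_ids]
    current = snp_ids
    round_no = 0
    while len(current) >= 2:
        n_keep = ceil(keep_fraction * len(current))
        if n_keep < 2 or n_keep >= len(current):
            break
        stage_seeds = ss.generate_state(2, dtype=np.uint64)
        ss = np.random.SeedSequence(int(stage_seeds[1]))
        forest = fit_forest(
            train,
            snp_ids=current,
            n_trees=n_trees,
            mtry=mtry,
            min_terminal=min_terminal,
            mode=mode,
            seed=int(stage_seeds[0] % (2**31)),
        )
        imp = importance_liaw(forest, train, seed=int(stage_seeds[0] % (2**31)) + 1)
        if trend_p is not None:
            imp = imp.assign(trend_p=imp["snp_id"].map(trend_p).fillna(1.0))
        else:
            imp = imp.assign(trend_p=1.0)
        imp = imp.sort_values(
            ["importance", "trend_p", "snp_id"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        current = imp["snp_id"].head(n_keep).tolist()
        sets.append(current)
        round_no += 1
    if target_sizes is not None:
        sizes = np.array([len(s) for s in sets])
        chosen: dict[int, list[str]] = {}
        for t in target_sizes:
            k = int(np.argmin(np.abs(sizes - t)))
            chosen[len(sets[k])] = sets[k]
        sets = [chosen[s] for s in sorted(chosen, reverse=True)]
    return sets


# ----------------------------------------------------------------------
# JSON serialization (nested node records)
# ----------------------------------------------------------------------

def _node_record(est: DecisionTreeClassifier, node: int) -> dict:
    t = est.tree_
    counts = t.value[node, 0] * t.weighted_n_node_samples[node]
    classes = list(est.classes_)
    c = {0: 0.0, 1: 0.0}
    for k, cls in enumerate(classes):
        c[int(cls)] = float(counts[k])
    n_samples = int(t.n_node_samples[node])
    rec = {
        "n_samples": n_samples,
        "class_counts": [round(c[0]), round(c[1])],
        "node_value": c[1] / (c[0] + c[1]) if (c[0] + c[1]) > 0 else 0.0,
    }
    if t.children_left[node] == -1:
        rec["split_snp"] = None
        rec["split_point"] = None
        rec["children"] = None
    else:
        rec["split_snp"] = int(t.feature[node])
        # canonical dosage cuts: a threshold in (0,1) is the <=0 cut, in
        # [1,2) the <=1 cut (left child takes dosage <= cut, as sklearn does)
        rec["split_point"] = 0.5 if t.threshold[node] < 1.0 else 1.5
        rec["children"] = [
            _node_record(est, int(t.children_left[node])),
            _node_record(est, int(t.children_right[node])),
        ]
    return rec


def forest_to_json(forest: ProbabilityForest) -> str:
    """Serialize a forest to a JSON document of nested node records.

    Schema: top level holds mode, n_trees, mtry, min_terminal, seed and
    snp_ids; ``trees`` is a list of root node records.  Each node record
    has split_snp (index into snp_ids, null for a leaf), split_point
    (dosage cut; left child takes dosage <= cut), n_samples, class_counts
    [controls, cases], node_value (leaf case relative frequency) and
    children ([left, right] or null).
    """
    doc = {
        "mode": forest.mode,
        "n_trees": forest.n_trees,
        "mtry": forest.mtry,
        "min_terminal": forest.min_terminal,
        "seed": forest.seed,
        "snp_ids": list(forest.snp_ids),
        "trees": [_node_record(est, 0) for est in forest.trees],
    }
    return json.dumps(doc)
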