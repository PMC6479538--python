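"""Adaptive stratified k-fold cross-validation driver.

The fold count adapts to class imbalance: k = 10 when the smaller class
holds more than 10 observations, otherwise k equals the smaller class size
so every fold still contains at least one observation of each class.
Stratification is done per class: shuffle (seeded) and deal round-robin
into the k folds, so each fold's minority count is the floor or ceiling of
its proportional share.

Each fold fits one forest on the other k-1 folds; all ten class-assignment
methods are post-hoc readings of that single trace.  Metrics are reported
per (method, sample, metric) as a mean over folds with the standard error
sd / sqrt(k).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .aggregation import ProbMethod, Scope, derive_tree_cutoffs
from .data import Dataset, as_binary
from .forest import ForestConfig, extract_trace, fit_forest, predict_tree_probs
from .methods import MethodSpec, enumerate_methods, run_method


def choose_k(labels) -> int:
    """Adaptive fold count: 10, or the smaller class size if that is <= 10."""
    y = as_binary(labels)
    smaller = int(min(y.sum(), (~y).sum()))
    if smaller < 2:
        raise ValueError("cannot stratify: a class has fewer than 2 members")
    return 10 if smaller > 10 else smaller


@dataclass
class FoldPlan:
    """Stratified fold assignment (values 0..k-1, one per observation)."""

    k: int
    assignment: np.ndarray
    stratified: bool = True

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train positions, held-out positions) for one fold."""
        held = np.flatnonzero(self.assignment == fold)
        rest = np.flatnonzero(self.assignment != fold)
        return rest, held


def make_folds(labels, k: int, seed: int = 0) -> FoldPlan:
    """Seeded stratified partition: per class, shuffle then deal round-robin."""
    y = as_binary(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if min(y.sum(), (~y).sum()) < k:
        raise ValueError("k exceeds the smaller class size; stratification infeasible")
    rng = np.random.default_rng(seed)
    assignment = np.empty(y.size, dtype=int)
    for cls in (False, True):
        members = np.flatnonzero(y == cls)
        rng.shuffle(members)
        assignment[members] = np.arange(members.size) % k
    return FoldPlan(k=k, assignment=assignment)


@dataclass
class EvaluationTable:
    """Long-format fold-level metrics plus mean +/- SE aggregation."""

    long: pd.DataFrame   # dataset, method, sample, metric, fold, value
    k: int

    def aggregate(self) -> pd.DataFrame:
        grouped = self.long.groupby(["dataset", "method", "sample", "metric"])["value"]
        out = grouped.agg(
            mean="mean",
            se=lambda v: v.std(ddof=1) / np.sqrt(v.notna().sum()) if v.notna().sum() > 1 else np.nan,
            n_folds="count",
        ).reset_index()
        return out

    def to_csv(self, long_path, aggregate_path=None) -> None:
        self.long.to_csv(long_path, index=False)
        if aggregate_path is not None:
            self.aggregate().to_csv(aggregate_path, index=False)


def _fold_rows(dataset_name, fold, spec, metrics) -> list[dict]:
    rows = []
    for sample, quad in metrics.items():
        for metric in ("AUC", "score", "TPR", "TNR"):
            rows.append({
                "dataset": dataset_name,
                "method": spec.name,
                "sample": sample,
                "metric": metric,
                "fold": fold,
                "value": quad[metric],
            })
    return rows


def cross_validate(dataset: Dataset, forest_config: ForestConfig | None = None,
                   methods: list[MethodSpec] | None = None,
                   seed: int = 0) -> EvaluationTable:
    """Run every method through adaptive stratified k-fold CV.

    One forest is fitted per fold (seeded from ``seed``); tree-level Youden
    cutoffs are derived once per fold and shared across the methods that
    need them.  Fold-level failures are recorded as NaN rows rather than
    aborting the run.
    """
    if forest_config is None:
        forest_config = ForestConfig()
    if methods is None:
        methods = enumerate_methods()
    y = dataset.y
    k = choose_k(y)
    ss = np.random.SeedSequence(seed)
    fold_seed, *tree_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(k + 1)]
    plan = make_folds(y, k, seed=fold_seed)

    rows: list[dict] = []
    for fold in range(k):
        train_pos, val_pos = plan.fold_indices(fold)
        train, val = dataset.subset(train_pos), dataset.subset(val_pos)
        forest = fit_forest(train, replace(forest_config, seed=tree_seeds[fold]))
        trace = extract_trace(forest, train)
        val_probs = predict_tree_probs(forest, val)

        needed = {m.prob_method for m in methods}
        cutoff_cache = {}
        if ProbMethod.VOTE_INB in needed:
            cutoff_cache[ProbMethod.VOTE_INB] = derive_tree_cutoffs(trace, train.y, Scope.INB)
        if ProbMethod.VOTE_TRAIN in needed:
            cutoff_cache[ProbMethod.VOTE_TRAIN] = derive_tree_cutoffs(trace, train.y, Scope.TRAIN)

        for spec in methods:
            try:
                result = run_method(
                    trace, train.y, spec,
                    val_tree_probs=val_probs, val_labels=val.y,
                    tree_cutoffs=cutoff_cache.get(spec.prob_method),
                )
                rows.extend(_fold_rows(dataset.name, fold, spec, result.metrics))
            except ValueError:
                for sample in ("train", "INB", "OOB", "validation"):
                    rows.extend(_fold_rows(dataset.name, fold, spec, {
                        sample: dict.fromkeys(("AUC", "score", "TPR", "TNR"), np.nan)}))
    return EvaluationTable(long=pd.DataFrame(rows), k=k)
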