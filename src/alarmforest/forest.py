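"""Bagged-forest backend and per-tree bookkeeping.

Tree induction itself is delegated to scikit-learn's
:class:`~sklearn.ensemble.RandomForestClassifier` under a pinned contract:
fully grown unpruned trees (no depth limit, minimum leaf size 1), bootstrap
samples of size n drawn with replacement, and mtry-feature subsampling at
every split.  What this module adds is the *trace*: for every training
observation and every tree, the tree's estimated probability of a true
alarm and a 0/1 flag recording whether the observation was In-Bag (sampled
at least once into that tree's bootstrap) or Out-of-Bag.  All downstream
probability-aggregation schemes are post-hoc readings of this n x m object.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import _generate_sample_indices

from .data import Dataset, POSITIVE


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyper-parameters.

    n_trees : number of trees m (default 500).
    mtry : features tried per split; None means floor(sqrt(p)), the
        standard classification default.
    seed : reproducibility seed for bootstrap draws and split sampling.

    Bootstrap samples always have size n (the training-set size).
    """

    n_trees: int = 500
    mtry: int | None = None
    seed: int = 0

    def validate(self, p: int) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and not (1 <= self.mtry <= p):
            raise ValueError(f"mtry must be in [1, {p}]")

    def resolve_mtry(self, p: int) -> int:
        if self.mtry is not None:
            return self.mtry
        return max(1, int(np.floor(np.sqrt(p))))


@dataclass
class FittedForest:
    """A fitted scikit-learn forest plus the training schema."""

    model: RandomForestClassifier
    feature_names: tuple
    n_train: int
    config: ForestConfig

    @property
    def n_trees(self) -> int:
        return len(self.model.estimators_)

    @property
    def _positive_column(self) -> int:
        return int(np.flatnonzero(self.model.classes_ == POSITIVE)[0])


@dataclass
class EnsembleTrace:
    """Per-tree probabilities and In-Bag flags for the training sample.

    tree_probs[i, t] is tree t's estimated P(YES) for observation i;
    inbag[i, t] is 1 when observation i entered tree t's bootstrap sample
    at least once (multiplicity is deliberately discarded) and 0 when the
    observation is Out-of-Bag for that tree.
    """

    tree_probs: np.ndarray
    inbag: np.ndarray
    ids: pd.Index | None = None
    config: ForestConfig | None = None

    def __post_init__(self) -> None:
        self.tree_probs = np.asarray(self.tree_probs, dtype=float)
        self.inbag = np.asarray(self.inbag, dtype=np.int8)
        if self.tree_probs.ndim != 2:
            raise ValueError("tree_probs must be a 2-d n x m array")
        if self.tree_probs.shape != self.inbag.shape:
            raise ValueError("tree_probs and inbag shapes differ")
        if ((self.tree_probs < 0) | (self.tree_probs > 1)).any():
            raise ValueError("tree probabilities must lie in [0, 1]")
        if not np.isin(self.inbag, (0, 1)).all():
            raise ValueError("inbag flags must be 0/1")
        if self.ids is None:
            self.ids = pd.RangeIndex(self.tree_probs.shape[0])

    @property
    def n(self) -> int:
        return self.tree_probs.shape[0]

    @property
    def n_trees(self) -> int:
        return self.tree_probs.shape[1]

    def to_csv(self, probs_path, inbag_path) -> None:
        """Audit export: two CSV matrices keyed by observation id / tree."""
        cols = [f"tree{t + 1}" for t in range(self.n_trees)]
        pd.DataFrame(self.tree_probs, index=self.ids, columns=cols).to_csv(
            probs_path, index_label="id")
        pd.DataFrame(self.inbag, index=self.ids, columns=cols).to_csv(
            inbag_path, index_label="id")


def fit_forest(train: Dataset, config: ForestConfig) -> FittedForest:
    """Fit a bagged forest of fully grown trees on ``train``.

    Raises ``ValueError`` on degenerate input (Dataset construction already
    rejects single-class labels) or an invalid configuration.
    """
    config.validate(train.p)
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.resolve_mtry(train.p),
        bootstrap=True,
        max_depth=None,
        min_samples_leaf=1,
        min_samples_split=2,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(train.features.to_numpy(dtype=float), train.labels.to_numpy())
    return FittedForest(
        model=model,
        feature_names=tuple(train.features.columns),
        n_train=train.n,
        config=replace(config, mtry=config.resolve_mtry(train.p)),
    )


def _inbag_matrix(forest: FittedForest) -> np.ndarray:
    """0/1 In-Bag flags, n x m, recovered from each tree's bootstrap seed."""
    n = forest.n_train
    flags = np.zeros((n, forest.n_trees), dtype=np.int8)
    for t, tree in enumerate(forest.model.estimators_):
        idx = _generate_sample_indices(tree.random_state, n, n, None)
        flags[np.unique(idx), t] = 1
    return flags


def _check_schema(forest: FittedForest, data: Dataset) -> None:
    if tuple(data.features.columns) != forest.feature_names:
        raise ValueError(
            "feature schema mismatch: forest was trained on "
            f"{forest.feature_names}, got {tuple(data.features.columns)}"
        )


def extract_trace(forest: FittedForest, train: Dataset) -> EnsembleTrace:
    """Per-tree P(YES) and In-Bag flags for the forest's own training data."""
    _check_schema(forest, train)
    if train.n != forest.n_train:
        raise ValueError(
            f"forest was fitted on {forest.n_train} observations, got {train.n}")
    probs = predict_tree_probs(forest, train)
    return EnsembleTrace(
        tree_probs=probs,
        inbag=_inbag_matrix(forest),
        ids=train.ids,
        config=forest.config,
    )


def predict_tree_probs(forest: FittedForest, data: Dataset | pd.DataFrame) -> np.ndarray:
    """n_new x m matrix of per-tree P(YES) for (possibly unseen) data.

    No In-Bag flags apply: downstream, all trees are used for new
    observations.  An empty table yields an empty (0, m) result.
    """
    if isinstance(data, Dataset):
        _check_schema(forest, data)
        X = data.features.to_numpy(dtype=float)
    else:
        if tuple(data.columns) != forest.feature_names:
            raise ValueError("feature schema mismatch")
        X = np.asarray(data, dtype=float)
    if X.shape[0] == 0:
        return np.empty((0, forest.n_trees))
    col = forest._positive_column
    out = np.empty((X.shape[0], forest.n_trees))
    for t, tree in enumerate(forest.model.estimators_):
        out[:, t] = tree.predict_proba(X)[:, col]
    return out


def bootstrap_unique_fraction(n: int, replicates: int = 20, seed: int = 0) -> float:
    """Monte-Carlo estimate of the distinct fraction in one size-n bootstrap.

    Draws ``replicates`` with-replacement samples of size n from n items and
    returns the mean fraction of distinct indices.  For large n this
    converges to 1 - 1/e ~ 0.632, the classical In-Bag share; the Out-of-Bag
    share is its complement.
    """
    rng = np.random.default_rng(seed)
    fractions = np.empty(replicates)
    for r in range(replicates):
        draw = rng.integers(0, n, size=n)
        fractions[r] = np.unique(draw).size / n
    return float(fractions.mean())
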