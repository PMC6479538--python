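"""First-level probability assignment from an ensemble trace.

Given the n x m per-tree probability matrix and the In-Bag flag matrix, a
training observation's probability of being a true alarm can be assembled
in four ways:

* ``AVG`` — arithmetic mean of the per-tree probabilities, taken directly
  with no inner step;
* ``VOTE_INB`` — each tree first casts a YES/NO vote at its own
  Youden-optimal cutoff derived on its In-Bag observations, then the
  probability is the YES-vote fraction;
* ``VOTE_TRAIN`` — as above but tree cutoffs are derived on the whole
  training sample;
* ``VOTE_05`` — tree votes at the fixed cutoff 0.5, the standard
  majority-voting forest.

Each scheme is evaluated over one of three tree *scopes* per observation:
only the trees that held it In-Bag, only the trees for which it was
Out-of-Bag, or all trees (TRAIN).  For new (validation) observations all
trees are used.  A tree votes YES iff its probability strictly exceeds the
cutoff, so a probability of exactly 0.5 votes NO under ``VOTE_05``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .data import as_binary
from .forest import EnsembleTrace
from .metrics import youden_cutoff

logger = logging.getLogger(__name__)


class Scope(str, Enum):
    """Which trees contribute to a training observation's probability."""

    INB = "INB"
    OOB = "OOB"
    TRAIN = "TRAIN"


class ProbMethod(str, Enum):
    """First-level probability scheme (tree-cutoff source in parentheses)."""

    AVG = "Avg Prob"              # no tree-level cutoff
    VOTE_INB = "Voting Prob INB"  # per-tree Youden cutoff on the In-Bag sample
    VOTE_TRAIN = "Voting Prob Train"  # per-tree Youden cutoff on the training sample
    VOTE_05 = "Voting Prob 0.5"   # fixed tree-level cutoff 0.5


VOTING_METHODS = (ProbMethod.VOTE_INB, ProbMethod.VOTE_TRAIN, ProbMethod.VOTE_05)


@dataclass
class ProbabilityVector:
    """Per-observation P(YES) with provenance and an undefined mask.

    ``values`` holds NaN where the observation's scope contained zero trees
    (e.g. an observation that was never Out-of-Bag); such entries are
    excluded from downstream cutoff derivation and metrics.
    """

    values: np.ndarray
    undefined: np.ndarray
    method: ProbMethod
    scope: Scope | str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.undefined = np.asarray(self.undefined, dtype=bool)
        defined = self.values[~self.undefined]
        if ((defined < 0) | (defined > 1)).any():
            raise ValueError("defined probabilities must lie in [0, 1]")

    @property
    def defined(self) -> np.ndarray:
        return ~self.undefined

    def to_frame(self, ids=None) -> pd.DataFrame:
        """CSV-ready export: id, method, scope, probability, undefined."""
        n = self.values.size
        return pd.DataFrame({
            "id": np.arange(n) if ids is None else np.asarray(ids),
            "method": str(getattr(self.method, "value", self.method)),
            "scope": str(getattr(self.scope, "value", self.scope)),
            "probability": self.values,
            "undefined": self.undefined,
        })


def _tree_mask(inbag: np.ndarray, scope: Scope) -> np.ndarray:
    scope = Scope(scope)
    if scope is Scope.INB:
        return inbag == 1
    if scope is Scope.OOB:
        return inbag == 0
    return np.ones_like(inbag, dtype=bool)


def _masked_mean(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    counts = mask.sum(axis=1)
    undefined = counts == 0
    totals = (values * mask).sum(axis=1)
    out = np.full(values.shape[0], np.nan)
    np.divide(totals, counts, out=out, where=~undefined)
    if undefined.any():
        logger.warning("%d observation(s) have an empty tree scope", int(undefined.sum()))
    return out, undefined


def average_probability(trace: EnsembleTrace, scope: Scope) -> ProbabilityVector:
    """Mean per-tree probability over the scope's trees, per observation."""
    mask = _tree_mask(trace.inbag, scope)
    values, undefined = _masked_mean(trace.tree_probs, mask)
    return ProbabilityVector(values, undefined, ProbMethod.AVG, Scope(scope))


def tree_votes(tree_probs: np.ndarray, tree_cutoffs) -> np.ndarray:
    """Binary vote matrix: vote[i, t] = 1 iff tree_probs[i, t] > cutoff[t]."""
    tree_probs = np.asarray(tree_probs, dtype=float)
    cutoffs = np.asarray(tree_cutoffs, dtype=float)
    if cutoffs.ndim == 0:
        cutoffs = np.full(tree_probs.shape[1], float(cutoffs))
    if cutoffs.shape != (tree_probs.shape[1],):
        raise ValueError(
            f"expected {tree_probs.shape[1]} tree cutoffs, got {cutoffs.shape}")
    return (tree_probs > cutoffs[None, :]).astype(np.int8)


def voting_probability(votes: np.ndarray, inbag: np.ndarray, scope: Scope,
                       method: ProbMethod = ProbMethod.VOTE_05) -> ProbabilityVector:
    """YES-vote fraction among the scope's trees, per observation."""
    votes = np.asarray(votes)
    inbag = np.asarray(inbag)
    if votes.shape != inbag.shape:
        raise ValueError("votes and inbag shapes differ")
    mask = _tree_mask(inbag, scope)
    values, undefined = _masked_mean(votes.astype(float), mask)
    return ProbabilityVector(values, undefined, method, Scope(scope))


def derive_tree_cutoffs(trace: EnsembleTrace, labels, source: Scope) -> np.ndarray:
    """Per-tree Youden-optimal vote cutoffs.

    For each tree, the cutoff maximizes J on that tree's probability column
    restricted to its In-Bag observations (``source=INB``) or over all
    training observations (``source=TRAIN``).  A tree whose derivation
    subsample is single-class falls back to 0.5 with a logged warning.
    """
    source = Scope(source)
    if source is Scope.OOB:
        raise ValueError("tree cutoffs are derived from the INB or TRAIN sample")
    y = as_binary(labels)
    if y.shape[0] != trace.n:
        raise ValueError("labels are not aligned with the trace rows")
    cutoffs = np.full(trace.n_trees, 0.5)
    fallbacks = 0
    for t in range(trace.n_trees):
        sel = trace.inbag[:, t] == 1 if source is Scope.INB else slice(None)
        ys = y[sel]
        if ys.all() or not ys.any():
            fallbacks += 1
            continue
        cutoffs[t] = youden_cutoff(trace.tree_probs[sel, t], ys).threshold
    if fallbacks:
        logger.warning(
            "%d tree(s) had a single-class %s derivation sample; cutoff 0.5 used",
            fallbacks, source.value)
    return cutoffs


def scope_probability(trace: EnsembleTrace, method: ProbMethod, scope: Scope,
                      tree_cutoffs=None) -> ProbabilityVector:
    """Dispatch one (method, scope) probability vector from a trace."""
    method = ProbMethod(method)
    if method is ProbMethod.AVG:
        return average_probability(trace, scope)
    if method is ProbMethod.VOTE_05:
        tree_cutoffs = np.full(trace.n_trees, 0.5)
    elif tree_cutoffs is None:
        raise ValueError(f"{method.value} requires derived tree cutoffs")
    votes = tree_votes(trace.tree_probs, tree_cutoffs)
    return voting_probability(votes, trace.inbag, scope, method)


def validation_probability(val_tree_probs: np.ndarray, method: ProbMethod,
                           tree_cutoffs=None) -> ProbabilityVector:
    """All-trees probability for new observations.

    ``AVG`` averages the per-tree probabilities; the voting schemes count
    YES votes at the tree cutoffs frozen on the training fold.
    """
    method = ProbMethod(method)
    val_tree_probs = np.asarray(val_tree_probs, dtype=float)
    if method is ProbMethod.AVG:
        values = val_tree_probs.mean(axis=1) if val_tree_probs.shape[0] else np.empty(0)
    else:
        if method is ProbMethod.VOTE_05:
            tree_cutoffs = np.full(val_tree_probs.shape[1], 0.5)
        if tree_cutoffs is None:
            raise ValueError(f"{method.value} requires the training fold's tree cutoffs")
        votes = tree_votes(val_tree_probs, tree_cutoffs)
        values = votes.mean(axis=1) if votes.shape[0] else np.empty(0)
    undefined = np.zeros(val_tree_probs.shape[0], dtype=bool)
    return ProbabilityVector(values, undefined, method, "validation")
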