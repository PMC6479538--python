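"""The ten class-assignment methods.

Class labels come from a two-level aggregation: a first-level probability
scheme (one of the four in :mod:`.aggregation`) followed by a second-level
final cutoff that is either fixed at 0.5 or Youden-optimized on the In-Bag
or whole-training probability vector.  The legal combinations give exactly
ten named methods; "Vote 0.5 0.5" is the standard majority-voting random
forest.

The final cutoff is always derived on training data only — validation
labels are never consulted before metric computation.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .aggregation import (ProbMethod, ProbabilityVector, Scope,
                          derive_tree_cutoffs, scope_probability,
                          validation_probability)
from .data import as_binary, as_labels
from .forest import EnsembleTrace
from .metrics import auc, challenge_score, confusion, tpr_tnr, youden_cutoff


class CutoffSource(str, Enum):
    """Where the second-level (final) cutoff comes from."""

    INB = "INB"
    TRAIN = "TRAIN"
    FIXED = "0.5"


@dataclass(frozen=True)
class MethodSpec:
    """One named (probability scheme, final-cutoff source) combination."""

    name: str
    prob_method: ProbMethod
    final_cutoff_source: CutoffSource

    @property
    def is_standard_rf(self) -> bool:
        """True for "Vote 0.5 0.5", the plain majority-voting forest."""
        return (self.prob_method is ProbMethod.VOTE_05
                and self.final_cutoff_source is CutoffSource.FIXED)


_METHOD_TABLE = (
    ("Prob INB", ProbMethod.AVG, CutoffSource.INB),
    ("Prob Train", ProbMethod.AVG, CutoffSource.TRAIN),
    ("Prob 0.5", ProbMethod.AVG, CutoffSource.FIXED),
    ("Vote INB INB", ProbMethod.VOTE_INB, CutoffSource.INB),
    ("Vote INB 0.5", ProbMethod.VOTE_INB, CutoffSource.FIXED),
    ("Vote Train Train", ProbMethod.VOTE_TRAIN, CutoffSource.TRAIN),
    ("Vote Train 0.5", ProbMethod.VOTE_TRAIN, CutoffSource.FIXED),
    ("Vote 0.5 INB", ProbMethod.VOTE_05, CutoffSource.INB),
    ("Vote 0.5 Train", ProbMethod.VOTE_05, CutoffSource.TRAIN),
    ("Vote 0.5 0.5", ProbMethod.VOTE_05, CutoffSource.FIXED),
)

SAMPLES = ("train", "INB", "OOB", "validation")
METRICS = ("AUC", "score", "TPR", "TNR")


def enumerate_methods() -> list[MethodSpec]:
    """All ten methods, in their canonical order."""
    return [MethodSpec(n, pm, cs) for n, pm, cs in _METHOD_TABLE]


def method_by_name(name: str) -> MethodSpec:
    for spec in enumerate_methods():
        if spec.name == name:
            return spec
    raise KeyError(f"unknown method {name!r}")


def derive_final_cutoff(scope_vectors: dict, labels, spec: MethodSpec) -> float:
    """Second-level cutoff for ``spec`` from training-fold probabilities.

    ``scope_vectors`` maps Scope -> ProbabilityVector for the spec's
    probability scheme.  INB and TRAIN sources run a Youden optimization on
    the corresponding vector; the fixed source returns 0.5.
    """
    if spec.final_cutoff_source is CutoffSource.FIXED:
        return 0.5
    scope = Scope.INB if spec.final_cutoff_source is CutoffSource.INB else Scope.TRAIN
    vector = scope_vectors[scope]
    y = as_binary(labels)
    sel = vector.defined
    ys, ps = y[sel], vector.values[sel]
    if ys.all() or not ys.any():
        raise ValueError(
            f"{spec.name}: cutoff derivation sample is single-class")
    return youden_cutoff(ps, ys).threshold


@dataclass
class ClassificationResult:
    """Final labels for one sample under one method."""

    labels: np.ndarray          # YES/NO strings; entries at undefined probs are ""
    probabilities: ProbabilityVector
    cutoff: float
    spec: MethodSpec

    @property
    def defined(self) -> np.ndarray:
        return self.probabilities.defined


def classify(probs: ProbabilityVector, cutoff: float, spec: MethodSpec | None = None,
             tie_break: str = "deterministic",
             rng: np.random.Generator | None = None) -> ClassificationResult:
    """Discretize probabilities at ``cutoff``: YES iff probability > cutoff.

    With ``tie_break="random"`` an observation sitting exactly at the
    cutoff is assigned a class by a fair coin from ``rng`` (the classical
    random tie assignment of majority voting); the default is the
    deterministic NO, chosen for reproducibility.  Undefined probabilities
    yield empty labels and stay out of all metrics.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("final cutoff must lie in [0, 1]")
    flags = probs.values > cutoff
    if tie_break == "random":
        if rng is None:
            raise ValueError("random tie-breaking requires an rng")
        at = probs.values == cutoff
        flags = np.where(at, rng.random(flags.size) < 0.5, flags)
    elif tie_break != "deterministic":
        raise ValueError(f"unknown tie_break {tie_break!r}")
    labels = as_labels(flags).astype(object)
    labels[probs.undefined] = ""
    return ClassificationResult(labels=labels, probabilities=probs,
                                cutoff=cutoff, spec=spec)


def sample_metrics(result: ClassificationResult, labels) -> dict:
    """AUC/score/TPR/TNR of one classified sample, skipping undefined rows."""
    y = as_binary(labels)
    sel = result.defined
    y, yhat = y[sel], as_binary(result.labels[sel])
    scores = result.probabilities.values[sel]
    cc = confusion(y, yhat)
    tpr, tnr = tpr_tnr(cc)
    single_class = y.all() or not y.any()
    return {
        "AUC": np.nan if single_class else auc(scores, y),
        "score": challenge_score(cc),
        "TPR": tpr,
        "TNR": tnr,
        "n_scored": int(sel.sum()),
    }


@dataclass
class MethodResult:
    """Per-sample classifications and metric quadruples for one method."""

    spec: MethodSpec
    final_cutoff: float
    results: dict        # sample name -> ClassificationResult
    metrics: dict        # sample name -> {AUC, score, TPR, TNR}


def run_method(trace: EnsembleTrace, labels, spec: MethodSpec,
               val_tree_probs=None, val_labels=None,
               tree_cutoffs=None, tie_break: str = "deterministic",
               rng: np.random.Generator | None = None) -> MethodResult:
    """Execute one method end to end on a fitted fold.

    Training-side samples (train / INB / OOB) are scored from the trace's
    scope probabilities; the validation sample, when given, uses all trees
    with cutoffs frozen on the training fold.
    """
    spec_pm = spec.prob_method
    if tree_cutoffs is None and spec_pm in (ProbMethod.VOTE_INB, ProbMethod.VOTE_TRAIN):
        source = Scope.INB if spec_pm is ProbMethod.VOTE_INB else Scope.TRAIN
        tree_cutoffs = derive_tree_cutoffs(trace, labels, source)

    scope_vectors = {s: scope_probability(trace, spec_pm, s, tree_cutoffs)
                     for s in (Scope.INB, Scope.OOB, Scope.TRAIN)}
    cutoff = derive_final_cutoff(scope_vectors, labels, spec)

    samples = {
        "train": (scope_vectors[Scope.TRAIN], labels),
        "INB": (scope_vectors[Scope.INB], labels),
        "OOB": (scope_vectors[Scope.OOB], labels),
    }
    if val_tree_probs is not None:
        val_vec = validation_probability(val_tree_probs, spec_pm, tree_cutoffs)
        samples["validation"] = (val_vec, val_labels)

    results, metrics = {}, {}
    for sample, (vector, truth) in samples.items():
        res = classify(vector, cutoff, spec, tie_break=tie_break, rng=rng)
        results[sample] = res
        metrics[sample] = sample_metrics(res, truth)
    return MethodResult(spec=spec, final_cutoff=cutoff,
                        results=results, metrics=metrics)
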