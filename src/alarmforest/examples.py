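"""The illustrative 3-observation, 4-tree trace.

A hand-sized ensemble trace used throughout the docs and tests: three
training observations, four trees, with per-tree P(YES) and In-Bag flags
small enough to verify every aggregation by hand.  ``reference_*`` return
the correct aggregated probabilities (rounded to two decimals, as they are
usually displayed) so the ``worked-example`` CLI command can audit an
installation end to end.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .aggregation import Scope, average_probability, tree_votes, voting_probability
from .forest import EnsembleTrace

#: Per-tree P(YES); rows = observations, columns = trees.
EXAMPLE_TREE_PROBS = np.array([
    [0.6, 0.7, 0.8, 0.2],
    [0.5, 0.7, 0.1, 0.1],
    [0.1, 0.9, 0.4, 0.8],
])

#: In-Bag flags (1 = the tree's bootstrap sample contained the observation).
EXAMPLE_INBAG = np.array([
    [1, 0, 1, 0],
    [1, 1, 0, 0],
    [0, 1, 1, 0],
])

#: Per-tree probabilities for one new (validation) observation.
EXAMPLE_VALIDATION_ROW = np.array([0.5, 0.7, 0.1, 0.1])


def example_trace() -> EnsembleTrace:
    return EnsembleTrace(tree_probs=EXAMPLE_TREE_PROBS.copy(),
                         inbag=EXAMPLE_INBAG.copy())


def example_votes() -> np.ndarray:
    """Tree votes of the example at the fixed tree cutoff 0.5.

    Note observation 2 / tree 1 sits exactly at 0.5 and votes NO under the
    strict-> rule.
    """
    return tree_votes(EXAMPLE_TREE_PROBS, 0.5)


def reference_average_table() -> pd.DataFrame:
    """Expected INB/OOB/TRAIN averaged probabilities, 2 decimals.

    Every cell is a hand computation from the trace above; e.g. observation
    2's In-Bag trees are trees 1 and 2, so its In-Bag average is
    (0.5 + 0.7) / 2 = 0.60.
    """
    return pd.DataFrame(
        {"Avg Prob INB": [0.70, 0.60, 0.65],
         "Avg Prob OOB": [0.45, 0.10, 0.45],
         "Avg Prob Train": [0.58, 0.35, 0.55]},
        index=pd.Index([1, 2, 3], name="observation"),
    )


def reference_voting_table() -> pd.DataFrame:
    """Expected INB/OOB/TRAIN voting probabilities, 2 decimals."""
    return pd.DataFrame(
        {"Vote Prob INB": [1.00, 0.50, 0.50],
         "Vote Prob OOB": [0.50, 0.00, 0.50],
         "Vote Prob Train": [0.75, 0.25, 0.50]},
        index=pd.Index([1, 2, 3], name="observation"),
    )


_SCOPE_LABEL = {Scope.INB: "INB", Scope.OOB: "OOB", Scope.TRAIN: "Train"}


def matches_reference(computed: pd.DataFrame, reference: pd.DataFrame,
                      decimals: int = 2) -> np.ndarray:
    """Cell-wise agreement with a table printed to ``decimals`` places.

    A printed value represents anything within half a display unit, so the
    check is |computed - printed| <= 0.5 * 10^-decimals (plus float slop);
    e.g. a computed 0.575 matches a printed 0.58.
    """
    tol = 0.5 * 10.0 ** (-decimals) + 1e-9
    return np.abs(computed.to_numpy() - reference.to_numpy()) <= tol


def computed_average_table() -> pd.DataFrame:
    """INB/OOB/TRAIN averaged probabilities computed from the trace."""
    trace = example_trace()
    return pd.DataFrame(
        {f"Avg Prob {label}": average_probability(trace, s).values
         for s, label in _SCOPE_LABEL.items()},
        index=pd.Index([1, 2, 3], name="observation"),
    )


def computed_voting_table() -> pd.DataFrame:
    """INB/OOB/TRAIN voting probabilities computed from the votes."""
    votes = example_votes()
    return pd.DataFrame(
        {f"Vote Prob {label}": voting_probability(votes, EXAMPLE_INBAG, s).values
         for s, label in _SCOPE_LABEL.items()},
        index=pd.Index([1, 2, 3], name="observation"),
    )
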