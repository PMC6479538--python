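"""Synthetic imbalanced alarm datasets with a known Bayes AUC.

Class-conditional Gaussian model: each informative feature is N(0, 1) for
false alarms (NO) and N(delta, 1) for true alarms (YES); remaining
features are pure N(0, 1) noise for both classes.  A single informative
feature therefore has the closed-form best-achievable AUC
Phi(delta / sqrt(2)), which gives every downstream module an exact oracle
to recover.

:func:`generate_challenge_suite` emulates the five ICU arrhythmia alarm
datasets of the 2015 PhysioNet/CinC Challenge training set — same names
and exact NO/YES class counts (750 recordings in total) — with controllable
class separation in place of the real waveform-derived features.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import Dataset, as_labels

#: (NO, YES) alarm counts per arrhythmia type in the challenge training set.
CHALLENGE_COUNTS = {
    "Ventricular Tachycardia": (252, 89),
    "Asystole": (100, 22),
    "Extreme Tachycardia": (9, 131),
    "Ventricular Fibrillation or Flutter": (52, 6),
    "Extreme Bradycardia": (43, 46),
}

#: Default mean shift of informative features; see docs/methods.md.
DEFAULT_DELTA = 1.5


def bayes_auc(delta: float) -> float:
    """Best-achievable AUC of one informative feature: Phi(delta / sqrt(2))."""
    return float(norm.cdf(delta / np.sqrt(2.0)))


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters for one imbalanced binary dataset."""

    n_pos: int
    n_neg: int
    p: int = 10
    n_informative: int = 3
    delta: float = DEFAULT_DELTA
    seed: int = 0
    name: str = "synthetic"

    def validate(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("each class needs at least one observation")
        if not 0 <= self.n_informative <= self.p:
            raise ValueError("n_informative must lie in [0, p]")
        if self.p < 1:
            raise ValueError("need at least one feature")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")


def generate_dataset(spec: SyntheticSpec) -> Dataset:
    """Draw one dataset from the class-conditional Gaussian model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    y = np.zeros(n, dtype=bool)
    y[: spec.n_pos] = True
    X = rng.standard_normal((n, spec.p))
    X[y, : spec.n_informative] += spec.delta
    # shuffle rows so class blocks are not positional
    perm = rng.permutation(n)
    X, y = X[perm], y[perm]
    features = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(spec.p)])
    return Dataset(features=features, labels=pd.Series(as_labels(y)), name=spec.name)


def generate_challenge_suite(seed: int = 0, delta: float = DEFAULT_DELTA,
                             p: int = 10, n_informative: int = 3) -> dict[str, Dataset]:
    """Five named datasets with the challenge's exact class counts."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(CHALLENGE_COUNTS))
    suite = {}
    for child, (name, (n_neg, n_pos)) in zip(children, CHALLENGE_COUNTS.items()):
        spec = SyntheticSpec(
            n_pos=n_pos, n_neg=n_neg, p=p, n_informative=n_informative,
            delta=delta, seed=int(child.generate_state(1)[0] % (2 ** 31)),
            name=name,
        )
        suite[name] = generate_dataset(spec)
    return suite


def write_suite(suite: dict[str, Dataset], out_dir, label_column: str = "alarm") -> dict:
    """Write each dataset as CSV plus a manifest JSON; returns the manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"label_column": label_column, "datasets": []}
    for name, ds in suite.items():
        fname = name.lower().replace(" ", "_") + ".csv"
        ds.to_csv(out / fname, label_column=label_column)
        counts = ds.class_counts()
        manifest["datasets"].append({
            "name": name, "file": fname,
            "n_no": counts["NO"], "n_yes": counts["YES"],
        })
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
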