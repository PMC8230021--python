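"""Evaluation harness: k-fold cross-validation and the radius sweep.

Classifiers plug in behind a minimal fit/predict contract; a native
3-nearest-neighbor voter (Euclidean, majority vote, ties broken by the
single nearest neighbor) ships so evaluation needs no external ML stack.
External learners (e.g. sklearn estimators) satisfy the contract as-is.

The radius sweep reproduces the selection protocol: normalize once, run
the greedy selector at each radius on the full table, then cross-validate
classifiers on the selected subset.  Selecting on the full table before
CV is optimistic relative to nested selection; the harness documents and
reproduces that protocol rather than fixing it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .core import DecisionTable, NeighborhoodDecisionSystem
from .entropy import DEFAULT_CONFIG, EntropyConfig
from .selection import select_features

__all__ = [
    "ClassifierContract",
    "KNNClassifier",
    "cross_validate",
    "SweepRow",
    "SweepResult",
    "radius_sweep",
    "DEFAULT_GRID",
]

# radius grid 0.05..1.0 step 0.05
DEFAULT_GRID = tuple(np.round(np.arange(1, 21) * 0.05, 2).tolist())


@runtime_checkable
class ClassifierContract(Protocol):
    """fit/predict duck type; ``name`` labels sweep-result columns."""

    name: str

    def fit(self, X: np.ndarray, y: Sequence) -> "ClassifierContract": ...

    def predict(self, X: np.ndarray) -> list: ...


class KNNClassifier:
    """k-nearest-neighbor majority vote with nearest-single-neighbor tie-break."""

    def __init__(self, k: int = 3):
        self.k = k
        self.name = f"{k}NN"

    def fit(self, X, y):
        self._X = np.asarray(X, dtype=float)
        self._y = list(y)
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = []
        for row in X:
            d = np.sqrt(((self._X - row) ** 2).sum(axis=1))
            order = np.argsort(d, kind="stable")[: min(self.k, len(d))]
            votes: dict = {}
            for idx in order:
                votes[self._y[idx]] = votes.get(self._y[idx], 0) + 1
            top = max(votes.values())
            winners = {lab for lab, v in votes.items() if v == top}
            if len(winners) == 1:
                out.append(next(iter(winners)))
            else:  # tie: the nearest neighbor among tied labels decides
                out.append(next(self._y[idx] for idx in order if self._y[idx] in winners))
        return out


def _majority_baseline(labels: Sequence) -> float:
    _, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    return float(counts.max() / counts.sum())


def cross_validate(
    table: DecisionTable,
    features: Sequence[int],
    classifier: ClassifierContract,
    k: int = 10,
    seed: int = 0,
) -> float:
    """Mean test accuracy over stratified k folds restricted to ``features``.

    Rows are put in canonical sample_id order before folding, so the fold
    assignment — and hence the score — is invariant to input row order for
    a given seed.  Falls back to plain (unstratified) folds with a warning
    when some class has fewer samples than folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    features = sorted(set(int(f) for f in features))
    if not features:
        raise ValueError("features must be non-empty")
    order = np.argsort(np.array([str(s) for s in table.sample_ids]), kind="stable")
    X = table.values[np.ix_(order, features)]
    y = np.array([table.labels[i] for i in order], dtype=object)

    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(X, y)
    else:
        warnings.warn(
            f"class with {counts.min()} samples < {k} folds; using plain k-fold"
        )
        splitter = KFold(n_splits=min(k, len(y)), shuffle=True, random_state=seed)
        folds = splitter.split(X)

    correct = total = 0
    for train, test in folds:
        clf = classifier.fit(X[train], y[train].tolist())
        pred = clf.predict(X[test])
        correct += sum(p == t for p, t in zip(pred, y[test]))
        total += len(test)
    return correct / total


def loo_accuracy(table: DecisionTable, features: Sequence[int],
                 classifier: ClassifierContract) -> float:
    """Leave-one-out accuracy on ``features`` (deterministic, no seed)."""
    features = sorted(set(int(f) for f in features))
    X = table.values[:, features]
    y = list(table.labels)
    n = table.n_samples
    hits = 0
    for i in range(n):
        mask = np.arange(n) != i
        clf = classifier.fit(X[mask], [y[j] for j in range(n) if j != i])
        hits += clf.predict(X[i:i + 1])[0] == y[i]
    return hits / n


@dataclass(frozen=True)
class SweepRow:
    delta: float
    n_selected: int
    selected: tuple[int, ...]
    per_classifier_accuracy: dict[str, float]

    @property
    def mean_accuracy(self) -> float:
        accs = self.per_classifier_accuracy.values()
        return float(sum(accs) / len(accs))


@dataclass(frozen=True)
class SweepResult:
    rows: tuple[SweepRow, ...]

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "delta": r.delta,
                    "n_selected": r.n_selected,
                    "selected": list(r.selected),
                    "per_classifier_accuracy": r.per_classifier_accuracy,
                    "mean_accuracy": r.mean_accuracy,
                }
                for r in self.rows
            ],
            indent=2,
        )

    def to_tsv(self) -> str:
        names = list(self.rows[0].per_classifier_accuracy) if self.rows else []
        lines = ["\t".join(["delta", "n_selected"] + names + ["mean_accuracy"])]
        for r in self.rows:
            cells = [f"{r.delta:g}", str(r.n_selected)]
            cells += [f"{r.per_classifier_accuracy[n]:.4f}" for n in names]
            cells.append(f"{r.mean_accuracy:.4f}")
            lines.append("\t".join(cells))
        return "\n".join(lines)


def radius_sweep(
    table: DecisionTable,
    grid: Sequence[float] = DEFAULT_GRID,
    classifiers: Sequence[ClassifierContract] = (),
    k: int = 10,
    seed: int = 0,
    p: float = 2.0,
    config: EntropyConfig = DEFAULT_CONFIG,
) -> SweepResult:
    """Select features at each radius in ``grid``, then cross-validate.

    ``table`` must already be normalized into [0,1].  If selection comes
    back empty at some radius, accuracies record the majority-class
    baseline and n_selected = 0 so the row stays well-defined.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if any(d <= 0 for d in grid):
        raise ValueError("all radii must be > 0")
    classifiers = list(classifiers) or [KNNClassifier(3)]
    rows = []
    for delta in sorted(grid):
        nds = NeighborhoodDecisionSystem(table, delta=delta, p=p)
        trace = select_features(nds, config)
        if trace.selected:
            accs = {
                c.name: cross_validate(table, trace.selected, c, k=k, seed=seed)
                for c in classifiers
            }
        else:
            base = _majority_baseline(table.labels)
            accs = {c.name: base for c in classifiers}
        rows.append(SweepRow(float(delta), len(trace.selected), trace.selected, accs))
    return SweepResult(tuple(rows))


def plot_sweep(result: SweepResult, path: str) -> None:
    """Write a two-axis radius-sweep figure (feature count + mean accuracy)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    deltas = [r.delta for r in result.rows]
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(deltas, [r.n_selected for r in result.rows], "o-", color="tab:blue")
    ax1.set_xlabel("neighborhood radius")
    ax1.set_ylabel("selected features", color="tab:blue")
    ax2 = ax1.twinx()
    ax2.plot(deltas, [r.mean_accuracy for r in result.rows], "s--", color="tab:red")
    ax2.set_ylabel("mean accuracy", color="tab:red")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
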