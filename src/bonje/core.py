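"""Neighborhood decision systems and neighborhood rough set primitives.

A *decision table* holds samples described by continuous condition
attributes plus one categorical decision attribute.  A *neighborhood
decision system* (NDS) augments the table with a Minkowski distance of
order ``p`` and a neighborhood radius ``delta``: instead of the equivalence
classes of classical rough sets, each sample ``x_i`` is granulated into the
set of samples within distance ``delta`` of it on a chosen attribute
subset ``B``.  Lower/upper approximations of the decision classes and
their size ratio — the neighborhood approximate precision ``P_B(D)`` —
are the algebraic-view uncertainty measure built on those granules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DecisionTable",
    "NeighborhoodDecisionSystem",
    "normalize_min_max",
    "minkowski_distance",
    "neighborhood_granule",
    "decision_class",
    "lower_upper_approximation",
    "approximate_precision",
]


@dataclass(frozen=True)
class DecisionTable:
    """Samples x continuous condition attributes, plus one decision column.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_features)
        Condition attribute values; must be finite floats.
    labels : sequence
        Decision attribute, one categorical value per sample.
    feature_names : sequence of str, optional
        Unique attribute names; defaults to ``f0..f{m-1}``.
    sample_ids : sequence, optional
        Opaque row identifiers; defaults to ``0..n-1``.
    """

    values: np.ndarray
    labels: tuple
    feature_names: tuple[str, ...] = ()
    sample_ids: tuple = ()
    # label -> class code in first-appearance order
    _codes: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        if values.shape[0] == 0:
            raise ValueError("decision table has no samples")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"missing/non-finite value at row {bad[0]}, column {bad[1]}"
            )
        labels = tuple(self.labels)
        if len(labels) != values.shape[0]:
            raise ValueError("labels length must equal the number of samples")
        names = tuple(self.feature_names) or tuple(
            f"f{j}" for j in range(values.shape[1])
        )
        if len(names) != values.shape[1]:
            raise ValueError("feature_names length must match feature count")
        if len(set(names)) != len(names):
            raise ValueError("feature_names must be unique")
        ids = tuple(self.sample_ids) or tuple(range(values.shape[0]))
        if len(ids) != values.shape[0]:
            raise ValueError("sample_ids length must equal the number of samples")
        # first-appearance order keeps class codes reproducible
        seen: dict = {}
        codes = np.array([seen.setdefault(l, len(seen)) for l in labels])
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "_codes", codes)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def class_codes(self) -> np.ndarray:
        """Integer class per sample, coded in first-appearance order."""
        return self._codes

    @property
    def n_classes(self) -> int:
        return int(self._codes.max()) + 1

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature name: {name!r}") from None


def normalize_min_max(table: DecisionTable) -> DecisionTable:
    """Map every feature column into [0, 1] by (x - min) / (max - min).

    Constant columns map to all zeros so they stay inert rather than
    raising.  Labels, names and ids are preserved.
    """
    vals = table.values
    lo = vals.min(axis=0)
    span = vals.max(axis=0) - lo
    out = np.zeros_like(vals)
    nz = span > 0
    out[:, nz] = (vals[:, nz] - lo[nz]) / span[nz]
    return DecisionTable(out, table.labels, table.feature_names, table.sample_ids)


@dataclass(frozen=True)
class NeighborhoodDecisionSystem:
    """A [0,1]-valued decision table with radius ``delta`` and order ``p``.

    Pairwise per-feature distance powers ``|x_ik - x_jk|**p`` are cached so
    subset distances are sums over the cached stack — the greedy search
    grows ``B`` one attribute at a time and never recomputes a distance.
    """

    table: DecisionTable
    delta: float = 0.3
    p: float = 2.0
    _pow: np.ndarray = field(init=False, repr=False, compare=False)
    _class_eq: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.p < 1:
            raise ValueError("Minkowski order p must be >= 1")
        v = self.table.values
        if v.min() < 0 or v.max() > 1:
            raise ValueError(
                "condition values must lie in [0, 1]; run normalize_min_max first"
            )
        diff = np.abs(v[:, None, :] - v[None, :, :])  # (n, n, m)
        object.__setattr__(self, "_pow", diff**self.p)
        codes = self.table.class_codes
        object.__setattr__(self, "_class_eq", codes[:, None] == codes[None, :])

    @property
    def n(self) -> int:
        return self.table.n_samples

    def _check_B(self, B: Iterable[int]) -> np.ndarray:
        B = np.asarray(sorted(set(int(b) for b in B)), dtype=int)
        if B.size == 0:
            raise ValueError("attribute subset B must be non-empty")
        if B.min() < 0 or B.max() >= self.table.n_features:
            raise IndexError("attribute index out of range")
        return B

    def distance_matrix(self, B: Iterable[int]) -> np.ndarray:
        """All pairwise Minkowski distances restricted to attributes ``B``."""
        B = self._check_B(B)
        return self._pow[:, :, B].sum(axis=2) ** (1.0 / self.p)

    def adjacency(self, B: Iterable[int]) -> np.ndarray:
        """Boolean (n, n) matrix: within-``delta`` on ``B`` (inclusive)."""
        B = self._check_B(B)
        # compare distance powers against delta**p: same order, no root
        return self._pow[:, :, B].sum(axis=2) <= self.delta**self.p

    @property
    def class_matrix(self) -> np.ndarray:
        """Boolean (n, n) matrix of label agreement."""
        return self._class_eq


def minkowski_distance(
    nds: NeighborhoodDecisionSystem, i: int, j: int, B: Iterable[int]
) -> float:
    """Minkowski distance of order ``p`` between samples ``i`` and ``j`` on ``B``."""
    B = nds._check_B(B)
    return float(nds._pow[i, j, B].sum() ** (1.0 / nds.p))


def neighborhood_granule(
    nds: NeighborhoodDecisionSystem, i: int, B: Iterable[int]
) -> frozenset[int]:
    """Samples within ``delta`` of sample ``i`` on attributes ``B`` (inclusive)."""
    return frozenset(np.flatnonzero(nds.adjacency(B)[i]).tolist())


def decision_class(nds: NeighborhoodDecisionSystem, i: int) -> frozenset[int]:
    """Samples sharing sample ``i``'s decision label."""
    return frozenset(np.flatnonzero(nds._class_eq[i]).tolist())


def lower_upper_approximation(
    nds: NeighborhoodDecisionSystem, B: Iterable[int], X: Iterable[int]
) -> tuple[frozenset[int], frozenset[int]]:
    """Neighborhood lower and upper approximations of sample set ``X`` w.r.t. ``B``.

    lower = { i : granule(i, B) ⊆ X },  upper = { i : granule(i, B) ∩ X ≠ ∅ }.
    """
    adj = nds.adjacency(B)
    mask = np.zeros(nds.n, dtype=bool)
    mask[list(X)] = True
    lower = np.flatnonzero((adj & ~mask).sum(axis=1) == 0)
    upper = np.flatnonzero((adj & mask).sum(axis=1) > 0)
    return frozenset(lower.tolist()), frozenset(upper.tolist())


def approximate_precision(nds: NeighborhoodDecisionSystem, B: Iterable[int]) -> float:
    """Neighborhood approximate precision P_B(D) of the decision.

    Ratio of the sizes of the unions, over decision classes, of the lower
    and upper approximations.  Every granule contains its own sample, so
    the upper union is the whole universe and the ratio reduces to the
    fraction of samples whose granule lies inside their own class.
    """
    adj = nds.adjacency(B)
    consistent = (adj & ~nds._class_eq).sum(axis=1) == 0
    return float(consistent.mean())
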