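"""Decision-table I/O, the embedded toy system, and a synthetic generator.

The toy system is the 4-sample, 3-attribute table used throughout the
worked examples.  The synthetic generator emulates the statistical shape
of tumor-microarray benchmarks — a handful of class-informative
dimensions buried in many irrelevant ones — at desk scale, and returns
the ground-truth partition of features so selection quality is testable
without any external download.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import arff as _scipy_arff

from .core import DecisionTable, normalize_min_max

__all__ = [
    "toy_table",
    "SyntheticSpec",
    "generate_table",
    "read_table",
    "write_csv",
]

# 4-sample toy neighborhood decision system (attributes a, b, c; decision d)
_TOY_CSV = """\
a,b,c,d
0.12,0.41,0.61,Y
0.21,0.15,0.14,Y
0.31,0.11,0.26,N
0.61,0.13,0.23,N
"""


def toy_table() -> DecisionTable:
    """The embedded 4-sample toy decision table (values already in [0,1])."""
    table = _read_csv_text(_TOY_CSV, label_column="d", delimiter=",")
    return DecisionTable(
        table.values, table.labels, table.feature_names,
        sample_ids=("x1", "x2", "x3", "x4"),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic decision-table generator.

    ``class_separation`` is the gap between per-class means of relevant
    features in units of the within-class spread ``noise_sd``.  Redundant
    features are affine copies of randomly chosen relevant features plus
    small jitter; noise features are class-independent uniform draws.
    The generator is a pure function of the spec: identical specs yield
    byte-identical tables.
    """

    n_samples: int = 80
    n_classes: int = 2
    n_relevant: int = 2
    n_redundant: int = 0
    n_noise: int = 20
    class_separation: float = 5.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_relevant < 1:
            raise ValueError("need at least one relevant feature")
        if self.n_classes < 1 or self.n_samples < self.n_classes:
            raise ValueError("inconsistent sample/class counts")
        if self.class_separation <= 0 or self.noise_sd < 0:
            raise ValueError("class_separation must be > 0, noise_sd >= 0")


def generate_table(spec: SyntheticSpec) -> tuple[DecisionTable, dict[str, frozenset[int]]]:
    """Generate a table plus the ground-truth feature partition.

    Returns ``(table, truth)`` with ``truth`` mapping ``"relevant"``,
    ``"redundant"`` and ``"noise"`` to feature-index sets.  Columns are
    min–max normalized; labels are balanced across classes up to rounding.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, spec.n_classes
    labels = np.arange(n) % k  # balanced up to rounding
    cols = []
    gap = spec.class_separation * max(spec.noise_sd, 1e-12)
    for _ in range(spec.n_relevant):
        # class means spaced by the separation gap, random class order
        means = rng.permutation(k) * gap
        cols.append(means[labels] + rng.normal(0, spec.noise_sd, n))
    relevant = np.arange(spec.n_relevant)
    for _ in range(spec.n_redundant):
        src = cols[rng.integers(spec.n_relevant)]
        a, b = rng.uniform(0.5, 2.0), rng.uniform(-1, 1)
        cols.append(a * src + b + rng.normal(0, 0.05 * spec.noise_sd, n))
    for _ in range(spec.n_noise):
        cols.append(rng.uniform(0, 1, n))
    values = np.column_stack(cols)
    m = values.shape[1]
    names = (
        [f"rel{j}" for j in range(spec.n_relevant)]
        + [f"red{j}" for j in range(spec.n_redundant)]
        + [f"noise{j}" for j in range(spec.n_noise)]
    )
    table = normalize_min_max(
        DecisionTable(values, tuple(f"c{l}" for l in labels), tuple(names))
    )
    truth = {
        "relevant": frozenset(relevant.tolist()),
        "redundant": frozenset(range(spec.n_relevant, spec.n_relevant + spec.n_redundant)),
        "noise": frozenset(range(m - spec.n_noise, m)),
    }
    return table, truth


def _read_csv_text(text: str, label_column: str | None, delimiter: str) -> DecisionTable:
    reader = csv.reader(_io.StringIO(text), delimiter=delimiter)
    rows = [r for r in reader if r]
    if len(rows) < 2:
        raise ValueError("CSV needs a header row and at least one sample")
    header = [h.strip() for h in rows[0]]
    label_col = len(header) - 1 if label_column is None else header.index(label_column)
    feat_idx = [j for j in range(len(header)) if j != label_col]
    values = np.empty((len(rows) - 1, len(feat_idx)))
    labels = []
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise ValueError(f"row {i + 1}: expected {len(header)} cells, got {len(row)}")
        for jj, j in enumerate(feat_idx):
            cell = row[j].strip()
            if cell == "":
                raise ValueError(f"missing value at row {i + 1}, column {header[j]!r}")
            try:
                values[i, jj] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {cell!r} at row {i + 1}, column {header[j]!r}"
                ) from None
        labels.append(row[label_col].strip())
    return DecisionTable(values, tuple(labels), tuple(header[j] for j in feat_idx))


def read_table(
    path: str | Path,
    format: str | None = None,
    label_column: str | None = None,
    delimiter: str = ",",
) -> DecisionTable:
    """Read a decision table from CSV or ARFF.

    CSV: header of feature names, one designated label column (default:
    the last).  ARFF: numeric attributes become conditions; the nominal
    attribute (default: the last, conventionally ``class``) becomes the
    decision.  Missing or non-numeric condition cells are rejected with
    the offending row/column named.
    """
    path = Path(path)
    fmt = format or ("arff" if path.suffix.lower() == ".arff" else "csv")
    if fmt == "csv":
        return _read_csv_text(path.read_text(), label_column, delimiter)
    if fmt != "arff":
        raise ValueError(f"unknown format {fmt!r} (expected 'csv' or 'arff')")
    data, meta = _scipy_arff.loadarff(str(path))
    label_name = label_column
    if label_name is None:
        nominal = [n for n in meta.names() if meta[n][0] == "nominal"]
        if not nominal:
            raise ValueError("ARFF has no nominal attribute to use as decision")
        label_name = nominal[-1]
    feat_names = [n for n in meta.names() if n != label_name]
    for n in feat_names:
        if meta[n][0] != "numeric":
            raise ValueError(f"condition attribute {n!r} is not numeric")
    values = np.column_stack([np.asarray(data[n], dtype=float) for n in feat_names])
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"missing value at row {i}, column {feat_names[j]!r}")
    labels = tuple(
        v.decode() if isinstance(v, bytes) else str(v) for v in data[label_name]
    )
    return DecisionTable(values, labels, tuple(feat_names))


def write_csv(table: DecisionTable, path: str | Path, label_name: str = "class") -> None:
    """Write a decision table as CSV (conditions first, label last)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(table.feature_names) + [label_name])
        for i in range(table.n_samples):
            w.writerow([repr(float(v)) for v in table.values[i]] + [table.labels[i]])
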