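"""Rank-based multi-algorithm comparison: Friedman, Iman–Davenport, Nemenyi.

Given an algorithms × datasets accuracy matrix, each dataset ranks the
algorithms (rank 1 = highest accuracy, ties share the midrank).  The
Friedman statistic

    χF² = 12N / (M(M+1)) · Σ_i R_i²  −  3N(M+1)

tests whether M algorithms perform alike over N datasets (R_i = average
rank of algorithm i); the Iman–Davenport correction

    F_F = (N−1)·χF² / (N(M−1) − χF²)

is referred to an F distribution with (M−1, (M−1)(N−1)) degrees of
freedom.  When the null is rejected, the Nemenyi post-hoc critical
distance CD = q_α √(M(M+1)/(6N)) separates significantly different
average ranks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "AccuracyMatrix",
    "RankMatrix",
    "FriedmanReport",
    "NemenyiReport",
    "rank_with_ties",
    "friedman_chi2",
    "iman_davenport_ff",
    "nemenyi_cd",
    "compare_algorithms",
    "read_accuracy_matrix",
]

# Two-tailed Nemenyi critical values q_alpha = studentized range(alpha, M, inf)/sqrt(2)
# as tabulated in Demsar (2006), "Statistical comparisons of classifiers over
# multiple data sets", JMLR 7, Table 5(a); M = number of algorithms, 2..20.
_Q_ALPHA = {
    0.05: [1.960, 2.343, 2.569, 2.728, 2.850, 2.949, 3.031, 3.102, 3.164,
           3.219, 3.268, 3.313, 3.354, 3.391, 3.426, 3.458, 3.489, 3.517, 3.544],
    0.10: [1.645, 2.052, 2.291, 2.459, 2.589, 2.693, 2.780, 2.855, 2.920,
           2.978, 3.030, 3.077, 3.120, 3.159, 3.196, 3.230, 3.261, 3.291, 3.319],
}


@dataclass(frozen=True)
class AccuracyMatrix:
    """Algorithms × datasets accuracy table (values in [0, 1])."""

    algorithms: tuple[str, ...]
    datasets: tuple[str, ...]
    values: np.ndarray  # shape (M, N)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.algorithms), len(self.datasets)):
            raise ValueError("values shape must be (n_algorithms, n_datasets)")
        if len(self.algorithms) < 2 or len(self.datasets) < 2:
            raise ValueError("need at least 2 algorithms and 2 datasets")
        if not np.isfinite(v).all():
            raise ValueError("accuracy matrix has missing cells")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class RankMatrix:
    """Per-dataset midranks (M × N) and the average rank per algorithm."""

    ranks: np.ndarray
    algorithms: tuple[str, ...] = ()

    def __post_init__(self):
        r = np.asarray(self.ranks, dtype=float)
        if r.ndim != 2:
            raise ValueError("ranks must be 2-D (algorithms x datasets)")
        object.__setattr__(self, "ranks", r)
        if not self.algorithms:
            object.__setattr__(
                self, "algorithms", tuple(f"alg{i}" for i in range(r.shape[0]))
            )

    @property
    def M(self) -> int:
        return self.ranks.shape[0]

    @property
    def N(self) -> int:
        return self.ranks.shape[1]

    @property
    def avg_rank(self) -> np.ndarray:
        return self.ranks.mean(axis=1)


def rank_with_ties(acc: AccuracyMatrix) -> RankMatrix:
    """Column-wise descending-accuracy midranks (rank 1 = best; ties averaged)."""
    ranks = np.column_stack(
        [_st.rankdata(-acc.values[:, j], method="average")
         for j in range(acc.values.shape[1])]
    )
    return RankMatrix(ranks, acc.algorithms)


def friedman_chi2(ranks: RankMatrix | Sequence[float], N: int | None = None) -> float:
    """Friedman χF² from a rank matrix, or from average ranks plus ``N``.

    The second form lets published average-rank rows (often rounded) be
    fed directly, reproducing printed statistics exactly.
    """
    if isinstance(ranks, RankMatrix):
        R = ranks.avg_rank
        N = ranks.N
    else:
        if N is None:
            raise ValueError("N (number of datasets) required with raw average ranks")
        R = np.asarray(ranks, dtype=float)
    M = len(R)
    return float(12 * N / (M * (M + 1)) * (R**2).sum() - 3 * N * (M + 1))


def iman_davenport_ff(chi2: float, N: int, M: int) -> float:
    """Iman–Davenport F_F = (N−1)χF² / (N(M−1) − χF²)."""
    denom = N * (M - 1) - chi2
    if denom <= 0:
        raise ValueError(
            f"degenerate statistic: N(M-1)={N * (M - 1)} <= chi2={chi2:g} "
            "(rank variance saturated)"
        )
    return float((N - 1) * chi2 / denom)


@dataclass(frozen=True)
class FriedmanReport:
    chi2: float
    ff: float
    df1: int
    df2: int
    f_critical: float
    alpha: float
    reject_null: bool


@dataclass(frozen=True)
class NemenyiReport:
    alpha: float
    q_alpha: float
    cd: float
    similar_pairs: tuple[tuple[str, str], ...]


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper-tail F critical value via the inverse CDF."""
    return float(_st.f.ppf(1 - alpha, df1, df2))


def nemenyi_cd(M: int, N: int, alpha: float = 0.10) -> float:
    """Nemenyi critical distance CD = q_α √(M(M+1)/(6N))."""
    try:
        q = _Q_ALPHA[alpha][M - 2]
    except (KeyError, IndexError):
        raise ValueError(
            f"no critical value for M={M}, alpha={alpha}; "
            "supported M = 2..20, alpha in {0.05, 0.10}"
        ) from None
    return float(q * np.sqrt(M * (M + 1) / (6 * N)))


def compare_algorithms(
    acc: AccuracyMatrix | RankMatrix, alpha: float = 0.10
) -> dict:
    """Full pipeline: midranks → Friedman/Iman–Davenport → Nemenyi.

    Accepts an accuracy matrix (ranked internally) or a ready-made rank
    matrix.  Returns a JSON-serializable report with the rank table, the
    test statistics, the critical distance and critical-difference-diagram
    data (algorithms ordered by average rank, plus pairs whose rank gap is
    within CD — "similar" groups drawn as connector bars).
    """
    rm = rank_with_ties(acc) if isinstance(acc, AccuracyMatrix) else acc
    M, N = rm.M, rm.N
    chi2 = friedman_chi2(rm)
    ff = iman_davenport_ff(chi2, N, M)
    df1, df2 = M - 1, (M - 1) * (N - 1)
    crit = f_critical(alpha, df1, df2)
    friedman = FriedmanReport(chi2, ff, df1, df2, crit, alpha, ff > crit)

    cd = nemenyi_cd(M, N, alpha)
    avg = rm.avg_rank
    order = np.argsort(avg, kind="stable")
    similar = tuple(
        (rm.algorithms[i], rm.algorithms[j])
        for a, i in enumerate(order)
        for j in order[a + 1:]
        if abs(avg[i] - avg[j]) <= cd
    )
    q = _Q_ALPHA[alpha][M - 2]
    nemenyi = NemenyiReport(alpha, q, cd, similar)
    return {
        "ranks": rm.ranks.tolist(),
        "avg_rank": avg.tolist(),
        "algorithms": list(rm.algorithms),
        "friedman": friedman.__dict__,
        "nemenyi": {
            "alpha": alpha,
            "q_alpha": q,
            "cd": cd,
            "similar_pairs": [list(p) for p in similar],
        },
        "cd_diagram": {
            "positions": [
                {"algorithm": rm.algorithms[i], "avg_rank": float(avg[i])}
                for i in order
            ],
            "cd": cd,
        },
    }


def read_accuracy_matrix(path, delimiter: str | None = None) -> AccuracyMatrix:
    """Read an algorithms × datasets accuracy table from TSV/CSV.

    First column = algorithm names, header row = dataset names.
    """
    import pandas as pd

    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return AccuracyMatrix(
        tuple(str(a) for a in df.index),
        tuple(str(d) for d in df.columns),
        df.to_numpy(dtype=float),
    )


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2)
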