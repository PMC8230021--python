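"""Neighborhood entropy measures fusing the algebraic and information views.

For each sample the neighborhood granule ``n_B(x_i)``, the decision class
``[x_i]_D`` and their union — the *joint neighborhood granule* — yield two
per-sample measures:

* credibility  ``nα_i = |n_B(x_i) ∩ [x_i]_D| / |n_B(x_i) ∪ [x_i]_D|``
* coverage     ``nκ_i = |n_B(x_i) ∩ [x_i]_D| / |[x_i]_D|``

The *neighborhood joint entropy*

    Hδ(D,B) = -(P_B(D)/|U|) Σ_i log( nα_i · nκ_i )

weights the averaged log-measures by the approximate precision ``P_B(D)``,
so a subset with an empty combined lower approximation scores exactly 0.
It is the evaluation function the greedy feature selector maximizes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .core import NeighborhoodDecisionSystem

__all__ = [
    "EntropyConfig",
    "PerSampleMeasures",
    "joint_granule",
    "credibility_coverage",
    "classic_neighborhood_entropy",
    "new_average_neighborhood_entropy",
    "neighborhood_conditional_entropy",
    "neighborhood_joint_entropy",
    "significance",
    "per_sample_measures",
    "explain",
]


@dataclass(frozen=True)
class EntropyConfig:
    """Logarithm base used by every entropy measure (default 10)."""

    log_base: float = 10.0

    def __post_init__(self):
        if not self.log_base > 1:
            raise ValueError("log_base must be > 1")

    @property
    def ln_base(self) -> float:
        return math.log(self.log_base)


DEFAULT_CONFIG = EntropyConfig()


@dataclass(frozen=True)
class PerSampleMeasures:
    """Set sizes and credibility/coverage for one sample under subset B."""

    granule_size: int
    class_size: int
    intersection_size: int
    joint_granule_size: int
    credibility: float
    coverage: float


def _sizes(nds: NeighborhoodDecisionSystem, B: Iterable[int]):
    """Vectors of granule / class / intersection / joint-granule sizes."""
    adj = nds.adjacency(B)
    cls = nds.class_matrix
    g = adj.sum(axis=1)
    c = cls.sum(axis=1)
    m = (adj & cls).sum(axis=1)
    return g, c, m, g + c - m


def _precision(nds, adj):
    return float(((adj & ~nds.class_matrix).sum(axis=1) == 0).mean())


def joint_granule(
    nds: NeighborhoodDecisionSystem, i: int, B: Iterable[int]
) -> frozenset[int]:
    """Union of sample ``i``'s neighborhood granule on ``B`` and its class."""
    row = nds.adjacency(B)[i] | nds.class_matrix[i]
    return frozenset(np.flatnonzero(row).tolist())


def credibility_coverage(
    nds: NeighborhoodDecisionSystem, i: int, B: Iterable[int]
) -> tuple[float, float]:
    """Neighborhood credibility and coverage of sample ``i`` under ``B``."""
    g, c, m, j = _sizes(nds, B)
    return float(m[i] / j[i]), float(m[i] / c[i])


def per_sample_measures(
    nds: NeighborhoodDecisionSystem, B: Iterable[int]
) -> list[PerSampleMeasures]:
    g, c, m, j = _sizes(nds, B)
    return [
        PerSampleMeasures(int(g[i]), int(c[i]), int(m[i]), int(j[i]),
                          float(m[i] / j[i]), float(m[i] / c[i]))
        for i in range(nds.n)
    ]


def classic_neighborhood_entropy(
    nds: NeighborhoodDecisionSystem,
    B: Iterable[int],
    config: EntropyConfig = DEFAULT_CONFIG,
) -> float:
    """Average neighborhood entropy -(1/|U|) Σ log(|n_B(x_i)|/|U|)."""
    g = nds.adjacency(B).sum(axis=1)
    return float(-np.log(g / nds.n).sum() / (nds.n * config.ln_base))


def new_average_neighborhood_entropy(
    nds: NeighborhoodDecisionSystem,
    B: Iterable[int],
    config: EntropyConfig = DEFAULT_CONFIG,
) -> float:
    """Precision-weighted entropy Hδ(B) over granule vs joint-granule sizes."""
    adj = nds.adjacency(B)
    P = _precision(nds, adj)
    if P == 0.0:
        return 0.0
    g, c, m, j = _sizes(nds, B)
    return float(-P * np.log(g / j).sum() / (nds.n * config.ln_base))


def neighborhood_conditional_entropy(
    nds: NeighborhoodDecisionSystem,
    B: Iterable[int],
    config: EntropyConfig = DEFAULT_CONFIG,
) -> float:
    """Hδ(D|B) = -(P_B(D)/|U|) Σ log(|n∩[x]|² / (|n|·|[x]|))."""
    adj = nds.adjacency(B)
    P = _precision(nds, adj)
    if P == 0.0:
        return 0.0
    g, c, m, j = _sizes(nds, B)
    return float(-P * np.log(m**2 / (g * c)).sum() / (nds.n * config.ln_base))


def neighborhood_joint_entropy(
    nds: NeighborhoodDecisionSystem,
    B: Iterable[int],
    config: EntropyConfig = DEFAULT_CONFIG,
) -> float:
    """Hδ(D,B) = -(P_B(D)/|U|) Σ log(|n∩[x]|² / (|n∪[x]|·|[x]|)).

    Equals -(P/|U|) Σ log(nα_i · nκ_i); the selection criterion.
    """
    adj = nds.adjacency(B)
    P = _precision(nds, adj)
    if P == 0.0:
        return 0.0
    g, c, m, j = _sizes(nds, B)
    return float(-P * np.log(m**2 / (j * c)).sum() / (nds.n * config.ln_base))


def significance(
    nds: NeighborhoodDecisionSystem,
    b: int,
    B: Iterable[int],
    config: EntropyConfig = DEFAULT_CONFIG,
) -> float:
    """Sig(b, B, D) = Hδ(D, B∪{b}) - Hδ(D, B); Hδ(D,{b}) when B is empty.

    May be negative: the joint entropy is non-monotonic under subset growth.
    """
    B = set(int(x) for x in B)
    if b in B:
        raise ValueError(f"attribute {b} already in B")
    with_b = neighborhood_joint_entropy(nds, B | {b}, config)
    if not B:
        return with_b
    return with_b - neighborhood_joint_entropy(nds, B, config)


def explain(
    nds: NeighborhoodDecisionSystem,
    B: Iterable[int],
    config: EntropyConfig = DEFAULT_CONFIG,
    as_json: bool = False,
) -> str:
    """Per-sample audit of all sets and measures under ``B``.

    Mirrors a hand calculation: granules, joint granules, credibility,
    coverage, approximate precision and each entropy, sample by sample.
    """
    B = sorted(set(int(x) for x in B))
    names = nds.table.feature_names
    ids = nds.table.sample_ids
    meas = per_sample_measures(nds, B)
    adj = nds.adjacency(B)
    cls = nds.class_matrix
    rows = []
    for i in range(nds.n):
        rows.append({
            "sample": str(ids[i]),
            "granule": [str(ids[k]) for k in np.flatnonzero(adj[i])],
            "class": [str(ids[k]) for k in np.flatnonzero(cls[i])],
            "joint_granule": [str(ids[k]) for k in np.flatnonzero(adj[i] | cls[i])],
            "credibility": meas[i].credibility,
            "coverage": meas[i].coverage,
        })
    summary = {
        "B": [names[b] for b in B],
        "delta": nds.delta,
        "p": nds.p,
        "log_base": config.log_base,
        "approximate_precision": _precision(nds, adj),
        "H_neighborhood": classic_neighborhood_entropy(nds, B, config),
        "H_B": new_average_neighborhood_entropy(nds, B, config),
        "H_D_given_B": neighborhood_conditional_entropy(nds, B, config),
        "H_D_B": neighborhood_joint_entropy(nds, B, config),
        "samples": rows,
    }
    if as_json:
        return json.dumps(summary, indent=2)
    lines = [
        f"B = {{{', '.join(summary['B'])}}}  delta={nds.delta}  p={nds.p}"
        f"  log base {config.log_base:g}",
        f"P_B(D) = {summary['approximate_precision']:.6g}",
    ]
    for r in rows:
        lines.append(
            f"  {r['sample']}: n_B = {{{', '.join(r['granule'])}}}"
            f"  n_B,D = {{{', '.join(r['joint_granule'])}}}"
            f"  na = {r['credibility']:.4f}  nk = {r['coverage']:.4f}"
        )
    lines.append(
        f"H(B) = {summary['H_B']:.6f}   H(D|B) = {summary['H_D_given_B']:.6f}"
        f"   H(D,B) = {summary['H_D_B']:.6f}"
    )
    return "\n".join(lines)
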