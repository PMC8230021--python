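"""Greedy forward feature selection maximizing neighborhood joint entropy.

Starting from the empty subset, each step scores every remaining
attribute by Hδ(D, B∪{b}) and accepts the argmax only if it *strictly*
improves the current Hδ(D,B).  The first step with no strict improvement
stops the search — the criterion is non-monotonic, so the stop rule is
"no strict gain", not saturation of the full-set value.  Every step is
recorded in a trace for auditing and replay.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

from .core import NeighborhoodDecisionSystem
from .entropy import DEFAULT_CONFIG, EntropyConfig, neighborhood_joint_entropy

__all__ = ["SelectionStep", "SelectionTrace", "select_features", "verify_feature_subset"]

log = logging.getLogger(__name__)

# two float pipelines can disagree in the last ulp; the stop rule hinges
# on detecting equality of entropies, so compare with a tiny absolute slack
EQUALITY_TOL = 1e-12


@dataclass(frozen=True)
class SelectionStep:
    candidate_scores: dict[int, float]
    chosen: int | None
    H_after: float


@dataclass(frozen=True)
class SelectionTrace:
    """Ordered audit trail of the greedy search."""

    steps: tuple[SelectionStep, ...]
    selected: tuple[int, ...]
    final_H: float
    warning: str | None = None

    def selected_names(self, table) -> list[str]:
        return [table.feature_names[i] for i in self.selected]

    def to_json(self, feature_names=None) -> str:
        def key(b):
            return feature_names[b] if feature_names else str(b)

        return json.dumps(
            {
                "selected": [key(b) for b in self.selected],
                "final_H": self.final_H,
                "warning": self.warning,
                "steps": [
                    {
                        "candidate_scores": {key(b): s for b, s in st.candidate_scores.items()},
                        "chosen": None if st.chosen is None else key(st.chosen),
                        "H_after": st.H_after,
                    }
                    for st in self.steps
                ],
            },
            indent=2,
        )


def select_features(
    nds: NeighborhoodDecisionSystem, config: EntropyConfig = DEFAULT_CONFIG
) -> SelectionTrace:
    """Run the greedy forward search; returns the full trace.

    Ties among equal-best candidates break toward the lowest attribute
    index, making the search deterministic.  A one-class decision is
    degenerate (every entropy is 0): returns an empty selection with a
    warning instead of raising.
    """
    m = nds.table.n_features
    if m == 0:
        raise ValueError("decision table has no condition attributes")
    if nds.table.n_classes < 2:
        msg = "decision has a single class; nothing to discriminate"
        warnings.warn(msg)
        return SelectionTrace(steps=(), selected=(), final_H=0.0, warning=msg)

    B: list[int] = []
    H_cur = 0.0
    steps: list[SelectionStep] = []
    while len(B) < m:
        scores = {
            b: neighborhood_joint_entropy(nds, B + [b], config)
            for b in range(m)
            if b not in B
        }
        best = min(scores, key=lambda b: (-scores[b], b))
        if scores[best] > H_cur + EQUALITY_TOL:
            B.append(best)
            H_cur = scores[best]
            steps.append(SelectionStep(scores, best, H_cur))
            log.info("step %d: add %s, H(D,B)=%.6f", len(steps), best, H_cur)
        else:
            steps.append(SelectionStep(scores, None, H_cur))
            log.info("step %d: best candidate %.6f <= current %.6f, stop",
                     len(steps), scores[best], H_cur)
            break
    return SelectionTrace(steps=tuple(steps), selected=tuple(B), final_H=H_cur)


def verify_feature_subset(
    nds: NeighborhoodDecisionSystem,
    B,
    config: EntropyConfig = DEFAULT_CONFIG,
) -> dict:
    """Check the two reduct conditions for subset ``B``.

    cond1: Hδ(D,B) ≥ Hδ(D,C) — B preserves the full attribute set's
    joint entropy.  cond2: every member is necessary — dropping any
    b ∈ B strictly decreases Hδ(D,B).  ``offending`` lists cond2
    violators.  The greedy search does not enforce cond1 (the criterion
    is non-monotonic); this report makes the check explicit.
    """
    B = sorted(set(int(b) for b in B))
    if not B:
        raise ValueError("B must be non-empty")
    full = list(range(nds.table.n_features))
    H_B = neighborhood_joint_entropy(nds, B, config)
    H_C = neighborhood_joint_entropy(nds, full, config)
    offending = []
    for b in B:
        rest = [x for x in B if x != b]
        H_rest = neighborhood_joint_entropy(nds, rest, config) if rest else 0.0
        if not H_B > H_rest + EQUALITY_TOL:
            offending.append(b)
    return {
        "cond1": H_B >= H_C - EQUALITY_TOL,
        "cond2": not offending,
        "offending": offending,
        "H_B": H_B,
        "H_C": H_C,
    }
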