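"""Neighborhood rough set primitives: examples, invariants, brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bonje import (
    DecisionTable,
    NeighborhoodDecisionSystem,
    approximate_precision,
    decision_class,
    lower_upper_approximation,
    minkowski_distance,
    neighborhood_granule,
    normalize_min_max,
)
from conftest import random_system


# ---------------------------------------------------------------- ingestion

def test_table_rejects_bad_input():
    with pytest.raises(ValueError, match="no samples"):
        DecisionTable(np.empty((0, 2)), ())
    with pytest.raises(ValueError, match="missing"):
        DecisionTable(np.array([[1.0, np.nan]]), ("a",))
    with pytest.raises(ValueError, match="unique"):
        DecisionTable(np.ones((1, 2)), ("a",), ("x", "x"))
    with pytest.raises(ValueError, match="labels length"):
        DecisionTable(np.ones((2, 2)), ("a",))


def test_class_codes_first_appearance_order():
    t = DecisionTable(np.zeros((4, 1)), ("N", "Y", "N", "Z"))
    assert t.class_codes.tolist() == [0, 1, 0, 2]
    assert t.n_classes == 3


# ------------------------------------------------------------ normalization

def test_normalize_min_max_column_arithmetic():
    col = np.array([[0.12], [0.21], [0.31], [0.61]])
    out = normalize_min_max(DecisionTable(col, ("a",) * 4)).values[:, 0]
    np.testing.assert_allclose(out, (col[:, 0] - 0.12) / 0.49)
    assert out[0] == 0.0 and out[-1] == 1.0


def test_normalize_identity_and_constant_column():
    vals = np.array([[0.0, 5.0], [0.5, 5.0], [1.0, 5.0]])
    out = normalize_min_max(DecisionTable(vals, ("a",) * 3)).values
    np.testing.assert_array_equal(out[:, 0], vals[:, 0])  # already [0,1]
    np.testing.assert_array_equal(out[:, 1], 0.0)  # constant -> zeros


def test_normalize_is_idempotent():
    rng = np.random.default_rng(7)
    t = DecisionTable(rng.uniform(-3, 9, (10, 3)), ("a",) * 10)
    once = normalize_min_max(t)
    twice = normalize_min_max(once)
    np.testing.assert_array_equal(once.values, twice.values)


# ----------------------------------------------------------------- distance

def test_minkowski_examples_from_toy_table(toy_nds):
    assert minkowski_distance(toy_nds, 0, 1, [0]) == pytest.approx(0.09)
    assert minkowski_distance(toy_nds, 0, 0, [0, 1, 2]) == 0.0
    assert minkowski_distance(toy_nds, 0, 1, [0, 2]) == pytest.approx(
        np.hypot(0.09, 0.47)
    )


def test_empty_attribute_set_rejected(toy_nds):
    with pytest.raises(ValueError, match="non-empty"):
        minkowski_distance(toy_nds, 0, 1, [])
    with pytest.raises(ValueError, match="non-empty"):
        neighborhood_granule(toy_nds, 0, [])


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=60, deadline=None)
def test_distance_symmetry_and_triangle(seed):
    rng = np.random.default_rng(seed)
    nds = random_system(rng)
    n, m = nds.n, nds.table.n_features
    B = list(rng.choice(m, size=int(rng.integers(1, m + 1)), replace=False))
    i, j, k = rng.integers(0, n, 3)
    dij = minkowski_distance(nds, i, j, B)
    assert dij == minkowski_distance(nds, j, i, B)
    dik = minkowski_distance(nds, i, k, B)
    dkj = minkowski_distance(nds, k, j, B)
    assert dij <= dik + dkj + 1e-12


# ----------------------------------------------------------------- granules

def test_toy_granules_match_worked_example(toy_nds):
    # attribute a, delta=0.3: boundary case d(x3,x4)=0.3 is inclusive
    expect = [{0, 1, 2}, {0, 1, 2}, {0, 1, 2, 3}, {2, 3}]
    for i, e in enumerate(expect):
        assert neighborhood_granule(toy_nds, i, [0]) == e


def test_granule_degenerate_radii(toy):
    everything = NeighborhoodDecisionSystem(toy, delta=2.0)
    assert neighborhood_granule(everything, 0, [0, 1, 2]) == {0, 1, 2, 3}
    only_self = NeighborhoodDecisionSystem(toy, delta=0.0)
    assert neighborhood_granule(only_self, 2, [0, 1, 2]) == {2}


def test_decision_classes_partition_universe(toy_nds):
    assert decision_class(toy_nds, 0) == {0, 1}
    assert decision_class(toy_nds, 2) == {2, 3}
    single = NeighborhoodDecisionSystem(
        DecisionTable(np.eye(3), ("s",) * 3), delta=0.5
    )
    assert all(decision_class(single, i) == {0, 1, 2} for i in range(3))


# ----------------------------------------------------------- approximations

def test_lower_upper_on_toy_table(toy_nds):
    lower, upper = lower_upper_approximation(toy_nds, [0], {2, 3})
    assert lower == {3}
    assert upper == {0, 1, 2, 3}
    lo, up = lower_upper_approximation(toy_nds, [0], {0, 1, 2, 3})
    assert lo == up == {0, 1, 2, 3}
    lo, up = lower_upper_approximation(toy_nds, [0], set())
    assert lo == up == set()


def test_approximate_precision_examples(toy_nds, toy):
    assert approximate_precision(toy_nds, [0]) == 0.25
    # attribute b: every granule is the whole universe -> empty lowers
    assert approximate_precision(toy_nds, [1]) == 0.0
    one_class = NeighborhoodDecisionSystem(
        DecisionTable(toy.values, ("s",) * 4), delta=0.3
    )
    assert approximate_precision(one_class, [0, 1, 2]) == 1.0


# ------------------------------------------------------- property / oracles

def _brute_granule(nds, i, B):
    vals = nds.table.values
    out = set()
    for j in range(nds.n):
        d = sum(abs(vals[i, k] - vals[j, k]) ** nds.p for k in B) ** (1 / nds.p)
        if d <= nds.delta:
            out.add(j)
    return out


def _brute_lower_upper(nds, B, X):
    lower, upper = set(), set()
    for i in range(nds.n):
        g = _brute_granule(nds, i, B)
        if g <= X:
            lower.add(i)
        if g & X:
            upper.add(i)
    return lower, upper


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=80, deadline=None)
def test_granules_and_approximations_match_naive_enumeration(seed):
    rng = np.random.default_rng(seed)
    nds = random_system(rng, n_max=8)
    m = nds.table.n_features
    B = list(rng.choice(m, size=int(rng.integers(1, m + 1)), replace=False))
    X = {int(x) for x in rng.choice(nds.n, size=int(rng.integers(0, nds.n + 1)),
                                    replace=False)}
    for i in range(nds.n):
        g = neighborhood_granule(nds, i, B)
        assert g == _brute_granule(nds, i, B)
        assert i in g  # reflexivity
    assert lower_upper_approximation(nds, B, X) == _brute_lower_upper(nds, B, X)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=80, deadline=None)
def test_granule_antimonotone_and_precision_monotone(seed):
    rng = np.random.default_rng(seed)
    nds = random_system(rng, m_max=4)
    m = nds.table.n_features
    feats = list(range(m))
    for size1 in range(1, m + 1):
        B2 = rng.choice(feats, size=size1, replace=False).tolist()
        B1 = B2[: int(rng.integers(1, size1 + 1))]
        for i in range(nds.n):
            assert neighborhood_granule(nds, i, B2) <= neighborhood_granule(nds, i, B1)
        assert approximate_precision(nds, B1) <= approximate_precision(nds, B2) + 1e-15
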