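import itertools

import numpy as np
import pytest

from coreflink.mln_core import (
    Assignment,
    DataError,
    Factor,
    GroundNetwork,
    InfeasibilityError,
    NetworkSizeError,
    brute_force_map,
    feature_counts,
    hard_satisfied,
    learn,
    map_infer,
    objective_value,
)

A, B, C = ("p", 1), ("p", 2), ("q", 1)


def test_network_rejects_undeclared_atom():
    with pytest.raises(ValueError):
        GroundNetwork(hidden=[A], factors=[Factor(((B, True),), ("t", None))])


def test_objective_and_counts():
    net = GroundNetwork(
        hidden=[A, B],
        factors=[
            Factor(((A, True),), ("w1", None)),
            Factor(((A, False), (B, True)), ("w2", None)),
        ],
    )
    w = {("w1", None): 2.0, ("w2", None): 0.5}
    assert objective_value(net, w, {A: True, B: False}) == 2.0
    assert objective_value(net, w, {A: False, B: False}) == 0.5
    assert feature_counts(net, {A: True, B: True}) == {("w1", None): 1, ("w2", None): 1}


def test_unit_factor_drives_atom():
    net = GroundNetwork(hidden=[A], factors=[Factor(((A, True),), ("w", None))])
    assert map_infer(net, {("w", None): 1.0}) == {A: True}
    assert map_infer(net, {("w", None): -1.0}) == {A: False}


def test_tie_break_prefers_all_false():
    net = GroundNetwork(hidden=[A, B], factors=[])
    assert map_infer(net, {}) == {A: False, B: False}


def test_hard_clause_forces_atom():
    net = GroundNetwork(hidden=[A, B], factors=[Factor(((A, True), (B, True)), None)])
    out = map_infer(net, {})
    assert sum(out.values()) == 1  # minimal satisfaction, not both


def test_hard_implication_chains():
    # A must be true; A => B
    net = GroundNetwork(
        hidden=[A, B],
        factors=[Factor(((A, True),), None), Factor(((A, False), (B, True)), None)],
    )
    assert map_infer(net, {}) == {A: True, B: True}


def test_infeasible_hard_constraints_raise():
    net = GroundNetwork(
        hidden=[A],
        factors=[Factor(((A, True),), None), Factor(((A, False),), None)],
    )
    with pytest.raises(InfeasibilityError):
        map_infer(net, {})
    with pytest.raises(InfeasibilityError):
        brute_force_map(net, {})


def test_soft_clause_weighs_against_unit_evidence():
    # strong soft clause (¬A ∨ B) vs weak unit evidence against B
    net = GroundNetwork(
        hidden=[A, B],
        factors=[
            Factor(((A, True),), ("a", None)),
            Factor(((B, True),), ("b", None)),
            Factor(((A, False), (B, True)), ("t", None)),
        ],
    )
    w = {("a", None): 2.0, ("b", None): -0.5, ("t", None): 1.0}
    assert map_infer(net, w) == {A: True, B: True}
    w[("t", None)] = 0.1  # now too weak to flip B
    assert map_infer(net, w) == {A: True, B: False}


def test_atom_bonus_biases_decoding():
    net = GroundNetwork(hidden=[A], factors=[Factor(((A, True),), ("w", None))])
    assert map_infer(net, {("w", None): -0.5}, atom_bonus={A: 1.0}) == {A: True}


def test_brute_force_rejects_large_networks():
    atoms = [("p", i) for i in range(21)]
    with pytest.raises(NetworkSizeError):
        brute_force_map(GroundNetwork(hidden=atoms, factors=[]), {})


def _random_network(rng, n_atoms, n_factors):
    atoms = [("p", i) for i in range(n_atoms)]
    factors = []
    for k in range(n_factors):
        size = min(int(rng.integers(1, 4)), n_atoms)
        lits = tuple(
            (atoms[int(i)], bool(rng.integers(2)))
            for i in rng.choice(n_atoms, size=size, replace=False)
        )
        hard = rng.random() < 0.15
        factors.append(Factor(lits, None if hard else ("w", k)))
    weights = {("w", k): float(rng.normal()) for k in range(n_factors)}
    return GroundNetwork(hidden=atoms, factors=factors), weights


def test_map_matches_brute_force_oracle():
    rng = np.random.default_rng(123)
    for _ in range(30):
        net, w = _random_network(rng, int(rng.integers(2, 13)), int(rng.integers(1, 15)))
        try:
            exact = brute_force_map(net, w)
        except InfeasibilityError:
            with pytest.raises(InfeasibilityError):
                map_infer(net, w)
            continue
        ilp = map_infer(net, w)
        assert hard_satisfied(net, ilp)
        assert objective_value(net, w, ilp) == pytest.approx(
            objective_value(net, w, exact), abs=1e-9
        )


def test_learn_rejects_gold_violating_hard_constraints():
    net = GroundNetwork(hidden=[A], factors=[Factor(((A, True),), None)])
    with pytest.raises(DataError):
        learn([(net, {A: False})], epochs=1)


def test_learn_separates_simple_pattern():
    # atoms carrying feature f+ are true in gold, those carrying f- false
    instances = []
    for k in range(6):
        atom = ("p", k)
        key = ("f", "pos" if k % 2 == 0 else "neg")
        net = GroundNetwork(hidden=[atom], factors=[Factor(((atom, True),), key)])
        instances.append((net, {atom: k % 2 == 0}))
    w = learn(instances, epochs=5, C=1.0, seed=0)
    assert w[("f", "pos")] > 0
    assert w.get(("f", "neg"), 0.0) <= 0
    for net, gold in instances:
        assert map_infer(net, w) == gold


def test_learn_is_deterministic():
    rng = np.random.default_rng(7)
    instances = []
    for k in range(5):
        net, w = _random_network(rng, 4, 5)
        gold: Assignment = brute_force_map(net, {k: 1.0 for k in w})
        instances.append((net, gold))
    w1 = learn(instances, epochs=2, seed=3)
    w2 = learn(instances, epochs=2, seed=3)
    assert w1 == w2
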