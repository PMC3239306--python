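"""A compact Markov Logic engine: grounding, MAP inference, learning.

A *ground network* holds the hidden ground atoms of one inference instance
together with ground factors.  Every factor is a disjunction (clause) over
hidden-atom literals — observed atoms are resolved away at grounding time —
and is either HARD (must be satisfied) or soft with a weight shared across
all groundings of its template (optionally keyed by a feature slot, giving
per-feature weights).

MAP inference maximizes the total weight of satisfied soft factors subject
to the hard ones, via the standard 0-1 linear program: one binary variable
per hidden atom, one satisfaction variable per non-unit soft factor (unit
factors fold directly into atom objective coefficients), and linear
implication rows tying each satisfaction variable to its clause.  Solved
with HiGHS through :func:`scipy.optimize.milp`; a brute-force enumerator
over all assignments serves as the exactness oracle for small networks.

Weights are learned online with a passive-aggressive max-margin update:
loss-augmented MAP decoding, then a margin-scaled step toward the gold
feature counts, with weight averaging across updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, milp

Atom = tuple  # ("role", 13, 4, "Theme") — predicate name followed by constants
WeightKey = tuple  # (template_id, feature or None)
Assignment = dict  # Atom -> bool
WeightVector = dict  # WeightKey -> float

HARD = None  # sentinel weight key for hard factors


class InfeasibilityError(RuntimeError):
    pass


class NetworkSizeError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class Factor:
    """A ground clause over hidden atoms.

    ``literals`` is a disjunction of (atom, positive) pairs; ``key`` is the
    weight key (template id, feature slot) or ``None`` for a HARD factor.
    """

    literals: tuple[tuple[Atom, bool], ...]
    key: WeightKey | None

    @property
    def hard(self) -> bool:
        return self.key is None

    def satisfied(self, assignment: Mapping[Atom, bool]) -> bool:
        return any(
            bool(assignment.get(atom, False)) == positive
            for atom, positive in self.literals
        )


@dataclass
class GroundNetwork:
    hidden: list[Atom]
    factors: list[Factor] = field(default_factory=list)

    def __post_init__(self):
        known = set(self.hidden)
        for f in self.factors:
            for atom, _ in f.literals:
                if atom not in known:
                    raise ValueError(f"factor references undeclared atom {atom}")


def objective_value(
    network: GroundNetwork, weights: WeightVector, assignment: Mapping[Atom, bool]
) -> float:
    """Total weight of satisfied soft factors under the assignment."""
    return sum(
        weights.get(f.key, 0.0)
        for f in network.factors
        if not f.hard and f.satisfied(assignment)
    )


def feature_counts(
    network: GroundNetwork, assignment: Mapping[Atom, bool]
) -> dict[WeightKey, int]:
    """Per-weight-key counts of satisfied soft factors (the model features)."""
    counts: dict[WeightKey, int] = {}
    for f in network.factors:
        if not f.hard and f.satisfied(assignment):
            counts[f.key] = counts.get(f.key, 0) + 1
    return counts


def hard_satisfied(network: GroundNetwork, assignment: Mapping[Atom, bool]) -> bool:
    return all(f.satisfied(assignment) for f in network.factors if f.hard)


# -- MAP inference -----------------------------------------------------------


def map_infer(
    network: GroundNetwork,
    weights: WeightVector,
    atom_bonus: Mapping[Atom, float] | None = None,
) -> Assignment:
    """Exact MAP assignment by 0-1 linear programming.

    ``atom_bonus`` adds per-atom objective terms (used for loss-augmented
    decoding).  Ties between optima are broken toward fewer true atoms,
    then toward earlier atoms staying false, via an epsilon penalty far
    below the weight resolution.
    """
    atoms = network.hidden
    n = len(atoms)
    if n == 0:
        if any(f.hard and not f.literals for f in network.factors):
            raise InfeasibilityError("empty hard clause is unsatisfiable")
        return {}
    index = {a: k for k, a in enumerate(atoms)}

    soft_multi: list[tuple[Factor, float]] = []
    coef = np.zeros(n)
    if atom_bonus:
        for atom, b in atom_bonus.items():
            if atom in index:
                coef[index[atom]] += b
    hard_rows: list[Factor] = []
    scale = 1.0
    for f in network.factors:
        if f.hard:
            if not f.literals:
                raise InfeasibilityError("empty hard clause is unsatisfiable")
            hard_rows.append(f)
            continue
        w = weights.get(f.key, 0.0)
        if w == 0.0:
            continue
        scale = max(scale, abs(w))
        if len(f.literals) == 1:
            atom, positive = f.literals[0]
            # w * [x == positive]  ==  const + (w if positive else -w) * x
            coef[index[atom]] += w if positive else -w
        else:
            soft_multi.append((f, w))

    # the per-atom penalty must sit above the solver's feasibility/optimality
    # tolerances (~1e-7) to be respected, yet sum to far less than any real
    # weight difference so it can only ever break exact ties
    eps = 1e-5 * scale / (n + 1)
    tie = eps * (1.0 + np.arange(n) / (10.0 * n))
    m = len(soft_multi)

    # decision vector: [x_0..x_{n-1}, z_0..z_{m-1}]
    c = np.concatenate([-(coef - tie), -np.array([w for _, w in soft_multi])])

    rows, cols, vals, lo, up = [], [], [], [], []
    r = 0
    for f in hard_rows:
        n_neg = 0
        for atom, positive in f.literals:
            rows.append(r)
            cols.append(index[atom])
            vals.append(1.0 if positive else -1.0)
            n_neg += 0 if positive else 1
        lo.append(1.0 - n_neg)
        up.append(np.inf)
        r += 1
    for zi, (f, w) in enumerate(soft_multi):
        zcol = n + zi
        # z <= sum(pos x) + sum(neg (1-x))
        n_neg = 0
        rows.append(r)
        cols.append(zcol)
        vals.append(1.0)
        for atom, positive in f.literals:
            rows.append(r)
            cols.append(index[atom])
            vals.append(-1.0 if positive else 1.0)
            n_neg += 0 if positive else 1
        lo.append(-np.inf)
        up.append(float(n_neg))
        r += 1
        for atom, positive in f.literals:
            # z >= each literal
            rows.append(r)
            cols.append(zcol)
            vals.append(1.0)
            rows.append(r)
            cols.append(index[atom])
            if positive:
                vals.append(-1.0)
                lo.append(0.0)
            else:
                vals.append(1.0)
                lo.append(1.0)
            up.append(np.inf)
            r += 1

    nvar = n + m
    constraints = []
    if r:
        A = sp.csr_matrix((vals, (rows, cols)), shape=(r, nvar))
        constraints.append(LinearConstraint(A, np.array(lo), np.array(up)))
    integrality = np.concatenate([np.ones(n), np.zeros(m)])
    from scipy.optimize import Bounds

    res = milp(
        c=c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(0.0, 1.0),
        # default MIP gaps (rel 1e-4) dwarf the tie-break penalty; demand
        # the exact optimum so tie-breaking and determinism are real
        options={"mip_rel_gap": 0.0},
    )
    if res.status == 2 or res.x is None:
        raise InfeasibilityError(_describe_infeasibility(hard_rows))
    x = res.x[:n]
    return {a: bool(round(x[index[a]])) for a in atoms}


def _describe_infeasibility(hard_rows: Sequence[Factor]) -> str:
    # name a constraint violated by the all-false assignment as a witness
    for f in hard_rows:
        if not f.satisfied({}):
            return f"hard constraints infeasible; e.g. unsatisfied clause {f.literals}"
    return "hard constraints jointly infeasible"


def brute_force_map(network: GroundNetwork, weights: WeightVector) -> Assignment:
    """Exact optimum by exhaustive enumeration; oracle for small networks.

    Ties are broken toward fewer true atoms, then toward the
    lexicographically smallest truth tuple in atom order.
    """
    atoms = network.hidden
    n = len(atoms)
    if n > 20:
        raise NetworkSizeError(f"{n} hidden atoms exceed the oracle limit of 20")
    index = {a: k for k, a in enumerate(atoms)}
    codes = np.arange(2**n, dtype=np.uint32)
    # bit k of the code is atom k's truth value; atom 0 occupies the highest
    # bit so that ascending codes enumerate truth tuples lexicographically
    bits = (codes[:, None] >> (n - 1 - np.arange(n))) & 1  # (2^n, n)
    bits = bits.astype(bool)

    feasible = np.ones(len(codes), dtype=bool)
    objective = np.zeros(len(codes))
    for f in network.factors:
        sat = np.zeros(len(codes), dtype=bool)
        for atom, positive in f.literals:
            sat |= bits[:, index[atom]] == positive
        if f.hard:
            feasible &= sat
        else:
            objective += weights.get(f.key, 0.0) * sat
    if not feasible.any():
        raise InfeasibilityError("hard constraints jointly infeasible")
    objective[~feasible] = -np.inf
    best_obj = objective.max()
    tied = np.flatnonzero(objective >= best_obj - 1e-12)
    counts = bits[tied].sum(axis=1)
    tied = tied[counts == counts.min()]
    winner = tied.min()  # smallest code == lexicographically smallest tuple
    return {a: bool(bits[winner, index[a]]) for a in atoms}


# -- learning ---------------------------------------------------------------


def default_loss_weights(atoms: Iterable[Atom]) -> dict[Atom, float]:
    """Weighted-hamming loss: role atoms count double (the primary target)."""
    return {a: (2.0 if a[0] == "role" else 1.0) for a in atoms}


def learn(
    instances: Sequence[tuple[GroundNetwork, Assignment]],
    epochs: int = 3,
    C: float = 0.1,
    seed: int = 0,
    initial: WeightVector | None = None,
) -> WeightVector:
    """Online passive-aggressive max-margin learning with weight averaging.

    Per instance: loss-augmented MAP decode, then a clipped
    margin-over-squared-distance step toward the gold feature counts.  The
    instance order is a fixed seeded shuffle per epoch; returned weights
    are the average over all updates, which stabilizes the online path.
    """
    rng = np.random.default_rng(seed)
    w: WeightVector = dict(initial or {})
    w_sum: WeightVector = {}
    steps = 0

    for idx, (network, gold) in enumerate(instances):
        if not hard_satisfied(network, gold):
            raise DataError(f"gold assignment of instance {idx} violates a hard constraint")

    order = np.arange(len(instances))
    for _ in range(max(1, epochs)):
        rng.shuffle(order)
        for idx in order:
            network, gold = instances[int(idx)]
            loss_w = default_loss_weights(network.hidden)
            bonus = {
                a: loss_w[a] * (1.0 - 2.0 * float(bool(gold.get(a, False))))
                for a in network.hidden
            }
            pred = map_infer(network, w, atom_bonus=bonus)
            if pred != {a: bool(gold.get(a, False)) for a in network.hidden}:
                phi_g = feature_counts(network, gold)
                phi_p = feature_counts(network, pred)
                delta = {
                    k: phi_g.get(k, 0) - phi_p.get(k, 0)
                    for k in set(phi_g) | set(phi_p)
                }
                delta = {k: v for k, v in delta.items() if v}
                loss = sum(
                    loss_w[a]
                    for a in network.hidden
                    if bool(pred.get(a, False)) != bool(gold.get(a, False))
                )
                score_p = objective_value(network, w, pred)
                score_g = objective_value(network, w, gold)
                margin = loss + score_p - score_g
                norm = sum(v * v for v in delta.values())
                if margin > 0 and norm > 0:
                    tau = min(C, margin / norm)
                    for k, v in delta.items():
                        w[k] = w.get(k, 0.0) + tau * v
            steps += 1
            for k, v in w.items():
                w_sum[k] = w_sum.get(k, 0.0) + v

    if steps == 0:
        return dict(w)
    return {k: v / steps for k, v in w_sum.items()}
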