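"""Analytically tractable generators for testing the engines and the checker.

Toy networks with closed-form behavior:

* ``decay``        A -> 0 at rate d:  E[A(t)] = A0 * exp(-d t)
* ``birth_death``  0 -> A at rate k, A -> 0 at rate d: stationary mean k/d
  (Poisson stationary distribution)
* ``dimerization`` A + A -> B at rate k: the total A + 2B is conserved
* ``two_state_switch`` A <-> B (rates k_on / k_off): A + B conserved,
  stationary mean A_tot * k_off / (k_on + k_off)

plus seeded Bernoulli samplers for the hypothesis-testing module and
random formula/trace generators for fuzzing the BLTL checker against a
brute-force oracle.
"""

from __future__ import annotations

import numpy as np

from . import bltl
from .reaction_model import (
    ConservationRelation,
    MassAction,
    ParameterSet,
    Reaction,
    ReactionNetwork,
    SpeciesDef,
)
from .simulate import Trace

__all__ = [
    "make_toy_network",
    "make_bernoulli_sampler",
    "random_formula",
    "random_trace",
]


def make_toy_network(kind: str, **params: float) -> ReactionNetwork:
    """Build one of the closed-form toy networks (see module docstring)."""
    if kind == "decay":
        d = params.pop("d", 0.01)
        a0 = params.pop("A0", 1000.0)
        _reject_extra(params)
        return ReactionNetwork(
            (SpeciesDef("A", a0),),
            (Reaction("decay", ("A",), (), MassAction(d)),),
            parameters=ParameterSet({"d": d}),
        )
    if kind == "birth_death":
        k = params.pop("k", 50.0)
        d = params.pop("d", 0.1)
        a0 = params.pop("A0", 0.0)
        _reject_extra(params)
        return ReactionNetwork(
            (SpeciesDef("A", a0),),
            (
                Reaction("birth", (), ("A",), MassAction(k)),
                Reaction("death", ("A",), (), MassAction(d)),
            ),
            parameters=ParameterSet({"k": k, "d": d}),
        )
    if kind == "dimerization":
        k = params.pop("k", 1e-3)
        a0 = params.pop("A0", 100.0)
        _reject_extra(params)
        return ReactionNetwork(
            (SpeciesDef("A", a0), SpeciesDef("B", 0.0, role="complex")),
            (Reaction("dimerize", ("A", "A"), ("B",), MassAction(k)),),
            parameters=ParameterSet({"k": k}),
        )
    if kind == "two_state_switch":
        k_on = params.pop("k_on", 0.1)
        k_off = params.pop("k_off", 0.2)
        a0 = params.pop("A0", 100.0)
        _reject_extra(params)
        return ReactionNetwork(
            (SpeciesDef("A", a0), SpeciesDef("B", 0.0, variant_of="A")),
            (
                Reaction("switch_on", ("A",), ("B",), MassAction(k_on)),
                Reaction("switch_off", ("B",), ("A",), MassAction(k_off)),
            ),
            conservation=(ConservationRelation(("A", "B"), a0),),
            parameters=ParameterSet({"k_on": k_on, "k_off": k_off}),
        )
    raise ValueError(f"unknown toy network kind {kind!r}")


def _reject_extra(params: dict) -> None:
    if params:
        raise ValueError(f"unknown parameters: {sorted(params)}")


def make_bernoulli_sampler(p: float, seed: int):
    """Seeded iid Bernoulli(p) stream for :func:`hmgb1smc.smc.smc_decide`."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def sampler() -> int:
        return int(rng.random() < p)

    return sampler


# ---------------------------------------------------------------------------
# fuzzing inputs for the checker/oracle equivalence test

#: ranges used by the fuzzers: temporal bounds and thresholds are drawn so
#: that satisfiable and unsatisfiable formulas both occur frequently on the
#: random traces below (counts in [0, 20], sojourns in [0.5, 10]).
_BOUND_RANGE = (1.0, 100.0)
_THRESHOLD_RANGE = (0.0, 20.0)


def random_trace(length: int, species: tuple[str, ...], rng: np.random.Generator) -> Trace:
    """Random piecewise-constant trace with integer counts in [0, 20]."""
    if length < 1:
        raise ValueError("length must be >= 1")
    sojourns = rng.uniform(0.5, 10.0, size=length)
    times = np.concatenate([[0.0], np.cumsum(sojourns[:-1])])
    values = rng.integers(0, 21, size=(length, len(species))).astype(float)
    return Trace(
        species, times, values=values,
        horizon=float(times[-1] + sojourns[-1]), origin="synthetic",
    )


def random_formula(depth: int, rng: np.random.Generator,
                   species: tuple[str, ...] = ("x", "y")) -> bltl.Formula:
    """Random BLTL formula of at most the given connective depth."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        name = species[rng.integers(len(species))]
        cmp = ("<", ">", "<=", ">=", "=")[rng.integers(5)]
        threshold = float(rng.integers(int(_THRESHOLD_RANGE[0]),
                                       int(_THRESHOLD_RANGE[1]) + 1))
        return bltl.AtomicProposition(bltl.Var(name), cmp, bltl.Const(threshold))
    kind = rng.integers(6)
    bound = float(np.round(rng.uniform(*_BOUND_RANGE), 1))
    if kind == 0:
        return bltl.Not(random_formula(depth - 1, rng, species))
    if kind == 1:
        return bltl.And(random_formula(depth - 1, rng, species),
                        random_formula(depth - 1, rng, species))
    if kind == 2:
        return bltl.Or(random_formula(depth - 1, rng, species),
                       random_formula(depth - 1, rng, species))
    if kind == 3:
        return bltl.Until(random_formula(depth - 1, rng, species),
                          random_formula(depth - 1, rng, species), bound)
    if kind == 4:
        return bltl.F(bound, random_formula(depth - 1, rng, species))
    return bltl.G(bound, random_formula(depth - 1, rng, species))
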