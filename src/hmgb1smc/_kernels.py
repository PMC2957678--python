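"""Numba kernels shared by the SSA and ODE engines.

The reaction set is compiled to flat arrays:

``kind``      0 = zeroth order, 1 = first order, 2 = bimolecular (distinct),
              3 = homodimer, 4 = Hill
``idx1/idx2`` reactant species indices (-1 when unused); for Hill ``idx1``
              is the regulator index
``c1..c4``    rate-law constants: mass action uses ``c1 = k``; Hill uses
              ``c1 = vmax, c2 = K^n (precomputed), c3 = n, c4 = basal``

Propensities use the stochastic combinatorial form c*(c-1)/2 for homodimers;
the deterministic right-hand side uses c**2/2.  The SSA kernel keeps the
propensity vector up to date incrementally through the reaction dependency
graph (the rate-law branches are written out inline in the hot loop — a
factored-out helper costs a native call per update and dominates runtime).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "compile_network",
    "dependency_graph",
    "seed_rng",
    "ssa_chunk",
    "deterministic_rates",
    "rhs",
]


def compile_network(network):
    """Flatten a ReactionNetwork into arrays for the kernels."""
    from .reaction_model import Hill, MassAction

    idx = network.species_index
    R = len(network.reactions)
    kind = np.zeros(R, dtype=np.int8)
    idx1 = np.full(R, -1, dtype=np.int64)
    idx2 = np.full(R, -1, dtype=np.int64)
    c1 = np.zeros(R)
    c2 = np.zeros(R)
    c3 = np.zeros(R)
    c4 = np.zeros(R)
    for r, rxn in enumerate(network.reactions):
        law = rxn.rate_law
        if isinstance(law, MassAction):
            reactants = rxn.reactants
            c1[r] = law.k
            if len(reactants) == 0:
                kind[r] = 0
            elif len(reactants) == 1:
                kind[r] = 1
                idx1[r] = idx[reactants[0]]
            elif reactants[0] == reactants[1]:
                kind[r] = 3
                idx1[r] = idx[reactants[0]]
            else:
                kind[r] = 2
                idx1[r] = idx[reactants[0]]
                idx2[r] = idx[reactants[1]]
        else:
            assert isinstance(law, Hill)
            kind[r] = 4
            idx1[r] = idx[law.regulator]
            c1[r] = law.vmax
            c2[r] = law.K ** law.n  # K^n, so the kernel computes one pow
            c3[r] = law.n
            c4[r] = law.basal
    stoich = network.stoichiometry_matrix()  # (R, S) int64
    return kind, idx1, idx2, c1, c2, c3, c4, stoich


def dependency_graph(kind, idx1, idx2, stoich):
    """For each reaction, which propensities change when it fires.

    Returns a flattened adjacency (offsets, targets) over reaction indices.
    """
    R, S = stoich.shape
    reads: list[set[int]] = [set() for _ in range(R)]
    for r in range(R):
        if idx1[r] >= 0:
            reads[r].add(int(idx1[r]))
        if idx2[r] >= 0:
            reads[r].add(int(idx2[r]))
    affected: list[list[int]] = []
    for r in range(R):
        changed = {s for s in range(S) if stoich[r, s] != 0}
        affected.append([q for q in range(R) if reads[q] & changed])
    offsets = np.zeros(R + 1, dtype=np.int64)
    for r in range(R):
        offsets[r + 1] = offsets[r] + len(affected[r])
    targets = np.array(
        [q for lst in affected for q in lst] or [0], dtype=np.int64
    )
    return offsets, targets


@njit(cache=True)
def seed_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _propensities(state, kind, idx1, idx2, c1, c2, c3, c4, out):
    R = kind.shape[0]
    total = 0.0
    for r in range(R):
        k = kind[r]
        if k == 0:
            a = c1[r]
        elif k == 1:
            a = c1[r] * state[idx1[r]]
        elif k == 2:
            a = c1[r] * state[idx1[r]] * state[idx2[r]]
        elif k == 3:
            c = state[idx1[r]]
            a = c1[r] * c * (c - 1.0) * 0.5
        else:  # Hill; c2 holds K^n
            rr = state[idx1[r]]
            if rr <= 0.0:
                a = c4[r]
            else:
                rn = rr ** c3[r]
                a = c4[r] + c1[r] * rn / (c2[r] + rn)
        if a < 0.0:
            a = 0.0
        out[r] = a
        total += a
    return total


@njit(cache=True)
def ssa_chunk(state, t, t_end, kind, idx1, idx2, c1, c2, c3, c4, stoich,
              dep_off, dep_tgt, times, rxn_out):
    """Run the direct method for at most ``len(times)`` events.

    Mutates ``state`` in place; fills ``times``/``rxn_out``.  Returns
    ``(n_events, t, done)`` where ``done`` is True when the simulation
    reached ``t_end`` (or an absorbing state) before filling the chunk.
    The propensity total is refreshed periodically to bound float drift.
    """
    R = kind.shape[0]
    props = np.empty(R)
    total = _propensities(state, kind, idx1, idx2, c1, c2, c3, c4, props)
    n = 0
    cap = times.shape[0]
    refresh = 0
    while n < cap:
        if total <= 0.0:
            # absorbing (or numerically dead) state: confirm with a full
            # recompute before declaring the trace finished
            total = _propensities(state, kind, idx1, idx2, c1, c2, c3, c4, props)
            if total <= 0.0:
                return n, t_end, True
        u = np.random.random()
        while u <= 0.0:  # guard log(0)
            u = np.random.random()
        dt = -np.log(u) / total
        if t + dt > t_end:
            return n, t_end, True
        t += dt
        target = np.random.random() * total
        acc = 0.0
        chosen = R - 1
        for r in range(R):
            acc += props[r]
            if target < acc:
                chosen = r
                break
        for s in range(stoich.shape[1]):
            d = stoich[chosen, s]
            if d != 0:
                state[s] += d
        for j in range(dep_off[chosen], dep_off[chosen + 1]):
            q = dep_tgt[j]
            k = kind[q]
            if k == 0:
                a = c1[q]
            elif k == 1:
                a = c1[q] * state[idx1[q]]
            elif k == 2:
                a = c1[q] * state[idx1[q]] * state[idx2[q]]
            elif k == 3:
                c = state[idx1[q]]
                a = c1[q] * c * (c - 1.0) * 0.5
            else:
                rr = state[idx1[q]]
                if rr <= 0.0:
                    a = c4[q]
                else:
                    rn = rr ** c3[q]
                    a = c4[q] + c1[q] * rn / (c2[q] + rn)
            if a < 0.0:
                a = 0.0
            total += a - props[q]
            props[q] = a
        refresh += 1
        if refresh >= 16384:
            total = _propensities(state, kind, idx1, idx2, c1, c2, c3, c4, props)
            refresh = 0
        times[n] = t
        rxn_out[n] = chosen
        n += 1
    return n, t, False


@njit(cache=True)
def deterministic_rates(state, kind, idx1, idx2, c1, c2, c3, c4, out):
    """Continuous rate vector (homodimer c**2/2, counts clipped at 0)."""
    R = kind.shape[0]
    for r in range(R):
        k = kind[r]
        if k == 0:
            a = c1[r]
        elif k == 1:
            a = c1[r] * max(state[idx1[r]], 0.0)
        elif k == 2:
            a = c1[r] * max(state[idx1[r]], 0.0) * max(state[idx2[r]], 0.0)
        elif k == 3:
            c = max(state[idx1[r]], 0.0)
            a = c1[r] * c * c * 0.5
        else:
            rr = max(state[idx1[r]], 0.0)
            if rr <= 0.0:
                a = c4[r]
            else:
                rn = rr ** c3[r]
                a = c4[r] + c1[r] * rn / (c2[r] + rn)
        out[r] = a
    return out


@njit(cache=True)
def rhs(state, kind, idx1, idx2, c1, c2, c3, c4, stoich_t, rates_buf):
    deterministic_rates(state, kind, idx1, idx2, c1, c2, c3, c4, rates_buf)
    return stoich_t @ rates_buf


@njit(cache=True)
def window_end(times, bound):
    """For each k, the largest j with times[j] <= times[k] + bound.

    O(n) two-pointer scan over the sorted entry-time array (both the array
    and the queries are sorted, so no per-element binary search is needed).
    """
    n = times.shape[0]
    out = np.empty(n, dtype=np.int64)
    j = 0
    for k in range(n):
        if j < k:
            j = k
        limit = times[k] + bound
        while j + 1 < n and times[j + 1] <= limit:
            j += 1
        out[k] = j
    return out


@njit(cache=True)
def next_true_scan(b):
    """next_true[k] = smallest index >= k with b true, n if none (one pass)."""
    n = b.shape[0]
    out = np.empty(n, dtype=np.int64)
    nxt = n
    for k in range(n - 1, -1, -1):
        if b[k]:
            nxt = k
        out[k] = nxt
    return out
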