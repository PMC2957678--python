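"""Trace generation: Gillespie SSA (direct method) and deterministic ODE.

Both engines produce :class:`Trace` objects — timed sequences of states with
piecewise-constant semantics, the common currency consumed by the BLTL
checker (:mod:`hmgb1smc.bltl`).  SSA traces are event-resolved (one state per
reaction firing, stored compactly as an event log); ODE traces are sampled on
a uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .reaction_model import ReactionNetwork

__all__ = [
    "SimulationConfig",
    "Trace",
    "TraceState",
    "IntegrationError",
    "TraceParseError",
    "simulate_ssa",
    "simulate_ode",
    "write_trace",
    "read_trace",
]


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


class TraceParseError(ValueError):
    """Malformed trace file."""


@dataclass(frozen=True)
class SimulationConfig:
    """Engine settings: horizon ``t_end`` (min), SSA ``seed``, ODE grid/tolerances."""

    t_end: float
    seed: int | None = None
    ode_grid_dt: float = 1.0
    rtol: float = 1e-6
    atol: float = 1e-3
    max_events: int = 150_000_000

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.ode_grid_dt <= 0:
            raise ValueError("ode_grid_dt must be > 0")


@dataclass(frozen=True)
class TraceState:
    """One state and the time spent in it before the next transition."""

    state: dict[str, float]
    sojourn: float


class Trace:
    """A timed state sequence sigma = (s0,t0),(s1,t1),...

    ``times`` are the entry times of each state (``times[0] == 0``); the
    sojourn of state i is ``times[i+1] - times[i]``, and the final state's
    sojourn extends to ``horizon``.  States are stored either densely
    (``values`` matrix, n_states x n_species) or as an SSA event log
    (initial state + per-event reaction index + stoichiometry), from which
    individual species series are reconstructed on demand.
    """

    def __init__(
        self,
        species: tuple[str, ...],
        times: np.ndarray,
        *,
        values: np.ndarray | None = None,
        events: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
        horizon: float,
        origin: str,
        seed: int | None = None,
    ):
        self.species = tuple(species)
        self.times = np.asarray(times, dtype=float)
        self.horizon = float(horizon)
        self.origin = origin
        self.seed = seed
        if (values is None) == (events is None):
            raise ValueError("exactly one of values/events required")
        self._values = values
        self._events = events  # (initial_state, rxn_idx, stoich matrix R x S)
        self._series_cache: dict[str, np.ndarray] = {}
        n = len(self.times)
        if n == 0 or self.times[0] != 0.0:
            raise ValueError("trace must start at time 0")
        if values is not None and values.shape != (n, len(self.species)):
            raise ValueError("values shape mismatch")
        if self.horizon < self.times[-1]:
            raise ValueError("horizon shorter than the last state's entry time")

    # -- basic structure ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_states(self) -> int:
        return len(self.times)

    def sojourns(self) -> np.ndarray:
        out = np.empty(len(self.times))
        out[:-1] = np.diff(self.times)
        out[-1] = self.horizon - self.times[-1]
        return out

    def series(self, name: str) -> np.ndarray:
        """Counts of one species (or a ``*_tot`` conserved total) per state.

        ``X_tot`` resolves to the sum of ``X`` and its active/phosphorylated
        variant (``X_a``/``X_p``); ``PIP_tot`` resolves to PIP2 + PIP3.
        """
        if name in self._series_cache:
            return self._series_cache[name]
        if name in self.species:
            out = self._one_series(self.species.index(name))
        elif name.endswith("_tot"):
            base = name[:-4]
            if base == "PIP":
                members = ["PIP2", "PIP3"]
            else:
                members = [
                    s for s in (base, base + "_a", base + "_p") if s in self.species
                ]
            if not members or not any(m in self.species for m in members):
                raise KeyError(name)
            out = sum(self._one_series(self.species.index(m)) for m in members)
        else:
            # case-insensitive fallback (formulas in the literature write P53)
            lowered = {s.lower(): i for i, s in enumerate(self.species)}
            if name.lower() in lowered:
                out = self._one_series(lowered[name.lower()])
            else:
                raise KeyError(name)
        self._series_cache[name] = out
        return out

    def _one_series(self, j: int) -> np.ndarray:
        if self._values is not None:
            return self._values[:, j].astype(float)
        init, rxn_idx, stoich = self._events
        out = np.empty(len(self.times))
        out[0] = init[j]
        if len(rxn_idx):
            deltas = stoich[:, j].astype(np.int64)[rxn_idx]
            out[1:] = init[j] + np.cumsum(deltas)
        return out

    def values_matrix(self) -> np.ndarray:
        """Dense (n_states, n_species) matrix; materialized for event traces."""
        if self._values is not None:
            return self._values
        return np.column_stack([self._one_series(j) for j in range(len(self.species))])

    def states(self):
        """Iterate :class:`TraceState` (convenience; dense materialization)."""
        mat = self.values_matrix()
        soj = self.sojourns()
        for i in range(len(self.times)):
            yield TraceState(dict(zip(self.species, mat[i])), float(soj[i]))

    def __eq__(self, other) -> bool:  # used by round-trip tests
        if not isinstance(other, Trace):
            return NotImplemented
        return (
            self.species == other.species
            and self.origin == other.origin
            and self.seed == other.seed
            and np.isclose(self.horizon, other.horizon)
            and len(self) == len(other)
            and np.allclose(self.times, other.times)
            and np.allclose(self.values_matrix(), other.values_matrix())
        )


# ---------------------------------------------------------------------------
# SSA


_SSA_CHUNK = 1 << 20


def simulate_ssa(network: ReactionNetwork, config: SimulationConfig) -> Trace:
    """Exact SSA (Gillespie direct method) trace up to ``config.t_end``.

    Waiting times are exponential with the total propensity as rate; the next
    reaction is chosen proportionally to its propensity.  When the total
    propensity reaches zero the final state's sojourn extends to ``t_end``.
    The same seed reproduces the identical event sequence.
    """
    if config.seed is None:
        raise ValueError("SSA requires a seed")
    init = network.initial_state()
    if not np.all(init == np.floor(init)):
        raise ValueError("SSA requires integer initial counts")
    kind, idx1, idx2, c1, c2, c3, c4, stoich = _kernels.compile_network(network)
    dep_off, dep_tgt = _kernels.dependency_graph(kind, idx1, idx2, stoich)
    _kernels.seed_rng(config.seed)
    state = init.copy()
    t = 0.0
    times_chunks: list[np.ndarray] = []
    rxn_chunks: list[np.ndarray] = []
    total_events = 0
    while True:
        times = np.empty(_SSA_CHUNK)
        rxns = np.empty(_SSA_CHUNK, dtype=np.int16)
        n, t, done = _kernels.ssa_chunk(
            state, t, config.t_end, kind, idx1, idx2, c1, c2, c3, c4, stoich,
            dep_off, dep_tgt, times, rxns,
        )
        if n:
            times_chunks.append(times[:n])
            rxn_chunks.append(rxns[:n])
            total_events += n
        if done:
            break
        if total_events > config.max_events:
            raise RuntimeError(
                f"SSA exceeded max_events={config.max_events} before t_end"
            )
    all_times = np.concatenate([[0.0], *times_chunks]) if times_chunks else np.zeros(1)
    all_rxns = (
        np.concatenate(rxn_chunks) if rxn_chunks else np.zeros(0, dtype=np.int16)
    )
    return Trace(
        network.species_names,
        all_times,
        events=(init.astype(np.int64), all_rxns, stoich),
        horizon=config.t_end,
        origin="ssa",
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# ODE


def simulate_ode(network: ReactionNetwork, config: SimulationConfig) -> Trace:
    """Integrate d(count)/dt = stoichiometry^T . rates on a uniform grid.

    Uses a stiff-capable integrator (LSODA); all species are integrated and
    the conservation relations can be verified post hoc.  Each grid state's
    sojourn is ``ode_grid_dt``.
    """
    kind, idx1, idx2, c1, c2, c3, c4, stoich = _kernels.compile_network(network)
    stoich_t = np.ascontiguousarray(stoich.T.astype(float))
    rates_buf = np.empty(len(network.reactions))

    def f(t, y):
        return _kernels.rhs(y, kind, idx1, idx2, c1, c2, c3, c4, stoich_t, rates_buf)

    n_steps = int(np.floor(config.t_end / config.ode_grid_dt + 1e-9))
    t_eval = np.arange(n_steps + 1) * config.ode_grid_dt
    sol = solve_ivp(
        f,
        (0.0, config.t_end),
        network.initial_state(),
        method="LSODA",
        t_eval=t_eval,
        rtol=config.rtol,
        atol=config.atol,
    )
    if not sol.success:
        last = sol.t[-1] if len(sol.t) else 0.0
        raise IntegrationError(f"ODE integration failed: {sol.message}", last)
    values = sol.y.T.copy()
    values[values < 0] = 0.0  # clip solver noise below zero
    return Trace(
        network.species_names,
        t_eval,
        values=values,
        horizon=config.t_end,
        origin="ode",
        seed=None,
    )


# ---------------------------------------------------------------------------
# trace persistence (TSV)


def write_trace(trace: Trace, path) -> None:
    """TSV with a ``time`` column plus one column per species.

    Metadata (origin, seed, horizon) goes into ``#`` header comments so the
    round trip preserves it.
    """
    mat = trace.values_matrix()
    with open(path, "w") as fh:
        fh.write(f"# origin: {trace.origin}\n")
        fh.write(f"# seed: {'' if trace.seed is None else trace.seed}\n")
        fh.write(f"# horizon: {trace.horizon!r}\n")
        fh.write("time\t" + "\t".join(trace.species) + "\n")
        for i, t in enumerate(trace.times):
            row = "\t".join(repr(float(v)) for v in mat[i])
            fh.write(f"{float(t)!r}\t{row}\n")


def read_trace(path) -> Trace:
    """Inverse of :func:`write_trace`."""
    origin, seed, horizon = "unknown", None, None
    rows: list[list[float]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("origin:"):
                    origin = body.split(":", 1)[1].strip()
                elif body.startswith("seed:"):
                    s = body.split(":", 1)[1].strip()
                    seed = int(s) if s else None
                elif body.startswith("horizon:"):
                    horizon = float(body.split(":", 1)[1].strip())
                continue
            if header is None:
                header = line.split("\t")
                if not header or header[0] != "time" or len(header) < 2:
                    raise TraceParseError(
                        f"line {lineno}: header must start with 'time'"
                    )
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise TraceParseError(
                    f"line {lineno}: expected {len(header)} cells, got {len(cells)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as e:
                raise TraceParseError(f"line {lineno}: {e}") from None
    if header is None or not rows:
        raise TraceParseError("empty trace file")
    data = np.asarray(rows)
    times = data[:, 0]
    if np.any(np.diff(times) < 0):
        bad = int(np.argmax(np.diff(times) < 0)) + 2
        raise TraceParseError(f"line {bad + 3}: time column must be non-decreasing")
    if horizon is None:
        horizon = float(times[-1])
    return Trace(
        tuple(header[1:]),
        times,
        values=data[:, 1:],
        horizon=horizon,
        origin=origin,
        seed=seed,
    )
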