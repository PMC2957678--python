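"""Reaction networks: species, stoichiometry, rate laws, conservation relations.

A :class:`ReactionNetwork` is the static description shared by the two
simulation engines (:mod:`hmgb1smc.simulate`): a list of species with initial
molecule counts, a list of reactions with either mass-action or Hill rate
laws, and the conservation relations (constant active+inactive totals of the
signaling proteins) that the dynamics must preserve.

Rates are expressed per minute and amounts in molecule counts throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ConfigurationError",
    "NetworkValidationError",
    "SpeciesDef",
    "MassAction",
    "Hill",
    "Reaction",
    "ConservationRelation",
    "ParameterSet",
    "ReactionNetwork",
    "reaction_rate",
    "load_network",
    "save_network",
]

SPECIES_ROLES = ("protein", "mRNA", "complex", "ligand", "receptor", "lipid")


class ConfigurationError(ValueError):
    """A required parameter or configuration entry is missing."""


class NetworkValidationError(ValueError):
    """The network violates a structural invariant (bad cross-reference, ...)."""


@dataclass(frozen=True)
class SpeciesDef:
    """A molecular species.

    ``variant_of`` links an active ("_a") or phosphorylated ("_p") form back
    to its base species, which is how conserved pairs are annotated.
    """

    name: str
    initial_count: float = 0.0
    role: str = "protein"
    variant_of: str | None = None

    def __post_init__(self) -> None:
        if not self.name or not self.name.replace("_", "a").isalnum():
            raise NetworkValidationError(f"invalid species name {self.name!r}")
        if self.initial_count < 0:
            raise NetworkValidationError(
                f"species {self.name!r}: initial_count must be >= 0"
            )
        if self.role not in SPECIES_ROLES:
            raise NetworkValidationError(
                f"species {self.name!r}: unknown role {self.role!r}"
            )


@dataclass(frozen=True)
class MassAction:
    """Mass-action rate law with rate constant ``k`` (units depend on order)."""

    k: float

    kind = "mass_action"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise NetworkValidationError("mass_action: k must be >= 0")


@dataclass(frozen=True)
class Hill:
    """Sigmoidal synthesis law ``basal + vmax * R^n / (K^n + R^n)``.

    ``regulator`` names the transcription factor R; ``n`` is the (positive)
    cooperativity coefficient, ``K`` the half-activation count.
    """

    vmax: float
    K: float
    n: float
    regulator: str
    basal: float = 0.0

    kind = "hill"

    def __post_init__(self) -> None:
        if min(self.vmax, self.K, self.basal) < 0:
            raise NetworkValidationError("hill: vmax, K and basal must be >= 0")
        if self.n <= 0:
            raise NetworkValidationError("hill: n must be > 0")


RateLaw = MassAction | Hill


@dataclass(frozen=True)
class Reaction:
    """One reaction channel.

    ``reactants``/``products`` are multisets of species names (tuples with
    repetitions).  Pure synthesis has no reactants, pure degradation no
    products.  Mass-action reactions are elementary: at most two reactant
    molecules per species.
    """

    label: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_law: RateLaw

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        if not self.reactants and not self.products:
            raise NetworkValidationError(
                f"reaction {self.label!r}: reactants and products both empty"
            )
        if isinstance(self.rate_law, MassAction):
            counts = Counter(self.reactants)
            if any(c > 2 for c in counts.values()):
                raise NetworkValidationError(
                    f"reaction {self.label!r}: mass-action multiplicity > 2"
                )
            if len(self.reactants) > 2:
                raise NetworkValidationError(
                    f"reaction {self.label!r}: more than two reactant molecules"
                )

    def stoichiometry(self) -> dict[str, int]:
        """Net change per firing, as species -> integer delta."""
        delta: Counter[str] = Counter(self.products)
        delta.subtract(Counter(self.reactants))
        return {s: d for s, d in delta.items() if d != 0}


@dataclass(frozen=True)
class ConservationRelation:
    """``sum(counts of members) == total`` at every simulated state."""

    members: tuple[str, ...]
    total: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if len(self.members) < 2:
            raise NetworkValidationError("conservation relation needs >= 2 members")


@dataclass(frozen=True)
class ParameterSet:
    """Named scalar rate parameters.

    ``notes`` carries free-text cross-references for parameters that have an
    alternative symbol in the deterministic formulation of the model (the
    three mutation knobs d_ARF, d_P21, d_RAS in particular).
    """

    values: Mapping[str, float]
    notes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))
        object.__setattr__(self, "notes", dict(self.notes))
        for name, v in self.values.items():
            if v < 0:
                raise NetworkValidationError(f"parameter {name!r} must be >= 0")

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise ConfigurationError(f"missing parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def updated(self, **changes: float) -> "ParameterSet":
        """A copy with some parameters replaced (used by sweeps)."""
        vals = dict(self.values)
        vals.update(changes)
        return ParameterSet(vals, self.notes)


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple[SpeciesDef, ...]
    reactions: tuple[Reaction, ...]
    conservation: tuple[ConservationRelation, ...] = ()
    parameters: ParameterSet = field(default_factory=lambda: ParameterSet({}))

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "conservation", tuple(self.conservation))
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def species_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_count for s in self.species], dtype=float)

    def stoichiometry_matrix(self) -> np.ndarray:
        """(n_reactions, n_species) matrix of net count changes."""
        idx = self.species_index
        mat = np.zeros((len(self.reactions), len(self.species)), dtype=np.int64)
        for r, rxn in enumerate(self.reactions):
            for name, d in rxn.stoichiometry().items():
                mat[r, idx[name]] = d
        return mat

    @property
    def n_free_variables(self) -> int:
        """Species count minus the number of independent conservation relations."""
        if not self.conservation:
            return len(self.species)
        idx = self.species_index
        mat = np.zeros((len(self.conservation), len(self.species)))
        for i, rel in enumerate(self.conservation):
            for m in rel.members:
                mat[i, idx[m]] = 1.0
        return len(self.species) - int(np.linalg.matrix_rank(mat))

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dup = [n for n, c in Counter(names).items() if c > 1]
            raise NetworkValidationError(f"duplicate species names: {dup}")
        declared = set(names)
        labels = [r.label for r in self.reactions]
        if len(set(labels)) != len(labels):
            dup = [l for l, c in Counter(labels).items() if c > 1]
            raise NetworkValidationError(f"duplicate reaction labels: {dup}")
        for s in self.species:
            if s.variant_of is not None and s.variant_of not in declared:
                raise NetworkValidationError(
                    f"species {s.name!r}: variant_of {s.variant_of!r} not declared"
                )
        for rxn in self.reactions:
            for name in (*rxn.reactants, *rxn.products):
                if name not in declared:
                    raise NetworkValidationError(
                        f"reaction {rxn.label!r}: unknown species {name!r}"
                    )
            if isinstance(rxn.rate_law, Hill) and rxn.rate_law.regulator not in declared:
                raise NetworkValidationError(
                    f"reaction {rxn.label!r}: unknown regulator "
                    f"{rxn.rate_law.regulator!r}"
                )
        for rel in self.conservation:
            for m in rel.members:
                if m not in declared:
                    raise NetworkValidationError(
                        f"conservation relation: unknown species {m!r}"
                    )
        self._check_conservation_stoichiometry()

    def _check_conservation_stoichiometry(self) -> None:
        """Every reaction must leave each conserved total unchanged (static check)."""
        for rel in self.conservation:
            members = set(rel.members)
            for rxn in self.reactions:
                net = sum(d for s, d in rxn.stoichiometry().items() if s in members)
                if net != 0:
                    raise NetworkValidationError(
                        f"reaction {rxn.label!r} changes conserved total "
                        f"of {rel.members} by {net}"
                    )

    # -- convenience -------------------------------------------------------

    def with_parameters(self, params: ParameterSet) -> "ReactionNetwork":
        return replace(self, parameters=params)

    def with_initial(self, **counts: float) -> "ReactionNetwork":
        idx = self.species_index
        for name in counts:
            if name not in idx:
                raise NetworkValidationError(f"unknown species {name!r}")
        new_species = tuple(
            replace(s, initial_count=counts.get(s.name, s.initial_count))
            for s in self.species
        )
        # Conserved totals follow the initial counts they are defined from.
        new_totals = []
        for rel in self.conservation:
            total = sum(
                counts.get(m, dict(zip(self.species_names, self.initial_state()))[m])
                for m in rel.members
            )
            new_totals.append(ConservationRelation(rel.members, total))
        return replace(self, species=new_species, conservation=tuple(new_totals))


def reaction_rate(
    reaction: Reaction,
    state: Mapping[str, float],
    mode: str = "stochastic",
) -> float:
    """Instantaneous rate (events/min) of one reaction at a given state.

    Mass action: ``k * prod(reactant counts)``; a homodimer pair ``A + A``
    contributes ``c*(c-1)/2`` in stochastic mode and ``c**2 / 2`` in
    deterministic mode (the standard SSA/ODE correspondence with a shared k).
    Hill: ``basal + vmax * R^n / (K^n + R^n)`` with R the regulator count.
    """
    if mode not in ("stochastic", "deterministic"):
        raise ValueError(f"unknown mode {mode!r}")
    law = reaction.rate_law
    if isinstance(law, Hill):
        r = float(state[law.regulator])
        if r < 0:
            raise ValueError(f"negative count for {law.regulator!r}")
        if r == 0.0:
            return law.basal
        log_ratio = law.n * (np.log(law.K) - np.log(r)) if law.K > 0 else -np.inf
        if log_ratio > 700.0:  # (K/r)^n overflows; rate is pinned at basal
            return law.basal
        return law.basal + law.vmax / (1.0 + np.exp(log_ratio))
    rate = law.k
    counts = Counter(reaction.reactants)
    for name, mult in counts.items():
        c = float(state[name])
        if c < 0:
            raise ValueError(f"negative count for {name!r}")
        if mult == 1:
            rate *= c
        else:  # homodimer
            rate *= c * (c - 1.0) / 2.0 if mode == "stochastic" else c * c / 2.0
    return max(rate, 0.0)


# ---------------------------------------------------------------------------
# structured-text (YAML) persistence


def _rate_law_to_dict(law: RateLaw) -> dict:
    if isinstance(law, MassAction):
        return {"kind": "mass_action", "k": float(law.k)}
    return {
        "kind": "hill",
        "vmax": float(law.vmax),
        "K": float(law.K),
        "n": float(law.n),
        "regulator": law.regulator,
        "basal": float(law.basal),
    }


def _rate_law_from_dict(d: Mapping, where: str) -> RateLaw:
    kind = d.get("kind")
    try:
        if kind == "mass_action":
            return MassAction(k=float(d["k"]))
        if kind == "hill":
            return Hill(
                vmax=float(d["vmax"]),
                K=float(d["K"]),
                n=float(d["n"]),
                regulator=str(d["regulator"]),
                basal=float(d.get("basal", 0.0)),
            )
    except KeyError as e:
        raise ConfigurationError(f"{where}: rate law missing field {e}") from None
    raise ConfigurationError(f"{where}: unknown rate law kind {kind!r}")


def save_network(network: ReactionNetwork, path) -> None:
    """Write a network as a YAML config (inverse of :func:`load_network`)."""
    doc = {
        "species": [
            {
                "name": s.name,
                "initial": float(s.initial_count),
                "role": s.role,
                **({"variant_of": s.variant_of} if s.variant_of else {}),
            }
            for s in network.species
        ],
        "reactions": [
            {
                "label": r.label,
                "reactants": list(r.reactants),
                "products": list(r.products),
                "rate": _rate_law_to_dict(r.rate_law),
            }
            for r in network.reactions
        ],
        "conservation": [
            {"members": list(rel.members), "total": float(rel.total)}
            for rel in network.conservation
        ],
        "parameters": {k: float(v) for k, v in network.parameters.values.items()},
        "parameter_notes": dict(network.parameters.notes),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_network(path) -> ReactionNetwork:
    """Load a YAML network config written by :func:`save_network`."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            mark = getattr(e, "problem_mark", None)
            locus = f" at line {mark.line + 1}" if mark is not None else ""
            raise ConfigurationError(f"malformed network config{locus}: {e}") from e
    if not isinstance(doc, Mapping):
        raise ConfigurationError("malformed network config: not a mapping")
    species = tuple(
        SpeciesDef(
            name=str(d["name"]),
            initial_count=float(d.get("initial", 0.0)),
            role=str(d.get("role", "protein")),
            variant_of=d.get("variant_of"),
        )
        for d in doc.get("species", [])
    )
    reactions = tuple(
        Reaction(
            label=str(d["label"]),
            reactants=tuple(d.get("reactants", []) or []),
            products=tuple(d.get("products", []) or []),
            rate_law=_rate_law_from_dict(d.get("rate", {}), f"reaction {d.get('label')!r}"),
        )
        for d in doc.get("reactions", [])
    )
    conservation = tuple(
        ConservationRelation(tuple(d["members"]), float(d["total"]))
        for d in doc.get("conservation", [])
    )
    params = ParameterSet(
        {str(k): float(v) for k, v in (doc.get("parameters") or {}).items()},
        {str(k): str(v) for k, v in (doc.get("parameter_notes") or {}).items()},
    )
    return ReactionNetwork(species, reactions, conservation, params)
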