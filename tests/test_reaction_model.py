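"""Reaction network structure, rate laws and config round trips."""

import numpy as np
import pytest

from hmgb1smc.hmgb1 import TABLE1_INITIAL_COUNTS, build_hmgb1_network
from hmgb1smc.reaction_model import (
    ConfigurationError,
    ConservationRelation,
    Hill,
    MassAction,
    NetworkValidationError,
    ParameterSet,
    Reaction,
    ReactionNetwork,
    SpeciesDef,
    load_network,
    reaction_rate,
    save_network,
)


class TestRateLaws:
    @pytest.mark.parametrize(
        "law,reactants,state,expected",
        [
            # k * A * B by definition
            (MassAction(0.1), ("A", "B"), {"A": 10, "B": 5}, 5.0),
            # half-saturation point R = K gives vmax/2
            (Hill(vmax=1, K=100, n=2, regulator="R"), (), {"R": 100}, 0.5),
            # hand oracle: 200^2 / (100^2 + 200^2) = 0.8
            (Hill(vmax=1, K=100, n=2, regulator="R"), (), {"R": 200}, 0.8),
            # zeroth order
            (MassAction(7.0), (), {}, 7.0),
        ],
    )
    def test_rate_examples(self, law, reactants, state, expected):
        rxn = Reaction("r", reactants, ("X",) if not reactants else (), law)
        assert reaction_rate(rxn, state) == pytest.approx(expected)

    def test_homodimer_stochastic_vs_deterministic(self):
        rxn = Reaction("dim", ("A", "A"), ("B",), MassAction(0.2))
        assert reaction_rate(rxn, {"A": 10}) == pytest.approx(0.2 * 10 * 9 / 2)
        assert reaction_rate(rxn, {"A": 10}, mode="deterministic") == pytest.approx(
            0.2 * 100 / 2
        )

    def test_negative_count_rejected(self):
        rxn = Reaction("r", ("A",), (), MassAction(1.0))
        with pytest.raises(ValueError, match="negative"):
            reaction_rate(rxn, {"A": -1})

    def test_hill_bounded_and_monotone(self):
        law = Hill(vmax=3.0, K=50.0, n=3.0, regulator="R", basal=0.5)
        rxn = Reaction("syn", (), ("X",), law)
        rates = [reaction_rate(rxn, {"R": r}) for r in np.linspace(0, 1e4, 200)]
        assert all(b >= a for a, b in zip(rates, rates[1:]))  # monotone
        assert rates[0] == pytest.approx(0.5)  # basal at R=0
        assert max(rates) < 0.5 + 3.0  # bounded below basal+vmax
        assert reaction_rate(rxn, {"R": 50.0}) == pytest.approx(0.5 + 1.5)

    def test_mass_action_monotone_in_each_reactant(self):
        rxn = Reaction("r", ("A", "B"), (), MassAction(0.3))
        r1 = reaction_rate(rxn, {"A": 2, "B": 9})
        r2 = reaction_rate(rxn, {"A": 3, "B": 9})
        r3 = reaction_rate(rxn, {"A": 3, "B": 10})
        assert r1 < r2 < r3


class TestValidation:
    def test_unknown_reactant_rejected(self):
        with pytest.raises(NetworkValidationError, match="FOO"):
            ReactionNetwork(
                (SpeciesDef("A", 1),),
                (Reaction("r", ("FOO",), (), MassAction(1.0)),),
            )

    def test_empty_species_with_reaction_rejected(self):
        with pytest.raises(NetworkValidationError):
            ReactionNetwork((), (Reaction("r", ("A",), (), MassAction(1.0)),))

    def test_duplicate_species_rejected(self):
        with pytest.raises(NetworkValidationError, match="duplicate"):
            ReactionNetwork((SpeciesDef("A", 1), SpeciesDef("A", 2)), ())

    def test_negative_initial_rejected(self):
        with pytest.raises(NetworkValidationError):
            SpeciesDef("A", -1)

    def test_trimolecular_mass_action_rejected(self):
        with pytest.raises(NetworkValidationError):
            Reaction("r", ("A", "A", "A"), (), MassAction(1.0))

    def test_hill_unknown_regulator_rejected(self):
        with pytest.raises(NetworkValidationError, match="regulator"):
            ReactionNetwork(
                (SpeciesDef("A", 1),),
                (Reaction("r", (), ("A",), Hill(1, 1, 1, regulator="Z")),),
            )

    def test_conservation_violating_reaction_rejected(self):
        # A -> (nothing) destroys the conserved A+B total
        with pytest.raises(NetworkValidationError, match="conserved"):
            ReactionNetwork(
                (SpeciesDef("A", 5), SpeciesDef("B", 0)),
                (Reaction("leak", ("A",), (), MassAction(1.0)),),
                conservation=(ConservationRelation(("A", "B"), 5.0),),
            )

    def test_missing_parameter_named_in_error(self):
        params = ParameterSet({k: 1.0 for k in ["k_rage_act"]})
        with pytest.raises(ConfigurationError, match="k_rage_deact"):
            build_hmgb1_network(params)


class TestHMGB1Network:
    def test_structural_counts(self, hmgb1_network):
        assert len(hmgb1_network.species) == 31
        assert len(hmgb1_network.reactions) == 59
        assert len(hmgb1_network.conservation) == 8
        assert hmgb1_network.n_free_variables == 23

    def test_reference_initial_counts(self, hmgb1_network):
        init = dict(zip(hmgb1_network.species_names, hmgb1_network.initial_state()))
        for name, expected in TABLE1_INITIAL_COUNTS.items():
            assert init[name] == expected
        # unlisted species start at zero; HMGB1 takes the dose argument
        assert init["CyclinE"] == 0 and init["E2F"] == 0 and init["PTEN"] == 0
        assert init["HMGB1"] == 1e3
        assert build_hmgb1_network(hmgb1_init=42).initial_state()[0] == 42

    def test_conserved_pairs(self, hmgb1_network):
        totals = {rel.members: rel.total for rel in hmgb1_network.conservation}
        assert totals[("AKT", "AKT_p")] == 1e5
        assert totals[("PIP2", "PIP3")] == 1e5
        assert totals[("RAGE", "RAGE_a")] == 1e3

    def test_hill_laws_exactly_on_synthesis_of_six_proteins(self, hmgb1_network):
        hill_products = {
            rxn.products[0]
            for rxn in hmgb1_network.reactions
            if isinstance(rxn.rate_law, Hill)
        }
        assert hill_products == {"PTEN", "mdm2", "CyclinD", "Myc", "E2F", "CyclinE"}

    def test_dose_knob_rebuilds_conservation(self, hmgb1_network):
        net = hmgb1_network.with_initial(AKT=3e5)
        totals = {rel.members: rel.total for rel in net.conservation}
        assert totals[("AKT", "AKT_p")] == 3e5


class TestPersistence:
    def test_round_trip_identity(self, hmgb1_network, tmp_path):
        path = tmp_path / "net.yaml"
        save_network(hmgb1_network, path)
        loaded = load_network(path)
        assert loaded == hmgb1_network

    def test_undeclared_species_reference_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "species:\n- {name: A, initial: 1}\n"
            "reactions:\n- {label: r, reactants: [FOO], products: [],"
            " rate: {kind: mass_action, k: 1.0}}\n"
        )
        with pytest.raises(NetworkValidationError, match="FOO"):
            load_network(path)

    def test_malformed_yaml_reports_locus(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("species:\n  - {name: A, initial: 1\n")
        with pytest.raises(ConfigurationError, match="line"):
            load_network(path)


try:
    from hypothesis import given, settings, strategies as st

    class TestRateLawProperties:
        @settings(deadline=None, max_examples=200, derandomize=True)
        @given(
            vmax=st.floats(0.01, 1e3), K=st.floats(1.0, 1e5),
            n=st.floats(0.5, 12.0), basal=st.floats(0.0, 10.0),
            r=st.floats(0.0, 1e6),
        )
        def test_hill_rate_stays_in_band(self, vmax, K, n, basal, r):
            law = Hill(vmax=vmax, K=K, n=n, regulator="R", basal=basal)
            rxn = Reaction("syn", (), ("X",), law)
            rate = reaction_rate(rxn, {"R": r})
            assert basal <= rate < basal + vmax + 1e-9
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass
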