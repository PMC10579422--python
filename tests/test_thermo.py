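"""Standard and in-situ Gibbs energies from the packaged formation table."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from syntherm.errors import (
    ActivityError,
    ReactionBalanceError,
    SpeciesLookupError,
    ValidationError,
)
from syntherm.reactions import (
    ACETATE_OXIDATION,
    ACETICLASTIC_NET,
    HYDROGENOTROPHIC_METHANOGENESIS,
    OVERALL_MINERALISATION,
    PROPIONATE_OXIDATION,
)
from syntherm.thermo import (
    ATM_PA,
    R_KJ,
    T_REF,
    ReactionScheme,
    ThermoTable,
    ThermodynamicState,
    delta_g_at_state,
    delta_g_standard,
    delta_g_standard_at_temperature,
    delta_h_standard,
    parse_formula,
    reaction_quotient_ln,
    validate_reaction,
)

from conftest import random_admissible_state


class TestStandardEnergies:
    @pytest.mark.parametrize(
        "reaction, expected",
        [
            (ACETATE_OXIDATION, 55.0),                 # acetate -> 2 CO2 + 4 H2
            (HYDROGENOTROPHIC_METHANOGENESIS, -130.8),  # 4 H2 + CO2 -> CH4
            (ACETICLASTIC_NET, -75.8),                  # acetate -> CH4 + CO2
        ],
    )
    def test_guild_reaction_dg0_matches_literature(self, reaction, expected):
        assert delta_g_standard(reaction) == pytest.approx(expected, abs=0.1)

    def test_propionate_oxidation_dg0_hand_sum(self):
        # independent hand-sum of the packaged formation energies:
        # -369.41 - 394.36 + 3*0 - (-361.08 - 2*237.17) = +71.65
        assert delta_g_standard(PROPIONATE_OXIDATION) == pytest.approx(71.65, abs=1e-9)

    def test_empty_reaction_is_zero(self):
        assert delta_g_standard(ReactionScheme("empty", {})) == 0.0

    def test_unknown_species_raises_naming_it(self):
        bogus = ReactionScheme("bogus", {"butyrate": -1.0})
        with pytest.raises(SpeciesLookupError, match="butyrate"):
            delta_g_standard(bogus)

    def test_unbalanced_reaction_rejected_with_residuals(self):
        lopsided = ReactionScheme("lopsided", {"H2": -1.0, "CH4": 1.0})
        with pytest.raises(ReactionBalanceError, match="element C"):
            delta_g_standard(lopsided)

    def test_hess_additivity_on_scaled_sums(self):
        a = PROPIONATE_OXIDATION
        b = ACETATE_OXIDATION.scaled(2.0)
        total = delta_g_standard(a + b)
        assert total == pytest.approx(
            delta_g_standard(a) + 2.0 * delta_g_standard(ACETATE_OXIDATION), abs=1e-9
        )


class TestTemperatureCorrection:
    def test_reference_temperature_is_identity(self):
        dg = delta_g_standard(HYDROGENOTROPHIC_METHANOGENESIS)
        assert delta_g_standard_at_temperature(
            HYDROGENOTROPHIC_METHANOGENESIS, None, T_REF
        ) == pytest.approx(dg, abs=1e-12)

    def test_methanogenesis_at_325K_matches_hand_evaluation(self):
        # spreadsheet-style evaluation of the two-term Gibbs-Helmholtz form
        # with the packaged table values dG = -130.78, dH = -252.96
        t = 325.15
        expected = (t / 298.15) * (-130.78) + (1 - t / 298.15) * (-252.96)
        got = delta_g_standard_at_temperature(HYDROGENOTROPHIC_METHANOGENESIS, None, t)
        assert got == pytest.approx(expected, abs=1e-9)
        assert delta_h_standard(HYDROGENOTROPHIC_METHANOGENESIS) == pytest.approx(
            -252.96, abs=1e-9
        )

    def test_reaction_with_dh_equal_dg_is_temperature_independent(self):
        # H2 + CO2 -> formate + H+ has dG != dH, so build a synthetic table
        rows = [
            {"name": "X", "phase": "aqueous", "formula": "C", "charge": "0",
             "dgf0_kj_mol": "-100.0", "dhf0_kj_mol": "-100.0"},
            {"name": "Y", "phase": "aqueous", "formula": "C", "charge": "0",
             "dgf0_kj_mol": "-60.0", "dhf0_kj_mol": "-60.0"},
        ]
        table = ThermoTable.from_rows(rows)
        rxn = ReactionScheme("iso", {"X": -1.0, "Y": 1.0})
        for t in (280.0, 298.15, 350.0):
            assert delta_g_standard_at_temperature(rxn, table, t) == pytest.approx(
                40.0, abs=1e-12
            )

    def test_out_of_range_temperature_rejected(self):
        with pytest.raises(ValidationError):
            delta_g_standard_at_temperature(ACETATE_OXIDATION, None, 400.0)


class TestReactionQuotient:
    def test_standard_state_gives_zero(self):
        state = ThermodynamicState(
            temperature=T_REF,
            ph=7.0,  # H+ does not participate in this reaction
            solutes={},
            gases={"H2": ATM_PA, "CO2": ATM_PA, "CH4": ATM_PA},
        )
        assert reaction_quotient_ln(
            HYDROGENOTROPHIC_METHANOGENESIS, state
        ) == pytest.approx(0.0, abs=1e-12)

    def test_halving_h2_raises_lnq_by_stoichiometric_power(self):
        base = ThermodynamicState(
            temperature=T_REF, ph=7.0, gases={"H2": ATM_PA, "CO2": ATM_PA, "CH4": ATM_PA}
        )
        halved = base.with_gas("H2", ATM_PA / 2.0)
        dq = reaction_quotient_ln(
            HYDROGENOTROPHIC_METHANOGENESIS, halved
        ) - reaction_quotient_ln(HYDROGENOTROPHIC_METHANOGENESIS, base)
        assert dq == pytest.approx(4.0 * math.log(2.0), abs=1e-12)

    def test_acetate_oxidation_lnq_hand_evaluation(self):
        # pH 8.5, acetate 0.03 M, pCO2 0.3 atm, pH2 8 Pa; hand-computed sum
        state = ThermodynamicState(
            temperature=325.15,
            ph=8.5,
            solutes={"acetate": 0.03},
            gases={"H2": 8.0, "CO2": 0.3 * ATM_PA},
        )
        expected = (
            2.0 * math.log(0.3)
            + 4.0 * math.log(8.0 / ATM_PA)
            - math.log(0.03)
            + 8.5 * math.log(10.0)
        )
        assert reaction_quotient_ln(ACETATE_OXIDATION, state) == pytest.approx(
            expected, rel=1e-12
        )

    def test_zero_activity_is_an_informative_error(self):
        state = ThermodynamicState(temperature=T_REF, ph=7.0, gases={"CO2": ATM_PA})
        with pytest.raises(ActivityError, match="H2"):
            reaction_quotient_ln(HYDROGENOTROPHIC_METHANOGENESIS, state)

    @given(st.integers(0, 10_000))
    def test_lnq_matches_product_of_activities_oracle(self, seed):
        """ln Q equals the log of a brute-force product of powered activities."""
        rng = np.random.default_rng(seed)
        state = random_admissible_state(rng)
        table = ThermoTable.default()
        for reaction in (PROPIONATE_OXIDATION, ACETATE_OXIDATION,
                         HYDROGENOTROPHIC_METHANOGENESIS, OVERALL_MINERALISATION):
            product = 1.0
            for name, nu in reaction.stoichiometry.items():
                sp = table.species(name)
                if sp.phase == "water":
                    a = 1.0
                elif sp.name == "H+":
                    a = 10.0 ** (-state.ph)
                elif sp.phase == "gas":
                    a = state.gases[name] / ATM_PA
                else:
                    a = state.solutes[name]
                product *= a ** nu
            assert reaction_quotient_ln(reaction, state) == pytest.approx(
                math.log(product), rel=1e-9, abs=1e-9
            )


class TestDeltaGAtState:
    def test_q_of_one_at_reference_reduces_to_dg0(self):
        state = ThermodynamicState(
            temperature=T_REF, ph=7.0, gases={"H2": ATM_PA, "CO2": ATM_PA, "CH4": ATM_PA}
        )
        assert delta_g_at_state(HYDROGENOTROPHIC_METHANOGENESIS, state) == pytest.approx(
            delta_g_standard(HYDROGENOTROPHIC_METHANOGENESIS), abs=1e-9
        )

    def test_hess_linearity_at_state(self, seed=7):
        rng = np.random.default_rng(seed)
        state = random_admissible_state(rng)
        summed = PROPIONATE_OXIDATION + ACETATE_OXIDATION
        assert delta_g_at_state(summed, state) == pytest.approx(
            delta_g_at_state(PROPIONATE_OXIDATION, state)
            + delta_g_at_state(ACETATE_OXIDATION, state),
            abs=1e-9,
        )

    def test_propionate_oxidation_in_reported_band_at_batch_state(self):
        """At a representative batch state the SPO reaction sits in the
        -10..-30 kJ band reported for these cultures."""
        state = ThermodynamicState(
            temperature=325.15,
            ph=8.5,
            solutes={"propionate": 0.03, "acetate": 0.03},
            gases={"H2": 8.0, "CO2": 0.3 * ATM_PA},
        )
        dg = delta_g_at_state(PROPIONATE_OXIDATION, state)
        assert -30.0 < dg < -10.0

    @given(st.integers(0, 10_000))
    def test_dg_slope_in_ln_ph2_is_n_rt(self, seed):
        """For a reaction producing n mol H2, dΔG/d(ln pH2) = n·R·T."""
        rng = np.random.default_rng(seed)
        state = random_admissible_state(rng)
        p1 = state.gases["H2"]
        p2 = p1 * 3.7
        for reaction, n in ((PROPIONATE_OXIDATION, 3.0), (ACETATE_OXIDATION, 4.0),
                            (HYDROGENOTROPHIC_METHANOGENESIS, -4.0)):
            slope = (
                delta_g_at_state(reaction, state.with_gas("H2", p2))
                - delta_g_at_state(reaction, state.with_gas("H2", p1))
            ) / math.log(p2 / p1)
            assert slope == pytest.approx(n * R_KJ * state.temperature, rel=1e-9)


class TestValidation:
    def test_packaged_reactions_are_balanced(self):
        for rxn in (PROPIONATE_OXIDATION, ACETATE_OXIDATION,
                    HYDROGENOTROPHIC_METHANOGENESIS, ACETICLASTIC_NET,
                    OVERALL_MINERALISATION):
            assert validate_reaction(rxn) == []

    def test_acetate_oxidation_as_misprinted_is_oxygen_unbalanced(self):
        # the widely circulated misprint writes the products as 2 CO2 + 4 H2O;
        # hydrogen happens to balance (8 = 8) but oxygen does not (4 vs 8)
        misprint = ReactionScheme(
            "acetate_oxidation_misprint",
            {"acetate": -1, "H+": -1, "H2O": -2 + 4, "CO2": 2},
        )
        violations = validate_reaction(misprint)
        assert violations and any("element O" in v for v in violations)
        assert not any("element H" in v for v in violations)

    def test_single_electron_charge_imbalance_named(self):
        rxn = ReactionScheme("charged", {"H+": 1.0})
        violations = validate_reaction(rxn)
        assert any("charge" in v for v in violations)

    def test_parse_formula(self):
        assert parse_formula("C3H5O2") == {"C": 3, "H": 5, "O": 2}
        assert parse_formula("H") == {"H": 1}
        with pytest.raises(ValidationError):
            parse_formula("3H")

    def test_state_validation(self):
        with pytest.raises(ValidationError):
            ThermodynamicState(temperature=200.0, ph=7.0)
        with pytest.raises(ValidationError):
            ThermodynamicState(temperature=300.0, ph=15.0)
        with pytest.raises(ValidationError):
            ThermodynamicState(temperature=300.0, ph=7.0, solutes={"acetate": -1.0})
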