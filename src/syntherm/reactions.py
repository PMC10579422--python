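"""The guild reactions of the dual propionate syntrophy.

Three guilds chain propionate to methane: syntrophic propionate oxidisers
(SPO) convert propionate to acetate, CO2 and 3 H2; syntrophic acetate
oxidisers (SAO) convert acetate to 2 CO2 and 4 H2; hydrogenotrophic
methanogens (HM) reduce CO2 with 4 H2 to CH4. Summed with weights
(1, 1, 1.75) the intermediates cancel and one mole of propionate is
mineralised to 1.75 CH4 + 1.25 CO2 (7 H2 = 4 from SAO + 3 from SPO).

Formate-carrier variants replace each n H2 by n formate⁻ + n H⁺ − n CO2
(via H2 + CO2 ⇌ formate⁻ + H⁺); both electron carriers were seen expressed
in these communities. A bicarbonate-referenced set is provided for users who
prefer dissolved-inorganic-carbon bookkeeping; the gaseous-CO2 set is the
default because the guild equations are conventionally written with CO2(g).
"""

from __future__ import annotations

from typing import Dict

from .thermo import ReactionScheme

# --- hydrogen-carrier reaction set -----------------------------------------

#: SPO: propionate⁻ + 2 H2O → acetate⁻ + CO2 + 3 H2
PROPIONATE_OXIDATION = ReactionScheme(
    "propionate_oxidation_h2",
    {"propionate": -1, "H2O": -2, "acetate": 1, "CO2": 1, "H2": 3},
)

#: SAO: acetate⁻ + H⁺ + 2 H2O → 2 CO2 + 4 H2
ACETATE_OXIDATION = ReactionScheme(
    "acetate_oxidation_h2",
    {"acetate": -1, "H+": -1, "H2O": -2, "CO2": 2, "H2": 4},
)

#: HM: 4 H2 + CO2 → CH4 + 2 H2O
HYDROGENOTROPHIC_METHANOGENESIS = ReactionScheme(
    "hydrogenotrophic_methanogenesis",
    {"H2": -4, "CO2": -1, "CH4": 1, "H2O": 2},
)

#: Net aceticlastic conversion: acetate⁻ + H⁺ → CH4 + CO2
ACETICLASTIC_NET = ReactionScheme(
    "aceticlastic_net",
    {"acetate": -1, "H+": -1, "CH4": 1, "CO2": 1},
)

#: Overall mineralisation: propionate⁻ + H⁺ + ½ H2O → 1.75 CH4 + 1.25 CO2
OVERALL_MINERALISATION = ReactionScheme(
    "overall_mineralisation",
    {"propionate": -1, "H+": -1, "H2O": -0.5, "CH4": 1.75, "CO2": 1.25},
)

#: Electron-carrier interconversion: H2 + CO2 → formate⁻ + H⁺
CARRIER_INTERCONVERSION = ReactionScheme(
    "h2_formate_interconversion",
    {"H2": -1, "CO2": -1, "formate": 1, "H+": 1},
)

# --- formate-carrier variants ----------------------------------------------

PROPIONATE_OXIDATION_FORMATE = ReactionScheme(
    "propionate_oxidation_formate",
    {"propionate": -1, "H2O": -2, "CO2": -2, "acetate": 1, "formate": 3, "H+": 3},
)

ACETATE_OXIDATION_FORMATE = ReactionScheme(
    "acetate_oxidation_formate",
    {"acetate": -1, "H2O": -2, "CO2": -2, "formate": 4, "H+": 3},
)

FORMATE_METHANOGENESIS = ReactionScheme(
    "formate_methanogenesis",
    {"formate": -4, "H+": -4, "CH4": 1, "CO2": 3, "H2O": 2},
)

# --- bicarbonate-referenced alternates (not default) ------------------------

PROPIONATE_OXIDATION_BICARB = ReactionScheme(
    "propionate_oxidation_h2_bicarbonate",
    {"propionate": -1, "H2O": -3, "acetate": 1, "bicarbonate": 1, "H+": 1, "H2": 3},
)

ACETATE_OXIDATION_BICARB = ReactionScheme(
    "acetate_oxidation_h2_bicarbonate",
    {"acetate": -1, "H2O": -4, "bicarbonate": 2, "H+": 1, "H2": 4},
)

METHANOGENESIS_BICARB = ReactionScheme(
    "hydrogenotrophic_methanogenesis_bicarbonate",
    {"H2": -4, "bicarbonate": -1, "H+": -1, "CH4": 1, "H2O": 3},
)

#: Weights turning per-reaction ΔG into kJ per mole of propionate mineralised.
GUILD_WEIGHTS: Dict[str, float] = {"spo": 1.0, "sao": 1.0, "hm": 1.75}


def guild_reactions(carrier: str = "hydrogen") -> Dict[str, ReactionScheme]:
    """The SPO/SAO/HM reaction set for the chosen electron carrier."""
    if carrier == "hydrogen":
        return {
            "spo": PROPIONATE_OXIDATION,
            "sao": ACETATE_OXIDATION,
            "hm": HYDROGENOTROPHIC_METHANOGENESIS,
        }
    if carrier == "formate":
        return {
            "spo": PROPIONATE_OXIDATION_FORMATE,
            "sao": ACETATE_OXIDATION_FORMATE,
            "hm": FORMATE_METHANOGENESIS,
        }
    raise ValueError(f"carrier must be 'hydrogen' or 'formate', got {carrier!r}")
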