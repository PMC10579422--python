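"""Per-guild in-situ Gibbs energies and the per-propionate energy partition.

Because one mole of mineralised propionate drives the SPO reaction once,
the SAO reaction once and the methanogenic reaction 1.75 times
(3 H2 from SPO + 4 H2 from SAO = 7 H2 = 1.75 × 4 H2), the energy available
to each guild per mole of propionate is the per-reaction ΔG weighted by
(1, 1, 1.75). The weighted sum equals the ΔG of the overall mineralisation
scheme at the same state — the intermediates cancel exactly — which serves
as a built-in conservation check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

import pandas as pd

from .reactions import (
    CARRIER_INTERCONVERSION,
    GUILD_WEIGHTS,
    OVERALL_MINERALISATION,
    guild_reactions,
)
from .thermo import ThermodynamicState, ThermoTable, delta_g_at_state


@dataclass(frozen=True)
class GuildEnergyReport:
    """Per-guild ΔG values and the per-mole-propionate energy partition.

    ``dg_spo`` is kJ per mol propionate oxidised, ``dg_sao`` kJ per mol
    acetate oxidised, ``dg_hm`` kJ per mol CH4 formed; ``per_propionate``
    rescales each guild to kJ per mol propionate mineralised and ``total``
    is their sum (= ΔG of the overall scheme).
    """

    dg_spo: float
    dg_sao: float
    dg_hm: float
    per_propionate: Dict[str, float]
    total: float
    carrier: str

    def to_frame(self) -> pd.DataFrame:
        reactions = guild_reactions(self.carrier)
        rows = []
        for guild, dg in zip(("spo", "sao", "hm"), (self.dg_spo, self.dg_sao, self.dg_hm)):
            rows.append(
                {
                    "guild": guild,
                    "reaction": reactions[guild].name,
                    "dg_kj": dg,
                    "weight": GUILD_WEIGHTS[guild],
                    "dg_per_propionate_kj": self.per_propionate[guild],
                }
            )
        return pd.DataFrame(rows)


def guild_energies(
    state: ThermodynamicState,
    carrier: str = "hydrogen",
    table: Optional[ThermoTable] = None,
) -> GuildEnergyReport:
    """Evaluate ΔG of the three guild reactions at ``state``.

    The state must supply activities for every species of the chosen
    carrier's reaction set (propionate, acetate, CO2, CH4 and H2 — plus
    formate when ``carrier="formate"``).
    """
    reactions = guild_reactions(carrier)
    dg = {g: delta_g_at_state(r, state, table) for g, r in reactions.items()}
    per_propionate = {g: GUILD_WEIGHTS[g] * dg[g] for g in dg}
    return GuildEnergyReport(
        dg_spo=dg["spo"],
        dg_sao=dg["sao"],
        dg_hm=dg["hm"],
        per_propionate=per_propionate,
        total=math.fsum(per_propionate.values()),
        carrier=carrier,
    )


def overall_delta_g(
    state: ThermodynamicState, table: Optional[ThermoTable] = None
) -> float:
    """ΔG of propionate⁻ + H⁺ + ½H2O → 1.75 CH4 + 1.25 CO2 at ``state``."""
    return delta_g_at_state(OVERALL_MINERALISATION, state, table)


def carrier_equilibrium_check(
    state: ThermodynamicState, table: Optional[ThermoTable] = None
) -> float:
    """ΔG of H2 + CO2 ⇌ formate⁻ + H⁺ at ``state`` (kJ).

    Zero indicates the two electron carriers are at interconversion
    equilibrium, at which the hydrogen- and formate-based partitions agree.
    """
    return delta_g_at_state(CARRIER_INTERCONVERSION, state, table)
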