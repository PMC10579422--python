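"""Hydrogen-partial-pressure feasibility windows.

For a fixed background state (acids, CO2, CH4, pH, T), the in-situ ΔG of any
reaction with H2 coefficient n is linear in ln pH2:

    ΔG(pH2) = A + n·R·T·ln(pH2/1 atm),   A = ΔG at pH2 = 1 atm.

An H2-producing guild (SPO or SAO, n > 0) therefore needs pH2 *below* an
upper bound to stay exergonic beyond a threshold, while the H2-consuming
methanogen (n < 0) needs pH2 *above* a lower bound. The overlap is the
window in which the syntrophy can operate; it is empty when the threshold
is too demanding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .errors import ValidationError
from .reactions import guild_reactions
from .thermo import (
    ATM_PA,
    R_KJ,
    ReactionScheme,
    ThermodynamicState,
    ThermoTable,
    delta_g_at_state,
)


@dataclass(frozen=True)
class H2Window:
    """Feasible hydrogen partial-pressure interval, in Pa.

    ``lower`` comes from the H2-consuming reaction, ``upper`` from the
    H2-producing one; both reactions attain exactly ``threshold`` kJ at
    their respective endpoint. ``empty`` flags lower > upper.
    """

    lower: float
    upper: float
    threshold: float
    empty: bool


def h2_window(
    producer: ReactionScheme,
    consumer: ReactionScheme,
    state_without_h2: ThermodynamicState,
    threshold: float = 0.0,
    table: Optional[ThermoTable] = None,
) -> H2Window:
    """Closed-form window where both reactions have ΔG ≤ ``threshold``.

    ``state_without_h2`` fixes every activity except H2 (any H2 entry in it
    is ignored and replaced). The producer must have a positive H2
    coefficient and the consumer a negative one.
    """
    n_p = producer.coefficient("H2")
    n_c = consumer.coefficient("H2")
    if n_p <= 0:
        raise ValidationError(
            f"producer {producer.name!r} must have a positive H2 coefficient, got {n_p}"
        )
    if n_c >= 0:
        raise ValidationError(
            f"consumer {consumer.name!r} must have a negative H2 coefficient, got {n_c}"
        )
    ref = state_without_h2.with_gas("H2", ATM_PA)  # pH2 = 1 atm -> ln term = 0
    rt = R_KJ * ref.temperature
    a_p = delta_g_at_state(producer, ref, table)
    a_c = delta_g_at_state(consumer, ref, table)
    upper = math.exp((threshold - a_p) / (n_p * rt)) * ATM_PA
    lower = math.exp((a_c - threshold) / (abs(n_c) * rt)) * ATM_PA
    return H2Window(lower=lower, upper=upper, threshold=threshold, empty=lower > upper)


def window_report(
    state_without_h2: ThermodynamicState,
    thresholds: Sequence[float] = (0.0, -10.0),
    table: Optional[ThermoTable] = None,
) -> pd.DataFrame:
    """Tabulate SPO/HM and SAO/HM windows over the given ΔG thresholds.

    Both a zero threshold (strict exergonicity) and −10 kJ (a commonly used
    minimum energy quantum) are reported by default.
    """
    reactions = guild_reactions("hydrogen")
    rows = []
    for pair_name, producer in (("spo/hm", reactions["spo"]), ("sao/hm", reactions["sao"])):
        for threshold in thresholds:
            w = h2_window(producer, reactions["hm"], state_without_h2, threshold, table)
            rows.append(
                {
                    "pair": pair_name,
                    "threshold_kj": threshold,
                    "lower_pa": w.lower,
                    "upper_pa": w.upper,
                    "empty": w.empty,
                }
            )
    return pd.DataFrame(rows)
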