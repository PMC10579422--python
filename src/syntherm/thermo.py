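"""Gibbs-energy bookkeeping for anaerobic guild reactions.

The module turns a table of standard formation energies into standard and
in-situ reaction Gibbs energies:

* ``delta_g_standard`` — ΔG° at 298.15 K from stoichiometry-weighted
  formation energies,
* ``delta_g_standard_at_temperature`` — Gibbs–Helmholtz correction with
  temperature-independent ΔH°,
* ``reaction_quotient_ln`` — ln Q from a culture snapshot (solutes vs 1 M,
  gases vs 1 atm, water activity 1, H⁺ via 10^−pH),
* ``delta_g_at_state`` — ΔG = ΔG°(T) + RT ln Q.

Conventions: energies in kJ per mole of reaction as written; temperatures in
kelvin; solute concentrations in mol L⁻¹; gas partial pressures in Pa at the
API boundary (converted to atm internally, 101325 Pa/atm). Activity
coefficients and ionic-strength corrections are deliberately out of scope.
"""

from __future__ import annotations

import csv
import io
import math
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Union

from .errors import (
    ActivityError,
    ReactionBalanceError,
    SpeciesLookupError,
    ValidationError,
)

#: Gas constant, kJ mol⁻¹ K⁻¹.
R_KJ = 8.314e-3
#: Reference temperature of the formation tables, K.
T_REF = 298.15
#: Pascals per standard atmosphere (gas standard state).
ATM_PA = 101325.0

LN10 = math.log(10.0)

_PHASES = ("gas", "aqueous", "water")
_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Dict[str, int]:
    """Parse an empirical formula like ``"C3H5O2"`` into element counts."""
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(text):
        if match.start() != pos:
            raise ValidationError(f"cannot parse formula {text!r} at position {pos}")
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise ValidationError(f"cannot parse formula {text!r} at position {pos}")
    return counts


@dataclass(frozen=True)
class ChemicalSpecies:
    """A named compound with phase and standard formation thermodynamics.

    ``dgf0`` and ``dhf0`` are the standard Gibbs energy and enthalpy of
    formation at 298.15 K in kJ mol⁻¹ (1 M aqueous / 1 atm gas standard
    states, elemental convention for H2 and H⁺).
    """

    name: str
    formula: Mapping[str, int]
    charge: int
    phase: str
    dgf0: float
    dhf0: float

    def __post_init__(self) -> None:
        if self.phase not in _PHASES:
            raise ValidationError(
                f"species {self.name!r}: phase must be one of {_PHASES}, got {self.phase!r}"
            )
        if not (math.isfinite(self.dgf0) and math.isfinite(self.dhf0)):
            raise ValidationError(f"species {self.name!r}: non-finite formation energy")
        for element, count in self.formula.items():
            if not (isinstance(count, int) and count >= 0):
                raise ValidationError(
                    f"species {self.name!r}: element count {element}={count!r} "
                    "must be a non-negative integer"
                )
        if not isinstance(self.charge, int):
            raise ValidationError(f"species {self.name!r}: charge must be an integer")


@dataclass(frozen=True)
class ReactionScheme:
    """A stoichiometric map over species names.

    Products carry positive coefficients, reactants negative. Coefficients
    may be fractional (the overall mineralisation uses 1.75 CH4).
    """

    name: str
    stoichiometry: Mapping[str, float]

    def coefficient(self, species: str) -> float:
        return self.stoichiometry.get(species, 0.0)

    def scaled(self, factor: float, name: Optional[str] = None) -> "ReactionScheme":
        return ReactionScheme(
            name or f"{factor}*{self.name}",
            {s: factor * nu for s, nu in self.stoichiometry.items()},
        )

    def __add__(self, other: "ReactionScheme") -> "ReactionScheme":
        merged: Dict[str, float] = dict(self.stoichiometry)
        for species, nu in other.stoichiometry.items():
            merged[species] = merged.get(species, 0.0) + nu
        merged = {s: nu for s, nu in merged.items() if nu != 0.0}
        return ReactionScheme(f"{self.name}+{other.name}", merged)


@dataclass(frozen=True)
class ThermodynamicState:
    """One snapshot of a culture: T, pH, solute molarities, gas pressures.

    ``solutes`` maps species name to mol L⁻¹; ``gases`` maps species name to
    partial pressure in Pa.
    """

    temperature: float
    ph: float
    solutes: Mapping[str, float] = field(default_factory=dict)
    gases: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.temperature > 273.15:
            raise ValidationError(f"temperature {self.temperature} K must exceed 273.15 K")
        if not 0.0 < self.ph < 14.0:
            raise ValidationError(f"pH {self.ph} outside (0, 14)")
        for pool, unit in ((self.solutes, "mol/L"), (self.gases, "Pa")):
            for species, value in pool.items():
                if value < 0:
                    raise ValidationError(f"{species}: negative value {value} {unit}")

    def with_gas(self, species: str, partial_pressure_pa: float) -> "ThermodynamicState":
        gases = dict(self.gases)
        gases[species] = partial_pressure_pa
        return replace(self, gases=gases)

    def with_solute(self, species: str, molar: float) -> "ThermodynamicState":
        solutes = dict(self.solutes)
        solutes[species] = molar
        return replace(self, solutes=solutes)


class ThermoTable:
    """Registry of :class:`ChemicalSpecies` keyed by name.

    The packaged default ships as a versioned TSV resource; user tables in
    the same dialect load via :meth:`from_tsv`.
    """

    def __init__(self, species: Mapping[str, ChemicalSpecies]):
        self._species = dict(species)

    def __contains__(self, name: str) -> bool:
        return name in self._species

    def __iter__(self):
        return iter(self._species.values())

    def species(self, name: str) -> ChemicalSpecies:
        try:
            return self._species[name]
        except KeyError:
            raise SpeciesLookupError(
                f"species {name!r} not in thermodynamic table "
                f"(available: {sorted(self._species)})"
            ) from None

    @classmethod
    def from_rows(cls, rows) -> "ThermoTable":
        species = {}
        for row in rows:
            sp = ChemicalSpecies(
                name=row["name"],
                formula=parse_formula(row["formula"]),
                charge=int(row["charge"]),
                phase=row["phase"],
                dgf0=float(row["dgf0_kj_mol"]),
                dhf0=float(row["dhf0_kj_mol"]),
            )
            species[sp.name] = sp
        return cls(species)

    @classmethod
    def from_tsv(cls, path: Union[str, Path, io.TextIOBase]) -> "ThermoTable":
        if isinstance(path, io.TextIOBase):
            text = path.read()
        else:
            text = Path(path).read_text()
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        return cls.from_rows(csv.DictReader(lines, delimiter="\t"))

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "ThermoTable":
        text = resources.files("syntherm.data").joinpath("thermo_table.tsv").read_text()
        return cls.from_tsv(io.StringIO(text))


def _table(table: Optional[ThermoTable]) -> ThermoTable:
    return table if table is not None else ThermoTable.default()


def validate_reaction(
    reaction: ReactionScheme, table: Optional[ThermoTable] = None
) -> List[str]:
    """Report element and charge balance violations (empty list iff balanced)."""
    table = _table(table)
    residuals: Dict[str, float] = {}
    charge = 0.0
    for name, nu in reaction.stoichiometry.items():
        sp = table.species(name)
        for element, count in sp.formula.items():
            residuals[element] = residuals.get(element, 0.0) + nu * count
        charge += nu * sp.charge
    violations = [
        f"element {element} residual {residual:+g}"
        for element, residual in sorted(residuals.items())
        if abs(residual) > 1e-9
    ]
    if abs(charge) > 1e-9:
        violations.append(f"charge residual {charge:+g}")
    return violations


def _require_balanced(reaction: ReactionScheme, table: ThermoTable) -> None:
    violations = validate_reaction(reaction, table)
    if violations:
        raise ReactionBalanceError(
            f"reaction {reaction.name!r} is unbalanced: " + "; ".join(violations)
        )


def delta_g_standard(
    reaction: ReactionScheme, table: Optional[ThermoTable] = None
) -> float:
    """ΔG° at 298.15 K, kJ per mole of reaction as written."""
    table = _table(table)
    _require_balanced(reaction, table)
    return sum(nu * table.species(s).dgf0 for s, nu in reaction.stoichiometry.items())


def delta_h_standard(
    reaction: ReactionScheme, table: Optional[ThermoTable] = None
) -> float:
    """ΔH° at 298.15 K, kJ per mole of reaction as written."""
    table = _table(table)
    _require_balanced(reaction, table)
    return sum(nu * table.species(s).dhf0 for s, nu in reaction.stoichiometry.items())


def delta_g_standard_at_temperature(
    reaction: ReactionScheme,
    table: Optional[ThermoTable] = None,
    temperature: float = T_REF,
) -> float:
    """ΔG°(T) by Gibbs–Helmholtz with temperature-independent ΔH°.

    ΔG°(T) = (T/T°)·ΔG°(T°) + (1 − T/T°)·ΔH°(T°). Valid for liquid-water
    systems between 273.15 and 373.15 K; heat-capacity terms are omitted.
    """
    if not 273.15 <= temperature <= 373.15:
        raise ValidationError(
            f"temperature {temperature} K outside the supported 273.15–373.15 K range"
        )
    ratio = temperature / T_REF
    return ratio * delta_g_standard(reaction, table) + (1.0 - ratio) * delta_h_standard(
        reaction, table
    )


def ln_activity(
    species: ChemicalSpecies, state: ThermodynamicState
) -> float:
    """ln of the activity of one species at a state.

    Water is taken at unit activity; H⁺ at 10^−pH; gases against 1 atm;
    aqueous solutes against 1 M.
    """
    if species.phase == "water":
        return 0.0
    if species.name == "H+":
        return -state.ph * LN10
    if species.phase == "gas":
        p = state.gases.get(species.name, 0.0)
        if p <= 0.0:
            raise ActivityError(
                f"gas {species.name!r} has zero/absent partial pressure; "
                "ΔG is undefined at zero activity"
            )
        return math.log(p / ATM_PA)
    c = state.solutes.get(species.name, 0.0)
    if c <= 0.0:
        raise ActivityError(
            f"solute {species.name!r} has zero/absent concentration; "
            "ΔG is undefined at zero activity"
        )
    return math.log(c)


def reaction_quotient_ln(
    reaction: ReactionScheme,
    state: ThermodynamicState,
    table: Optional[ThermoTable] = None,
) -> float:
    """ln Q = Σ ν·ln a over the reaction's species at the given state."""
    table = _table(table)
    return sum(
        nu * ln_activity(table.species(name), state)
        for name, nu in reaction.stoichiometry.items()
    )


def delta_g_at_state(
    reaction: ReactionScheme,
    state: ThermodynamicState,
    table: Optional[ThermoTable] = None,
) -> float:
    """In-situ ΔG = ΔG°(T) + R·T·ln Q, kJ per mole of reaction as written."""
    table = _table(table)
    dg0 = delta_g_standard_at_temperature(reaction, table, state.temperature)
    return dg0 + R_KJ * state.temperature * reaction_quotient_ln(reaction, state, table)
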