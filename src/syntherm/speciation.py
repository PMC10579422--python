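"""Aqueous chemistry linking raw measurements to thermodynamic states.

Covers the three conversions needed before any ΔG can be evaluated on a
digester sample: the unionized (free) ammonia fraction of total ammonia
nitrogen, Henderson–Hasselbalch dissociation of the volatile fatty acids,
and Henry's-law partitioning between headspace partial pressures and
dissolved concentrations.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Union

from .errors import SpeciesLookupError, ValidationError
from .thermo import ATM_PA, T_REF

#: Molar masses, g mol⁻¹.
N_MOLAR_MASS = 14.007
NH3_MOLAR_MASS = 17.031


@dataclass(frozen=True)
class AmmoniaResult:
    """Free-ammonia speciation of a total-ammonia-nitrogen (TAN) pool.

    ``nh3_n`` expresses the unionized pool on a nitrogen-mass basis
    (g N L⁻¹); ``nh3_mass`` on an NH3-mass basis (g NH3 L⁻¹). Both are
    reported because the two bases differ by 17.031/14.007 and field reports
    rarely say which one they use.
    """

    fraction_unionized: float
    nh3_n: float
    nh3_mass: float


def free_ammonia(tan: float, ph: float, temperature: float) -> AmmoniaResult:
    """Unionized ammonia from TAN (g N L⁻¹), pH and temperature (K).

    Uses the Anthonisen-form fraction 10^pH / (exp(6344/T) + 10^pH), which
    folds the temperature dependence of the NH4⁺ acidity constant into the
    exp(6344/T) term. The fraction rises with both pH and temperature.
    """
    if tan < 0:
        raise ValidationError(f"TAN must be non-negative, got {tan}")
    if not 0.0 < ph < 14.0:
        raise ValidationError(f"pH {ph} outside (0, 14)")
    if not 273.15 < temperature < 373.15:
        raise ValidationError(f"temperature {temperature} K outside liquid-water range")
    ten_ph = 10.0 ** ph
    fraction = ten_ph / (math.exp(6344.0 / temperature) + ten_ph)
    nh3_n = tan * fraction
    return AmmoniaResult(
        fraction_unionized=fraction,
        nh3_n=nh3_n,
        nh3_mass=nh3_n * NH3_MOLAR_MASS / N_MOLAR_MASS,
    )


def fraction_dissociated(pka: float, ph: float) -> float:
    """Henderson–Hasselbalch anion fraction 1/(1 + 10^(pKa − pH))."""
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


@dataclass(frozen=True)
class HenryConstant:
    """Henry solubility at 298.15 K with a van't Hoff temperature slope.

    ``kh_298`` in mol L⁻¹ atm⁻¹; ``vant_hoff`` is d(ln kH)/d(1/T) in K, so
    kH(T) = kh_298 · exp(vant_hoff · (1/T − 1/298.15)).
    """

    name: str
    kh_298: float
    vant_hoff: float

    def at(self, temperature: float) -> float:
        return self.kh_298 * math.exp(
            self.vant_hoff * (1.0 / temperature - 1.0 / T_REF)
        )


class HenryTable:
    """Henry constants keyed by species name, loaded from the TSV resource."""

    def __init__(self, constants: Dict[str, HenryConstant]):
        self._constants = dict(constants)

    def constant(self, name: str) -> HenryConstant:
        try:
            return self._constants[name]
        except KeyError:
            raise SpeciesLookupError(
                f"no Henry constant for {name!r} (available: {sorted(self._constants)})"
            ) from None

    @classmethod
    def from_tsv(cls, path: Union[str, Path, io.TextIOBase]) -> "HenryTable":
        text = path.read() if isinstance(path, io.TextIOBase) else Path(path).read_text()
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        constants = {}
        for row in csv.DictReader(lines, delimiter="\t"):
            constants[row["name"]] = HenryConstant(
                name=row["name"],
                kh_298=float(row["kh_298_mol_l_atm"]),
                vant_hoff=float(row["vant_hoff_K"]),
            )
        return cls(constants)

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "HenryTable":
        text = resources.files("syntherm.data").joinpath("henry_constants.tsv").read_text()
        return cls.from_tsv(io.StringIO(text))


def dissolved_from_partial_pressure(
    species: str,
    partial_pressure: float,
    temperature: float,
    table: Optional[HenryTable] = None,
) -> float:
    """Dissolved concentration (mol L⁻¹) in Henry equilibrium with a gas.

    ``partial_pressure`` in Pa; converted to atm against the 1 atm standard
    state before applying kH(T).
    """
    if partial_pressure < 0:
        raise ValidationError(f"partial pressure must be non-negative, got {partial_pressure}")
    table = table if table is not None else HenryTable.default()
    kh = table.constant(species).at(temperature)
    return kh * (partial_pressure / ATM_PA)


def partial_pressure_from_dissolved(
    species: str,
    concentration: float,
    temperature: float,
    table: Optional[HenryTable] = None,
) -> float:
    """Inverse of :func:`dissolved_from_partial_pressure`; returns Pa."""
    if concentration < 0:
        raise ValidationError(f"concentration must be non-negative, got {concentration}")
    table = table if table is not None else HenryTable.default()
    kh = table.constant(species).at(temperature)
    return concentration / kh * ATM_PA


@lru_cache(maxsize=1)
def acid_pka_table() -> Dict[str, float]:
    """pKa values (298.15 K) of the packaged volatile fatty acids."""
    text = resources.files("syntherm.data").joinpath("acid_pka.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return {row["name"]: float(row["pka"]) for row in csv.DictReader(lines, delimiter="\t")}
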