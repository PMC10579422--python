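"""Seeded batch simulator of the dual propionate syntrophy.

A serum-bottle mass-balance model of three guilds — syntrophic propionate
oxidisers (SPO), syntrophic acetate oxidisers (SAO) and hydrogenotrophic
methanogens (HM) — growing on Monod kinetics throttled by a thermodynamic
limitation factor

    F_T = max(0, 1 − exp((ΔG + ΔG_min)/(R·T))),

with ΔG evaluated from the packaged thermodynamic table at the instantaneous
state. H2, CO2 and CH4 partition instantaneously between liquid and a fixed
headspace by Henry equilibrium; pH and temperature are held constant
(bicarbonate-buffered medium). Anabolic carbon is drawn from (and returned
to by decay) the CO2 pool so that total carbon closes exactly while the
catabolic stoichiometry — and hence the 1.75 CH4 per propionate — is
untouched.

The gas pools are tiny (a few Pa of H2 against mol-per-day fluxes), which
makes the system stiff with relaxation times of seconds; integration
therefore uses the implicit-capable LSODA solver rather than an explicit
fixed-step scheme.

``simulate`` returns a noiseless :class:`~syntherm.kinetics.BatchTimeSeries`;
``observe`` overlays seeded multiplicative lognormal measurement noise.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ComputationError, ValidationError
from .kinetics import BatchTimeSeries
from .reactions import guild_reactions
from .speciation import HenryTable, acid_pka_table, fraction_dissociated
from .thermo import (
    ATM_PA,
    R_KJ,
    ThermoTable,
    delta_g_standard_at_temperature,
)

#: Ideal-gas constant in headspace units, L atm mol⁻¹ K⁻¹.
R_L_ATM = 0.0820574
#: Grams of biomass per mole of biomass carbon (CH1.8O0.5N0.2).
BIOMASS_G_PER_MOL_C = 24.63
#: Concentration floor below which a substrate is treated as exhausted.
FLOOR_M = 1e-9


@dataclass(frozen=True)
class GuildParameters:
    """Kinetic parameters of one guild.

    ``vmax`` in mol substrate (g biomass)⁻¹ day⁻¹ (substrate = the acid for
    SPO/SAO, H2 for HM), ``ks`` in mol L⁻¹ of the same substrate,
    ``yield_g_per_mol`` in g biomass per mol substrate, ``decay`` in day⁻¹
    and ``dg_min`` the minimum energy quantum (kJ per guild reaction) that
    offsets ΔG inside the limitation factor F_T.
    """

    vmax: float
    ks: float
    yield_g_per_mol: float
    decay: float
    dg_min: float = 10.0

    def __post_init__(self) -> None:
        if self.ks <= 0:
            raise ValidationError("ks must be strictly positive")
        for name in ("vmax", "yield_g_per_mol", "decay", "dg_min"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SimulationScenario:
    """Initial state, physics and observation plan of one batch assay."""

    name: str = "scenario"
    temperature: float = 325.15          # K
    ph: float = 8.5
    liquid_volume: float = 0.5           # L
    headspace_ratio: float = 1.0         # headspace:liquid
    propionate0: float = 0.037           # mol/L
    acetate0: float = 0.004              # mol/L
    formate0: float = 1e-4               # mol/L, inert residual
    h2_pa0: float = 1.0
    co2_atm0: float = 0.30
    ch4_atm0: float = 1e-4
    biomass0: Dict[str, float] = field(
        default_factory=lambda: {"spo": 0.02, "sao": 0.005, "hm": 0.03}
    )
    guilds: Dict[str, GuildParameters] = field(
        default_factory=lambda: {
            "spo": GuildParameters(0.038, 1.0e-3, 2.5, 0.01, 10.0),
            "sao": GuildParameters(0.055, 1.5e-2, 2.2, 0.01, 3.0),
            "hm": GuildParameters(1.2, 6.0e-8, 0.3, 0.01, 12.0),
        }
    )
    t_end: float = 100.0                 # days
    interval: float = 1.0                # days between observations
    noise_cv: float = 0.05
    seed: int = 12021

    @property
    def headspace_volume(self) -> float:
        return self.liquid_volume * self.headspace_ratio

    @classmethod
    def from_toml(cls, path: Union[str, Path]) -> "SimulationScenario":
        raw = tomllib.loads(Path(path).read_text())
        return cls._from_mapping(raw)

    @classmethod
    def default(cls) -> "SimulationScenario":
        raw = tomllib.loads(
            resources.files("syntherm.data").joinpath("scenario_default.toml").read_text()
        )
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw) -> "SimulationScenario":
        cond = raw["conditions"]
        init = raw["initial"]
        obs = raw["observation"]
        guilds = {
            g: GuildParameters(
                vmax=raw[g]["vmax"],
                ks=raw[g]["ks"],
                yield_g_per_mol=raw[g]["yield_g_per_mol"],
                decay=raw[g]["decay"],
                dg_min=raw[g].get("dg_min", 10.0),
            )
            for g in ("spo", "sao", "hm")
        }
        return cls(
            name=raw.get("name", "scenario"),
            temperature=cond["temperature_K"],
            ph=cond["ph"],
            liquid_volume=cond["liquid_volume_L"],
            headspace_ratio=cond["headspace_ratio"],
            propionate0=init["propionate_mM"] / 1000.0,
            acetate0=init["acetate_mM"] / 1000.0,
            formate0=init.get("formate_mM", 0.1) / 1000.0,
            h2_pa0=init["h2_pa"],
            co2_atm0=init["co2_atm"],
            ch4_atm0=init["ch4_atm"],
            biomass0={
                "spo": init["biomass_spo_g_L"],
                "sao": init["biomass_sao_g_L"],
                "hm": init["biomass_hm_g_L"],
            },
            guilds=guilds,
            t_end=obs["t_end_days"],
            interval=obs["interval_days"],
            noise_cv=obs["noise_cv"],
            seed=obs["seed"],
        )


class _Physics:
    """Precomputed constants for one scenario (T-corrected ΔG°, Henry, gas)."""

    def __init__(self, scenario: SimulationScenario, table: Optional[ThermoTable]):
        s = scenario
        t = s.temperature
        self.rt = R_KJ * t
        reactions = guild_reactions("hydrogen")
        self.dg0 = {
            g: delta_g_standard_at_temperature(r, table, t) for g, r in reactions.items()
        }
        henry = HenryTable.default()
        self.kh = {g: henry.constant(g).at(t) for g in ("H2", "CO2", "CH4")}
        # mol per atm of partial pressure, for the whole bottle
        head = s.headspace_volume / (R_L_ATM * t)
        self.mol_per_atm = {g: self.kh[g] * s.liquid_volume + head for g in self.kh}
        pka = acid_pka_table()
        self.f_prop = fraction_dissociated(pka["propionate"], s.ph)
        self.f_ac = fraction_dissociated(pka["acetate"], s.ph)
        self.ln_h = -s.ph * math.log(10.0)

    def pressures_atm(self, n_h2: float, n_co2: float, n_ch4: float):
        return (
            n_h2 / self.mol_per_atm["H2"],
            n_co2 / self.mol_per_atm["CO2"],
            n_ch4 / self.mol_per_atm["CH4"],
        )


def _rates(y, s: SimulationScenario, phys: _Physics):
    """Instantaneous guild rates and per-guild ΔG at state vector ``y``.

    Returns (r_spo, r_sao, r_hm, dg) with r in mol reaction-substrate
    L⁻¹ day⁻¹ (propionate, acetate and H2 respectively) and dg the
    per-reaction ΔG (NaN where a substrate is exhausted).
    """
    prop, ac, n_h2, n_co2, n_ch4 = y[0], y[1], y[2], y[3], y[4]
    x = {"spo": y[5], "sao": y[6], "hm": y[7]}
    p_h2, p_co2, p_ch4 = phys.pressures_atm(max(n_h2, 0.0), max(n_co2, 0.0), max(n_ch4, 0.0))
    if p_h2 <= 0 or p_co2 <= 0 or p_ch4 <= 0:
        raise ComputationError(
            f"gas pool exhausted (pH2={p_h2:g}, pCO2={p_co2:g}, pCH4={p_ch4:g} atm); "
            "ΔG undefined at zero activity"
        )
    ln_h2, ln_co2, ln_ch4 = math.log(p_h2), math.log(p_co2), math.log(p_ch4)
    rt = phys.rt
    dg = {"spo": math.nan, "sao": math.nan, "hm": math.nan}
    rate = {"spo": 0.0, "sao": 0.0, "hm": 0.0}

    prop_a = max(prop, 0.0) * phys.f_prop
    ac_a = max(ac, 0.0) * phys.f_ac
    c_h2 = phys.kh["H2"] * p_h2  # dissolved H2, mol/L

    if prop_a > FLOOR_M and ac_a > FLOOR_M:
        dg["spo"] = phys.dg0["spo"] + rt * (
            math.log(ac_a) + ln_co2 + 3.0 * ln_h2 - math.log(prop_a)
        )
        g = s.guilds["spo"]
        ft = max(0.0, 1.0 - math.exp((dg["spo"] + g.dg_min) / rt))
        rate["spo"] = g.vmax * x["spo"] * (prop / (g.ks + prop)) * ft if prop > 0 else 0.0

    if ac_a > FLOOR_M:
        dg["sao"] = phys.dg0["sao"] + rt * (
            2.0 * ln_co2 + 4.0 * ln_h2 - math.log(ac_a) - phys.ln_h
        )
        g = s.guilds["sao"]
        ft = max(0.0, 1.0 - math.exp((dg["sao"] + g.dg_min) / rt))
        rate["sao"] = g.vmax * x["sao"] * (ac / (g.ks + ac)) * ft if ac > 0 else 0.0

    dg["hm"] = phys.dg0["hm"] + rt * (ln_ch4 - 4.0 * ln_h2 - ln_co2)
    g = s.guilds["hm"]
    ft = max(0.0, 1.0 - math.exp((dg["hm"] + g.dg_min) / rt))
    rate["hm"] = g.vmax * x["hm"] * (c_h2 / (g.ks + c_h2)) * ft

    return rate, dg


def _deriv(t, y, s: SimulationScenario, phys: _Physics):
    rate, _ = _rates(y, s, phys)
    r_spo, r_sao, r_h2 = rate["spo"], rate["sao"], rate["hm"]
    vl = s.liquid_volume
    g = s.guilds
    dx = {
        "spo": g["spo"].yield_g_per_mol * r_spo - g["spo"].decay * max(y[5], 0.0),
        "sao": g["sao"].yield_g_per_mol * r_sao - g["sao"].decay * max(y[6], 0.0),
        "hm": g["hm"].yield_g_per_mol * r_h2 - g["hm"].decay * max(y[7], 0.0),
    }
    growth_c = (dx["spo"] + dx["sao"] + dx["hm"]) / BIOMASS_G_PER_MOL_C  # mol C/L/d
    return [
        -r_spo,                                  # propionate, mol/L
        r_spo - r_sao,                           # acetate, mol/L
        vl * (3.0 * r_spo + 4.0 * r_sao - r_h2),  # H2, mol in bottle
        vl * (r_spo + 2.0 * r_sao - 0.25 * r_h2 - growth_c),  # CO2, mol
        vl * 0.25 * r_h2,                        # CH4, mol
        dx["spo"], dx["sao"], dx["hm"],          # biomass, g/L
        r_spo, r_sao, 0.25 * r_h2,               # cumulative extents, mol/L
    ]


def simulate(
    scenario: Optional[SimulationScenario] = None,
    table: Optional[ThermoTable] = None,
) -> BatchTimeSeries:
    """Integrate the noiseless batch model and sample it on the schedule.

    The returned series carries channels propionate/acetate/formate (mM),
    ch4 (cumulative mM per litre of liquid), h2/co2/ch4_gas (Pa), ph and
    temperature, plus a ``provenance["diagnostics"]`` block with per-guild
    ΔG, rates, biomass and cumulative reaction extents at each observation
    time (inputs to the invariant checks and the energy-partition stage).
    """
    s = scenario if scenario is not None else SimulationScenario.default()
    phys = _Physics(s, table)
    y0 = [
        s.propionate0,
        s.acetate0,
        s.h2_pa0 / ATM_PA * phys.mol_per_atm["H2"],
        s.co2_atm0 * phys.mol_per_atm["CO2"],
        s.ch4_atm0 * phys.mol_per_atm["CH4"],
        s.biomass0["spo"],
        s.biomass0["sao"],
        s.biomass0["hm"],
        0.0,
        0.0,
        0.0,
    ]
    times = np.arange(0.0, s.t_end + 0.5 * s.interval, s.interval)
    sol = solve_ivp(
        _deriv,
        (0.0, float(times[-1])),
        y0,
        method="LSODA",
        t_eval=times,
        args=(s, phys),
        rtol=1e-8,
        atol=[1e-12, 1e-12, 1e-16, 1e-14, 1e-14, 1e-12, 1e-12, 1e-12, 1e-12, 1e-12, 1e-12],
        max_step=1.0,
    )
    if not sol.success:
        raise ComputationError(f"integration failed: {sol.message}")
    y = sol.y
    if np.any(y[:8] < -1e-8):
        raise ComputationError(
            "integrator produced a negative state; smallest value "
            f"{float(y[:8].min()):g}"
        )
    n = len(times)
    dgs = {g: np.full(n, np.nan) for g in ("spo", "sao", "hm")}
    rates = {g: np.zeros(n) for g in ("spo", "sao", "hm")}
    fts = {g: np.zeros(n) for g in ("spo", "sao", "hm")}
    for k in range(n):
        rate, dg = _rates(y[:, k], s, phys)
        for g in rate:
            rates[g][k] = rate[g]
            dgs[g][k] = dg[g]
            if rate[g] > 0:
                dg_min = s.guilds[g].dg_min
                fts[g][k] = max(0.0, 1.0 - math.exp((dg[g] + dg_min) / phys.rt))
    p_h2 = y[2] / phys.mol_per_atm["H2"] * ATM_PA
    p_co2 = y[3] / phys.mol_per_atm["CO2"] * ATM_PA
    p_ch4 = y[4] / phys.mol_per_atm["CH4"] * ATM_PA
    channels = {
        "propionate": np.maximum(y[0], 0.0) * 1000.0,
        "acetate": np.maximum(y[1], 0.0) * 1000.0,
        "formate": np.full(n, s.formate0 * 1000.0),
        "ch4": np.maximum((y[4] - y0[4]) / s.liquid_volume, 0.0) * 1000.0,
        "h2": p_h2,
        "co2": p_co2,
        "ch4_gas": p_ch4,
        "ph": np.full(n, s.ph),
        "temperature": np.full(n, s.temperature),
    }
    units = {
        "propionate": "mM",
        "acetate": "mM",
        "formate": "mM",
        "ch4": "mM",
        "h2": "Pa",
        "co2": "Pa",
        "ch4_gas": "Pa",
        "ph": "-",
        "temperature": "K",
    }
    diagnostics = {
        "dg": dgs,
        "ft": fts,
        "rate": rates,
        "biomass": {"spo": y[5].copy(), "sao": y[6].copy(), "hm": y[7].copy()},
        "extent": {"spo": y[8].copy(), "sao": y[9].copy(), "hm": y[10].copy()},
        "h2_mol": y[2].copy(),
        "co2_mol": y[3].copy(),
        "ch4_mol": y[4].copy(),
    }
    return BatchTimeSeries(
        time=times,
        channels=channels,
        units=units,
        provenance={
            "assay": s.name,
            "seed": s.seed,
            "noiseless": True,
            "diagnostics": diagnostics,
        },
    )


#: Channels that receive multiplicative measurement noise; pH and
#: temperature are regulated/instrumented quantities and stay noiseless.
NOISY_CHANNELS = ("propionate", "acetate", "formate", "ch4", "h2", "co2", "ch4_gas")


def observe(
    noiseless: BatchTimeSeries, cv: float, seed: int
) -> BatchTimeSeries:
    """Overlay seeded multiplicative lognormal noise of coefficient of
    variation ``cv`` (independent across points and channels); the
    cumulative CH4 channel is re-monotonised with a running maximum.
    """
    if cv < 0:
        raise ValidationError("noise cv must be non-negative")
    if cv == 0:
        return noiseless
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv * cv))
    channels = {}
    for name, values in noiseless.channels.items():
        if name in NOISY_CHANNELS:
            factors = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=values.shape)
            noisy = values * factors
            if name == "ch4":
                noisy = np.maximum.accumulate(noisy)
            channels[name] = noisy
        else:
            channels[name] = values.copy()
    provenance = dict(noiseless.provenance)
    provenance.update({"noiseless": False, "noise_cv": cv, "noise_seed": seed})
    provenance.pop("diagnostics", None)
    return BatchTimeSeries(
        time=noiseless.time.copy(),
        channels=channels,
        units=dict(noiseless.units),
        provenance=provenance,
    )
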