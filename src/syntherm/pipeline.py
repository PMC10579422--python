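"""End-to-end batch analysis: ΔG trajectories, kinetics, partition, windows.

``run_pipeline`` applies, per assay: (i) a per-timepoint guild ΔG
trajectory and energy partition, (ii) exponential-phase kinetics for the
acid and methane channels, (iii) the H2 feasibility window table at a
representative mid-degradation state. Missing H2 (or other gas) channels
degrade gracefully: the thermodynamic stages are skipped with a warning and
kinetics are still produced.

Reports are emitted as JSON (full precision) and TSV (4 significant
digits, so text outputs are byte-stable across platforms).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import SynthermError
from .feasibility import window_report
from .io import read_timeseries
from .kinetics import BatchTimeSeries, fit_kinetics, methane_yield, volumetric_rate
from .partition import guild_energies
from .thermo import ThermodynamicState, ThermoTable

log = logging.getLogger("syntherm")


def _state_at(
    series: BatchTimeSeries, k: int, config: AnalysisConfig
) -> ThermodynamicState:
    ch = series.channels
    solutes = {}
    for acid in ("propionate", "acetate", "formate"):
        if acid in ch:
            solutes[acid] = float(ch[acid][k]) / 1000.0
    gases = {"H2": float(ch["h2"][k])}
    gases["CO2"] = float(ch["co2"][k]) if "co2" in ch else config.default_co2_pa
    gases["CH4"] = float(ch["ch4_gas"][k]) if "ch4_gas" in ch else config.default_ch4_pa
    return ThermodynamicState(
        temperature=float(ch["temperature"][k]) if "temperature" in ch else 325.15,
        ph=float(ch["ph"][k]) if "ph" in ch else 8.5,
        solutes=solutes,
        gases=gases,
    )


def analyse_series(
    series: BatchTimeSeries,
    config: Optional[AnalysisConfig] = None,
    table: Optional[ThermoTable] = None,
) -> Dict[str, object]:
    """Analyse one assay; returns a bundle of DataFrames and reports."""
    config = config or AnalysisConfig()
    bundle: Dict[str, object] = {"warnings": []}

    # kinetics on whichever channels are present
    kin = {}
    for channel in ("propionate", "acetate", "ch4"):
        if channel not in series.channels:
            continue
        try:
            kin[channel] = fit_kinetics(series, channel, config.min_points)
        except SynthermError as exc:
            bundle["warnings"].append(f"kinetics[{channel}]: {exc}")
    bundle["kinetics"] = kin
    for acid in ("propionate", "acetate"):
        if acid in series.channels:
            try:
                bundle[f"volumetric_rate_{acid}"] = volumetric_rate(
                    series, acid, config.window_days
                )
            except SynthermError as exc:
                bundle["warnings"].append(f"volumetric_rate[{acid}]: {exc}")
    if "ch4" in series.channels and "propionate" in series.channels:
        try:
            bundle["methane_yield"] = methane_yield(series, "propionate")
        except SynthermError as exc:
            bundle["warnings"].append(f"methane_yield: {exc}")

    # thermodynamic stages need an H2 channel
    if "h2" not in series.channels:
        bundle["warnings"].append("no h2 channel: ΔG trajectory, partition and windows skipped")
        return bundle

    rows = []
    for k in range(len(series)):
        try:
            state = _state_at(series, k, config)
            report = guild_energies(state, config.carrier, table)
            rows.append(
                {
                    "time_d": float(series.time[k]),
                    "dg_spo_kj": report.dg_spo,
                    "dg_sao_kj": report.dg_sao,
                    "dg_hm_kj": report.dg_hm,
                    "per_propionate_total_kj": report.total,
                }
            )
        except SynthermError:
            rows.append(
                {
                    "time_d": float(series.time[k]),
                    "dg_spo_kj": np.nan,
                    "dg_sao_kj": np.nan,
                    "dg_hm_kj": np.nan,
                    "per_propionate_total_kj": np.nan,
                }
            )
    bundle["dg_trajectory"] = pd.DataFrame(rows)

    # windows at the mid-degradation state (median H2 left out, closed form
    # fixes all non-H2 activities)
    mid = len(series) // 2
    try:
        state = _state_at(series, mid, config)
        bundle["windows"] = window_report(state, config.thresholds, table)
    except SynthermError as exc:
        bundle["warnings"].append(f"windows: {exc}")
    return bundle


def run_pipeline(
    config: AnalysisConfig, table: Optional[ThermoTable] = None
) -> Dict[str, Dict[str, object]]:
    """Run every assay in ``config.series_paths``; optionally write reports.

    Returns ``{assay_id: bundle}``. Deterministic given inputs. Errors in
    one assay are recorded under its id without aborting the rest.
    """
    if config.thermo_table and table is None:
        table = ThermoTable.from_tsv(config.thermo_table)
    results: Dict[str, Dict[str, object]] = {}
    for path in config.series_paths:
        assay = Path(path).stem
        try:
            series = read_timeseries(path)
            results[assay] = analyse_series(series, config, table)
        except SynthermError as exc:
            results[assay] = {"error": str(exc), "warnings": []}
            log.error("assay %s failed: %s", assay, exc)
    if config.output_dir:
        write_bundle(results, Path(config.output_dir))
    return results


def _sig4(x: float) -> float:
    return float(f"{x:.4g}") if np.isfinite(x) else x


def write_bundle(results: Dict[str, Dict[str, object]], outdir: Path) -> None:
    """Emit the report bundle as JSON (full precision) and TSV (4 s.f.)."""
    outdir.mkdir(parents=True, exist_ok=True)
    summary: Dict[str, object] = {}
    for assay, bundle in results.items():
        entry: Dict[str, object] = {"warnings": bundle.get("warnings", [])}
        if "error" in bundle:
            entry["error"] = bundle["error"]
        kin = bundle.get("kinetics", {})
        entry["kinetics"] = {
            ch: {
                "mu_per_day": rep.mu,
                "direction": rep.direction,
                "doubling_time_d": rep.doubling_time,
                "window": list(rep.window),
                "r_squared": rep.r_squared,
            }
            for ch, rep in kin.items()
        }
        for key in ("volumetric_rate_propionate", "volumetric_rate_acetate"):
            if key in bundle:
                entry[key] = bundle[key]
        if "methane_yield" in bundle:
            y = bundle["methane_yield"]
            entry["methane_yield"] = {
                "mol_per_mol": y.yield_mol_per_mol,
                "theoretical": y.theoretical,
                "ratio": y.ratio_to_theoretical,
            }
        summary[assay] = entry
        for name in ("dg_trajectory", "windows"):
            df = bundle.get(name)
            if isinstance(df, pd.DataFrame):
                out = df.copy()
                for col in out.select_dtypes("number").columns:
                    out[col] = out[col].map(_sig4)
                out.to_csv(outdir / f"{assay}_{name}.tsv", sep="\t", index=False)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
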