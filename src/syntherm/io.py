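"""Tidy CSV reading/writing for batch time series.

The on-disk layout is long ("tidy"): one row per (time, channel) pair with
columns ``time_d, channel, value, unit``. Units are validated against a
fixed registry; out-of-order times are sorted with a warning; duplicated
(time, channel) pairs are rejected.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import pandas as pd

from .errors import ValidationError
from .kinetics import BatchTimeSeries

log = logging.getLogger("syntherm")

REQUIRED_COLUMNS = ("time_d", "channel", "value", "unit")

#: Accepted units per channel.
UNIT_REGISTRY = {
    "propionate": {"mM"},
    "acetate": {"mM"},
    "formate": {"mM"},
    "ch4": {"mM", "mmol"},
    "h2": {"Pa"},
    "co2": {"Pa"},
    "ch4_gas": {"Pa"},
    "ph": {"-", "", "dimensionless"},
    "temperature": {"K"},
}


def read_timeseries(path: Union[str, Path]) -> BatchTimeSeries:
    """Load and validate a tidy CSV batch series."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"channel": str, "unit": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")

    bad_unit = []
    for idx, row in df.iterrows():
        allowed = UNIT_REGISTRY.get(row["channel"])
        if allowed is None:
            bad_unit.append(f"row {idx}: unknown channel {row['channel']!r}")
        elif str(row["unit"]) not in allowed and not (
            row["channel"] == "ph" and pd.isna(row["unit"])
        ):
            bad_unit.append(
                f"row {idx}: unit {row['unit']!r} not allowed for channel "
                f"{row['channel']!r} (allowed: {sorted(allowed)})"
            )
    if bad_unit:
        raise ValidationError(f"{path}: " + "; ".join(bad_unit))

    dup = df.duplicated(subset=["time_d", "channel"])
    if dup.any():
        rows = df.loc[dup, ["time_d", "channel"]].to_dict("records")
        raise ValidationError(f"{path}: duplicated (time, channel) rows: {rows}")

    in_order = df.groupby("channel")["time_d"].apply(
        lambda s: s.is_monotonic_increasing
    )
    if not in_order.all():
        log.warning("%s: times out of order; sorting", path)
    wide = df.pivot(index="time_d", columns="channel", values="value").sort_index()
    if wide.isna().any().any():
        holes = [
            f"channel {c!r} missing at t={wide.index[m][:3].tolist()}"
            for c, m in ((c, wide[c].isna().to_numpy()) for c in wide.columns)
            if m.any()
        ]
        raise ValidationError(f"{path}: incomplete channels: " + "; ".join(holes))
    units = df.groupby("channel")["unit"].first().fillna("-").to_dict()
    return BatchTimeSeries(
        time=wide.index.to_numpy(dtype=float),
        channels={c: wide[c].to_numpy(dtype=float) for c in wide.columns},
        units={c: str(units.get(c, "-")) for c in wide.columns},
        provenance={"path": str(path)},
    )


def write_timeseries(series: BatchTimeSeries, path: Union[str, Path]) -> None:
    """Write a series in the tidy CSV dialect accepted by ``read_timeseries``."""
    rows = []
    for name, values in series.channels.items():
        unit = series.units.get(name, "-")
        for t, v in zip(series.time, values):
            rows.append({"time_d": t, "channel": name, "value": v, "unit": unit})
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def to_tidy(series: BatchTimeSeries) -> pd.DataFrame:
    """The series as a tidy DataFrame (no file round trip)."""
    rows = []
    for name, values in series.channels.items():
        unit = series.units.get(name, "-")
        for t, v in zip(series.time, values):
            rows.append({"time_d": t, "channel": name, "value": v, "unit": unit})
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
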