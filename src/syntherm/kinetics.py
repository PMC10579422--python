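"""Batch-kinetics estimation: specific rates, doubling times, yields.

Specific rates µ are slopes of ln(value) against time over a detected
exponential window; doubling time is ln 2 / µ. Methane yields are mole
ratios of cumulative CH4 to acid consumed (theoretical 1.75 for propionate,
1.0 for acetate under complete syntrophic mineralisation). Volumetric
degradation rates are reported in g of acid anion per litre per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import ComputationError, InsufficientDataError, ValidationError

#: Molar masses of the acid anions, g mol⁻¹ (matching mM reporting of the
#: dissociated acids at digester pH; free-acid masses are 74.08 / 60.05).
MOLAR_MASS = {"propionate": 73.07, "acetate": 59.04, "formate": 45.02}

#: Theoretical methane yields, mol CH4 per mol acid mineralised.
THEORETICAL_YIELD = {"propionate": 1.75, "acetate": 1.0}

LN2 = math.log(2.0)


@dataclass
class BatchTimeSeries:
    """Longitudinal record of one batch assay.

    ``time`` is in days and strictly increasing; ``channels`` maps channel
    names (propionate, acetate, formate, ch4, h2, ph, temperature, ...) to
    arrays of equal length; ``units`` records the unit of each channel;
    ``provenance`` carries free-text metadata (assay id, seed, scenario).
    """

    time: np.ndarray
    channels: Dict[str, np.ndarray]
    units: Dict[str, str] = field(default_factory=dict)
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or len(self.time) < 1:
            raise ValidationError("time must be a non-empty 1-D array")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")
        for name in list(self.channels):
            arr = np.asarray(self.channels[name], dtype=float)
            if arr.shape != self.time.shape:
                raise ValidationError(
                    f"channel {name!r} has length {arr.size}, expected {self.time.size}"
                )
            if name not in ("ph", "temperature") and np.any(arr < 0):
                raise ValidationError(f"channel {name!r} contains negative values")
            self.channels[name] = arr

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ValidationError(
                f"series has no channel {name!r} (available: {sorted(self.channels)})"
            ) from None

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class KineticsReport:
    """Specific-rate estimate for one channel of one assay."""

    channel: str
    mu: float                  # day⁻¹, magnitude of the log-linear slope
    direction: str             # "growth" or "consumption"
    doubling_time: float       # days, ln 2 / mu
    window: Tuple[int, int]    # [start, stop) indices of the fitted window
    r_squared: float


def _window_r2_slope(t: np.ndarray, ln_y: np.ndarray) -> Tuple[float, float]:
    """R² and slope of the OLS line of ln_y on t.

    A zero-variance (flat) window scores R² = 0, not 1: detection looks for
    exponential *change*, and crediting plateaus with perfect fits would let
    any flat tail outcompete the growth phase. A genuinely constant series
    then still yields the full window through the longest-window tie rule.
    """
    t_mean = t.mean()
    y_mean = ln_y.mean()
    st = t - t_mean
    sy = ln_y - y_mean
    ss_tt = float(st @ st)
    ss_yy = float(sy @ sy)
    slope = float(st @ sy) / ss_tt
    if ss_yy <= 1e-300:
        return 0.0, slope
    ss_res = ss_yy - slope * float(st @ sy)
    return 1.0 - ss_res / ss_yy, slope


def detect_exponential_phase(
    time: np.ndarray, values: np.ndarray, min_points: int = 4
) -> Tuple[int, int]:
    """Contiguous window of ≥ ``min_points`` maximising log-linear fit R².

    Only windows of strictly positive values are considered. Ties (within
    1e-12) are broken toward the longer, then the earlier window. Returns
    ``(start, stop)`` with ``stop`` exclusive.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if min_points < 2:
        raise ValidationError("min_points must be at least 2")
    positive = values > 0
    if positive.sum() < min_points:
        raise InsufficientDataError(
            f"need at least {min_points} strictly positive values, "
            f"found {int(positive.sum())}"
        )
    ln_all = np.where(positive, np.log(np.where(positive, values, 1.0)), np.nan)

    best: Optional[Tuple[float, int, int]] = None  # (r2, length, start)
    n = len(values)
    for start in range(n - min_points + 1):
        if not positive[start]:
            continue
        stop_max = start
        while stop_max < n and positive[stop_max]:
            stop_max += 1
        for stop in range(start + min_points, stop_max + 1):
            r2, _ = _window_r2_slope(time[start:stop], ln_all[start:stop])
            if best is None:
                best = (r2, stop - start, start)
                continue
            cand = (r2, stop - start, start)
            if r2 > best[0] + 1e-12:
                best = cand
            elif abs(r2 - best[0]) <= 1e-12:
                if cand[1] > best[1] or (cand[1] == best[1] and cand[2] < best[2]):
                    best = cand
    if best is None:
        raise InsufficientDataError(
            f"no contiguous window of {min_points} strictly positive values"
        )
    _, length, start = best
    return start, start + length


def specific_rate(
    time: np.ndarray, values: np.ndarray, window: Tuple[int, int]
) -> float:
    """Signed OLS slope of ln(value) vs time (day⁻¹) over ``window``.

    Positive for growth (e.g. cumulative CH4), negative for substrate
    decline; callers that want a consumption rate take the magnitude.
    """
    start, stop = window
    t = np.asarray(time, dtype=float)[start:stop]
    y = np.asarray(values, dtype=float)[start:stop]
    if len(t) < 2:
        raise InsufficientDataError("window must contain at least 2 points")
    if np.any(y <= 0):
        raise ComputationError("window contains non-positive values; ln undefined")
    _, slope = _window_r2_slope(t, np.log(y))
    return slope


def doubling_time(mu: float) -> float:
    """t_d = ln 2 / µ (days); µ must be strictly positive."""
    if mu <= 0:
        raise ComputationError(f"doubling time undefined for mu = {mu} <= 0")
    return LN2 / mu


def fit_kinetics(
    series: BatchTimeSeries, channel: str, min_points: int = 4
) -> KineticsReport:
    """Detect the exponential phase of a channel and report µ, t_d and R²."""
    values = series.channel(channel)
    window = detect_exponential_phase(series.time, values, min_points)
    start, stop = window
    r2, slope = _window_r2_slope(
        series.time[start:stop], np.log(values[start:stop])
    )
    mu = abs(slope)
    return KineticsReport(
        channel=channel,
        mu=mu,
        direction="consumption" if slope < 0 else "growth",
        doubling_time=doubling_time(mu) if mu > 0 else math.inf,
        window=window,
        r_squared=r2,
    )


@dataclass(frozen=True)
class YieldResult:
    """Observed and theoretical methane yield per mole of acid consumed."""

    acid: str
    yield_mol_per_mol: float
    theoretical: float
    ratio_to_theoretical: float


def methane_yield(
    series: BatchTimeSeries,
    acid: str = "propionate",
    ch4_channel: str = "ch4",
    span: Optional[Tuple[int, int]] = None,
) -> YieldResult:
    """(ΔCH4)/(Δacid) in mole units over the evaluation span.

    Cumulative CH4 and the acid are assumed to share a per-volume basis
    (both mM, i.e. mmol per litre of liquid). The acid must decline and
    cumulative CH4 must be non-decreasing over the span.
    """
    start, stop = span if span is not None else (0, len(series))
    acid_vals = series.channel(acid)[start:stop]
    ch4_vals = series.channel(ch4_channel)[start:stop]
    if len(acid_vals) < 2:
        raise InsufficientDataError("span must contain at least 2 points")
    if np.any(np.diff(ch4_vals) < -1e-9 * max(1.0, float(ch4_vals.max()))):
        raise ValidationError("cumulative CH4 channel must be non-decreasing")
    consumed = float(acid_vals[0] - acid_vals[-1])
    if consumed <= 0:
        raise ComputationError(
            f"{acid} does not decline over the span (Δ = {-consumed:+g}); yield undefined"
        )
    produced = float(ch4_vals[-1] - ch4_vals[0])
    theoretical = THEORETICAL_YIELD.get(acid, math.nan)
    y = produced / consumed
    return YieldResult(
        acid=acid,
        yield_mol_per_mol=y,
        theoretical=theoretical,
        ratio_to_theoretical=y / theoretical if theoretical == theoretical else math.nan,
    )


def volumetric_rate(
    series: BatchTimeSeries,
    acid: str = "propionate",
    window_days: float = 5.0,
) -> float:
    """Maximum degradation rate in g L⁻¹ day⁻¹ over sliding windows.

    Evaluates (Δconcentration)/(Δt) over every point pair separated by at
    most ``window_days`` and returns the maximum, converted with the anion
    molar mass. Positive values indicate net consumption.
    """
    t = series.time
    if window_days <= 0:
        raise ValidationError("window_days must be positive")
    if window_days > float(t[-1] - t[0]):
        raise ValidationError(
            f"window of {window_days} d exceeds the series span of {t[-1] - t[0]:g} d"
        )
    c = series.channel(acid) * MOLAR_MASS[acid] / 1000.0  # mM -> g/L
    best = -math.inf
    n = len(t)
    for i in range(n - 1):
        for j in range(i + 1, n):
            dt = t[j] - t[i]
            if dt > window_days:
                break
            best = max(best, (c[i] - c[j]) / dt)
    if not math.isfinite(best):
        raise InsufficientDataError("no window contains at least 2 points")
    return best
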