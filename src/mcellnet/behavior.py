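"""Behavioral measurement procedures for zebrafish swim and startle assays.

Covers three stages of the behavioral pipeline:

* swim-burst detection from far-field potential recordings — a potential
  deflection counts as a swim burst when its peak-to-peak amplitude is at
  least 8 mV and its duration lies within 30-200 ms;
* Mauthner-trial filtering — startle responses are all-or-none with a 5-15 ms
  latency, so responded trials with latencies outside that window are
  excluded as non-Mauthner-mediated;
* startle-probability tabulation per intensity (70-100 dB re 20 uPa in 5-dB
  steps) and four-parameter Boltzmann sigmoid fitting,
  Y = Bottom + (Top - Bottom) / (1 + exp((V50 - X)/Slope)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FieldPotentialTrace",
    "BurstEvent",
    "BoltzmannFit",
    "detect_swim_bursts",
    "filter_mauthner_trials",
    "startle_probability",
    "boltzmann",
    "fit_boltzmann",
    "INTENSITY_GRID",
    "MAUTHNER_WINDOW_MS",
]

#: acoustic stimulus grid (dB re 20 uPa)
INTENSITY_GRID = tuple(range(70, 101, 5))

#: latency window (ms) of Mauthner-mediated startle responses
MAUTHNER_WINDOW_MS = (5.0, 15.0)


@dataclass
class FieldPotentialTrace:
    """Far-field potential recording: voltage in mV at a fixed sample rate."""

    voltage_mV: np.ndarray
    sample_rate_hz: float

    def __post_init__(self):
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if self.voltage_mV.ndim != 1:
            raise ValueError("voltage series must be one-dimensional")

    @property
    def duration_s(self) -> float:
        return self.voltage_mV.size / self.sample_rate_hz

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.voltage_mV.size) * (1000.0 / self.sample_rate_hz)


@dataclass(frozen=True)
class BurstEvent:
    """One accepted swim burst."""

    onset_ms: float
    offset_ms: float
    peak_to_peak_mV: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class BurstDetectionResult:
    events: list
    count_per_minute: float
    rejected: list = field(default_factory=list)


def _candidate_segments(
    deviation: np.ndarray, enter: float, exit: float
) -> list[tuple[int, int]]:
    """Maximal runs where |deviation| >= exit that contain a sample >= enter.

    This is the hysteresis rule: an event is entered when the envelope
    exceeds the high threshold and extended outward while it stays above the
    low one, which prevents chatter on noisy shoulders.
    Returns half-open index pairs (start, stop).
    """
    above_low = deviation >= exit
    if not above_low.any():
        return []
    idx = np.flatnonzero(above_low)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    out = []
    for a, b in zip(run_starts, run_stops):
        if (deviation[a:b] >= enter).any():
            out.append((int(a), int(b)))
    return out


def _merge_segments(segs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not segs:
        return []
    merged = [segs[0]]
    for a, b in segs[1:]:
        pa, pb = merged[-1]
        if a - pb < max_gap:
            merged[-1] = (pa, b)
        else:
            merged.append((a, b))
    return merged


def detect_swim_bursts(
    trace: FieldPotentialTrace,
    min_amp_mV: float = 8.0,
    dur_range_ms: tuple[float, float] = (30.0, 200.0),
    enter_mV: float = 4.0,
    exit_mV: float = 2.0,
    merge_gap_ms: float = 10.0,
) -> BurstDetectionResult:
    """Detect swim bursts in a field-potential trace.

    Candidate events are found by hysteresis thresholding of the absolute
    deviation from the baseline (trace median): enter at ``enter_mV``,
    extend while above ``exit_mV``.  Candidates closer than ``merge_gap_ms``
    are merged, then the published acceptance rule is applied: peak-to-peak
    amplitude >= ``min_amp_mV`` and duration within ``dur_range_ms``.
    Returns accepted events and the count normalized per minute.
    """
    v = trace.voltage_mV
    if np.isnan(v).all():
        raise ValueError("trace contains only NaN samples")
    if trace.sample_rate_hz < 1000:
        warnings.warn(
            "sample rate below 1 kHz; burst boundaries will be coarse", stacklevel=2
        )
    ms_per_sample = 1000.0 / trace.sample_rate_hz
    baseline = float(np.nanmedian(v))
    dev = np.abs(v - baseline)
    segs = _candidate_segments(dev, enter_mV, exit_mV)
    gap = max(1, int(round(merge_gap_ms / ms_per_sample)))
    segs = _merge_segments(segs, gap)
    lo, hi = dur_range_ms
    events, rejected = [], []
    for a, b in segs:
        seg = v[a:b]
        ev = BurstEvent(
            onset_ms=a * ms_per_sample,
            offset_ms=b * ms_per_sample,
            peak_to_peak_mV=float(seg.max() - seg.min()),
        )
        if ev.peak_to_peak_mV >= min_amp_mV and lo <= ev.duration_ms <= hi:
            events.append(ev)
        else:
            rejected.append(ev)
    rate = len(events) / (trace.duration_s / 60.0) if trace.duration_s > 0 else 0.0
    return BurstDetectionResult(events=events, count_per_minute=rate, rejected=rejected)


def filter_mauthner_trials(
    trials: pd.DataFrame, window_ms: tuple[float, float] = MAUTHNER_WINDOW_MS
) -> pd.DataFrame:
    """Drop responded trials whose latency falls outside the Mauthner window.

    Responses slower than the window (or implausibly faster) are not
    Mauthner-mediated startles and are excluded from the table entirely;
    non-response trials are retained.  Expects columns ``responded`` (bool)
    and ``latency_ms`` (NaN allowed for non-responses).
    """
    if trials.empty:
        return trials.copy()
    lat = trials["latency_ms"]
    if (lat.dropna() < 0).any():
        raise ValueError("latencies must be non-negative")
    lo, hi = window_ms
    bad = trials["responded"] & ((lat < lo) | (lat > hi) | lat.isna())
    return trials.loc[~bad].reset_index(drop=True)


def startle_probability(
    trials: pd.DataFrame, grid=INTENSITY_GRID
) -> tuple[pd.DataFrame, pd.Series]:
    """Tabulate response probability per intensity.

    Returns ``(per_animal, mean)``: the per-animal per-intensity response
    fraction (wide table, animals as rows) and the across-animal mean per
    intensity.  Intensities in the table but not on the grid trigger a
    warning; grid intensities with no trials for an animal are NaN and are
    skipped by the mean.
    Expects columns ``animal_id``, ``intensity_dB``, ``responded``.
    """
    grid = list(grid)
    extra = sorted(set(trials["intensity_dB"].unique()) - set(grid))
    if extra:
        warnings.warn(f"intensities outside the requested grid ignored: {extra}",
                      stacklevel=2)
    sub = trials[trials["intensity_dB"].isin(grid)]
    per_animal = (
        sub.groupby(["animal_id", "intensity_dB"])["responded"]
        .mean()
        .unstack("intensity_dB")
        .reindex(columns=grid)
    )
    mean = per_animal.mean(axis=0, skipna=True)
    mean.name = "p_startle"
    return per_animal, mean


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted four-parameter Boltzmann sigmoid with goodness of fit."""

    Bottom: float
    Top: float
    V50: float
    Slope: float
    r_squared: float
    degenerate: bool = False

    def predict(self, x) -> np.ndarray:
        return boltzmann(np.asarray(x, float), self.Bottom, self.Top, self.V50, self.Slope)


def boltzmann(x, Bottom, Top, V50, Slope):
    """Y = Bottom + (Top - Bottom)/(1 + exp((V50 - X)/Slope))."""
    return Bottom + (Top - Bottom) / (1.0 + np.exp((V50 - np.asarray(x, float)) / Slope))


def fit_boltzmann(x, y, max_nfev: int = 10000) -> BoltzmannFit:
    """Least-squares fit of the Boltzmann sigmoid to (intensity, probability).

    Initial guesses follow a fixed rule for determinism: Bottom = min(y),
    Top = max(y), V50 = x closest to the mid-range response, Slope = 5 dB.
    A flat response (Top ~ Bottom) is returned flagged ``degenerate`` with a
    warning, since V50 and Slope are unidentifiable there.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct intensities to fit 4 parameters")
    b0, t0 = float(y.min()), float(y.max())
    if t0 - b0 < 1e-9:
        warnings.warn("flat response: Top ~ Bottom, V50/Slope unidentifiable",
                      stacklevel=2)
        return BoltzmannFit(b0, t0, float(np.median(x)), 5.0, 1.0, degenerate=True)
    mid = 0.5 * (b0 + t0)
    v50_0 = float(x[np.argmin(np.abs(y - mid))])
    p0 = (b0, t0, v50_0, 5.0)
    try:
        popt, _ = curve_fit(boltzmann, x, y, p0=p0, maxfev=max_nfev)
    except RuntimeError as err:
        raise RuntimeError(
            f"Boltzmann fit failed to converge (p0={p0}, n={x.size}): {err}"
        ) from err
    bottom, top, v50, slope = (float(p) for p in popt)
    if top < bottom:  # equivalent curve with swapped asymptotes and negated slope
        bottom, top, slope = top, bottom, -slope
    resid = y - boltzmann(x, bottom, top, v50, slope)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return BoltzmannFit(bottom, top, v50, slope, r2)
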