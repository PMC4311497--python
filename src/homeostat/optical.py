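"""Optical-signal metrics: calcium imaging, FM-dye puncta, dose-response.

Calcium: dF/F is the fractional fluorescence change relative to the mean
fluorescence over the 1 s preceding an event onset; transients are
detected as robust-SD threshold excursions of the dF/F series, and the
activity rate of a neuron is the sum of detected transient amplitudes
divided by the recording time (dF/F per minute) — since transient
amplitude grows ~linearly with spike count, this rate tracks firing
rate without spike inference.

FM dye: per-bouton releasable fluorescence dF and the density D of
FM-positive puncta per field give the total presynaptic strength
S = mean(dF) * D; the ratio S_burst/S_single between burst and
single-spike stimulation measures short-term presynaptic plasticity,
and destaining kinetics are summarized by 1/tau of an exponential fit.

Dose-response curves are fit with the four-parameter logistic (Hill)
model R(c) = bottom + (top - bottom) / (1 + (c/IC50)^h), least squares
in log10 concentration with multi-start IC50 initialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass(frozen=True)
class FluorTrace:
    """Uniformly sampled raw fluorescence (arbitrary units, > 0)."""

    samples: np.ndarray
    dt: float = 1.0 / 20.0       # 20-Hz frame rate
    roi_id: str = ""

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "samples",
                           np.asarray(self.samples, dtype=float))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt


@dataclass(frozen=True)
class CaEvent:
    onset: float
    amplitude: float             # peak dF/F


@dataclass(frozen=True)
class HillFitResult:
    ic50: float
    hill: float
    top: float
    bottom: float
    residual_norm: float
    identifiable: bool = True


def dff(trace: FluorTrace, event_onset: float,
        baseline_window: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """dF/F around an event: F0 = mean fluorescence over the 1 s before onset.

    Returns ``(t, dff)`` for the trace from onset onward, with
    ``dff = (F - F0)/F0``; raises if less than ``baseline_window`` of
    pre-onset data exists.
    """
    t = trace.times
    pre = (t >= event_onset - baseline_window) & (t < event_onset)
    if pre.sum() < max(1, int(round(baseline_window / trace.dt)) - 1):
        raise ValueError("insufficient pre-onset baseline data")
    f0 = float(trace.samples[pre].mean())
    if f0 <= 0:
        raise ValueError("non-positive baseline fluorescence")
    post = t >= event_onset
    return t[post], (trace.samples[post] - f0) / f0


def dff_series(trace: FluorTrace, baseline_window: float = 1.0) -> np.ndarray:
    """Whole-trace dF/F against the initial-baseline mean (for detection)."""
    n0 = max(1, int(round(baseline_window / trace.dt)))
    f0 = float(trace.samples[:n0].mean())
    if f0 <= 0:
        raise ValueError("non-positive baseline fluorescence")
    return (trace.samples - f0) / f0


def detect_transients(series: np.ndarray, dt: float = 1.0 / 20.0,
                      threshold_mult: float = 3.0,
                      min_separation: float = 0.5) -> list[CaEvent]:
    """Threshold detector for calcium transients on a dF/F series.

    Threshold = ``threshold_mult`` x robust SD (1.4826 * MAD) of the
    series; each suprathreshold excursion yields one event at its peak,
    and excursions whose gaps are shorter than ``min_separation`` are
    merged.  A flat series yields no events.
    """
    x = np.asarray(series, dtype=float)
    mad = np.median(np.abs(x - np.median(x)))
    thr = threshold_mult * 1.4826 * mad
    if thr == 0:
        # noise-free series (e.g. sparse transients on a silent baseline):
        # any excursion above the flat median is an event
        above = x > np.median(x)
    else:
        above = x > thr
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    # merge excursions separated by less than min_separation
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if (s - merged[-1][1]) * dt < min_separation:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        ipk = s + int(np.argmax(x[s:e + 1]))
        out.append(CaEvent(onset=float(s * dt), amplitude=float(x[ipk])))
    return out


def transient_rate(events: Sequence[CaEvent], duration_min: float) -> float:
    """Sum of transient amplitudes divided by recording time, dF/F per min."""
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    return float(sum(e.amplitude for e in events)) / duration_min


def fm_strength(puncta: pd.DataFrame, area: float | None = None
                ) -> dict[str, float]:
    """Presynaptic strength from an FM puncta table: S = mean(dF) * D.

    ``puncta`` has a ``dF`` column; the field ``area`` (image area units)
    comes from the argument or ``puncta.attrs['area']`` (default 1 image,
    making D puncta per image).
    """
    if len(puncta) == 0:
        raise ValueError("empty puncta set")
    if area is None:
        area = float(puncta.attrs.get("area", 1.0))
    if area <= 0:
        raise ValueError("area must be positive")
    mean_df = float(puncta["dF"].mean())
    d = len(puncta) / area
    return {"mean_dF": mean_df, "density": d, "S": mean_df * d}


def stp_ratio(s_burst: float, s_single: float) -> float:
    """Short-term plasticity ratio S_burst / S_single."""
    if s_single <= 0:
        raise ValueError("s_single must be positive")
    return s_burst / s_single


def destain_rate(trace: FluorTrace) -> dict[str, float]:
    """Destaining kinetics: fit A*exp(-t/tau) + C, return 1/tau.

    Raises on non-decaying or degenerate traces where the exponential
    fit cannot converge.
    """
    y = trace.samples
    if y.size < 5:
        raise ValueError("need >= 5 samples for the destain fit")
    t = trace.times
    if np.ptp(y) == 0:
        raise ValueError("constant trace: destain fit degenerate")
    a0 = float(y[0] - y[-1])
    c0 = float(y[-1])
    tau0 = float(t[-1] / 3 if t[-1] > 0 else 1.0)

    def model(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=(a0, tau0, c0),
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000)
    except (RuntimeError, ValueError) as err:
        raise ValueError(f"destain fit failed to converge: {err}") from err
    a, tau, c = popt
    if a <= 0:
        raise ValueError("trace is not decaying (fitted amplitude <= 0)")
    return {"tau_s": float(tau), "rate_per_s": float(1.0 / tau),
            "offset": float(c)}


def hill_fit(dose_response: pd.DataFrame) -> HillFitResult:
    """Four-parameter logistic fit of a dose-response table.

    Expects columns ``conc_uM`` (> 0) and ``response_pct``; least
    squares parameterized in log10(IC50) with five log-spaced IC50
    starts across the data range to avoid local minima.  Bounds:
    bottom >= 0, top <= 120, IC50 within the data range x[0.01, 100].
    Flat data leave the IC50 unidentifiable (flagged, NaN IC50).
    """
    c = dose_response["conc_uM"].to_numpy(dtype=float)
    r = dose_response["response_pct"].to_numpy(dtype=float)
    if np.unique(c).size < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if c.min() <= 0:
        raise ValueError("concentrations must be positive")
    if np.ptp(r) < 1e-9:
        return HillFitResult(float("nan"), float("nan"), float(r.mean()),
                             float(r.mean()), 0.0, identifiable=False)
    logc = np.log10(c)

    def model(p):
        log_ic50, h, top, bottom = p
        return bottom + (top - bottom) / (1.0 + 10.0 ** (h * (logc - log_ic50)))

    lo = [np.log10(c.min() * 0.01), 0.05, max(r.max() - 0.5 * np.ptp(r), 0.0), 0.0]
    hi = [np.log10(c.max() * 100.0), 10.0, 120.0, r.min() + 0.5 * np.ptp(r)]
    best = None
    for log_start in np.linspace(np.log10(c.min()), np.log10(c.max()), 5):
        p0 = [float(np.clip(log_start, lo[0], hi[0])), 1.0,
              float(np.clip(r.max(), lo[2], hi[2])),
              float(np.clip(r.min(), lo[3], hi[3]))]
        try:
            res = optimize.least_squares(lambda p: model(p) - r, p0,
                                         bounds=(lo, hi),
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ValueError("Hill fit failed from all starting points")
    log_ic50, h, top, bottom = best.x
    return HillFitResult(ic50=float(10.0 ** log_ic50), hill=float(h),
                         top=float(top), bottom=float(bottom),
                         residual_norm=float(np.sqrt(2.0 * best.cost)))


def ic50_fold(ic50_a: float, ic50_b: float) -> float:
    """Order-invariant IC50 fold shift: larger / smaller."""
    if min(ic50_a, ic50_b) <= 0:
        raise ValueError("IC50 values must be positive")
    return max(ic50_a, ic50_b) / min(ic50_a, ic50_b)
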