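"""Intracellular (whole-cell) metrics.

Integrated excitatory/inhibitory conductances from voltage-clamp current
records, the per-cell I/E conductance ratio, mEPSC event summaries with
the 200-event random subsampling used to pool cells fairly, F-I curves
from current-clamp step protocols, and input resistance from the
hyperpolarizing step series.

Conductance: for a current record I(t) held at V_M with synaptic
reversal V_rev, the integrated conductance is

    G = (1/T) * integral |I(t)| dt / |V_M - V_rev|

(trapezoidal quadrature), i.e. the mean synaptic conductance over the
record in nS when I is in pA and voltages in mV.  The record duration
normalization makes records of different lengths comparable; the raw
integral in nS*s is returned alongside.  Currents are rectified so both
inward excitatory and outward inhibitory currents give positive
conductances.  Typical reversals after junction-potential correction:
V_E ~ +10 mV, V_I ~ -65 mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CurrentTrace:
    """Uniformly sampled current record under voltage clamp."""

    samples: np.ndarray        # pA
    dt: float                  # s
    v_m: float                 # holding potential, mV
    v_rev: float               # synaptic reversal potential, mV

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def duration(self) -> float:
        return (len(self.samples) - 1) * self.dt


@dataclass(frozen=True)
class PSCEventList:
    """Detected postsynaptic-current events (times s, amplitudes pA > 0)."""

    times: np.ndarray
    amplitudes: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.size != a.size:
            raise ValueError("times and amplitudes differ in length")
        if a.size and a.min() <= 0:
            raise ValueError("amplitudes must be positive magnitudes")
        order = np.argsort(t, kind="stable")
        object.__setattr__(self, "times", t[order])
        object.__setattr__(self, "amplitudes", a[order])

    @property
    def n_events(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class StepProtocol:
    """Current-step protocol: injected currents and per-step responses.

    ``responses`` holds either sampled voltage traces (one row per step,
    for F-I spike counting / input resistance) with sample interval
    ``dt``, or precomputed steady-state voltages when 1-D.
    """

    currents_pa: np.ndarray
    responses: np.ndarray
    dt: float = 1e-4
    step_duration: float = 0.5

    def __post_init__(self) -> None:
        c = np.asarray(self.currents_pa, dtype=float)
        if c.size > 1 and not np.all(np.diff(c) > 0):
            raise ValueError("injected currents must be strictly increasing")
        object.__setattr__(self, "currents_pa", c)
        object.__setattr__(self, "responses", np.asarray(self.responses, dtype=float))


def integrated_conductance(trace: CurrentTrace) -> dict[str, float]:
    """Mean synaptic conductance of a current record, nS.

    Returns ``{"g_ns", "integral_ns_s"}``; pA / mV = nS.
    """
    dv = abs(trace.v_m - trace.v_rev)
    if dv == 0:
        raise ValueError("zero driving force: V_M equals V_rev")
    if trace.duration <= 0:
        raise ValueError("trace too short")
    integral_pa_s = float(np.trapezoid(np.abs(trace.samples), dx=trace.dt))
    return {"g_ns": integral_pa_s / dv / trace.duration,
            "integral_ns_s": integral_pa_s / dv}


def ie_ratio(g_i_per_cell: Sequence[float], g_e_per_cell: Sequence[float]
             ) -> float:
    """Mean over cells of each cell's G_I/G_E (not the ratio of means).

    Cells with G_E = 0 are excluded with a warning.
    """
    gi = np.asarray(g_i_per_cell, dtype=float)
    ge = np.asarray(g_e_per_cell, dtype=float)
    if gi.size != ge.size:
        raise ValueError("per-cell arrays differ in length")
    ok = ge > 0
    if not ok.all():
        import warnings
        warnings.warn(f"excluded {int((~ok).sum())} cell(s) with G_E = 0",
                      stacklevel=2)
    if not ok.any():
        raise ValueError("no cells with positive G_E")
    return float(np.mean(gi[ok] / ge[ok]))


def mepsc_summary(events: PSCEventList, duration: float) -> dict:
    """Amplitude/frequency summary and cumulative distributions of mEPSCs."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    amps = np.sort(events.amplitudes)
    ieis = np.diff(events.times)
    return {
        "n_events": events.n_events,
        "mean_amplitude_pa": float(amps.mean()) if amps.size else float("nan"),
        "frequency_hz": events.n_events / duration,
        "amplitude_cdf": (amps, np.arange(1, amps.size + 1) / amps.size),
        "iei_cdf": (np.sort(ieis), np.arange(1, ieis.size + 1) / max(ieis.size, 1)),
    }


def subsample_events(events: PSCEventList, k: int = 200, seed: int = 0
                     ) -> tuple[PSCEventList, bool]:
    """``k`` events uniformly without replacement, for fair pooling across cells.

    Returns ``(subsample, short)``; when fewer than ``k`` events exist
    all are returned and the ``short`` flag is set.
    """
    n = events.n_events
    if n <= k:
        return events, n < k
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 30]))
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return PSCEventList(events.times[idx], events.amplitudes[idx],
                        events.cell_id), False


def fold_change(reference_mean: float, test_mean: float,
                round_digits: int | None = None) -> float:
    """test / reference, optionally rounded to ``round_digits`` decimals."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    r = test_mean / reference_mean
    return round(r, round_digits) if round_digits is not None else r


def count_spikes(voltage_mv: np.ndarray, dt: float,
                 threshold_mv: float = 0.0, refractory_s: float = 0.002) -> int:
    """Upward threshold crossings with a refractory merge window."""
    v = np.asarray(voltage_mv, dtype=float)
    up = np.flatnonzero((v[1:] >= threshold_mv) & (v[:-1] < threshold_mv))
    if up.size == 0:
        return 0
    keep = np.concatenate([[True], np.diff(up) * dt > refractory_s])
    return int(keep.sum())


def fi_curve(protocol: StepProtocol, spike_threshold_mv: float = 0.0
             ) -> pd.DataFrame:
    """Firing rate per injected current from 500-ms depolarizing steps."""
    if protocol.responses.ndim != 2:
        raise ValueError("F-I needs one voltage trace per step")
    rows = []
    for i_pa, v in zip(protocol.currents_pa, protocol.responses):
        n = count_spikes(v, protocol.dt, spike_threshold_mv)
        rows.append({"current_pa": i_pa, "n_spikes": n,
                     "rate_hz": n / protocol.step_duration})
    return pd.DataFrame(rows)


def input_resistance(protocol: StepProtocol,
                     steady_state_fraction: float = 0.2) -> float:
    """Input resistance (MOhm) as the OLS slope of steady-state dV vs dI.

    Intended for hyperpolarizing series (e.g. -80 to -20 pA in 20-pA
    steps).  Steady-state voltage = mean over the last
    ``steady_state_fraction`` of each step when traces are supplied;
    1-D responses are taken as steady-state voltages directly.
    mV / pA = GOhm, so the slope is scaled to MOhm.
    """
    if protocol.responses.ndim == 2:
        n = protocol.responses.shape[1]
        tail = max(1, int(round(steady_state_fraction * n)))
        v = protocol.responses[:, -tail:].mean(axis=1)
    else:
        v = protocol.responses
    slope_mv_per_pa = float(np.polyfit(protocol.currents_pa, v, 1)[0])
    return slope_mv_per_pa * 1000.0   # GOhm -> MOhm
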