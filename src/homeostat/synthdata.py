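"""Synthetic-data generators emulating cultured-network recordings.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the analyses assume: log-normally distributed unit
firing rates skewed to low frequencies, synchronized network bursts on
top of background Poisson spiking, an acute pharmacological suppression
with slow population-level recovery but per-unit scatter, Poisson mEPSC
event trains with log-normal amplitudes, spike-linked calcium transients
that sum linearly, FM-dye puncta intensity tables, and sigmoidal
dose-response data.

These are statistical emulators, not biophysical simulations: there is no
conductance-based network model and no plasticity rule.  The perturbation
model writes the homeostatic recovery directly into each unit's rate
process,

    r_i(t) = base_i * [s0 + (1 - s0) * (1 - exp(-(t - onset)/tau)) * g_i]

with per-unit recovery multipliers g_i drawn log-normal with E[g] = 1
(log-mean -sigma^2/2), so the population mean recovers to ~100% of
baseline while individual units scatter around their set points — the
dissociation between macroscopic stability and microscopic instability is
built in, and the detection/classification stages are tested against it.

Reproducibility: each generator takes an explicit seed; ``gen_session``
derives one independent RNG substream per unit (plus one for the burst
process), so adding units does not perturb the spike times of existing
ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spikedata import RecordingSession, SpikeTrain, TimeSegment

__all__ = [
    "Perturbation", "SynthConfig", "SynthTruth",
    "gen_session", "gen_mepsc_events", "gen_calcium_trace",
    "gen_fm_puncta", "gen_dose_response",
]


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Independent, order-stable RNG substream for a (seed, key) pair."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


@dataclass(frozen=True)
class Perturbation:
    """Acute rate suppression with exponential population-level recovery.

    Defaults emulate a strong use-dependent synaptic blockade: immediate
    drop to ~1% of baseline and recovery with a time constant of ~1.2
    days so the population mean passes ~57% at 1 day and ~100% at 2 days.
    ``unit_dispersion`` is the SD of log g_i; at 0 every unit returns
    exactly to baseline, at the default 0.8 the population recovers while
    most units settle away from their own baseline.
    """

    onset: float = 3 * 3600.0
    suppression_factor: float = 0.012
    recovery_tau: float = 1.0e5
    unit_dispersion: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.suppression_factor <= 1.0:
            raise ValueError("suppression_factor must be in [0, 1]")
        if self.recovery_tau <= 0 or self.unit_dispersion < 0:
            raise ValueError("invalid perturbation parameters")


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterization of the synthetic MEA session generator.

    Defaults emulate one ~3-week-old hippocampal culture on a 59-electrode
    MEA: ~60 sorted units whose background rates are log-normal with
    median 0.3 Hz and log-SD 1.0 (heavily right-skewed on a linear
    scale), plus network bursts at 0.1 Hz, each recruiting ~60% of units
    for ~8 spikes at 10-ms intra-burst intervals — mature cultures are
    strongly burst-dominated, and with these defaults roughly half of
    all spikes fall inside network bursts.
    """

    n_units: int = 60
    rate_lognorm: tuple[float, float] = (0.3, 1.0)   # (median Hz, sigma of log)
    burst_event_rate: float = 0.1                    # Hz
    recruit_prob: float = 0.6
    spikes_per_event: float = 8.0
    intra_burst_isi: float = 0.010                   # s
    duration: float = 3600.0                         # s
    perturbation: Perturbation | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 0 or self.duration < 0:
            raise ValueError("n_units and duration must be non-negative")
        if not 0.0 <= self.recruit_prob <= 1.0:
            raise ValueError("recruit_prob must be in [0, 1]")
        if min(self.burst_event_rate, self.spikes_per_event,
               self.intra_burst_isi, self.rate_lognorm[0]) < 0:
            raise ValueError("rates and counts must be non-negative")


@dataclass
class SynthTruth:
    """Ground truth emitted alongside a synthetic session."""

    base_rates: dict[str, float]
    asymptotic_rates: dict[str, float]
    recovery_multipliers: dict[str, float]
    burst_times: np.ndarray
    burst_units: list[list[str]]          # units with >=1 emitted spike per event
    burst_spike_count: int                # total spikes emitted inside bursts
    config: SynthConfig = field(repr=False, default=None)


def _rate_factor(t: np.ndarray, p: Perturbation | None, g: float) -> np.ndarray:
    """Per-unit instantaneous rate relative to baseline."""
    t = np.asarray(t, dtype=np.float64)
    if p is None:
        return np.ones_like(t)
    s0, tau = p.suppression_factor, p.recovery_tau
    post = s0 + (1.0 - s0) * (1.0 - np.exp(-np.maximum(t - p.onset, 0.0) / tau)) * g
    return np.where(t < p.onset, 1.0, post)


def gen_session(config: SynthConfig) -> tuple[RecordingSession, SynthTruth]:
    """Generate a synthetic MEA session and its ground truth.

    Background spiking is an independent inhomogeneous Poisson process per
    unit (thinning of a homogeneous process at the unit's peak rate);
    network bursts are a homogeneous Poisson event process, each event
    recruiting each unit independently with ``recruit_prob``; a recruited
    unit emits ``max(1, Poisson(spikes_per_event))`` spikes spaced at the
    intra-burst ISI jittered +/-30%, thinned by the same perturbation
    factor as the background so suppression silences bursts too.
    """
    p = config.perturbation
    rng_units = _substream(config.seed, 0)
    med, sig = config.rate_lognorm
    base = med * np.exp(sig * rng_units.standard_normal(config.n_units))
    if p is not None and p.unit_dispersion > 0:
        d = p.unit_dispersion
        g = np.exp(-d * d / 2.0 + d * rng_units.standard_normal(config.n_units))
        # normalize so the base-rate-weighted mean is exactly 1: the
        # population mean rate recovers to its set point by construction
        # while individual units scatter around theirs
        g = g / np.average(g, weights=base)
    else:
        g = np.ones(config.n_units)

    unit_ids = [f"u{k:03d}" for k in range(config.n_units)]
    interval = TimeSegment(0.0, max(config.duration, 1e-4))
    T = config.duration

    # network-burst event process (substream 1)
    rng_burst = _substream(config.seed, 1)
    n_events = rng_burst.poisson(config.burst_event_rate * T)
    burst_times = np.sort(rng_burst.uniform(0.0, T, n_events))
    recruit = rng_burst.random((n_events, config.n_units)) < config.recruit_prob
    event_counts = np.maximum(
        rng_burst.poisson(config.spikes_per_event, (n_events, config.n_units)), 1)

    trains: dict[str, SpikeTrain] = {}
    burst_units: list[set[str]] = [set() for _ in range(n_events)]
    burst_spike_count = 0
    for k, uid in enumerate(unit_ids):
        rng = _substream(config.seed, 2, k)  # one substream per unit
        # background: thinned homogeneous Poisson at the unit's peak rate
        peak = base[k] * float(np.max(_rate_factor(
            np.array([0.0, T]), p, g[k])) if p is not None else 1.0)
        peak = max(peak, base[k] * 1e-12)
        n_bg = rng.poisson(peak * T)
        t_bg = rng.uniform(0.0, T, n_bg)
        keep = rng.random(n_bg) < _rate_factor(t_bg, p, g[k]) * base[k] / peak
        t_bg = t_bg[keep]

        # burst spikes for events that recruited this unit
        t_ev: list[np.ndarray] = []
        for e in np.flatnonzero(recruit[:, k]):
            n_sp = int(event_counts[e, k])
            isis = config.intra_burst_isi * rng.uniform(0.7, 1.3, n_sp)
            tt = burst_times[e] + np.concatenate([[0.0], np.cumsum(isis[:-1])])
            keep_ev = rng.random(n_sp) < _rate_factor(tt, p, g[k])
            tt = tt[keep_ev & (tt < T)]
            if tt.size:
                t_ev.append(tt)
                burst_units[e].add(uid)
                burst_spike_count += tt.size
        all_t = np.concatenate([t_bg, *t_ev]) if t_ev else t_bg
        with warnings.catch_warnings():
            # coincident background/burst spikes may collide at 0.1-ms
            # resolution; the collapse is intended, not worth a warning here
            warnings.simplefilter("ignore")
            trains[uid] = SpikeTrain(uid, np.sort(all_t), interval)

    epochs: dict[str, TimeSegment] = {}
    if p is not None and 0 < p.onset < T:
        epochs["baseline"] = TimeSegment(0.0, p.onset)
        epochs["perturbation"] = TimeSegment(p.onset, T)
    session = RecordingSession(trains=trains, duration=T, epochs=epochs)

    s0 = p.suppression_factor if p is not None else None
    asym = {
        uid: float(base[k] * (s0 + (1 - s0) * g[k])) if p is not None else float(base[k])
        for k, uid in enumerate(unit_ids)
    }
    truth = SynthTruth(
        base_rates={uid: float(base[k]) for k, uid in enumerate(unit_ids)},
        asymptotic_rates=asym,
        recovery_multipliers={uid: float(g[k]) for k, uid in enumerate(unit_ids)},
        burst_times=burst_times,
        burst_units=[sorted(s) for s in burst_units],
        burst_spike_count=burst_spike_count,
        config=config,
    )
    return session, truth


def gen_mepsc_events(rate: float, amp_lognorm: tuple[float, float],
                     duration: float, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Poisson mEPSC event train with log-normal amplitudes.

    Returns ``(times, amplitudes)``; default-style parameters for a
    control culture are rate ~2.1 Hz and median amplitude ~23 pA.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 10]))
    n = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, n))
    med, sig = amp_lognorm
    amps = med * np.exp(sig * rng.standard_normal(n))
    return times, amps


def gen_calcium_trace(train: SpikeTrain, unit_amp: float = 0.246,
                      decay_tau: float = 0.6, noise_sd: float = 0.0,
                      frame_rate: float = 20.0, baseline_f: float = 1.0,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Somatic calcium-indicator fluorescence for a spike train.

    Each spike adds an instantaneous-rise, exponentially decaying
    transient of fractional amplitude ``unit_amp`` (default 0.246, the
    single-spike dF/F of a fast genetically encoded indicator);
    amplitudes of coincident spikes sum linearly.  Returns
    ``(t, fluorescence)`` sampled at ``frame_rate`` with the trace in
    raw units around ``baseline_f`` plus additive Gaussian noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    t0, t1 = train.valid_interval.start, train.valid_interval.end
    t = t0 + np.arange(int(np.floor((t1 - t0) * frame_rate))) / frame_rate
    dff = np.zeros_like(t)
    for ts in train.times:
        m = t >= ts
        dff[m] += unit_amp * np.exp(-(t[m] - ts) / decay_tau)
    f = baseline_f * (1.0 + dff)
    if noise_sd > 0:
        f = f + baseline_f * noise_sd * rng.standard_normal(t.size)
    return t, f


def gen_fm_puncta(n: int, dF_lognorm: tuple[float, float], area: float,
                  stp_ratio: float, noise_sd: float = 0.1, seed: int = 0
                  ) -> dict[str, "pd.DataFrame"]:
    """Paired FM-dye puncta tables for single-spike and burst stimulation.

    Burst-condition dF values are the single-condition values scaled by
    ``stp_ratio`` with multiplicative log-normal noise; puncta density is
    ``n / area``.  Returns ``{"single": df, "burst": df}`` with columns
    ``punctum_id, dF, condition`` and attrs ``area``.
    """
    import pandas as pd
    if n <= 0:
        raise ValueError("empty puncta set")
    if area <= 0:
        raise ValueError("area must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 12]))
    med, sig = dF_lognorm
    single = med * np.exp(sig * rng.standard_normal(n))
    mult = (np.exp(noise_sd * rng.standard_normal(n) - noise_sd ** 2 / 2)
            if noise_sd > 0 else np.ones(n))
    burst = single * stp_ratio * mult
    out = {}
    for cond, vals in (("single", single), ("burst", burst)):
        df = pd.DataFrame({
            "punctum_id": np.arange(n), "dF": vals, "condition": cond})
        df.attrs["area"] = float(area)
        out[cond] = df
    return out


def gen_dose_response(ic50: float, hill: float, top: float, bottom: float,
                      concentrations: Sequence[float], noise_sd: float = 0.0,
                      seed: int = 0) -> "pd.DataFrame":
    """Four-parameter-logistic dose-response table with Gaussian noise.

    ``R(c) = bottom + (top - bottom) / (1 + (c/ic50)^hill)``; columns
    ``conc_uM, response_pct``.
    """
    import pandas as pd
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    c = np.asarray(concentrations, dtype=np.float64)
    resp = bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)
    if noise_sd > 0:
        resp = resp + noise_sd * rng.standard_normal(c.size)
    return pd.DataFrame({"conc_uM": c, "response_pct": resp})
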