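"""Firing-rate stability analyses.

Implements the per-unit stability test used to ask whether individual
neurons keep their firing-rate set points while the population mean
recovers: the two epochs to be compared are divided into 1-min rate
bins, the bins are pooled and randomly reassigned to two pseudo-groups
10,000 times, and the resulting null distribution of mean differences
yields a 95% interval.  A unit whose observed rate difference falls
outside that interval is classified as increased or decreased,
otherwise stable.

Also provided: hourly population mean-firing-rate (MFR) time courses as
percent of baseline, the coefficient-of-variation-vs-bin-size analysis,
the 20-min-segment representativeness check, two-sample KS comparison of
log-rate distributions, and the Spearman correlation between baseline
rate and subsequent percent change.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spikedata import (RecordingSession, SpikeTrain, TimeSegment,
                        hourly_segments, mean_firing_rate, restrict)

DEFAULT_BIN_WIDTH = 60.0      # s: 1-min rate bins
DEFAULT_N_ITER = 10_000
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class RateBins:
    """Per-bin firing rates of one unit over one segment."""

    unit_id: str
    segment: TimeSegment
    bin_width: float
    counts: np.ndarray

    @property
    def rates(self) -> np.ndarray:
        return self.counts / self.bin_width

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class ChangeClassification:
    """Outcome of the per-unit permutation stability test."""

    unit_id: str
    rate_a: float
    rate_b: float
    observed_diff: float
    null_lo: float
    null_hi: float
    label: str                  # increased | decreased | stable
    n_iter: int
    seed: int


def bin_rates(train: SpikeTrain, seg: TimeSegment,
              bin_width: float = DEFAULT_BIN_WIDTH) -> RateBins:
    """Spike counts in half-open bins; a trailing partial bin is dropped."""
    if seg.duration < bin_width:
        raise ValueError("segment shorter than one bin")
    n_bins = int(seg.duration // bin_width)
    edges = seg.start + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(train.times, bins=edges)
    return RateBins(train.unit_id, seg, bin_width, counts.astype(np.float64))


def _unit_seed(seed: int, unit_id: str) -> np.random.SeedSequence:
    # stable per-unit substream independent of unit iteration order
    return np.random.SeedSequence([int(seed), zlib.crc32(str(unit_id).encode())])


def permutation_change_test(a: RateBins, b: RateBins,
                            n_iter: int = DEFAULT_N_ITER,
                            alpha: float = DEFAULT_ALPHA,
                            seed: int = 0,
                            method: str = "permutation") -> ChangeClassification:
    """Classify a unit's rate change between two epochs against a shuffle null.

    ``observed_diff = mean(b) - mean(a)`` in Hz.  The null pools all bins
    and reassigns them ``n_iter`` times into pseudo-groups of the
    original sizes (``method="permutation"``, without replacement; the
    ``"bootstrap"`` variant resamples with replacement); the
    classification interval is the empirical
    ``[100*alpha/2, 100*(1-alpha/2)]`` percentile range of the null mean
    differences.  Values on the interval boundary are labeled stable
    (conservative).
    """
    if a.bin_width != b.bin_width:
        raise ValueError("bin widths differ")
    if a.n_bins < 2 or b.n_bins < 2:
        raise ValueError("need >= 2 bins per segment")
    ra, rb = a.rates, b.rates
    observed = float(rb.mean() - ra.mean())
    pooled = np.concatenate([ra, rb])
    na, n = ra.size, pooled.size
    rng = np.random.default_rng(_unit_seed(seed, a.unit_id))
    tot = pooled.sum()
    if method == "permutation":
        # vectorized group reassignment: random keys -> first na indices
        keys = rng.random((n_iter, n))
        idx_a = np.argpartition(keys, na - 1, axis=1)[:, :na]
        sum_a = pooled[idx_a].sum(axis=1)
        null = (tot - sum_a) / (n - na) - sum_a / na
    elif method == "bootstrap":
        idx = rng.integers(0, n, size=(n_iter, n))
        samp = pooled[idx]
        null = samp[:, na:].mean(axis=1) - samp[:, :na].mean(axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    lo, hi = np.percentile(null, [100 * alpha / 2, 100 * (1 - alpha / 2)],
                           method="nearest")
    if observed > hi:
        label = "increased"
    elif observed < lo:
        label = "decreased"
    else:
        label = "stable"
    return ChangeClassification(a.unit_id, float(ra.mean()), float(rb.mean()),
                                observed, float(lo), float(hi), label,
                                n_iter, seed)


def classify_population(session: RecordingSession, seg_a: TimeSegment,
                        seg_b: TimeSegment,
                        bin_width: float = DEFAULT_BIN_WIDTH,
                        n_iter: int = DEFAULT_N_ITER,
                        alpha: float = DEFAULT_ALPHA,
                        seed: int = 0,
                        method: str = "permutation"
                        ) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-unit stability test across a session; percentages over tested units.

    Units silent in both segments are excluded (their change is
    undefined); the per-unit table records every unit with its label.
    """
    rows = []
    for uid, tr in session.trains.items():
        a = bin_rates(tr, seg_a, bin_width)
        b = bin_rates(tr, seg_b, bin_width)
        if a.counts.sum() == 0 and b.counts.sum() == 0:
            continue
        c = permutation_change_test(a, b, n_iter, alpha, seed, method)
        rows.append({"unit_id": uid, "rate_a": c.rate_a, "rate_b": c.rate_b,
                     "observed_diff": c.observed_diff, "null_lo": c.null_lo,
                     "null_hi": c.null_hi, "label": c.label})
    table = pd.DataFrame(rows, columns=["unit_id", "rate_a", "rate_b",
                                        "observed_diff", "null_lo",
                                        "null_hi", "label"])
    n = len(table)
    summary = {
        "n_units": n,
        "pct_stable": 100.0 * (table["label"] == "stable").sum() / n if n else float("nan"),
        "pct_increased": 100.0 * (table["label"] == "increased").sum() / n if n else float("nan"),
        "pct_decreased": 100.0 * (table["label"] == "decreased").sum() / n if n else float("nan"),
    }
    return summary, table


def mfr_timecourse(session: RecordingSession,
                   baseline: TimeSegment | str | None = "baseline",
                   window_min: float = 20.0) -> pd.DataFrame:
    """Hourly population MFR as percent of the baseline-epoch mean.

    Each hour is represented by the first ``window_min`` minutes; the
    baseline is either an epoch label, an explicit segment, or (None)
    the first hourly window.
    """
    segs = hourly_segments(session, window_min)
    if not segs:
        raise ValueError("session shorter than one hour")
    hourly = np.array([
        np.mean([mean_firing_rate(tr, s) for tr in session.trains.values()])
        for s in segs])
    if isinstance(baseline, str):
        base_seg = session.epochs.get(baseline)
        if base_seg is None:
            base_seg = segs[0]
        base_hours = [h for h, s in zip(hourly, segs)
                      if s.start >= base_seg.start and s.end <= base_seg.end]
        base = float(np.mean(base_hours)) if base_hours else float(np.mean(
            [mean_firing_rate(tr, base_seg) for tr in session.trains.values()]))
    elif isinstance(baseline, TimeSegment):
        base = float(np.mean([mean_firing_rate(tr, baseline)
                              for tr in session.trains.values()]))
    else:
        base = float(hourly[0])
    return pd.DataFrame({
        "hour": np.arange(len(segs)),
        "mfr_hz": hourly,
        "pct_of_baseline": 100.0 * hourly / base if base > 0 else np.nan,
    })


def cv_by_binsize(train: SpikeTrain, window: TimeSegment,
                  bin_sizes: Sequence[float] = (10, 60, 300, 600, 1200, 1800, 3600)
                  ) -> pd.DataFrame:
    """Coefficient of variation (%) of per-bin rates at several bin sizes.

    CV = 100 * SD / mean of the rates in consecutive bins across the
    window (default 8-h windows upstream); NaN where the mean is 0.
    """
    rows = []
    for bs in bin_sizes:
        rb = bin_rates(train, window, bin_width=bs)
        r = rb.rates
        m = r.mean()
        rows.append({"bin_size_s": bs,
                     "cv_pct": 100.0 * r.std(ddof=0) / m if m > 0 else float("nan")})
    return pd.DataFrame(rows)


def segment_representativeness(session: RecordingSession,
                               window_min: float = 20.0) -> pd.DataFrame:
    """Ratio of each unit-hour's window MFR to its full-hour MFR.

    Quantifies how well the first ``window_min`` minutes of an hour
    represent the hour; the summary columns report the fraction of
    (unit, hour) pairs whose ratio deviates from 1 by more than 10% and
    20%.  Silent full hours are skipped.
    """
    n_hours = int(session.duration // 3600)
    rows = []
    for h in range(n_hours):
        full = TimeSegment(h * 3600.0, (h + 1) * 3600.0)
        part = TimeSegment(h * 3600.0, h * 3600.0 + window_min * 60.0)
        for uid, tr in session.trains.items():
            m_full = mean_firing_rate(tr, full)
            if m_full == 0:
                continue
            rows.append({"unit_id": uid, "hour": h,
                         "ratio": mean_firing_rate(tr, part) / m_full})
    df = pd.DataFrame(rows, columns=["unit_id", "hour", "ratio"])
    if len(df):
        dev = np.abs(df["ratio"] - 1.0)
        df.attrs["pct_beyond_10"] = 100.0 * float((dev > 0.10).mean())
        df.attrs["pct_beyond_20"] = 100.0 * float((dev > 0.20).mean())
    return df


def compare_rate_distributions(rates_a: np.ndarray, rates_b: np.ndarray
                               ) -> dict[str, float]:
    """Two-sample KS test on log10 firing rates; zero rates are excluded."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    a_pos, b_pos = a[a > 0], b[b > 0]
    res = stats.ks_2samp(np.log10(a_pos), np.log10(b_pos))
    return {"ks_statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n_excluded_zero": int((a <= 0).sum() + (b <= 0).sum())}


def baseline_change_correlation(rates_0: np.ndarray, rates_2d: np.ndarray
                                ) -> dict[str, float]:
    """Spearman correlation of baseline rate vs percent rate change.

    Change = 100 * (r2 - r0) / r0; zero-baseline units are excluded.
    Returns NaN correlation when the change is constant (undefined ranks).
    """
    r0 = np.asarray(rates_0, dtype=float)
    r2 = np.asarray(rates_2d, dtype=float)
    ok = r0 > 0
    r0, r2 = r0[ok], r2[ok]
    change = 100.0 * (r2 - r0) / r0
    if r0.size < 2 or np.ptp(change) == 0:
        return {"spearman_r": float("nan"), "p_value": float("nan"),
                "n_units": int(r0.size)}
    rho, p = stats.spearmanr(r0, change)
    return {"spearman_r": float(rho), "p_value": float(p), "n_units": int(r0.size)}
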