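# homeostat

Analysis pipeline for **firing-rate homeostasis in cultured neuronal
networks**, built for long-term multi-electrode array (MEA) recordings of
dissociated hippocampal cultures under chronic pharmacological
perturbation, together with the companion synaptic and optical readouts
(whole-cell conductances and mEPSCs, calcium imaging, FM-dye presynaptic
measurements, dose–response fits).

The central scientific question the pipeline addresses: when network
activity is chronically suppressed — for example by use-dependent
presynaptic inhibition through GABA_B receptors — the *population* mean
firing rate (MFR) slowly returns to its baseline set point, but do the
*individual* neurons return to theirs?  Answering it requires (i) robust
detection of collective events (network bursts) against a principled
null, and (ii) a per-unit statistical test of rate stability between
epochs.  Both are implemented here, driven by a synthetic-data generator
that reproduces the statistical structure of such recordings so every
stage is testable end to end without external data.

## Methods at a glance

**Network-burst detection.**  All units' spike times are pooled onto one
timeline Θ = ∪_{α,i}{t_i^α} and the local spike density is estimated by
Parzen kernel density estimation with a Gaussian kernel on a 50-ms grid:

    f̂(t) = Σ_i ρ_σ(t − t_i),   ρ_σ(t) = (2πσ²)^(−1/2) exp(−t²/2σ²)

with kernel variance σ² = 0.5 in squared grid steps (σ ≈ 35.4 ms).  The
detection threshold is the 95th percentile of the density of a
homogeneous Poisson process with the same spike count over the same
interval, estimated from 20 simulated surrogates — computed separately
for each hourly interval, because the culture's spike statistics drift.
Every maximal supra-threshold excursion is a candidate burst; candidates
carried by fewer than ~25% of the hour's active units (a unit is active
in a burst if it contributed ≥ 2 spikes) are discarded.  Single-unit
bursts are defined as ≥ 3 spikes at ≥ 50 Hz (every ISI ≤ 20 ms), with a
3 × 3 parameter sweep (2/3/4 spikes × 20/50/100 Hz) to establish
robustness.

**Per-unit stability test.**  For each unit, the two epochs to compare
are divided into 1-min rate bins; the bins are pooled and reshuffled
into two pseudo-groups 10,000 times to build a null distribution of
mean-rate differences.  A unit whose observed difference falls outside
the null's 95% interval is classified *increased* or *decreased*,
otherwise *stable*.  Population summaries report the percentage of each
class, the hourly population MFR as percent of baseline, two-sample
Kolmogorov–Smirnov comparisons of log-rate distributions, and the
Spearman correlation between baseline rate and subsequent percent
change.

**Synaptic and optical metrics.**  Integrated synaptic conductances
G = (1/T)·∫|I(t)|dt / |V_M − V_rev| (nS) and the per-cell I/E ratio;
mEPSC amplitude/frequency summaries with 200-event random subsampling
per cell; F–I curves and input resistance from step protocols; ΔF/F
(1-s pre-event baseline) and calcium-transient rates (sum of transient
amplitudes per minute); FM-dye presynaptic strength S = ΔF × D and the
short-term-plasticity ratio S_burst/S_single; destaining rate 1/τ from
exponential fits; IC50 from four-parameter-logistic dose–response fits.

## Worked example

Simulate a 6-hour, 40-unit recording with an acute suppression to ~1% of
baseline one hour in, followed by population-level recovery with
per-unit scatter, then run the analysis:

```python
import homeostat as h

cfg = h.SynthConfig(
    n_units=40, duration=6 * 3600.0, seed=42,
    perturbation=h.Perturbation(onset=3600.0, suppression_factor=0.012,
                                recovery_tau=1800.0, unit_dispersion=0.8))
session, truth = h.gen_session(cfg)

print(h.mfr_timecourse(session, baseline="baseline").round(2))

seg_a = h.TimeSegment(2400.0, 3600.0)                       # late baseline
seg_b = h.TimeSegment(session.duration - 1200.0, session.duration)
summary, table = h.classify_population(session, seg_a, seg_b, seed=1)
print(summary)

windows = h.detect_network_bursts(session, seed=2)
print(h.network_burst_metrics(windows[0][1], session, windows[0][0]))
```

Output:

```
 hour  mfr_hz  pct_of_baseline
    0    0.89           100.00
    1    0.29            32.76
    2    0.75            84.04
    3    0.83            93.28
    4    0.78            87.63
    5    0.81            90.35
{'n_units': 40, 'pct_stable': 37.5, 'pct_increased': 22.5, 'pct_decreased': 40.0}
{'fraction_spikes_in_bursts': 0.522, 'mean_duration': 0.244,
 'mean_spikes_per_burst': 198.177, 'burst_rate': 0.094}
```

Reading the numbers: the population MFR collapses in the perturbation
hour (33% of baseline, an average over the pre-onset portion of that
window and the suppressed remainder) and climbs back toward 100% as the
homeostatic recovery proceeds — yet only 37.5% of individual units are
classified as unchanged between late baseline and the final 20 minutes:
the population set point is restored while most single neurons settle at
new rates.  During baseline, roughly half of all spikes occur inside
network bursts, detected at ~0.09 Hz.

The same pipeline is available from the shell:

```sh
homeostat emulate --preset baclofen_like --seed 5 --out out/
homeostat simulate --seed 4 --n-units 30 --duration 3600 --out session.h5
homeostat detect-bursts --input session.h5 --seed 1 --out bursts.csv
```

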