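# Methods

This note documents the models, parameter choices, numerical details and
limitations of the `homeostat` package: what each procedure assumes,
which knobs matter, and what the synthetic-data generator does and does
not emulate.

## Data model and conventions

All times are in seconds, zero-based; every interval is half-open
`[start, end)` so segments compose without double counting.  Spike times
are kept at 0.1-ms resolution (10-kHz acquisition); duplicates at that
resolution are collapsed with a warning.  Hourly analyses use the first
20 minutes of each complete hour — the standard down-sampling for
multi-day MEA recordings — and incomplete trailing hours are dropped.
Session duration comes from file metadata when present, otherwise the
last spike time rounded up to the next whole second (trailing silence is
real data; the rounding keeps the last spike inside the half-open
validity interval).  Multiunit trains carry a flag and flow through the
same code paths, so they can be reported separately without special
casing.

## Network-burst detection

The pooled spike density is a Parzen kernel density estimate with a
Gaussian kernel evaluated on a uniform 50-ms grid.  The kernel variance
is 0.5 in units of squared grid steps, i.e. σ = √0.5 · 50 ms ≈ 35.4 ms.
A ~35-ms kernel matches sub-second burst timescales, whereas a 0.7-s
kernel would smear them; an explicit σ in seconds is accepted for users
who want the other convention.  Kernels are truncated at ±6σ (omitted
tail mass < 1e-8) and no edge reflection is applied; density mass is
conserved to better than 0.1% away from the interval edges, with a
documented negative bias within ~6σ of the edges.

The detection threshold is estimated per hourly interval, because spike
statistics drift over a multi-day recording: 20 homogeneous Poisson
surrogates are drawn conditioned on the interval's total spike count
(count-matched i.i.d. uniform times), each surrogate's density series is
computed, all grid samples are pooled, and the 95th percentile of that
pool is the threshold.  By construction, a stationary Poisson input then
has ≈5% of its own grid samples above threshold, which the calibration
tests verify.  The number of surrogates and the population over which
the percentile is taken are implementation choices; 20 count-matched
realizations give a threshold standard error well below the tolerance of
any downstream metric.

Every maximal supra-threshold run of grid samples is one candidate
burst.  Its extent is the run's outer grid-point edges ± half a grid
step, its peak is the run's argmax, and spikes are assigned by half-open
membership.  Runs separated by even a single sub-threshold sample are
not merged.

The participation filter removes candidates carried by few units.  A
unit is active in a candidate if it contributed at least 2 spikes
(configurable; 2–3 is typical).  The elimination cutoff is placed at the
predefined percentile — default 25, midpoint of the robust 20–30%
range — of the hour's active-unit histogram, in the sense of a
*fraction of the units active in that hour*: candidates recruiting fewer
than 25% of the hour's active units are discarded.  On bursty data the
active-count histogram is strongly bimodal (near-threshold density
noise involves 0–2 units; genuine network bursts recruit a large
fraction of the network), so any cutoff in the 20–30% band lands in the
gap between the clusters and the results are insensitive to the exact
value — the package's tests assert this insensitivity.  An alternative
`mode="histogram"` places the cutoff at the empirical percentile of the
candidates' own active-unit counts instead; it is provided for
comparison but is fragile: when fewer than a quarter of candidates are
noise it eliminates genuine low-recruitment bursts, and when more than a
quarter are noise it passes them.

Bursts crossing an hourly-window edge are truncated at the edge.

## Single-unit bursts

A single-unit burst is ≥ `min_spikes` spikes at ≥ `min_rate` (defaults 3
and 50 Hz).  "At a minimum rate" is interpreted as an inter-spike
interval criterion — every consecutive ISI ≤ 1/min_rate — the standard
max-interval convention.  This makes burst sets nest exactly under
parameter tightening, a property the tests assert across the full
2/3/4-spike × 20/50/100-Hz grid, and the detector is verified against an
exhaustive enumeration oracle.  An average-rate variant
(`criterion="mean_rate"`) is available; for maximal ISI-runs the two
coincide.

## Per-unit stability classification

The test asks whether a unit's mean rate differs between two epochs
beyond what its own minute-to-minute variability explains.  Each epoch
is divided into 1-min bins (trailing partial bins dropped), the bins are
pooled, and 10,000 random reassignments into pseudo-groups of the
original sizes generate a null distribution of mean differences.
Classification uses the empirical 2.5th/97.5th percentiles
(nearest-rank); values on the boundary are conservatively labeled
stable.  Shuffling is permutation *without* replacement by default —
the natural reading of reshuffling bins "into two groups" — with a
bootstrap-with-replacement variant behind a flag; on stationary data
both calibrate near the nominal 5% false-change rate.  Units silent in
both epochs are excluded (their change is undefined); zero-baseline
units are likewise excluded from percent-change correlations rather
than patched with pseudocounts.  No multiple-testing correction is
applied across units: the reported percentages are descriptive
per-unit classifications, not a family-wise inference.

Reproducibility: each unit's test draws from an RNG substream derived
from the global seed and a CRC of the unit id, so per-unit results do
not depend on unit iteration order.

Calibration and power (verified by simulation in the tests): the
false-change rate on stationary Poisson units lies in [3%, 7%] at
α = 0.05, and power at a threefold rate change (1 Hz vs 3 Hz, 20 + 20
one-minute bins) exceeds 0.9.

## Synthetic-data generator

The generator is a statistical emulator, not a biophysical simulation:
no conductance-based network, no plasticity rule, no development.  It
produces exactly the statistical features the analyses rely on:

* **Background spiking** — independent per-unit Poisson processes with
  rates drawn log-normal across units (default median 0.3 Hz, log-SD
  1.0), reproducing the right-skewed rate distribution of cultured
  networks.
* **Network bursts** — a homogeneous Poisson event process (default
  0.1 Hz); each event independently recruits each unit (default
  probability 0.6), and a recruited unit fires max(1, Poisson(8))
  spikes at 10-ms intra-burst ISIs jittered ±30%.  With these defaults
  roughly half of all spikes fall inside network bursts, the
  burst-dominated regime of mature cultures; the count-matched
  surrogate threshold then sits far above the background density, which
  is what makes clean burst detection possible in real data too.
* **Perturbation** — from the onset, each unit's rate is
  `base_i · [s0 + (1 − s0)(1 − e^{−(t−onset)/τ}) · g_i]`: an immediate
  drop to the suppression factor s0 (default 0.012) followed by an
  exponential population-level recovery (default τ = 1e5 s ≈ 1.2 days,
  so the population passes ~57% at one day and ~100% at two).  The
  per-unit multipliers g_i are log-normal with log-mean −σ²/2 and are
  normalized so their base-rate-weighted mean is exactly 1: the
  population MFR recovers to its set point *by construction* while
  individual units settle at dispersed new rates (default log-SD 0.8).
  The macro-stability/micro-instability dissociation is therefore a
  designed property of the generator, and the analysis stages are
  tested on their ability to detect it, not to produce it.
* **Auxiliary channels** — Poisson mEPSC trains with log-normal
  amplitudes; calcium traces in which each spike adds an
  instantaneous-rise, exponentially decaying ΔF/F transient of 0.246
  with linear summation, sampled at 20 Hz; paired FM puncta tables with
  a configurable burst/single scaling; four-parameter-logistic
  dose–response tables.

Reproducibility: one RNG substream per unit (plus one for unit-level
parameters and one for the burst event process), all derived from the
config seed, so identical configs give byte-identical sessions and
adding units does not perturb the spike times of existing ones.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: refractoriness and spike-sorting
contamination, non-Poisson ISI statistics outside bursts, burst-shape
diversity (onset ramps, propagation across the array), correlations
between units beyond shared burst events, slow drifts within an hour,
and any activity-dependent coupling between the perturbation and the
burst process beyond uniform rate scaling.

## Intracellular and optical metrics

* **Integrated conductance** — G = (1/T)·∫|I(t)|dt / |V_M − V_rev| by
  trapezoidal quadrature; pA/mV = nS.  The integral is normalized by
  record duration so that records of different lengths are comparable
  and the result carries nS; the raw integral (nS·s) is returned
  alongside.  Currents are rectified so inward excitatory and outward
  inhibitory currents both yield positive conductances.  The I/E ratio
  is the mean over cells of per-cell G_I/G_E — explicitly not the ratio
  of means, which can differ grossly (per-cell ratios 2 and 0.5 average
  to 1.25 while the ratio of summed conductances is 1.0).
* **mEPSC summaries** — frequency = count/duration; inter-event
  intervals from successive differences; 200 events per cell drawn
  uniformly without replacement for pooling (all events, flagged, when
  fewer exist).  The subsample is verified unbiased by resampling.
* **F–I and input resistance** — spikes are upward 0-mV crossings with
  a 2-ms refractory merge; rate = count/0.5 s.  R_in is the OLS slope
  of steady-state ΔV (mean of the last 20% of each step) against
  injected current over the −80…−20 pA series; mV/pA scaled to MΩ.
* **ΔF/F** — baseline F0 is the mean fluorescence over the 1 s before
  event onset; ΔF/F is gain-invariant by construction.  The transient
  detector (3 × robust SD via 1.4826·MAD, 0.5-s merge window) is this
  package's choice, fully configurable; the transient *rate* is the sum
  of detected amplitudes divided by recording time (ΔF/F·min⁻¹), which
  tracks firing rate because transient amplitude grows approximately
  linearly with spike count.
* **FM metrics** — S = mean(ΔF) × D with D = puncta count per field
  area (per image when no area is given); plasticity ratio
  S_burst/S_single; destaining fitted as A·e^{−t/τ} + C with the
  additive offset accommodating residual fluorescence, reported as 1/τ.
* **Dose–response** — four-parameter logistic fit in log10
  concentration, slope free (only the *apparent* IC50 is meaningful),
  bounds bottom ≥ 0, top ≤ 120, IC50 within the data range × [0.01, 100],
  five log-spaced IC50 starts to avoid local minima, and tight solver
  tolerances so noiseless data are recovered to ≤ 1e-6 relative error.
  Flat data are flagged unidentifiable rather than fitted.

## Problem sizes used in the automated checks

The calibration suites simulate 1,000 units for the permutation-test
false-change rate (10,000 shuffles each) and a 1-hour, 10-Hz pooled
train for the surrogate-threshold check; detector recall/precision and
filter-insensitivity checks use 20-minute, 30-unit sessions, and the
end-to-end perturbation scenarios use 12-hour, 30-unit sessions with a
2-hour recovery time constant — a time-compressed version of the
multi-day experiment that preserves the ordering onset ≪ τ ≪ session
length and therefore the qualitative signatures (population recovery
with per-unit scatter; sustained deficit without recovery).

## Known limitations

* Density edge bias: no kernel reflection at window edges; bursts
  within ~0.2 s of an edge may be shortened or missed.
* The surrogate threshold assumes within-hour stationarity; strong
  within-hour rate drifts inflate the apparent burst rate.
* The participation filter presumes a network-scale notion of
  collectivity; in very small recordings (≲ 10 units) the active-count
  clusters may not separate.
* The stability test treats 1-min bins as exchangeable; strong
  autocorrelation at the minute scale (e.g. minutes-long up/down
  states) would make it anticonservative.
* Hill fits with fewer than ~6 informative concentrations or data not
  spanning the IC50 are poorly identified even when the solver
  converges; the residual norm should be inspected.
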