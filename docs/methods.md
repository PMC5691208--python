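# Methods

## Data model and conventions

Spike times are seconds from recording onset; amplitudes are signed
negative extracellular peaks in µV. Electrodes on the n_rows × n_cols
grid (default 64×64, 42 µm pitch) are addressed by a 0-based row-major
index. Percentages (expression intensities, baseline-normalised MFR) are
kept on the printed scale, 100 = baseline, never converted to fractions.
Percent-of-baseline normalisation lives in the homeostasis module;
everything upstream reports Hz.

## Spike detection

Per electrode, the noise SD is estimated as MAD/0.6745 by default — the
plain sample SD is inflated by the spikes themselves on active
electrodes, and the `sd` option exists mainly for comparison. The
detector is differential rather than a level crossing: a candidate is a
strict negative local trough that is also the deepest sample within
± one peak lifetime (2 ms) — the latter non-maximum-suppression step
prevents noise wiggles on a spike's flanks from double-counting — and
fires when the excursion to the largest local maximum within the same
window exceeds `threshold_multiplier` (default 9) × noise SD. Detections
within the refractory period (1 ms) keep the larger-magnitude trough.
Timestamp and amplitude are taken at the negative peak, matching the
downstream negative-peak amplitude summaries.

Consequences tested as invariants: detection is translation-equivariant
and invariant under positive rescaling of the trace (threshold and signal
scale together through the MAD).

## Burst and network-burst criteria

A burst is a maximal run of ≥5 consecutive single-electrode spikes with
every ISI strictly below 100 ms ("lower than" is read as strict; the
boundary is exercised in tests on a 10 ms time grid). MBR averages
bursts/min over active electrodes only.

Network bursts: time is partitioned into contiguous 15 ms bins aligned
to t = 0 (alignment is unstated in the underlying protocol; fixing it
makes results deterministic). Per bin, participation is the number of
distinct *active* electrodes with ≥1 spike. The firing threshold, "15%
of the network spiking activity", is interpreted as 15% of the
active-electrode count: a participation-count threshold is the standard
criterion for MEA network bursts and is invariant to overall rate
rescaling, whereas a spike-count threshold would not be. Bins strictly
above threshold are event bins; event bins separated by less than the
150 ms window merge into one event, i.e. the 150 ms acts as a merge
horizon bounding one event's extent. Event count is therefore monotone
non-increasing in the threshold fraction (tested).

IBI distributions use onset-to-onset intervals (end-to-onset would mix
event duration into the interval statistic) on a log₁₀ axis, smoothed
with a Gaussian kernel whose bandwidth is 5% of the log-IBI range
(floored at 0.01 log units so a perfectly regular train still yields a
density), evaluated on 256 points spanning the data ± 3 bandwidths and
renormalised to unit trapezoid integral. The 5%-of-range rule preserves
the proportional-bandwidth idea of a "5% bin size" while being well
defined for any event list.

## Activity metrics and rate distributions

Active electrodes are those with 0.1 ≤ rate ≤ 10 Hz, bounds inclusive
(the conservative reading of "between"); the MFR averages active
electrodes only — silent and pathologically fast electrodes say nothing
about network tone. Rate maps are unfiltered by design so that
`map.sum() × duration` equals the total spike count.

Rate distributions are built on log₁₀ rate over the active band
([−1, 1], 20 equal bins), with occurrence = counts / 4096 so that the
histogram mass equals the active fraction of the array. The Gaussian fit
is the moment fit (MLE) to the raw log rates rather than a least-squares
fit to the histogram: it is bin-free and deterministic, and for
lognormal data the two agree to within bin resolution. Fits are withheld
below 10 active electrodes. The shift statistic is Δμ = μ₂ − μ₁;
scaling every rate by c shifts μ by exactly log₁₀ c and leaves σ
unchanged, which pins down its interpretation.

## Homeostasis classification

A trajectory needs a baseline (100%), a 2 h and a 48 h point. Response
direction is the sign of MFR(2 h) − 100 outside a ±5% dead-band (noise
should not be called a response). Restoration means
|MFR(48 h) − 100| ≤ tolerance with a default tolerance of 12%: the
published trajectories restore to ~101% and ~89% (restored) or fall to
~64% (not restored), so any tolerance in (11, 36)% separates them; 12%
is the tightest round value that accepts the 89% case and is exposed as
a parameter. Fold changes are plain ratios of percent values (the
baselines cancel), so `fold_change(a, b) · fold_change(b, a) = 1`.

## GABA-polarity-switch estimator

With three sampled DIVs per transporter, the mean trajectories are
interpolated piecewise-linearly — any smoother model is under-determined
— and the switch is the smallest t in the sampled range where
KCC2(t) ≥ NKCC1(t). Equality at a sampled DIV counts as a crossing, so
a genotype whose reference day is normalised to 100% for both
transporters crosses exactly at that day. If KCC2 stays below NKCC1
everywhere the estimate is "none within range" rather than an
extrapolation. Under this rule the packaged published means give
8.0 DIV (WT), 19.66 DIV (Lgdel) and 16.53 DIV (Dgcr8); figure-derived
estimates of the same crossings elsewhere (~20.5 and ~17.5 DIV) used an
unspecified smoother interpolation, so only the robust qualitative bound
— mutant crossings fall after 16 DIV — is treated as reproducible.

Raw per-culture intensities are not published, so the bootstrap is
parametric: each point mean is redrawn from Normal(mean, SEM), the
crossing recomputed, and the CI taken as the 2.5/97.5 percentiles of the
defined crossings, with the fraction of no-crossing replicates reported
alongside. Everything is driven by a single integer seed.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume,
not biophysics: per-electrode tonic firing is homogeneous Poisson with a
2 ms dead time, rates lognormal across electrodes
(log₁₀ r ~ Normal(μ, σ), clipped to [0.01, 20] Hz to stay near the
active band); network bursts are a Poisson event process in which each
event recruits a Binomial(n_active, participation) electrode subset,
each recruited electrode adding Poisson-many spikes with Gaussian jitter
(default SD 5 ms) around the event time. A 300 ms minimum separation is
enforced between generated events — networks cannot re-synchronise
instantly, and it guarantees a one-to-one mapping between planted and
detected events under the 150 ms merge horizon, keeping the planted
count a well-defined ground truth; the thinning removes <5% of events at
the default rates and stays within the Poisson-count tolerances used in
tests. A configurable fraction of electrodes additionally emits
intrinsic ≥5-spike bursts at `burst_rate_per_min` (default 20/min, a
mid-range in-vitro bursting rate) so single-electrode burst detection
has realistic targets. Determinism comes from expanding one seed into
per-electrode substreams via SeedSequence spawn-keys, so outputs do not
depend on evaluation order.

Raw traces insert a biphasic template (dominant negative lobe, pinned to
zero at both ends, minimum scaled to each spike's amplitude) into white
Gaussian noise; overlaps add linearly and edge spikes are truncated with
a warning. Real extracellular noise is coloured and electrodes are
correlated; none of that is modelled, so detector performance figures on
synthetic traces bound, rather than measure, real-data performance.

Expression curves are opposed logistics in DIV. The falling NKCC1 curve
has its midpoint at the requested crossing day and the rising KCC2
midpoint is solved so both curves pass through the same value there;
the sampled KCC2 values are then calibrated by a constant offset so the
*piecewise-linear interpolation of the noiseless samples* crosses
exactly at the requested day. The sampled trajectory is all any
estimator sees, so the generator's ground truth is made exact for it —
without this, the smooth-curve crossing and the three-point estimand
differ by a discretisation bias that would contaminate coverage
experiments with a fixed offset unrelated to the bootstrap. Sampled
means are perturbed with Normal(0, SEM) noise, matching the bootstrap's
noise model.

Named presets (`WT-8div`, `WT-16div`, `Lgdel-8div`, `Lgdel-16div`,
`Dgcr8-16div`) encode the qualitative developmental contrasts the tests
assert: the 8-DIV deletion-model network generates no network bursts,
the 16-DIV deletion-model network has a higher mean rate than wild type,
and rate/synchrony grow with age. Preset parameter values are
calibration choices for plausible developing cultures, not measured
quantities.

## Problem sizes and numerical choices

Tests run simulations at 60–600 s, 100–900 active electrodes, and 20–200
Monte-Carlo repetitions per experiment — sizes at which closed-form
Poisson/binomial expectations give tight (4σ) bounds while the whole
suite completes in well under a minute of simulation time. Detector
performance is assessed on single-electrode 60 s traces at 7.8 kHz
(20 seeds for planted-spike precision/recall at 12× noise SD and for
pure-noise false positives), burst detection against an exhaustive
brute-force scan on 200 random trains, fit recovery at n = 2000
electrodes over 50 seeds, and bootstrap coverage over 200 simulated
expression datasets at SEM 2%.

Degenerate inputs are defined rather than erroneous wherever a
convention is defensible: an all-silent recording has MFR 0 with an
empty mask; an amplitude summary with no qualifying spikes reports NaN
flagged unavailable; a regular event train gets the floored IBI
bandwidth; rate-distribution fits below 10 electrodes are flagged
unavailable and refuse shift computation.

## Known limitations

No spike sorting, artifact rejection, or electrode-failure handling; the
NB criterion reads "15% of network activity" as an active-electrode
participation threshold among several defensible readings; piecewise-
linear switch interpolation is a modelling choice that three time points
cannot validate; the parametric bootstrap assumes Gaussian, independent
point means; synthetic data are Poissonian and spatially uncorrelated,
unlike real developing cultures with propagating waves and superburst
patterns, which this package does not attempt to classify.
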