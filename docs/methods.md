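# Methods

## The measurement problem

Two *Apteronotus leptorhynchus* compete for a superior shelter over 6 h:
a 3 h dark phase (the species' active period, when essentially all
agonistic behavior happens) followed by a 3 h light phase, at the end of
which the shelter occupant is scored as the winner. Each fish's
quasi-sinusoidal EOD appears in multichannel voltage recordings as a
harmonic ladder whose fundamental (EODf) is individually distinct, so
both identity and communication signals can be read from the spectrogram
without tags. All times in this package are seconds from trial start;
the dark phase is the half-open interval [0, 10800) s and intervals are
half-open throughout.

## Spectral tracking

Spectrograms use n_fft = 2¹⁵ samples at 20 kHz (1.6384 s windows, 80%
overlap, ~0.33 s hop, 0.61 Hz bins), Hann-windowed, per channel. Peaks
on the channel-summed decibel spectrum are thresholded at
median + k·MAD (k = 5) — a dynamic criterion that adapts to broadband
noise level — and refined below bin resolution by parabolic
interpolation. Peaks are grouped into harmonic ladders: every peak
divided by orders 1–4 that lands in the plausible fundamental range
(400–1200 Hz) is a candidate, scored by the summed power of peaks within
±1 bin per order; candidates are accepted greedily so each peak supports
one group. A candidate without its fundamental peak needs two supporting
harmonics; a lone fundamental with no harmonic support is accepted only
at ≥ 5% of the strongest group's power, since a real fish that produces
a detectable fundamental also produces detectable overtones, whereas
isolated noise peaks do not.

Tracking links per-window detections greedily by the cost
`0.7·|Δf|/max_df + 0.3·d_profile`, where `d_profile` is the half-L1
distance between normalized per-channel power vectors — the electrical
image of the fish's position. `max_df` defaults to 30 Hz so that rises
(which move the fundamental by up to tens of Hz between hops) do not
sever the trace, while the profile term keeps identities apart when two
frequency traces cross. Traces missing longer than 3 windows are not
extended by frequency, but an otherwise-unmatched detection can
re-attach to a dormant trace when its power profile matches within 0.35:
frequency may have jumped arbitrarily far across a large rise while the
fish's position changed little. Detections beyond the configured fish
count are reported as surplus, never silently dropped. A pair is flagged
unresolvable when fewer than two traces achieve 10% coverage or their
median EODfs differ by < 0.5 Hz.

On synthetic recordings (two fish ≥ 10 Hz apart, high SNR) recovered
traces deviate < 0.01 Hz RMS from truth — far below the 1 Hz the
downstream 5 Hz rise threshold requires.

## Baselines, Q10, and sex

Baseline EODf is the 5th percentile of non-overlapping 5 min trace
snippets (linear interpolation between order statistics; missing samples
excluded, windows under 10% valid marked missing). The low percentile
makes the baseline robust to the strictly upward rise excursions.

EODf scales with water temperature as `f(T₂) = f(T₁)·Q10^((T₂−T₁)/10)`.
Q10 is estimated from baseline-window pairs: for windows (f₁,T₁),(f₂,T₂)
with |ΔT| ≥ 0.05 °C, `Q10 = (f₂/f₁)^(10/ΔT)`; the estimate is the median
over pairs pooled across fish. Two numerical choices matter here:

- **All window pairs, not only consecutive ones.** Under a ~1 °C drift
  per 6 h trial, consecutive 5 min windows differ by ~0.014 °C — below
  any sane ΔT floor for an exponent of 10/ΔT — so consecutive pairing
  yields no usable samples. Distant pairs span up to 1 °C. The pairing
  rule is a config switch (`pairs="all" | "consecutive"`).
- **Rise-free windows only.** A losing fish emits rises about once per
  minute, and decay tails (τ up to a minute) keep the trace elevated for
  most of the dark phase; even the 5th percentile is then biased upward.
  Because rises are confined to the (warm, early) dark phase, that bias
  co-varies with temperature and inflates Q10 (measured ≈ 1.42 instead
  of 1.37 on default synthetic conditions). `mask_rise_windows` blanks
  windows containing a detected rise or within 300 s after one; the
  remaining windows estimate the true 1.37 to ~0.001.

Correction to 25 °C applies `f25(t) = f(t)·Q10^((25−T(t))/10)` with the
5 min temperature log interpolated linearly. Correcting a synthetic
trial with the estimated Q10 reproduces the rise-free baseline of a
constant-25 °C control (same seed, hence identical noise and rises) to
< 0.01 Hz RMS. Sex is assigned from the median corrected EODf with a
strict threshold: > 740 Hz male, otherwise (including exactly 740 Hz)
female. The pairwise EODf difference is the difference of median
light-phase baselines, where EODfs are stable.

## Rise detection

Rises are detected on the uncorrected trace (temperature drift of
~Hz/hour is negligible against the 5 Hz threshold on rise timescales; a
flag allows detection on corrected traces). The detector alternates
between searching a maximum and a minimum with a fixed threshold: a peak
is committed once the series has fallen ≥ 5 Hz below the running
maximum, a trough once it has climbed ≥ 5 Hz above the running minimum.
Committed extrema alternate, so each peak exceeds its preceding trough
by at least the threshold — the "peak minus preceding trough" criterion.
The rise onset is the preceding trough (the first sample of a segment if
none precedes); size is peak frequency minus the baseline of the window
containing the onset, falling back to the trough frequency when no
baseline series is supplied. Gaps > 5 s split the trace into independent
segments; traces over 50% missing are processed with a warning.

On the synthetic study conditions (50 rises per trace, sizes 6–68 Hz,
decay 1–60 s, observation noise σ = 0.3 Hz) recall is ≈ 99% within
±2 s with ≤ 2 false positives per trace. A rise of exactly threshold
size on a noiseless trace decays asymptotically and never falls the full
threshold below its peak, so sizes at the detection limit are found only
with the help of noise — one reason the generator's minimum planted
size, like the reported detection floor, is 5 Hz but recall is
quantified from 6 Hz upward.

## Event-triggered coupling

For each agonistic event onset, lags `Δt = rise_time − event_onset` with
|Δt| ≤ 60 s are accumulated and smoothed with a Gaussian kernel
(σ = 1 s), then divided by the number of events — rises·s⁻¹ per event;
negative lags mean the rise preceded the event. Curves from several
trials are averaged after this per-trial normalization, not pooled raw,
so trials with many events do not dominate. The lag grid is 0.5 s
(well under the kernel width); kernel mass within the window is
conserved to ~1% apart from edge truncation.

Significance: 1000 surrogates shuffle the inter-rise intervals — which
preserves the interval distribution and rise count while destroying
alignment to events — rebuild times from a uniformly redrawn start
offset within the dark phase, and recompute the curve; the band is the
pointwise 1st/99th percentile. Under independent Poisson rises the
observed curve falls outside this band at ≈ 2% of lag points, as the
percentiles imply; with the generator's contact triggering
(probability 0.3 at +0.7 s) an excursion above the band appears at
pre-event lags in ≥ 90% (measured 100%) of runs. Uncertainty: 1000
jackknife resamples each drop a random 10% of rises; curves are rescaled
by 1/0.9 and the 98% band is the pointwise 1%/99% interval.

Window fractions compare the share of dark-phase rises falling in
(0, 5] s before an event (overlapping windows union-merged so a rise
counts once; a rise exactly at onset is not "prior") against the
multiplicative expected time fraction n_events·5 s/10800 s — kept
multiplicative even when windows overlap, because that is the comparison
quantity as defined; a union-corrected variant sits behind a flag.
During-chase fractions use merged chase intervals. Per-trial
(observed, expected) pairs feed a two-sided paired t-test; zero-variance
nonzero differences report ±inf with p = 0 and a warning instead of
failing.

## Outcome statistics

The outcome model is a binomial GLM with logistic link fit by IRLS
(statsmodels), one observation per trial with difference-coded
predictors; perfect separation is flagged rather than silently diverging
(the observation unit could alternatively be one point per fish — with
two antisymmetric points per trial that fit is equivalent, so the
per-trial form is used). ROC AUC is computed via midranks (ties count
½), identical to Mann–Whitney U/(n₁n₀) and verified against brute-force
pair counting; its SD comes from class-stratified bootstrap resampling,
which also guarantees both classes survive every replicate. Predictors
are left on their raw scale by default (a z-scoring flag exists) so
coefficients read in natural units.

Time-resolved discrimination scores each trial by its cumulative rise
count on a 60 s grid to 1800 s, losers as the positive class; at t = 0
all counts tie and AUC = 0.5. With the observed mean rates (184 vs 18
rises per 3 h, Poisson) a 30-trial cohort reaches AUC ≥ 0.95 well before
25 min.

Backward elimination refits the model after dropping the
largest-p-value feature while that p exceeds α = 0.05 (Wald p-values;
exactly collinear columns are removed first with a warning). α = 1
retains everything, α = 0 nothing.

The win–lose history test codes each fish's outcomes ±1, takes the mean
lag-1 autocorrelation across fish (constant sequences carry none and are
excluded), and compares against outcomes permuted within fish; the
two-sided p-value is centered on the permutation mean because unequal
win counts shift the null away from zero.

## The synthetic generator

Each trace is `baseline(T(t)) + Σ rises + noise`: temperature falls
linearly by 1 °C over the trial (readings every 5 min), baselines follow
the Q10 law from per-fish 25 °C values, and every rise jumps
instantaneously by its size and decays as `size·exp(−(t−t₀)/τ)`.
Defaults are the study conditions: 6 h trials, 3 h dark, ~0.33 s trace
sampling, Q10 = 1.37, loser/winner rise counts 184/18, sizes uniform on
[5, 68] Hz, decay τ uniform on [1, 60] s, chase durations from a normal
(7.4, 6.5) s truncated at zero, background rates of 36 contacts and 128
chases per dark phase, and trigger lags of 0.7 s (contacts) and 1.6 s
(chases) after loser rises. Choices the data description leaves open,
fixed here once:

- Rise onsets are uniform within the dark phase with a 30 s minimum
  spacing (order-statistics construction), keeping individual rises
  resolvable at the 5 Hz threshold while matching the ~1/min loser rate.
- Observation noise is Gaussian, σ = 0.2 Hz — small against the
  threshold, comparable to spectrogram quantization.
- The decay-time distribution and noise level are plausibility choices,
  not measured facts.
- Each loser rise triggers at most one event of one kind
  (`trigger_kind`, default contact); background events are homogeneous
  Poisson in the dark phase only. Overlapping chases are union-merged
  (count logged), and truncation at zero raises the realized mean chase
  duration to ~8.9 s.
- Raw synthesis gives each fish a 3-term harmonic series (amplitude
  ratio 0.4 per order) with per-channel gain 1/(1+(d/0.3 m)²) from a
  stationary position by default (a smooth random walk is optional), on
  a 5×3 electrode grid at 20 kHz, plus Gaussian channel noise.
- Cohorts draw sizes uniform on 9–19 cm, sexes at the observed 9/21
  male ratio, EODf₂₅ from sex-specific normals clipped at the 740 Hz
  cut-off; winners follow `P = expit(c·Δattributes)`; loser rise counts
  are negative binomial (dispersion 3.1, matching the observed CV ≈ 0.6)
  with a log-linear Δsize modulation whose sign flips with winner sex.

What passing tests on this generator do and do not show: they verify
the analysis chain (detection, correction, statistics) against known
ground truth under the reported magnitudes, but real recordings add
fish movement (time-varying power profiles), non-exponential and
overlapping rises, chirps, electrode artifacts, and annotation noise in
the event logs — none of which the defaults emulate. Conclusions about
detector recall or tracking RMS therefore bound performance under the
model, not in the tank.

## Problem sizes and determinism

Every stochastic routine takes a seed or Generator and is reproducible
bit-for-bit; the pipeline runner threads one global seed and writes a
manifest (config hash, seed, version) so reruns are verifiable. The
shipped verification runs use 100 traces for detector recall, 100
runs × 1000 permutations for band calibration and power, 50 replicates
of 500-trial cohorts for coefficient recovery, 30-trial cohorts for
time-resolved AUC, and 60 s 15-channel recordings for end-to-end
tracking; the acceptance script uses 40-run variants of the two
permutation studies. These sizes give binomial uncertainties comfortably
inside the asserted margins.

## Known limitations

- The tracker is a documented re-design around published FFT parameters,
  not a replica of the original cited tracker; with more than a handful
  of fish its greedy assignment would need replacing.
- Rises whose frequency jump exceeds `max_df` can detach their trace for
  a few windows until profile rescue re-attaches it; trace identity
  through simultaneous large rises of both fish is not guaranteed.
- Q10 estimation needs rise-free windows at distinct temperatures; a
  trial with continuous rise emission and no temperature variation
  returns an explicit error rather than a guess.
- The paired t-test and GLMs assume independent trials; repeated
  participation of the same fish (handled in the data by experience
  covariates) is not modeled as a random effect.
- Chirps — sub-second EODf excursions, a different signal class — are
  neither synthesized nor detected.
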