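# Methods

This note documents the models, parameter choices and numerical
decisions behind each pipeline stage, what the synthetic generators do
and do not emulate, and the known limitations.

All timestamps and windows are seconds internally; milliseconds appear
only in formatted output. Time intervals are half-open `[a, b)`, so
bins tile without double counting. Every tunable below lives in
`AnalysisConfig`, which rejects unknown keys and whose defaults are the
values stated here.

## Autocorrelograms and firing-pattern statistics

The ACG is one-sided (positive lags only) with zero-lag self-pairs
excluded; symmetric display is a plotting concern, and all statistics
use positive lags. Bin width defaults to 0.5 ms with a 0.5 s maximum
lag; counts are normalized by their mean over all bins up to the
maximum lag (the normalization range is configurable and recorded in
provenance). Units above the 50,000-spike cap contribute exactly their
first 50,000 spikes by time — a memory guard, recorded in
`n_spikes_used`.

Moving averages (2.5 ms display smoothing, 10 ms for the refractory
trough, 5 ms for evoked in vitro ACGs) are centered and shrink to the
valid overlap at the edges rather than zero-padding, which would
manufacture an artificial trough at lag zero. Windows must span an odd
number of bins; the nominal 5 ms in vitro window over 0.5 ms bins
(10 points) rounds up to 11 points.

The Burst Index normalizes the short-lag/long-lag contrast by the
larger of the two terms, so it is confined to [−1, 1] and invariant to
global rescaling; it is defined as 0 when both terms vanish. The Theta
Index needs a reference level for its "difference"; we use symmetric
flanking windows (50–75 ms and 225–250 ms) around the 100–200 ms search
band and the same max-normalization, which keeps the index in [−1, 1]
and insensitive to firing rate. The flank choice is exposed in
configuration and recorded in provenance.

The refractory estimate takes the 10 ms-smoothed ACG's value at its
smallest lag as the trough and the 180–200 ms mean as the asymptote,
and returns the smallest lag reaching the half-height between them —
a *relative* refractory measure: with heavy smoothing it is biased
upward by roughly half the smoothing window for very short dead times,
which is why recovery tolerances are max(5 ms, 30%).

Classification thresholds (Reg: refractory ≥ 40 ms and Theta Index
> 0; Burst-SB: Burst Index ≥ 0.4; else Burst-PL) are package defaults,
not literature constants; all validation uses ordering and recovery
properties rather than absolute boundaries.

## Event-related spike responses

PETHs use 10 ms bins by default (the analysis windows are fixed at
500 ms; the bin width is a package choice). Spike counts are exact
half-open binning; events whose window leaves the recording span are
dropped and counted.

The detection procedure, per direction (activation / inhibition):

1. extremum of the PETH within (0, 500 ms];
2. baseline = mean rate over [−500 ms, 0);
3. response window = contiguous bins around the extremum beyond the
   half-distance between extremum and baseline; a crossing that never
   occurs within the search window is replaced by the window edge;
4. matched baseline window: identical length, centered on the
   same-signed local extremum of the baseline period, *shifted inward*
   (never truncated) at the baseline-span edges;
5. one-sided Mann–Whitney U on per-trial spike counts, response window
   vs matched baseline window, at p < 0.01;
6. if both directions are significant, the direction whose window
   starts earlier is primary.

Two numerical choices matter for calibration. First, window finding
(steps 1–4) operates on a 20 ms-σ Gaussian-smoothed PETH so single
noisy bins do not truncate the half-distance walk; the significance
test always uses raw per-trial counts. Second, the matched baseline
window must cover exactly as many bins as the response window —
truncating it at the baseline edge breaks the symmetry between the two
extremum-selected samples and inflates the false-positive rate
(measured ≈5% family-wise at α = 0.01 with truncation vs ≈1.6% with
shifting). Mann–Whitney p-values use the normal approximation with tie
correction throughout, since per-trial spike counts are heavily tied
integers.

Optotagging: a unit is tagged when its mean rate from 10 ms after
pulse onset to pulse offset is ≤ 0.5 Hz *and* its pulse-aligned PETH
(1 ms bins, 5-point smoothed) drops below half the pre-pulse baseline
within 10 ms. The baseline is the mean rate over 1 s before the pulse
(a package choice); silent units return untagged with a flag rather
than a spurious latency.

Cell typing: PCA (full SVD) to three components, agglomerative
clustering with Ward linkage and Euclidean distance (both
configurable) cut at four clusters. The cluster whose mean response is
positive after both rewards and punishments is putative-cholinergic;
if several clusters qualify, the one with the largest combined mean
keeps the label. Mixed-sign clusters are labeled glutamatergic-like
and both-negative clusters GABAergic-like — a package convention for
the remaining classes, since only the both-activated rule is
principled.

## Fiber photometry

Preprocessing order: zero-phase (forward–backward) Butterworth
low-pass at 20 Hz, order 4, on both channels; OLS fit (gain + offset)
of the filtered 405 nm channel to the 465 nm channel over the whole
session; dF/F in percent; zero-phase 0.2 Hz high-pass, order 4, for
bleaching. Filters are applied as second-order sections for numerical
stability at high sampling rates. A constant isosbestic channel
degrades the OLS fit to a pure gain (offset 0). A non-positive fitted
isosbestic anywhere aborts with guidance, since dF/F would divide by
it. Robustness choices (filter order, robust-fit alternatives) are
configuration, and all applied parameters land in the output
provenance.

Validation of the correction compares the dF/F output against the
ground-truth transient trace *passed through the same linear filter
chain*: the prescribed 0.2 Hz high-pass removes genuine low-frequency
power of sparse transients, so correlating a band-limited output with
the unfiltered target would measure the filter passband rather than
correction quality.

Trial z-scoring offers two modes, selected by the caller because the
pipeline uses both: per-trial (each trial scored by its own 2 s
pre-cue baseline; zero-SD trials excluded with a warning) and session
(one pooled mean/SD from all pre-trigger baseline windows).

Response metrics operate on the trial-mean trace: peak and latency in
(0, 1 s]; half-maximum level is peak/2 because the z-scored baseline
is zero by construction; crossings are searched outward from the peak
with the window edge substituting for an absent crossing; AUC is the
sample sum between crossings divided by the sampling rate. The
trialwise cue test pairs each trial's response-window maximum
(0–0.5 s) with its baseline-window maximum (−0.5–0 s) and applies a
one-sided Wilcoxon signed-rank test at p < 0.05; the paired-maxima
reading of "baseline fluctuations" is a documented package choice, and
latency/duration are gated on that significance.

## Cross-signal coupling

The cross-correlogram mean-centers both signals by default (photometry
offsets are arbitrary; the flag is configurable and recorded), computes
every lag by FFT correlation, and normalizes by
√(R̂xx(0)·R̂yy(0)), so a self-correlation is exactly 1 at lag 0.
Positive lag means the second signal lags the first; the convention is
a package choice. The ±20 ms central exclusion is applied before peak
finding; session averages honor the masks pointwise and per-session
peak/lag tables support per-animal summaries.

Pupil diameter is the mean Euclidean distance of the three diagonal
landmark pairs — exactly 2r for diameters of a circle of radius r, and
invariant to rigid motion. Frames with missing landmarks are dropped
and linearly interpolated, then the series is interpolated onto the
photometry grid. Peak-triggered averaging detects local maxima of the
z-scored calcium trace above 2 SD with ≥ 1 s separation and averages
the target in (−2, +4) s windows.

Transfer entropy: series are z-scored, block-averaged to the target
rate (20 Hz default; not stated by the upstream procedure), discretized
into 200 equal-width bins spanning each series' own range, and the
plug-in TE computed over (present, own past, other past) with history
length 1 (configurable; longer histories are encoded as integer
state tuples). The plug-in estimator at 200 bins is strongly
positively biased at realistic sample sizes; that bias is documented,
not corrected — absolute 200-bin values are descriptive, and
directional comparisons should use coarse discretizations (the test
suite uses 4–8 bins) with the sampling interval and history chosen so
the expected coupling lag falls inside the history window.

## In vitro metrics

Spike detection: upward crossings of −20 mV (configurable; not a
recorded-protocol constant), each assigned the local voltage maximum
before the trace falls back below threshold, with events closer than
1 ms merged keeping the larger peak. Spike delay is the first AP peak
after step onset; a step without spikes returns an explicit no-spike
sentinel, never 0. Burst frequency is 1/mean of the three ISIs after
the first spike — algebraically 3/(t₄ − t₁) — and requires four
spikes. Evoked ACGs sum per-sweep pair counts (spikes are never paired
across sweeps), then mean-normalize and smooth. "The three subsequent
ISIs" is read as the intervals between spikes 1–2, 2–3 and 3–4 of the
step response. Per-sweep metrics are reported with the max over sweeps
as the cell-level summary, configurable.

## Tracing arithmetic

Input fractions: per animal, 100 × region count / animal total
(regions absent from an animal count as 0%), then across-animal mean
and SEM (ddof = 1; a single animal reports SEM 0). Animals with zero
labeled cells are excluded with a warning. Axon density reduces a
probability map either to its mean probability or to the fraction of
pixels at or above a threshold (default 0.5); both reductions are
implemented because the upstream description does not fix one, and the
mode is always recorded. Densities are relative (the imaged volume is
standardized but unquantified), so only within-animal percentage
comparisons are meaningful.

## Synthetic generators

The generators emulate the statistical structure each analysis
assumes, with defaults chosen as realistic study conditions:

- **Poisson trains** add an absolute dead time to exponential gaps, so
  the minimum ISI is exact and the realized rate is
  rate/(1 + rate·dead time).
- **Bursting trains**: Poisson burst onsets at 0.3 Hz, 3–6 spikes per
  burst at 6 ms intra-burst ISI with ±10% uniform jitter — the
  high-frequency spike clusters of bursting cholinergic neurons.
- **Regular-rhythmic trains**: 7 Hz cosine rate modulation (depth 0.8)
  on a 4 Hz base with a 60 ms dead time, realized by thinning.
- **Task sessions**: two cues with 90/10 outcome/omission
  contingencies, 0.4–0.6 s outcome delay, 5–9 s inter-trial intervals;
  responsive units multiply a 10 Hz base rate by a gain inside
  [latency, latency + duration] after their assigned event. Per-unit
  seeds spawn from one seed sequence, so adding units never perturbs
  existing streams.
- **Photometry**: 100 Hz, 300 s sessions; both channels share an
  exponential bleach (τ = 600 s) and a mean-reverting random-walk
  motion artifact (SD 0.5 on a baseline of 100); the calcium channel
  adds double-exponential transients (rise 50 ms, decay 600 ms —
  order-of-magnitude values for fast indicators, fixture parameters
  rather than scientific claims) of 4% dF/F by default, with
  independent Gaussian noise per channel.
- **Coupled pairs**: y = gain · x(t − lag) + noise on smooth (AR-1)
  signals, lag rounded to the nearest sample and recorded.
- **Pupil traces**: low-pass-filtered, lagged copies of the calcium
  signal plus noise, so information flows calcium → pupil by
  construction; a landmark generator places three circle diameters at
  fixed random orientations so the geometry stage can be tested end to
  end.

What the generators do *not* emulate: spike-sorting contamination and
drift, sensor nonlinearities and hemodynamic contamination in
photometry, blinking and illumination changes in pupil video,
inter-animal variability, and any behavioral state structure beyond
the imposed event-locked modulation. Passing recovery tests therefore
demonstrates correctness of the computations under the assumed
statistical models, not robustness to every artifact of real
recordings.

## Problem sizes used in validation

Recovery and calibration figures are computed at desk scale: 100
random trains (≤ 5,000 spikes) for the ACG oracle; 20 seeds per
condition for ordering, refractory, optotagging and theta checks; 500
null units for detection calibration; 10 seeds for cell typing; 40
seeds for transfer-entropy directionality; 120–300 s synthetic
sessions for photometry and coupling. These sizes give the rate
estimates a resolution of a few percent, matching the tolerances they
are compared against.
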