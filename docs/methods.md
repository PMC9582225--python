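# Methods

## Scope and data model

The package analyzes three modalities in long-format CSV tables:
trial-based fluorescence traces with a stimulus schedule, voltage-clamp
sweeps, and behavioral event durations. Time is expressed in seconds
from trial start (sample 0 at t = 0), which removes frame-rate
ambiguity between the 10.17 and 15 frames/s acquisitions the schedule
type supports. Concentrations are stored as v/v fractions (0.005–0.10)
and displayed as percent. Validation happens at the boundary: readers
reject missing columns, stimulus labels absent from the schedule,
non-finite samples, and trace lengths more than one sample away from
`trial_length_s × sampling_rate_hz`; downstream code never sees an
invalid dataset.

## Glomerular response metrics

Trials of one ROI × stimulus are trimmed to a common length (they may
differ by one sample due to acquisition rounding) and averaged
pointwise. On the averaged trace:

* **Baseline** — mean and SD over the `baseline_window_s` (default 1 s)
  immediately preceding stimulus onset. The SD is taken from the
  averaged trace, i.e. after trial averaging, because all metrics are
  defined on that trace.
* **Peak** — maximum sample in `(onset, onset + peak_window_s]`
  (default 3 s); ties broken by the earliest frame.
* **Responder rule** — ΔF = peak − baseline mean must exceed
  `responder_sd_multiple` (default 3) × baseline SD. With a noise-free
  baseline (SD = 0, as in noiseless synthetic input) the rule degrades
  to ΔF > 0 so that closed-loop tests remain well defined.
* **ΔF/F** — 100·ΔF/baseline mean, reported for responders only;
  non-responders carry an explicit 0 because per-mouse concentration
  means must include zeros for included glomeruli that did not respond
  at some concentration. A baseline mean ≤ 0 raises a
  degenerate-baseline error — ratio metrics are meaningless there.
* **Latency** — time of the first post-onset sample exceeding
  baseline mean + 3·SD, with no interpolation (whole frames). The
  calcium-response latency has no finer operational definition in this
  protocol; re-using the significance threshold makes the latency of
  every responder well defined and guarantees latency ≤ time-to-peak.
* **Integral** — Σ (100·(F − baseline)/baseline) · Δt from onset to
  trial end, the only stated window boundary.

**Blank subtraction.** The blank (deodorized air) ΔF/F of a glomerulus
is subtracted from each of its odorant ΔF/F values. Responder status is
then re-evaluated as `responder AND blank-subtracted ΔF/F > 0`: a
response that does not exceed the airflow component is not counted as
odorant-driven. The raw `dff_pct` field intentionally retains the
pre-subtraction value of 3-SD-significant responses, so a row can show
`is_responder = False` (revoked by the blank) alongside a nonzero
`dff_pct`; downstream modules use the blank-subtracted column and the
final responder flag.

## Tuning statistics

Lifetime sparseness is computed as

    S_L = (1 − ((Σ r_i)/n)² / (Σ r_i²/n)) / (1 − 1/n)

on the blank-subtracted ΔF/F vector floored at 0, with non-responsive
odorants contributing 0. The first numerator term is the **squared
mean**; the superficially similar Σ(r_i/n)² does not satisfy the
defining limits (uniform vector → 0), which the tests assert against a
direct-evaluation oracle. S_L is reported only for ROIs responding to
at least one odorant (undefined — NaN — otherwise), is invariant to
positive rescaling, and lies in [0, 1]; vectors whose squares
underflow to zero are treated as all-zero. Per-mouse aggregation is
the arithmetic mean over qualifying ROIs; mice without qualifying ROIs
are excluded with a logged warning.

## Concentration coding

A glomerulus enters the analysis of an odorant if it responds to ≥ 1
concentration (asserted by construction of the series). Three outputs:

* **Per-mouse mean amplitude** including explicit zeros where an
  included glomerulus did not respond.
* **Top-normalized amplitude** — each glomerulus's amplitudes divided
  by its response at the top (10 %) concentration, so every glomerulus
  contributes equally to the mouse mean. Glomeruli with a non-positive
  top-concentration amplitude are excluded for that odorant (logged);
  normalizing by a zero or negative response is undefined.
* **Ascending-pair differences** — metric(c_high) − metric(c_low) for
  adjacent ladder pairs only (0.5–1, 1–5, 5–10 %), per glomerulus,
  computed only when the glomerulus responds at both members; per-mouse
  means over the available glomeruli. The high-minus-low sign
  convention makes latency shortening negative.

## Saturation QC

Responses with ΔF/F > `saturation_dff_threshold_pct` (default 1000 %)
are screened for indicator saturation on the trial-averaged trace:
frame differences d_t = F_t − F_{t−1}; the count of frames from the
maximal rise (first frame on ties) to the first non-positive d_t,
counting from the frame immediately after the maximal rise. A count
≤ `saturation_max_frames` (default 2) flags a rapid-onset plateau. A
trace still rising at trial end reports the remaining frame count,
is never flagged, and logs a warning.

## EPSC kinetics

Each sweep is corrected by subtracting its mean over the 350 ms before
light onset. Peak amplitude (most negative sample within 250 ms of
onset) and onset latency are measured **per trial** and summarized as
trial means, matching the definition of jitter as the SD of "the onset
latencies of all trials"; jitter uses the sample (n−1) SD, which makes
the three-trial 1.0/1.2/1.4 ms example exactly 0.2 ms. Measuring onset
per trial also keeps the estimate unbiased by trial-to-trial latency
jitter, which smears the rise of a trial-averaged trace earlier — on
an averaged trace, the apparent onset approaches the earliest trial's
onset rather than the mean.

Onset is the sample at which the sweep reaches 5 % of its peak
amplitude *on the rise toward the peak*: the contiguous run of
at/below-level samples ending at the peak is walked back to its first
sample, with no interpolation. Anchoring at the peak makes the measure
robust to isolated noise excursions below the level before the event;
an estimator taking the globally first sub-level sample would trigger
on baseline noise whenever the 5 % level is comparable to the noise
SD. A responding sweep set in which no sweep reaches the level raises
an error (ill-formed input). The response criterion compares the mean
per-trial peak against 3 × the mean per-trial baseline SD (ΔF > 0 when
the baseline is noise-free); monosynaptic classification requires a
response with onset latency < 2 ms. Note that a peak taken as an
extremum over a long window is positively biased on pure noise, so the
3-SD response rule is meaningful for clearly evoked currents, not as a
false-positive-controlled detector.

Power curves simply map the kinetics over recorded (duration,
intensity) conditions; absent conditions yield absent rows, never
zeros, because incomplete power curves are common.

## Behavior scoring

* Two-choice: ratio = odor/(odor + MO); detection at ratio ≥ 0.75 (the
  inclusive reading of "a ratio of 0.75 indicates detection"); a
  zero-total trial has an undefined ratio and scores as not detected.
* Buried food: failures carry the 600 s timeout as a censored latency
  *and* a pass flag, so group comparisons can either include censored
  values or filter on the flag.
* Habituation–dishabituation: habituation(o) = trial 1 − trial 2;
  dishabituation(o→o′) = trial 1 of o′ − trial 3 of o. Water occupies
  the first position of the fixed order (water, almond, mint, vanilla),
  so the first transition is water→almond. Per-subject summaries are
  arithmetic means over the 4 odorants / 3 transitions; the combiner is
  a package choice, as the per-subject aggregate is not otherwise
  specified.

## Synthetic generators

The glomerular generator emulates the in vivo protocol: 20 s trials
(onset 4 s, 1 s stimulus), 3 trials per stimulus, 15 frames/s by
default, an optional blank carrying only a small mechanosensory
amplitude (default 2 % ΔF/F). Traces are

    F(t) = F0 · (1 + A(c)/100 · K(t − onset − latency)) + N(0, noise_sd)

with K a difference-of-exponentials kernel (rise τ 0.2 s, decay τ
1.0 s — a slow, GCaMP6s-like simulation default, not a measured
value) renormalized to its sampled peak so the configured amplitude is
exactly the discretized trace's peak. A(c) is a population Hill curve
A_max·cⁿ/(cⁿ+EC50ⁿ) times a per-glomerulus lognormal gain (σ = 0.4);
each glomerulus responds to a Bernoulli(tuning_sparsity = 0.25) subset
of the odorant panel. Latency decreases by 0.1 s per ascending ladder
step from a 0.8 s base. The presets encode the two concentration-coding
regimes: `mature_like` (EC50 0.007, n_H 4 — saturated above the 1 %
step) and `immature_like` (EC50 0.05, n_H 1 — graded across the
ladder). Indicator saturation is modeled as a hard fluorescence
ceiling (clip), because a clip produces the rapid-onset plateau
signature that the frame-difference QC is designed to catch.

EPSC sweeps are alpha-function inward currents (τ 1.5 ms, 10 kHz,
350 ms baseline) with per-trial onset = true onset + N(0, σ) and
Gaussian baseline noise, each sweep renormalized so its sampled peak
equals the configured amplitude; amplitude scales with light intensity
so power curves are monotone. Behavioral sniffing follows a geometric
within-odorant decay (first trial t, then t·ρ, t·ρ²) with an additive
jump J at each odorant change; the default J = t₁(1−ρ²) makes the
process stationary so the expected habituation difference is t₁(1−ρ)
for every odorant and the expected dishabituation difference is
exactly J. Ground-truth tables retain every configured amplitude,
latency, tuning set, onset, jitter and behavioral parameter for
parameter-recovery tests.

Each generator consumes a single `numpy.random.default_rng(seed)`
stream in a fixed, documented order (mouse → glomerulus → stimulus →
trial; cell → condition → sweep; group → subject), so identical
configs and seeds give byte-identical CSV output, and partial
regeneration is deliberately impossible rather than silently
inconsistent.

**What the generator does not emulate:** sniffing/respiration coupling
of response timing, inter-glomerular correlations and ephaptic
interactions, photobleaching and motion artifacts, indicator
nonlinearity short of hard saturation, non-Gaussian electrophysiology
noise (line pickup, spontaneous EPSCs), and session-level behavioral
drift. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated noise model, not robustness to every
artifact of real recordings.

## Test-bed problem sizes

The recovery suites run at desk scale: 2000 noise-only trials for the
responder-rule oracle comparison, 5 mice × 50 glomeruli per preset for
the concentration contrast, 200 cells × 10 sweeps at 10 kHz for EPSC
recovery, and 60 glomeruli per arm for the saturation rates. At these
sizes the full suite completes in seconds.

## Numerical conventions and edge cases

* Responder, latency and onset thresholds use strict/at-level sample
  comparisons with no interpolation; all window boundaries are
  half-open as stated per metric, with half-sample tolerances on the
  EPSC time grid to avoid float-boundary artifacts.
* Peak ties: earliest frame. Sparseness underflow: treated as an
  all-zero vector. Jitter with a single usable trial: 0.
* Latency estimates are quantized to the acquisition frame grid, so a
  recovered latency lies within one frame above the true value and
  ascending-pair latency differences are accurate to ±1 frame per pair.
* The onset of a threshold estimator reads systematically late by the
  time the underlying kernel needs to reach the 5 % level (≈ 0.03 ms
  for the alpha synapse used here) plus up to one sample of rounding;
  cells whose true onset lies within that margin below 2 ms can be
  classified as polysynaptic. This is the estimator's resolution, not
  a defect.

## Known limitations

* The ex vivo (30 s bath application) regime is expressible through the
  schedule type, but its peak-search window is not separately
  calibrated; the in vivo default (3 s) must be overridden by the user.
* The pipeline emits the per-mouse values that group-level statistical
  tests consume but deliberately implements none of the omnibus tests
  (ANOVAs, nested t-tests, multiple-comparison corrections).
* ROI segmentation is out of scope: traces arrive as already-extracted
  mean intensities, as produced by a Fiji-style workflow.
* The 3-SD responder rule applied to a max-over-window statistic has a
  substantial false-positive rate on pure noise (an extreme-value
  effect shared with the original procedure); specificity claims in the
  tests are therefore about agreement with the rule's independent
  re-implementation, not about the rule's own error rate.
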