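# Methods

## Problem and data model

During bilateral implantation of deep-brain-stimulation (DBS) leads in
the subcallosal cingulate (SCC), local field potentials (LFPs) are
recorded from all eight lead contacts (`L1..L4`, `R1..R4`, ventral to
dorsal) while each contact receives a test *cycle* of high-frequency
stimulation: 1 minute pre-stimulation baseline, 3 minutes of
stimulation (during which the amplifiers saturate and the signal is
unusable), and 1 minute post-stimulation.  The scientific question is
whether the minute after stimulation shows band-limited spectral power
changes relative to the minute before, ipsilateral to the stimulated
contact, and whether those changes differ between the contact later
used for chronic therapy ("effective") and its neighbor
("ineffective").

The package operates on EDF+ recordings plus three CSV sidecars
(artifact annotations, cycle metadata, clinical scores).  Because no
recordings are publicly deposited, a synthetic generator with known
ground truth stands in for patient data everywhere the pipeline is
exercised.

## Signal conditioning

The processing order is fixed and tested: **bandpass -> decimate ->
prune -> difference -> epoch**.

- *Bandpass*: 4th-order Butterworth, 1–50 Hz, applied forward–backward
  (`sosfiltfilt`), so the net phase response is zero and the effective
  magnitude response is 8th order.  Only "zero-phase 1–50 Hz" is
  dictated by the analysis design; the Butterworth realization is our
  choice for its monotone passband.
- *Decimation* to 128 Hz.  Integer ratios use polyphase decimation;
  non-integer native rates (e.g. 1525 Hz) use rational-factor
  polyphase resampling with the realized rate within 1e-6 of 128 Hz.
  A clean 60-second epoch is exactly 7,680 samples.
- *Artifact pruning* removes — does not blank — every sample whose
  timestamp lies in an annotated interval.  Intervals are half-open
  `[start, end)` on the sample grid, which makes interval arithmetic
  exact (a 5 s artifact at 128 Hz removes exactly 640 samples).  The
  retained samples are concatenated; `lost_fraction` records the
  removed share per epoch.  Splice points inject a small amount of
  spurious broadband energy; an optional guard (`splice_guard_s`)
  widens each gap before the spectral step, but the default is plain
  concatenation, matching the reference procedure.  An amplitude/
  duration detector (>100 μV sustained >250 ms) is provided as a QC
  helper only; manual annotation tables remain authoritative.
- *Differential (bipolar) derivation*: the signal analyzed around a
  contact of interest is the difference of its two flanking contacts
  (center L2 -> L1 − L3), removing common-mode and reference noise.
  Edge contacts (L1/L4/R1/R4) have only one neighbor and yield missing
  values.  An artifact annotation on either flanking contact
  invalidates those samples of the pair, since a bipolar sample is
  corrupt if either electrode is.
- *Epochs*: pre = `[stim_on − 60 s, stim_on)`, post = `[stim_off,
  stim_off + 60 s)`.  The pre window abuts stimulus onset with no
  guard gap.

## Spectral measure

Each epoch is decomposed with a complex-Morlet continuous wavelet
transform on 200 frequencies linearly spaced over [1, 50] Hz (grid
step 49/199 ≈ 0.246 Hz).  The wavelet has ~6 cycles per analysis
frequency (σ_t = 6 / 2πf), a standard time–frequency trade-off in
this range; the kernel is applied in the frequency domain with
L1-normalized amplitude so a unit sinusoid yields a peak modulus of
~1 at every grid frequency.  Moduli (not squared power) enter the
statistic by default; a `use_power` switch squares them.

Per frequency, the acute effect is

    rc = (median(v_post) − median(v_pre)) / median(v_pre)

over the epoch's retained time points.  A percentile bootstrap
resamples time points with replacement, independently within the pre
and post epochs (they can differ in retained length after pruning, so
paired resampling is not defined), evaluates `rc` per replicate, and
reports the 95% CI and its midpoint.  The five band values are the
unweighted means of CI midpoints over grid frequencies in δ [1,4),
θ [4,8), α [8,15), β [15,30) and γ [30,50] (the top band closed so
every grid point belongs to exactly one bin).

Because `rc` is a per-frequency ratio of magnitudes, every band value
is invariant to rescaling both epochs — amplifier gain, wavelet
normalization and μV calibration all cancel.

### Bootstrap implementation

The default replicate sampler draws each resample's median directly
from its exact distribution: the order statistics of a
with-replacement resample of size n are `ceil(n·U_(j))` for uniform
order statistics `U_(j)`, and the middle ones are generated from
Beta laws (`U_(m) ~ Beta(m, n−m+1)`, with `U_(m+1)` from its
conditional law for even n).  This is an exact draw — verified
distributionally against naive materialised resampling, which remains
available as `method="resample"` — and runs in O(n_boot) per
frequency after one sort, which is what makes cohort-scale simulation
practical on one core.  Temporal autocorrelation of CWT magnitudes is
ignored in the bootstrap, as in the reference procedure; a circular
moving-block bootstrap (`method="block"`) is available but off by
default.  `n_boot` defaults to 1000 (minimum 100); all samplers are
seeded, and the pipeline derives one deterministic substream per
cycle from the master seed.

## Group statistics

Samples are small (eleven 6-month responders), so inference is exact:

- **Wilcoxon signed-rank** (default one-sample test against zero, and
  the paired effective-vs-ineffective contrast): W is the
  positive-rank sum; the two-sided p enumerates all 2^n sign patterns
  over the observed mid-ranks (ties kept exactly, via a subset-sum
  convolution), with a seeded ≥1e5-draw Monte Carlo above n = 25.
- **Rank-sum against a zero pseudo-sample** is provided as the
  alternate one-sample test (the study description names both test
  families, and its printed one-sample W values exceed the
  signed-rank maximum, so the identity of the test actually used is
  not recoverable; we default to the signed-rank and record the
  method in every output row).  The massive tie at zero gets
  mid-ranks; the null enumerates all C(2n, n) assignments for
  combined n ≤ 20.  Note the zero pseudo-sample is not exchangeable
  with a continuous sample under a generic null, so these p-values
  are advisory; the validity property (P(p ≤ t) ≤ t + atom) is
  guaranteed and tested for the signed-rank under a symmetric null.
- **Hedges' g** with small-sample correction J = 1 − 3/(4n − 5)
  accompanies every test (one-sample and paired variants).
- **Bonferroni** over the 5 bands of each contrast: threshold
  0.05/5 = 0.01.  Contrast families are not pooled.
- A one-sample **Kolmogorov–Smirnov** check against a normal with the
  sample's own moments is advisory only (rank tests are used
  regardless).
- **Outcome correlation**: per-patient band changes against time to
  stable response, both Pearson and Spearman (the correlation type
  behind the published r = 0.59 is unstated), NA times excluded
  pairwise.

Statistics are restricted to 6-month responders by default.  Patients
whose effective contact is an edge contact contribute no differential
row; the tables carry the reduced n and a missing count rather than
imputing.

## Clinical definitions

Response: ≥50% decrease from baseline on the 17-item Hamilton
Depression Rating Scale (HDRS-17, range 0–52), boundary inclusive.
Time to stable response: first week starting three consecutive weeks
that each meet the 50% rule; NA when no run exists.  Cohort summaries
use sample (n−1) standard deviations, which is the convention that
reproduces the published baseline column (23.8 (2.8)); recomputing
the published 6-month column gives ≈9.3 (4.1) where the table prints
9.6 (4.5) — we reproduce the computation, not the printed cell.  The
clinical CSV accepts either a weekly HDRS series (from which the
stable-response week is derived) or an explicit
`time_to_stable_weeks` column (used when, as in the published table,
only the derived value is available).

## Synthetic data

Each contact records

    x_c(t) = Σ_bands g_c · osc_band(t) + background_c(t) + drift(t),

where `osc_band` is zero-phase-bandpassed Gaussian noise confined to
the inner 80% of its band (≥90% of its power inside the band edges;
amplitude is the equivalent-sinusoid amplitude, RMS·√2, default 15 μV
per band), `background_c` is independent 1/f^χ Gaussian noise (χ = 1,
2 μV-scale default 1.5 μV), `drift` is a common-mode component added
identically to every contact (differencing removes it), and the
contact gains g = (1.0, 0.75, 0.5, 0.25) ventral→dorsal ensure the
bipolar difference retains the oscillations.  The 3-minute
stimulation interval is overwritten with clipped high-amplitude
oscillation to emulate amplifier saturation.  Artifact transients
(default 1/min, 150 μV, 0.5 s, random per-contact polarity and gain)
are injected inside the analysis epochs and reported as ground-truth
annotations.

Post-stimulation effects are *amplitude multipliers* per band, so the
expected relative change of median CWT magnitude is `multiplier − 1`
(`multiplier² − 1` under the squared-power switch); the truth file
records both.  By default the generator uses **common random numbers
across the pre/post contrast**: the post epoch replays the pre
epoch's oscillation and background realization, scaled by the
multipliers.  This pins the ground truth to the configured effect
instead of letting it ride on the realization noise of two 1-minute
medians (a single minute of narrowband process has a fairly small
bandwidth–time product, and two independent realizations would add
±0.05–0.1 of irreducible scatter per band).  Real pre/post epochs are
of course independent; `paired_realization=False` restores that, and
the per-band scatter it produces is itself a useful reminder of what
a single cycle can and cannot resolve.  A side effect of common
random numbers is that per-patient band changes within a cohort cell
are nearly identical, so Hedges' g on synthetic cohorts comes out far
larger in magnitude than on real data; p-values and significance
patterns are the meaningful comparison there, not effect sizes.  What the generator does *not*
emulate: volume conduction geometry, nonstationary background drift
within epochs, stimulation waveform physics, or any relationship
between LFP effects and the clinical trajectory (clinical tables are
generated independently with a configured responder count).  Passing
recovery tests therefore demonstrates correctness of the measurement
chain, not clinical validity.

The default cohort mirrors the study design: 14 patients (11
responders), 8 channels at 1024 Hz, 4 analyzed cycles each
(left/right × effective/ineffective), hence 14×8×4×2 = 896 nominal
epochs.  Band-effect profiles follow the reported direction pattern —
left effective: θ 0.65, α 0.55 (largest), β 0.70, γ 0.75; right
effective: β 0.70, γ 0.65; left ineffective spares θ; δ always 1.0.
One responder receives an edge effective contact (L4) to exercise the
missing-differential path, and one pre-epoch is fully
artifact-annotated to exercise the empty-epoch path.

## Numerical choices and degenerate inputs

- CWT edge handling: zero padding beyond 8σ of the widest wavelet, so
  circular wraparound cannot reach returned samples; epochs shorter
  than two cycles of 1 Hz emit a warning and are computed anyway.
- A zero pre-epoch median raises rather than returning ±inf; a fully
  pruned epoch raises; both are recorded per cycle by the pipeline,
  which continues and accounts for every cycle as analyzed, skipped
  or errored.
- EDF encoding is 16-bit with per-channel symmetric physical ranges;
  roundtrip error is bounded by one quantization step per channel.
  Writing is implemented in-package (EDF+C, 1-second records);
  reading goes through MNE, so roundtrip tests cross two codebases.
- Exact-test p-values use the "2·min(tail)" two-sided convention,
  capped at 1, matching the brute-force enumeration oracles bit for
  bit on all tested samples.

## Problem sizes used in checks

The calibration and recovery suites run at sizes chosen to keep a
single-core run comfortable while leaving the conclusions unchanged:
bootstrap null coverage uses 500 simulated frequency rows of 300
points at 500 replicates; single-cycle recovery uses 20 generator
seeds at 500 replicates; the cohort-pattern check uses 5 full
14-patient cohorts at 200 replicates (the exact order-statistic
sampler makes a full cohort run take on the order of a minute).  The
number of bootstrap replicates affects only CI smoothness, not the
location of the midpoint estimates.

## Known limitations

- The published group-level W/p/g values were computed on patient
  recordings that are not publicly available and are not reproducible
  here; all statistical machinery is instead validated against
  enumeration oracles and generator ground truth.
- The per-frequency bootstrap ignores serial dependence of CWT
  magnitudes (block bootstrap available but not default), so CI
  widths on real, strongly autocorrelated data are optimistic.
- The EDF writer requires integer sampling rates and whole-second
  record counts (sufficient for the rates this pipeline encounters).
- Sham cycles are carried through the data model but no sham-specific
  contrast is implemented.
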