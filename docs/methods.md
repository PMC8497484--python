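# Methods

`frnkit` re-creates, end to end and on synthetic data, the analysis of a
shock-locked ERP experiment in which reward prediction error (RPE) is
manipulated independently of physical stimulus intensity. This note
documents the models, the parameter choices that matter, and what the
synthetic validation does and does not establish.

## The experimental design being emulated

Each trial announces its *stakes* (low: small or medium shock; high:
medium or large shock) and then delivers one of the two permissible
shocks, predetermined to a half/half split, so the choice task is
unlearnable. Cells are labelled LP, LN, HP, HN (low/high stakes x
positive/negative RPE). LN and HP share the medium shock, so the LN-HP
difference wave varies RPE while holding physical salience constant —
that contrast operationalizes the feedback-related negativity (FRN) here.
The full design is 5 blocks x 40 trials (20 high/20 low stakes per block,
random order), 200 trials per participant, 100 in the critical
comparison, 50 large shocks. A 1 s, 105 dB noise burst accompanies the
stakes cue on exactly 20% of trials (stratified across blocks, onset
uniform 2-5 s into the cue) for startle probing.

Win-stay/lose-shift scoring needs a convention for which consecutive
trials constitute a transition: because the response pair (the fractal
images) is unique to each block x stakes combination, transitions are
scored within those streams only — 190 scoreable transitions in the full
design. "Win" is the lower of the trial's two permissible shocks. The
block-end query is scored against the key whose realized mean shock
intensity was lower; ties make a query unscoreable and drop it from both
counts.

## Synthetic data generator

The generator is first-class code and defines the study conditions for
all validation.

* **Components.** Raised-cosine (Hann) bumps over fixed windows: an
  RPE-signed component (default window 150-260 ms, centre C2, peak at the
  205 ms midpoint), a later reversed-sign component (390-480 ms, POz),
  and an intensity-scaled salience component (gain per shock step,
  centre FCz). Sign convention: positive `rpe_amplitude` makes the
  positive-RPE cells (LP, HP) more positive. With amplitude `a`,
  `mean(LN) - mean(HP)` at the centre is exactly `-2a` at the window
  midpoint.
* **Topography.** Gaussian gain in great-circle distance from the centre
  electrode, sigma 0.33 rad (gain 0.5 about 1.2 electrode spacings out).
  A wider kernel was considered, but it leaves the first electrode ring
  at 75-81% gain while the per-sample group t statistic fluctuates ~13%
  (sd-of-sd sampling error at N = 44), so the t-map maximum would migrate
  off the centre electrode in a third of runs; 0.33 rad makes the
  simulated topography genuinely focal at its centre.
* **Noise.** 1/f (power exponent 1.0) noise synthesized in the frequency
  domain with random phases, mixed half/half from a channel-shared and a
  channel-independent stream and rescaled to an exact per-trace RMS
  (default 5 uV). The shared stream produces uniform inter-channel
  correlation ~0.5 — a deliberate, crude stand-in for volume conduction.
  Note its consequence: permutation nulls of cluster mass are heavy-tailed
  (coherent scalp-wide noise clusters), which is conservative and
  realistic in kind if not in spatial detail.
* **Artifacts.** Mutually exclusive per-trial classes shaped to be
  detected by exactly one preprocessing rule each: blink (frontal 200 uV
  slow deflection; absolute rule), jump (bipolar one-sample flip sized to
  exceed 50 uV/ms while staying under 100 uV; gradient rule), flatline
  (whole trial rescaled to < 12 uV range). On moderate-noise data the
  flagged set equals the injected set exactly, which the tests assert.
* **Montage.** A packaged plain-text file with 61 scalp electrodes
  (10-20/10-10 labels), both mastoids and a right suborbital site, as
  unit-sphere coordinates. M1 is the recording reference and is written
  as zeros.
* **Startle EMG.** On noise-burst trials, with probability
  `response_rate` a Gaussian-noise carrier under a Hann envelope peaking
  at 120 ms (half-width ~50 ms) is added to baseline EMG noise. The
  carrier is scaled by the analytic rectified-Gaussian factor
  sqrt(pi/2), by the envelope's 50 ms-window average, and by the RMS
  fraction of white noise surviving the 28 Hz high-pass + notch chain, so
  that the *processed* trace peaks near the nominal amplitude (default
  8 uV, + `stakes_delta`, default 0.91 uV, on high stakes). Baseline
  artifacts are high-frequency bursts in the baseline window.

**Behavioural calibration.** The simulated agent acts congruently
(win-stay/lose-shift) with probability 0.5545, drawn per participant from
a truncated normal with sd 0.0486; queries are answered correctly with
probability 0.6295. These values are derived in closed form from the
published group moments (mean difference 20.73, sd 23.04 over 190
transitions; query difference 2.59, sd 3.07 over 10 queries), not fitted.

**What passing tests do not show.** The generator has no distance-dependent
noise correlation, no ocular or muscle spectra beyond the stylized
artifact classes, no habituation, no trial-order effects, and free
(unpublished) component amplitudes. Recovery results therefore validate
the *machinery* under controlled conditions; they say nothing about
effect sizes in real recordings.

## Preprocessing

Fixed stage order: filter -> baseline (-200..0 ms) -> artifact rejection
-> mastoid re-reference -> optional spherical-spline interpolation ->
decimation to 100 Hz -> condition averages.

* **Filtering.** Notches at 60 and 50 Hz (second-order, Q = 30) plus a
  0.1 Hz high-pass and 30 Hz low-pass (Butterworth, order 4). The
  cascade's magnitude response is applied once, zero-phase, in the
  frequency domain on odd-reflection-padded epochs. A forward-backward
  time-domain pass was rejected after measurement: on 1 s epochs the
  0.1 Hz edge is transient-dominated (its settling time is tens of
  seconds; measured stopband suppression collapsed to ~10-19 dB), and
  two-pass magnitude squaring costs 1.8 dB at 25 Hz. The spectral
  application meets the design contracts exactly: 50 Hz -34 dB, 60 Hz
  -41 dB, 10 Hz 0.00 dB and zero phase, 25 Hz -0.9 dB.
* **Rejection rules.** Absolute: any scalp channel beyond 100 uV
  (post-baseline) in -200..700 ms. Gradient: |dv| between adjacent
  samples divided by the sample interval in ms above 50 uV/ms (at 500 Hz
  a 100 uV one-sample step). Flatline: *all* scalp channels with
  peak-to-peak range under 12 uV (a dead-recording detector); a
  per-channel variant is available behind `flat_rule="per_channel"`
  since the published wording is ambiguous. Rules are tested in the
  order absolute, gradient, flat, and the first hit is recorded.
* **Re-referencing** subtracts the mastoid average; data referenced to
  the left mastoid carry an implicit zero there, leaving the two mastoid
  channels equal and opposite afterwards.
* **Interpolation** is spherical-spline (Legendre order m = 4,
  regularization 1e-5, 50 series terms) over the remaining scalp
  channels.
* **Ocular ICA** is a pluggable hook (identity by default): the
  semi-automatic vendor procedure is operator-dependent and out of scope;
  threshold rejection handles the synthetic artifact classes.

## Cluster-randomisation test

One-sample t tests over participants at every (channel, timepoint);
samples significant at two-sided alpha 0.05 form clusters under the
adjacency "same channel, adjacent timepoints" or "same timepoint,
neighbouring channels"; components split by t sign; clusters below 25
samples (at the 100 Hz analysis rate) are discarded. The null
distribution of the maximum |sum of t| is built by flipping the sign of
each participant's whole difference map (the exact one-sample
randomisation scheme), default 5,000 permutations (400,000 available by
configuration). Cluster p = (b+1)/(m+1) by default — the plain b/m
estimator is available — then Bonferroni-multiplied by the number of
clusters found at the initial stage.

Channel neighbourhoods: great-circle distance at most 0.57 rad, chosen so
the median scalp neighbour count is 7 on the packaged montage;
zero-variance samples get t = 0 (mean 0) or +-infinity (degenerate,
always supra-threshold).

## Bayesian encoder mapping

Five encoders predict a direction (>, <, =) for each of the six pairwise
condition contrasts: RPE by voltage positivity (the conventional FRN
direction) or negativity, physical salience by positivity or negativity,
and a null encoder. The packaged prediction table enforces that the
signed pairs are elementwise reversals and that the null row is flat.

At each sample, each contrast's participant differences feed a one-sample
JZS Bayesian t test: Cauchy prior on the standardized effect, scale
sqrt(2)/2 (the conventional "medium" default), computed by quadrature of
the noncentral-t marginal likelihood under the substitution
delta = r tan(theta) (adaptive for scalars; 151-node Gauss-Legendre,
verified to ~1e-10 relative error, for whole maps). One-sided factors use
the half-line-truncated, renormalized prior; BF+ + BF- = 2 BF10 holds
and is tested. With equal 1/3 priors, p(greater) : p(less) : p(equal) =
BF+ : BF- : 1 (a two-hypothesis variant is available behind
`scheme="two_way"`). Each encoder's compound probability is the product
of its six predicted-cell probabilities, normalized across the five
encoders; samples above 0.975 are clustered with the same adjacency and
minimum-25 machinery as the t-based test.

## Startle chain and weighted statistics

EMG processing: 28 Hz high-pass + 50/60 Hz notches (zero-phase),
rectification, centred 50 ms rolling mean with truncated edges, baseline
subtraction (-50..0 ms). Classification: baseline artifact if the
pre-subtraction smoothed baseline exceeds 5 uV; non-startle if no
0-200 ms sample clears 5 uV; valid otherwise.

Group tests weight participants by valid-trial counts. Weights are
treated as relative frequencies rescaled to sum to the number of
independent participants `n_eff`; the weighted mean, variance
(denominator `n_eff - 1`), t (df = `n_eff - 1`), d and central-t CI follow.
`n_eff` defaults to the number of positive-weight rows, so zero-weighting
equals exclusion exactly; a caller who splits one participant across
duplicate rows passes the unchanged `n_eff`, making duplication exactly
equivalent to doubling that weight — the property that pins this scheme
down, and the reason `n_eff` is explicit: no normalization based only on
row counts can satisfy it. Weighted correlations use weighted covariances
(Spearman: on rank-transformed data) with p from
t = r sqrt(N-2)/sqrt(1-r^2). Outliers are screened at |z| > 3.29
(strict). The FRN amplitude entering the startle-FRN correlation is the
mean LN-HP difference at C2 over 150-260 ms.

## Power

Power for the one-sample t test is the upper-tail mass of the noncentral
t (df = n-1, noncentrality d sqrt(n)) beyond the central critical value.
One-tailed is the default for FRN-direction analyses: it yields minimal
n = 8 for power 0.8 and 18 for 0.99 at d = 1.0, matching the published
figures, whereas the two-tailed variant does not. (The published aside
"10 and 21 at d = 0.93" is instead consistent with a two-tailed
calculation at d = 1.0; neither tail convention reproduces it at 0.93 —
left as a documented discrepancy.)

## Validation conditions and problem sizes

Recovery studies use 44 participants, the full 200-trial schedule
generated at the 100 Hz analysis rate (components and rejection rules are
rate-invariant; the full 500 Hz chain is exercised separately), RPE
amplitude 3.5 uV against 3.5 uV noise RMS — the LN-HP difference is then
twice the noise RMS at the centre electrode, and about 10x the
participant-average contrast noise, in line with the overwhelming
strength of the published effect. Noise RMS below ~3 uV is not usable
here because clean trials would trip the 12 uV flatline rule. The
cluster recovery criterion (exactly one significant cluster, peak at C2
inside 150-260 ms) is evaluated over 20 seeds at 2,000 permutations;
type-I control uses 500 null datasets (10 channels x 100 timepoints,
1,000 permutations); encoder selectivity runs on a 24-channel
fronto-central/parietal strip. The Monte-Carlo-vs-enumeration check uses
10 participants so the 2^10 sign patterns enumerate exactly.

## Known limitations

* The generator's spatial noise model (uniform shared component) is the
  main realism gap; it makes cluster-mass nulls heavier than a
  distance-decaying model would.
* Filtering via the designed magnitude response assumes the epoch plus
  one reflection is representative; very long-period drift inside an
  epoch is attenuated only as the 0.1 Hz design prescribes.
* The BrainVision import path maps channel names against the packaged
  montage; recordings with other labels need renaming first.
* Real-data cluster p values and the startle-FRN correlation magnitude
  are properties of the original recordings and are deliberately not
  simulation targets; the pipeline's correctness is established by
  oracle agreement, invariants and parameter recovery instead.
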