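# Methods

`telltale` reimplements, end to end, a participant-specific deception-decoding
analysis for facial surface EMG (sEMG) recorded during an interactive
two-person word game, together with a synthetic-data generator that stands in
for human recordings. This note documents the models, the defaults and why
they were chosen, what the generator does and does not emulate, and the
numerical decisions that matter.

## The task and its signals

Two participants alternate as **Sender** and **Receiver**. On each trial the
Sender hears one of two one-syllable words ("KAV" or "ETZ") and either repeats
it (truth) or says the other word (lie); the Receiver then judges the message.
Four outcomes follow: L-T (lie believed), L-L (lie caught), T-T (truth
believed), T-L (truth disbelieved). In the first stage nothing is at stake; in
the second the Sender earns 6 points for L-T, 4 for T-L, 2 otherwise, the
Receiver earns 4 points for correct judgments, and each point is worth
0.2 NIS.

Facial muscle activity is recorded from an 8-electrode array on the right side
of the face at 2000 samples/s: electrodes 0–4 over the cheek (*zygomaticus
major*, ZM — smiling), 5–7 over the eyebrow (*corrugator supercilii*, CS —
frowning). A calibration block of three voluntary smiles followed by three
frowns (3 s each, 3 s gaps) precedes the game.

## Preprocessing

1. **Differential montage.** All C(8,2) = 28 electrode-pair differences
   (common-mode rejection); only the i &lt; j orientation is kept.
2. **Filtering.** 50 Hz notch (2nd-order IIR, Q = 30 — the bandwidth is a
   package choice) then 5–500 Hz 4th-order Butterworth band-pass. Both are
   applied forward–backward (zero phase), so epoch timing carries no group
   delay; the effective magnitude response is the squared design response,
   and the filter tests compare against exactly that.
3. **Peak envelope.** The filtered signal is rectified (absolute value — peak
   picking on zero-mean EMG is otherwise ill-defined), the maximum of each
   consecutive 50-ms window is located, and a not-a-knot cubic spline through
   the (position, value) nodes is evaluated at every sample and clipped at
   zero from below. The envelope is computed on the *continuous* recording
   and only then segmented, avoiding edge artifacts inside epochs.
4. **Channel selection.** Where the original workflow inspected calibration
   signals by eye, selection is automated: the ZM channel is the cheek pair
   (both electrodes in 0–4) with the largest smile-vs-rest envelope RMS
   ratio; the CS channel is whichever of (5,6), (6,7) has the largest
   frown-vs-rest ratio. All candidate ratios are reported, and a best ratio
   below 1.5 flags the selection as low-confidence. Whether this reproduces
   human choices on real recordings is untestable without the data.
5. **Epoching.** Three 1-s epochs per trial: [stimulus, +1 s),
   [speech onset, +1 s), [response − 1 s, response). Epochs may overlap.
   Trials with an epoch outside the recording, before 1 s, or reaching into
   the calibration block are dropped and counted, never fatal.

## Deception Detection Matrices

For each (muscle, event, stage) the epoch is tiled into m bins (10 ms at full
scale, m = 100) and every window (onset bin i, size j bins, i + j ≤ m) is
classified lie-vs-truth, giving a lower-triangular accuracy matrix with
m(m+1)/2 defined cells (5050 at m = 100).

Per window: features are the raw envelope samples in the window (a per-bin
mean mode exists for speed); PCA fitted across all trials of the stage
reduces them to two components (the explained-variance fraction is reported
and a warning emitted below 0.95). Accuracy is estimated by paired holdout:
one lie and one truth trial are held out, a linear classifier is trained on
the rest and scored on the held-out pair; the estimate is the mean over
held-out predictions across iterations (1000 at full scale), enumerated
exhaustively whenever #lie × #truth pairs does not exceed the iteration
budget. Stages are analyzed separately throughout. Fitting PCA on all trials
of the stage leaks marginal information into the test pair; this mirrors the
source procedure and is the default, with a leakage-free mode (PCA refit on
each training fold) behind a flag.

**Classifier.** The default is a regularized least-squares linear classifier
on ±1 labels (LS-SVM style, ridge only as a numerical guard). The procedure
this package reimplements described a linear SVM with a least-squares cost —
an ambiguous specification — and the least-squares reading has a decisive
practical property: the normal equations admit exact rank-one downdating, so
all holdout refits across all windows *and all label shuffles* reduce to
batched closed-form 3×3 solves sharing one PCA and one Gram matrix per
window. That is what makes shuffle-resolved DDMs tractable on one CPU. A
maximum-margin SVM (C = 1) is available via `classifier="svm"` for desk-scale
checks; the test suite verifies the fast path cell-for-cell against naive
per-pair refits.

Cells where a class has fewer than 2 trials are NaN ("undefined"), never 0.

## Cluster-based permutation significance

1000 shuffled DDMs per (participant, muscle, event, stage) rerun the
identical pipeline on label permutations (class counts preserved). The
threshold is the 95th percentile (linear interpolation between order
statistics) of accuracy pooled over all defined cells of that family's
shuffles — per-family pooling is the default; pooling across a participant's
six families is a config option, since the source description supports both
readings. Cells *strictly* exceeding the threshold are clustered by
adjacency on the (onset, size) grid — 4-connectivity by default,
8-connectivity via config; the grid metric is not standardized anywhere, so
the conservative choice is the default. Clusters smaller than 2 cells are
discarded; a cluster's statistic is the sum of its accuracies. Each shuffled
DDM contributes its best cluster statistic (0 if none) to the null; a real
cluster is significant iff it exceeds *all* null values, which bounds the
familywise p at 1/(N+1) (p &lt; .001 at N = 1000). Reported p-values use the
add-one convention (1 + #{null ≥ stat}) / (1 + N) so they are never zero.

## Grouping participants

Each participant's six significant-cluster counts (ZM/CS × stimulus, speech,
response) form a vector; participants are compared by 6-D Euclidean distance
and grouped by density peaks: ρ_i counts neighbors within a cutoff d_c
(hard cutoff, matching the "many similar participants" notion), δ_i is the
distance to the nearest participant of higher density (ties broken toward
the lower index; the global peak takes its maximum distance). Prototypes are
the points before the largest *relative* gap in the ranked γ = ρ·δ sequence
(at least 1, at most n/2; a fixed count can be forced); everyone joins their
nearest prototype, ties toward the higher-γ prototype.

**d_c default.** The classic prescription — a 1–2% average neighborhood —
assumes thousands of points. At cohort scale (n ≈ 40) it leaves almost every
ρ at 0 and the decision graph degenerates; the default here is the 20th
percentile of off-diagonal distances (~8 neighbors at n = 40), which
realizes the same intent at small n. The percentile is a config knob.

Per group, a paired t-test compares total ZM vs total CS counts and a
repeated-measures one-way ANOVA compares the three event sums (statsmodels
`AnovaRM`).

## Behavioral layer

Per participant: lie rate, successful lying (L-T / all lies — the complement
of the detection rate L-L / all lies, so human and machine detection share a
scale; the source text is ambiguous about the denominator and this is the
reading used throughout), detection rate, and reaction times split by
lie/truth (sender RT = speech − stimulus; receiver RT = response − speech).
Cohort-level: a logistic regression of lying on trial number and an
incentive dummy with standard errors clustered by participant (sandwich with
the G/(G−1) small-sample correction, via statsmodels GLM); the
percentage-bend robust correlation (Wilcox's estimator, bend constant
β = 0.2, t approximation with n − 2 df — implemented in-module and
cross-checked against pingouin); and the machine-vs-human comparison: a
paired t-test of each participant's maximal DDM accuracy against the human
detection rate, plus bend and Spearman correlations of classifier accuracy
with successful lying. Participants who never lie propagate NaN rates and
drop out of cohort tests.

## The synthetic generator

Real recordings from this paradigm are not publicly available, so the `synth`
module generates cohorts with the statistical structure the analysis assumes.

**Signal model.** Each muscle is one stochastic source: Gaussian noise
band-limited to 20–450 Hz multiplied by an activation envelope — a 1.5 µV
resting tone plus raised-cosine bursts (0.6 s, 0.1 s cosine ramps).
Calibration gestures burst at ~80 µV; every trial event elicits a burst in
both muscles (stimulus 25 µV, speech 35 µV, response 25 µV — speech loudest,
as orofacial movement dominates) with log-trial-to-trial amplitude jitter of
CV 0.35. Sources mix linearly into the 8 electrodes with distance-dependent
gains (ZM strictly dominant on electrodes 0–4, CS on 5–7, with small
per-participant jitter) plus 2 µV white sensor noise. These levels give
calibration contrast ratios well above the selection threshold and
burst-to-floor SNR typical of facial sEMG; they were fixed once as the
generator's study conditions.

**Planted effect.** A participant's `liar_type` names the telltale muscle
(or NULL). On lie trials the telltale muscle's burst amplitude in the
profile's `effect_events` is shifted by `effect_size` *standard deviations*
of the amplitude distribution, so the standardized lie-vs-truth envelope
difference (Cohen's d) equals `effect_size` at every magnitude — the
additive-in-SD formulation was chosen over a multiplicative (1 + e) scaling
precisely because it keeps the parameter on the d scale uniformly. The
default effect size (1.0, speech epoch) makes detection neither trivial nor
impossible: per-stage realized d fluctuates with sampling (SE ≈ 0.24 at 80
trials), which is the main source of participant-to-participant variability
in recovery.

**Behavior.** Lies follow a logistic trend centered at mid-session,
logit p_i = logit(base) + drift·(i − (n+1)/2), so `lie_base_rate` (default
0.5) stays the session-average while `lie_drift` (default 0.002 log-odds per
trial, the order observed empirically in this paradigm) raises late-session
lying. Sender and receiver reaction times are log-normal around profile
means (defaults 1.9 s and 4.4 s, matching the reported means; log-SD 0.40
and 0.30 to match the reported coefficients of variation). The Receiver is a
Bernoulli judge: hit rate `receiver_hit_rate` (default 0.485, near-chance)
on lies, false-alarm 0.5 on truths; cohort generation can couple the hit
rate to the participant's effect size (0.5 + 0.1·e), the structure that
produces a negative machine–human correlation without modeling perception.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: motor-unit interference structure and firing
statistics, electrode-skin impedance drift and motion artifacts, eye-blink
and ECG contamination, FACS-style action-unit kinematics, word-dependent
articulation differences, and any perceptual basis for the Receiver's
judgments. Effects are planted as single per-trial amplitude scalars; real
telltale expressions may be temporally structured within the epoch, which
would make window-resolved decoding *more* informative than in simulation.

## Numerical choices and degenerate inputs

- Determinism: every stochastic step flows from explicit integer seeds
  (participant seeds from a cohort seed via `SeedSequence`; per-DDM holdout
  draws from a counter-based Philox stream keyed by (seed, shuffle index),
  so a DDM built alone is bit-identical to the same row of a joint
  real-plus-shuffles run).
- Classifier ridge: 1e-8 × trace of the feature Gram — a numerical guard,
  not a tuning parameter; `ridge=0` recovers plain least squares and is used
  when testing against the lstsq oracle.
- Holdout ties (decision score exactly 0) count as incorrect for either
  class; sampling of holdout pairs is with replacement.
- Zero-variance windows yield NaN cells; zero-variance features raise in
  `reduce_dimensions`.
- Percentile convention everywhere: linear interpolation between order
  statistics (numpy default).
- Envelope of a signal shorter than two 50-ms windows raises; a ragged tail
  shorter than one window contributes one extra spline node.
- All-coincident grouping inputs: the index tie-break makes participant 0
  the single prototype; a single participant takes δ = 0.

## Scales used in the test suite

Full scale (m = 100, 1000 iterations, 1000 shuffles, 40 participants) is
compute-cluster-grade by construction (~5e8 classifier fits per participant
even with the fast path). The suite and the acceptance script therefore run
the pipeline's scaled-down conditions — m = 20 bins of 50 ms, 100
iterations, 200 shuffles, 80 trials/stage, incentivized stage — as the
package's standard desk-scale configuration (`RunConfig()` defaults), with
full-scale constants one `RunConfig.full_scale()` away. Reduced scales
change absolute cluster counts (shorter windows, fewer shuffles) but none of
the calibration or recovery properties being tested.

## Known limitations

- The envelope-amplitude effect model cannot represent liars whose telltale
  is a *timing* change rather than an amplitude change.
- Per-family threshold pooling at 200 shuffles makes the exceed-all rule
  conservative (nominal familywise rate 1/201 per DDM); absolute
  significant-cluster counts are therefore small at desk scale.
- EDF export is not provided (no EDF writer among the package's
  dependencies); signals interchange as in-memory arrays or plain CSV.
- The grouping step inherits density-peak clustering's sensitivity to d_c
  in near-degenerate geometries; the decision-graph table (ρ, δ, γ) is
  exported so such cases can be inspected.
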