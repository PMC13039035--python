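# Methods

## The scientific problem

When people move in the gravity field, part of the muscular effort merely
holds the body against gravity (the *tonic* component) and part produces the
motion itself (the *phasic* component). An efficient controller does not
fight gravity: when the gravity torque helps the intended motion — the
acceleration phase of a downward movement, the deceleration phase of an
upward one — it can *reduce* muscle drive below the level needed for static
gravity compensation. On the phasic EMG this appears as *negative epochs*:
intervals where the movement-related activity dips below zero. Their depth,
extent and frequency quantify how much the nervous system exploits gravity,
and changes in these metrics across age groups index a shift in motor
strategy (efficiency vs. postural safety). The package implements that
quantification end to end, together with the center-of-mass (CoM) kinematics,
group classification, walking energetics and a trajectory-optimization model
that probes the efficiency/stability trade-off, and a synthetic-data
generator so the whole chain is testable without the original recordings.

## EMG processing and phasic/tonic separation

Per trial: zero-phase third-order Butterworth band-pass 30–300 Hz,
full-wave rectification, zero-phase third-order low-pass at 5 Hz, then
trapezoidal integration over a 100 ms sliding window (centered; edge windows
truncated). The band-pass is applied to the *raw* signal, before
rectification: the information the later stages need is the low-frequency
envelope of the rectified signal, and that envelope is exactly what the
30 Hz high-pass edge would remove if rectification came first. A
`rectify_first` switch implements the literal alternative order for
comparison.

Movement windows are cut from 240 ms before movement onset to 90 ms after
offset for fast trials (75/75 ms for slow trials). Onset/offset come from
kinematics: displacement rising above 5% and 95% of the total movement
amplitude, the amplitude being measured between steady phases (200 ms
fast / 500 ms slow) before and after the movement; fast movements use the
vertical axis, slow movements the 3-D distance (noisier traces). A 5%
crossing must persist 25 ms to count as onset (suppresses noise-induced
false onsets; the tie-break is "first sustained crossing").

The tonic template of a task × muscle × direction block is the mean of its
slow trials after cutting and linear time-normalization to L = 1000 points
(L only sets quadrature resolution). Fast trials are ordered by movement
mean velocity (stable sort; ties keep acquisition order), averaged in
consecutive pairs from slowest to fastest (an odd trailing trial — the
fastest — is dropped), and the phasic trace of each pair is
(fast − tonic) / task-max, where task-max is the maximal integrated EMG of
that participant × task × muscle. Subtraction happens in normalized time;
the template is not rescaled to the pair duration (both live on the same
normalized axis).

## Negativity metrics

A negative epoch is a maximal run with phasic < −3 × SD of the pre-onset
stable margin, lasting at least 40 ms of real time. Per epoch, with
normalized-time trapezoids and the tonic brought to the same task-max units:

* `NA` — (negative part of the) phasic area over the epoch, ≤ 0;
* `TA` — tonic area over the same interval, > 0;
* `T` — epoch duration / movement duration;
* index = `T · NA / TA` ≤ 0 (lower = more gravity exploitation);
* amplitude = `100 · mean(phasic)/mean(tonic)` over the epoch
  (−100 = muscle silent, 0 = exact compensation).

Because NA and TA are both epoch integrals, the index grows *linearly* with
epoch length at fixed depth and tonic (NA/TA is then constant). Multiple
epochs per trial combine additively (areas are additive): indices and
durations sum, amplitude is the duration-weighted mean. Trials without
epochs contribute index 0, occurrence 0, duration 0 and a *missing*
amplitude. All four metrics are invariant to the task-max constant.
Aggregation: trials → focal antigravity muscles (arm task: anterior deltoid;
whole-body tasks: vastus lateralis and erector spinae L1) → task groups
(ARM; WB = mean of the three whole-body tasks). Empty cells stay missing.

## Classification control analysis

Binary young/older classification of the time-normalized phasic waveforms
(per muscle or all muscles concatenated), 5-fold cross-validation stratified
jointly on group and movement direction, standardization fit on training
folds only. LDA is the primary model (SVD solver; rank truncation provides
the regularization needed when features ≫ rows); QDA (behind a training-fold
PCA, since per-class covariances need fewer dimensions than class samples)
and a linear SVM are robustness hooks. The published 52.5% "fairness"
threshold construction is not described; the package provides an exact
binomial tail bound and a label-permutation quantile, without claiming
either is the original.

## Walking energetics

Metabolic power follows the Brockway combination P = 16.38·VO2 + 4.64·VCO2
with coefficients in J/mL, i.e. applying directly to gas-volume rates in
mL/s; breath files are ingested in mL/min (typical metabolic-cart export)
and converted, with an L/min switch. Per-breath powers are averaged with
time weights (inter-breath Voronoi cells clipped to the window): unweighted
means over irregular breaths would over-weight rapid breathing. Gross power
is the average over the last minute of the 3-min block; baseline the average
from 1 min to 30 s before block start (seated rest); net = (gross −
baseline)/mass in W/kg. Gait metrics: feet spacing = medio-lateral distance
of mean foot positions; steps = prominence-filtered peaks of the right
foot's antero-posterior excursion; step rate = (n−1)/(t_last − t_first);
step length = mean peak prominence, variability its SD.

## Split-plot statistics

The mixed ANCOVA (between: age group; within: task type; covariate:
movement duration, which varies within subjects) is computed in the two
classical error strata: the group effect on subject means against the
subject-level residual (adjusted for the between-subject part of the
covariate), and task, group × task, and the within-subject covariate part
against the within residual with subject intercepts absorbed. Type III sums
of squares with effect coding and a grand-mean-centered covariate; partial
η² per stratum; Greenhouse–Geisser-corrected p alongside the uncorrected one
for within factors with ≥ 3 levels. The no-covariate reduction agrees with
pingouin's `mixed_anova` to machine precision (tested), and the type-I error
of the interaction test is calibrated by simulation (2000 nulls, rejection
rate within [0.04, 0.06] at α = .05).

## Reaching simulations

A sagittal 3-link chain (shank, thigh, HAT = head–arms–trunk) pinned at the
ankle, parameters from the frozen anthropometric table for a 1.70 m / 70 kg
reference body; Lagrangian dynamics in absolute segment angles; no friction
or tissue elasticity. The chain tip stands for the shoulder/head end — the
model has no arm — so fingertip targets are raised by one hanging-arm length
(0.35 × height): the default target, (0.30 H forward, 0.45 H up), is the far
reaching distance, where the posture manifold leaves room for genuinely
different strategies. Joint limits are physiological (ankle −0.3…0.9, knee
−2.5…0.05, hip −0.2…2.8 rad, relative angles).

Transcription: decision variable = joint angular jerk at N = 40 trapezoidal
nodes (fixed 1 s duration isolates the weight effect); states follow by
exact trapezoidal integration and torques by inverse dynamics, leaving only
terminal equality constraints (tip on target, zero terminal velocity and
acceleration) and joint-range inequalities; SLSQP solves the NLP. Torques
pass through a first-order activation filter (40 ms). Composite cost:

    J = w_eff · (jerk/J* + λ·work/W*)/(1+λ) + (1 − w_eff) · stab/S*

with jerk = ∫Σü̇², work = ∫Σ|τ·q̇| (smoothed with a 1 W floor), stab = ∫Στ²,
each normalized by its own pure-cost optimum (J*, W*, S*; three
normalization solves per sweep). λ defaults to 4: the absolute work is the
energetic-efficiency criterion proper and jerk acts as a smoothness
regularizer — with equal mixing the jerk term dominates the solution family
and the efficiency/stability kinematic contrast disappears. The weight sweep
warm-starts each solution from the previous one and reports per-weight CoM
displacement (start-to-end distance / height) and peak CoM speed; across
w_eff the two increase together, the simulation's rendering of the
experimentally observed trade-off.

## Synthetic world

The generator emulates the study design: 20 young and 24 older participants;
arm raising (45°, ≈ 0.5 m endpoint amplitude), sit-to-stand/back-to-sit, and
whole-body reaching to 15%/30% of height; slow blocks ≈ 5 s per movement,
fast blocks task-specific (0.45–1.4 s), with older adults 3.5% slower on
fast trials. EMG envelopes = tonic baseline (0.2 mV with a mild 15%
posture dependence) + an agonist burst in the gravity-opposing phase +,
with probability 0.95 per fast trial, a negative epoch of depth 0.8 × tonic
(arm, both groups), 0.9 (whole-body, young) or 0.56 (whole-body, older —
the ratio of the published group means), placed in the gravity-assisted
phase. Epochs have raised-cosine shoulders (150 ms, capped at 10% of
movement duration) around a flat core of 0.2 × movement duration: sharp
square deactivation is non-physiological and would make any threshold
detector's output depend on the analysis filters' step response. Noise is
zero-mean Gaussian on the integrated-EMG scale (SD = 5% of the tonic
baseline, smoothed to envelope bandwidth), set so the −3·SD/40 ms detector
produces < 5% false positives on epoch-free trials. Raw mode multiplies the
envelope by a broadband carrier and exercises the full filter chain;
envelope mode feeds the integrated scale directly (where the noise model is
defined) and is what the Monte-Carlo suites use for speed.

Ground truth for recovery tests is computed *analytically* from the injected
pulse shape at the −3·SD level (threshold-crossing width and mean depth of
the raised-cosine pulse), independent of any pipeline code. Breath series
have a seated baseline (80 W), an exponential on-transient (τ = 30 s), a
plateau at baseline + net × mass (net 3.0/3.4 W/kg for normal/line walking,
RER 0.85, 3 s breaths, 3% multiplicative noise). Gait trajectories are
sinusoidal foot excursions with configured frequency, length and
medio-lateral spacing (0.18 m normal, 0.06 m line walking).

What a green test does and does not establish: the generator shares the
pipeline's structural assumptions (minimum-jerk kinematics, phase-locked
tonic, Gaussian envelope noise); recovery within 10% demonstrates the
pipeline's internal consistency and noise robustness, not the biological
validity of those assumptions. Real EMG nonstationarity, electrode artifacts
and marker occlusions are out of scope of the generator.

## Numerical choices and degenerate inputs

* Zero-phase filtering uses reflect padding (3 × order per second-order
  section); constants filter to themselves exactly; signals shorter than the
  warm-up are rejected.
* Epoch quadrature uses the normalized grid spacing 1/(L−1); pulse edges on
  grid points reproduce rectangle-rule hand calculations exactly.
* Silent-tonic epochs (TA ≤ 0) are discarded with a warning — the ratio
  metrics are undefined there.
* Velocity-bound detection breaks peak ties toward the earlier peak;
  single-sample degenerate peaks fail the onset < offset invariant and raise.
* The OC solver accepts iteration-limited SLSQP exits when terminal
  residuals are < 1e-4 (warm-started sweeps refine them); failures raise
  with the residual in the message, and sweeps fall back from warm to cold
  starts before flagging a weight as failed.
* Scaled-down Monte-Carlo worlds (shorter slow trials, fewer trials per
  block, 200 Hz envelopes, L = 300–400) are used in the test suite for CPU
  budget; injected effects, noise levels and thresholds are never changed
  from the stated defaults.

## Known limitations

* The anthropometric fractions are one frozen published set; other tables
  shift CoM magnitudes (not pipeline logic).
* The 3-link model is a deliberate simplification; its sweep reproduces the
  qualitative efficiency/stability trade-off, not any quantitative axis of
  the original multi-segment model.
* The split-plot ANCOVA mirrors point-and-click defaults (Type III, centered
  covariate) but is not guaranteed identical to any particular GUI package
  when designs are unbalanced.
* C3D reading requires the optional `ezc3d` package; the CSV motion dialect
  is the fully supported path.
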