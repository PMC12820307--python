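# Methods

`kin2emg` reimplements, as a tested pipeline, an analysis that predicts
8-channel upper-limb muscle activation envelopes from end-effector (hand)
kinematics with an LSTM, and probes three questions: whether the model
generalizes to movement types never seen in training, whether the swivel
angle (the arm's redundant elbow degree of freedom) helps, and whether
decomposing movements into submovement-like sub-sequences helps. Since the
kind of dataset this analysis targets (motion capture + surface EMG in a
controlled multi-task study) is not freely downloadable, the package ships
a synthetic study generator with a known ground-truth
kinematics-to-activation mapping; every downstream stage is validated
against that ground truth or against analytic oracles.

## Synthetic study generator

**Arm model.** A rigid right arm rooted at the shoulder: upper arm
`L_u = 0.30 m`, forearm `L_f = 0.25 m`, plus a short hand segment
(`0.08 m`) so wrist rotations are visible in the end-effector position.
The values are anthropometrically plausible; nothing downstream depends on
them. Six joint coordinates (shoulder azimuth/elevation, humeral rotation,
elbow flexion, forearm pronation, wrist flexion) drive a rotation-matrix
forward-kinematics chain; scapular motion is not modelled. The resting
pose hangs the arm parallel to the body with a slightly bent elbow
(0.05 rad): a perfectly straight hanging arm would leave the arm plane —
and hence the swivel angle — undefined at rest, whereas the slight bend
reproduces the realistic situation in which only the *vertical-axis*
swivel reference degenerates at rest (the case the moving help vector is
designed to survive).

**Task catalog.** 23 movement tasks (12 simple single-joint, 11 complex
multi-joint) named after common motor-control study movements (shoulder
flexion/abduction at 90 deg and with mixed endpoints, elbow and wrist
movements, breaststroke, waving, reading a watch, drawing shapes, ...).
Each task is a list of joint-space waypoints beginning and ending at rest,
with a nominal duration of 3–6.5 s, inside the 7.5 s instruction window
the emulated acquisition uses. Waypoint amplitudes are a modelling choice;
what matters downstream is that simple tasks are essentially single-plane,
single-joint excursions and complex tasks involve several joints and
out-of-plane motion. An availability grid marks 8 of the 23 tasks as
missing for one subject each (emulating electrode loss / mis-execution),
leaving 15 tasks shared by all five subjects; missing-cell emulation is
off by default and enabled per config.

**Trajectories.** Joint trajectories are piecewise minimum-jerk
interpolations through the waypoints
(`x(tau) = x0 + (x1-x0)(10 tau^3 - 15 tau^4 + 6 tau^5)`), the standard
model for point-to-point reaching; each leg's share of the task duration
is proportional to its largest joint excursion. Per repetition, waypoint
amplitudes and the duration are jittered by independent `N(1, 0.05^2)`
factors, and smooth execution noise (sd 0.5 deg per joint) is added. The
noise correlation time is 100 ms — on the physiological tremor scale, and
deliberately slower than the 200 ms RMS analysis window so that the
ground-truth envelope is recoverable by the package's own enveloping step
(with a faster choice the generating envelope itself would fluctuate
inside the window and no estimator could track it).

**Ground-truth EMG model.** Per channel, a neural drive
`u_i = sum_j [w+_ij max(0, omega_j) + w-_ij max(0, -omega_j)] + posture_i`
rectifies signed joint angular velocities (agonist/antagonist gains mirror
the recorded muscle set: deltoids on shoulder motion, biceps/triceps on
elbow flexion/extension, pronator teres on pronation, the carpi ulnaris
pair on wrist motion, with 0.05 cross-talk everywhere), adds a
gravity/posture term driven by shoulder elevation and elbow flexion, and
is low-pass filtered with a 60 ms activation time constant. Per-channel
gains are calibrated against a jitter-free pass over the catalog so
session envelopes stay in [0, 1], and per-subject lognormal gain jitter
(sd 15%) emulates inter-subject variability without destroying
learnability. Raw EMG at 2222 Hz is the envelope times unit-variance white
noise plus a baseline noise floor (sd 0.01) — amplitude-modulated noise,
whose windowed RMS is exactly the envelope in expectation. This is a
deliberate idealization: it contains no motion artifacts, electrode
cross-talk, fatigue drift, or frequency-domain structure, so passing tests
demonstrate that the pipeline recovers a mapping of this rectified-linear
form, not that real EMG is this easy.

**Determinism.** All randomness flows through `numpy` `SeedSequence`
spawning keyed on (subject, task, repetition); the same study seed
reproduces every array bit-for-bit.

## Preprocessing

EMG is synchronized to the 60 Hz kinematic clock by taking the RMS of all
raw samples within a 200 ms window centered on each kinematic timestamp
(closed interval; edge windows truncate rather than drop frames, which
would desynchronize inputs from targets). Envelopes are normalized per
subject and channel by the session-wide maximum — the session scope
mirrors the acquisition convention, and is knowingly not split-safe (the
maximum can come from a test repetition); a `split_safe_normalization`
flag is reserved for studying that leakage. End-effector positions are
min-max scaled to [-1, 1] per subject session; quaternion components pass
through unscaled (min-max would distort rotation geometry), and the swivel
angle maps fixedly from [0, pi] to [-1, 1].

## Swivel-angle geometry

The classic swivel angle is the angle between the shoulder-elbow-wrist
plane and a reference plane through shoulder, wrist and the vertical axis,
computed from the plane normals `n_A = (E-S) x (W-S)` and
`n_R = (W-S) x z`; the sign convention makes the angle zero when the elbow
hangs directly below the shoulder-wrist line, and the arccos form yields
an unsigned angle in [0, pi]. Two degeneracies are guarded explicitly:
shoulder-wrist within 2 deg of vertical (reference undefined — true at
rest for every task here) and elbow within 1% of the arm length of the
shoulder-wrist line (arm plane undefined, straight arm).

The elbow swivel angle (ESA) replaces the fixed vertical reference by a
help vector that starts as the x-axis at rest and is transported frame to
frame by the minimal rotation aligning successive shoulder-wrist
directions, then re-orthogonalized and renormalized (checked to 1e-9).
Minimal-rotation parallel transport is this package's reading of a
reference that "rotates with the movement"; it coincides with the fixed
vertical reference whenever the shoulder-wrist direction moves in a
vertical plane away from the degeneracy, which the test suite exploits.
Degenerate frames hold the last valid angle rather than interpolating —
holding is honest about the information content while keeping the feature
continuous for the model.

## Segmentation

The end-effector speed (central differences, 5-frame zero-phase moving
average) is thresholded at 5% of its peak with a 3-sample sustain to find
the active movement; sub-sequence boundaries are the points where the
discrete second derivative of speed changes sign — the submovement-like
decomposition into bell-shaped acceleration units. A minimum-jerk stroke
has exactly two such inflections, at `tau = (3 +/- sqrt(3))/6`, hence
three segments per stroke. Sign changes closer than 100 ms merge, and
curvature below 1e-8 of the peak speed counts as zero (flat stretches are
not inflections). Each sustained run is segmented independently; a
mid-movement pause therefore separates runs rather than contributing a
segment. The relative threshold makes the segmentation invariant to
global position rescaling, so it is immaterial whether it runs before or
after kinematic scaling.

## Protocol

Models are subject-specific. Within each task of the full 18-repetition
protocol, repetitions split 14/2/2 into train/validation/test, with the
middle contiguous block of four repetitions used for validation + test to
avoid the earliest and latest executions; all four reserved repetitions
are used, as 2 + 2, and the counts are configurable. Studies with fewer
repetitions split proportionally. Under leave-one-movement-out, the left-out task is absent
from train, validation and test, and all its repetitions form the
new-motion set; only tasks available for every subject enter the
rotation, which yields 15 left-out movements on the full availability
grid. The complexity experiment restricts the training pool to simple or
complex movements and always evaluates on both category-exclusive test
sets, so a specialist model's score on the opposite category measures
cross-category generalization to unseen movement types.

## Model

Input (7 features: scaled position + quaternion; 8 with the swivel angle)
→ LSTM(128) → dropout(0.2) → LSTM(64) → linear(8), mean squared error on
normalized envelopes, Adam at 1e-3, mini-batches of 16 variable-length
sequences, early stopping on validation loss (patience 20) with
best-epoch restore. The recurrent layers are implemented directly in
numpy with full backpropagation through time; variable-length batches are
padded and masked such that padded timesteps perform no recurrent state
update and contribute nothing to the loss denominator (packed-sequence
semantics), which the test suite verifies against numerical
differentiation and against single-sequence forward passes. The linear
head is not clamped to [0, 1]: overshoot on poorly predicted movements is
part of the behavior under study. Gradients are clipped at global norm 5.
Mini-batches are length-bucketed (shuffle, sort within four-batch
windows) to limit padding; this changes batch composition, not the
masking semantics.

Two training granularities: `1seq` trains and evaluates on whole
movement sequences; `nseq` on the segmentation's sub-sequences, with
per-segment predictions concatenated over the frames the segments cover
before scoring.

## Evaluation and statistics

Four metrics per trial, pooled over the flattened time-by-channel matrix:
MSE, squared Pearson correlation r^2, coefficient of determination R^2,
and the zero-line score `Z_s = 100 (1 - sum(y-x)^2 / sum y^2)` — an R^2
baselined at zero, the natural rest level of non-negative EMG envelopes
(100 = perfect, 0 = no better than silence, negative = worse than
silence). Pooling before aggregation is a package choice; per-channel
scoring then averaging is the main alternative and is deliberately not
mixed in. Undefined metrics (constant series, all-zero targets) are
recorded as missing, never coerced to zero. Summaries take medians over
runs, then movements, then subjects, reporting the median absolute
deviation of the last step.

Condition comparisons across subjects: zero-line scores are
Fisher-z-transformed (`arctanh(Z_s/100)` — the bounded score is
left-skewed; scores at the bound clip to 100 - 1e-6 with a warning), one
summary value per subject (median over movements and runs), Shapiro-Wilk
on the paired differences gates at alpha = 0.05 between a two-sided
paired t-test and the Wilcoxon signed-rank fallback. The paired effect
size `d = mean(diff)/sd(diff)` satisfies `d = |t|/sqrt(n)` exactly. No
multiple-testing correction is applied: each comparison is reported as a
single planned contrast.

## Desk-scale defaults and problem sizes

The default experiment configuration is a desk-scale study — 3 subjects x
8 tasks (4 simple, 4 complex, covering both swivel-relevance groups) x 8
repetitions, 2 left-out movements per subject, 2 training runs per cell —
with a proportionally smaller model (hidden sizes 32/16, learning rate
3e-3, at most 40 epochs with patience 6). These sizes are the package's
chosen benchmark conditions: the ground-truth mapping is learnable by
construction at this scale, and the full 2x2 condition grid runs on a
single CPU in minutes. The full-scale study (5 x 23 x 18, hidden 128/64,
patience 20) is reachable purely through configuration.

## Known limitations

- The generator's activation model is rectified-linear in joint
  velocities with a posture term; real EMG has nonlinear recruitment,
  co-activation, fatigue and crosstalk. Results on the benchmark bound
  what the pipeline can do, not what real data would give.
- The swivel angle is unsigned ([0, pi]); left/right of the reference
  plane is not distinguished (the arccos definition cannot).
- The ESA transport rule (minimal rotation) is one defensible reading of
  a "moving help vector"; other transports differ on out-of-plane
  motions.
- Session-wide EMG normalization leaks test-repetition amplitude
  information into training; kept because it matches the emulated
  acquisition convention.
- Segment boundaries are shared across all 8 target channels (one
  segmentation per trial, on the end-effector speed).
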