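# kin2emg

Predicting upper-limb muscle activity from end-effector kinematics with an
LSTM, on a fully synthetic arm-movement/EMG study.

## The problem

How much of a muscle's activation is determined by the movement of the
hand it serves? Given only the hand's position and orientation over time
(the *end effector*, 60 Hz), this package trains a recurrent network to
reproduce the activation envelopes of eight upper-arm muscles (surface
EMG, 2222 Hz, RMS-enveloped to the kinematic clock) and asks three
questions that matter for motor control and for rehabilitation/prosthetic
interfaces:

1. **Generalization** — does a model trained on known movements predict
   muscle activity for a movement *type* it has never seen
   (leave-one-movement-out)?
2. **Redundancy** — the arm has 7 degrees of freedom but the hand pose
   fixes only 6; does adding the *swivel angle* (the elbow's rotation
   about the shoulder-wrist axis) as an 8th input feature help?
3. **Decomposition** — does splitting movements into submovement-like
   sub-sequences at inflection points of the speed profile (`nseq`) beat
   training on whole sequences (`1seq`)?

Because the kind of dataset this requires is not publicly downloadable,
the package includes a first-class synthetic study generator: 5 subjects
x 23 movement tasks (12 simple, 11 complex) x 18 repetitions, minimum-jerk
joint trajectories, a known ground-truth kinematics-to-activation mapping,
and amplitude-modulated EMG noise. Every pipeline stage is tested against
that ground truth or against analytic oracles. See `docs/methods.md` for
the model and generator details.

## The core quantities

The prediction target is the normalized envelope `y` versus model output
`x`; the headline metric is the **zero-line score**

    Z_s = 100 * (1 - Σ(y_i - x_i)² / Σ y_i²),

an R² variant baselined at zero — the natural rest level of EMG — so 100
is perfect, 0 is no better than predicting silence, and negative is worse
than silence. MSE, squared Pearson correlation r², and the ordinary R²
are reported alongside. Condition comparisons across subjects use
Fisher-z-transformed scores (`arctanh(Z_s/100)`), a Shapiro–Wilk gate
between a paired t-test and Wilcoxon signed-rank, and the paired Cohen's
d = |t|/√n.

## Worked example

Run the main condition grid — {whole vs segmented sequences} x {without
vs with the swivel feature} — on the default desk-scale study (3 subjects
x 8 tasks x 8 repetitions, 2 training runs per cell):

```bash
kin2emg run-all --seed 1 --out results/grid
```

which prints the median zero-line scores per condition (output for
seed 1, medians and between-subject MADs rounded to 2 decimals):

```json
{
 "1seq_0elbow": {
  "test":       {"median": 78.16, "mad": 0.76},
  "new_motion": {"median": 52.95, "mad": 2.73}
 },
 "1seq_1elbow": {
  "test":       {"median": 77.96, "mad": 1.50},
  "new_motion": {"median": 51.06, "mad": 0.67}
 },
 "nseq_0elbow": {
  "test":       {"median": 86.34, "mad": 0.21},
  "new_motion": {"median": 44.16, "mad": 4.61}
 },
 "nseq_1elbow": {
  "test":       {"median": 87.07, "mad": 0.64},
  "new_motion": {"median": 46.27, "mad": 5.53}
 }
}
```

Read: held-out repetitions of known movements (`test`) are predicted well
(most of the signal energy explained), while entirely unseen movement
types (`new_motion`) lose 25–40 points in every condition — the model
generalizes, at a cost. The swivel feature barely moves either number
here. Note that `nseq` scores are computed over the segmented active
movement only (rest frames excluded), so its `test` and `new_motion`
entries are not directly comparable to the `1seq` rows. The per-trial
scores behind every summary cell land in `results/grid/reports.csv` for
the paired statistics (`kin2emg swivel-groups results/grid/reports.csv`).

Other entry points: `kin2emg simulate` (write a synthetic study as CSVs +
manifest), `kin2emg segment` (inflection-point segmentation of one
trial), `kin2emg complexity` (training pools restricted to simple or
complex movements, evaluated on category-exclusive test sets).

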