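"""End-to-end experiment orchestration.

Runs the full analysis grid on a synthetic study: the four-cell condition
grid {whole sequences (1seq), sub-sequences (nseq)} x {without (0elbow),
with (1elbow) the swivel-angle feature}, each under leave-one-movement-out
evaluation; the swivel-relevance movement grouping; and the movement-
complexity experiment (training pools restricted to simple or complex
movements, evaluated on category-exclusive test sets).

The default configuration is a desk-scale study (3 subjects x 8 tasks x
8 repetitions, 2 training runs per cell) that exercises every pipeline
stage on one CPU in minutes; the study dimensions and the model size scale
up via the config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arm_geometry, emg_preprocess, evaluation, protocol, segmentation
from . import model as model_mod
from . import stats as stats_mod
from .synthetic_data import StudyConfig, default_task_catalog, generate_study

CONDITIONS = (
    ("1seq", "0elbow"),
    ("1seq", "1elbow"),
    ("nseq", "0elbow"),
    ("nseq", "1elbow"),
)

#: Desk-scale task subset: 4 simple + 4 complex, covering both swivel groups.
DESK_TASKS = (
    "shoulder flexion (90)",
    "shoulder abduction (90)",
    "elbow flexion",
    "wrist pronation",
    "breaststroke",
    "reading a watch",
    "waving gestures",
    "drawing a line",
)

#: Movement groups for the swivel-relevance comparison.
CRUCIAL_ELBOW_TASKS = ("waving gestures", "breaststroke", "reading a watch")
NON_CRUCIAL_ELBOW_TASKS = (
    "shoulder abduction (90)",
    "shoulder flexion (90)",
    "wrist pronation",
    "elbow flexion",
)


@dataclass
class SimulationSection:
    n_subjects: int = 3
    n_reps: int = 8
    task_names: tuple = DESK_TASKS
    emulate_missing: bool = False
    baseline_noise_sd: float = 0.01
    rest_pad: float = 0.3

    def __post_init__(self):
        self.task_names = tuple(self.task_names)


@dataclass
class PreprocessingSection:
    window: float = 0.200
    split_safe_normalization: bool = False


@dataclass
class ModelSection:
    """Model hyperparameters; hidden sizes are scaled down at desk scale."""

    hidden_sizes: tuple = (32, 16)
    dropout_rate: float = 0.2
    batch_size: int = 16
    learning_rate: float = 3e-3
    max_epochs: int = 40
    patience: int = 6

    def __post_init__(self):
        self.hidden_sizes = tuple(self.hidden_sizes)


@dataclass
class ProtocolSection:
    n_val: int = 1
    n_test: int = 1
    left_out_tasks: tuple = ("elbow flexion", "reading a watch")
    n_runs: int = 2
    conditions: tuple = CONDITIONS

    def __post_init__(self):
        self.left_out_tasks = tuple(self.left_out_tasks)
        self.conditions = tuple(tuple(c) for c in self.conditions)


@dataclass
class EvaluationSection:
    level: str = "condition"


@dataclass
class ExperimentConfig:
    simulation: SimulationSection = field(default_factory=SimulationSection)
    preprocessing: PreprocessingSection = field(default_factory=PreprocessingSection)
    model: ModelSection = field(default_factory=ModelSection)
    protocol: ProtocolSection = field(default_factory=ProtocolSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(
            simulation=SimulationSection(**d.get("simulation", {})),
            preprocessing=PreprocessingSection(**d.get("preprocessing", {})),
            model=ModelSection(**d.get("model", {})),
            protocol=ProtocolSection(**d.get("protocol", {})),
            evaluation=EvaluationSection(**d.get("evaluation", {})),
            out_dir=d.get("out_dir"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def study_config_from(sim: SimulationSection) -> StudyConfig:
    catalog = {t.name: t for t in default_task_catalog()}
    unknown = [n for n in sim.task_names if n not in catalog]
    if unknown:
        raise ValueError(f"unknown task names: {unknown}")
    return StudyConfig(
        n_subjects=sim.n_subjects,
        n_reps=sim.n_reps,
        tasks=[catalog[n] for n in sim.task_names],
        emulate_missing=sim.emulate_missing,
        baseline_noise_sd=sim.baseline_noise_sd,
        rest_pad=sim.rest_pad,
    )


# ---------------------------------------------------------------------------
# Per-subject preparation
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    """Everything one subject's models train and evaluate on."""

    subject: int
    tasks: list
    envelopes: dict  # task -> list of (N, 8) normalized targets
    envelopes_raw: dict  # task -> list of pre-normalization RMS envelopes
    maxima: np.ndarray
    features7: dict  # task -> list of (N, 7)
    features8: dict  # task -> list of (N, 8)
    segmentations: dict  # task -> list of SegmentationResult

    def features(self, elbow: str) -> dict:
        return self.features8 if elbow == "1elbow" else self.features7


def prepare_subject(manifest, subject: int, window: float = 0.200) -> SubjectData:
    """Envelope, normalize, compute swivel series and scaled features."""
    tasks = manifest.available_tasks(subject)
    trials = {t: manifest.trials[(subject, t)] for t in tasks}
    flat = [tr for t in tasks for tr in trials[t]]
    processed, maxima = emg_preprocess.preprocess_subject_envelopes(flat, window)
    positions = [tr.eef_position for tr in flat]
    scaled_pos, _ = emg_preprocess.scale_kinematics_session(positions)

    envelopes, envelopes_raw = {}, {}
    features7, features8, segmentations = {}, {}, {}
    k = 0
    for t in tasks:
        envelopes[t], envelopes_raw[t] = [], []
        features7[t], features8[t], segmentations[t] = [], [], []
        for tr in trials[t]:
            p = processed[k]
            envelopes[t].append(p.emg_envelope)
            envelopes_raw[t].append(p.envelope_raw)
            swivel = arm_geometry.elbow_swivel_series(tr.shoulder, tr.elbow, tr.wrist)
            features7[t].append(
                arm_geometry.assemble_features(
                    scaled_pos[k], tr.eef_orientation, include_swivel=False
                )
            )
            features8[t].append(
                arm_geometry.assemble_features(
                    scaled_pos[k], tr.eef_orientation, swivel, include_swivel=True
                )
            )
            segmentations[t].append(segmentation.segment_movement(tr.eef_position))
            k += 1
    return SubjectData(
        subject=subject,
        tasks=tasks,
        envelopes=envelopes,
        envelopes_raw=envelopes_raw,
        maxima=maxima,
        features7=features7,
        features8=features8,
        segmentations=segmentations,
    )


# ---------------------------------------------------------------------------
# Single model: train + evaluate
# ---------------------------------------------------------------------------


def _sequences(data: SubjectData, task: str, reps, seq_mode: str, elbow: str):
    """(X, Y) training sequences for the given repetitions of one task."""
    feats = data.features(elbow)[task]
    out = []
    for r in reps:
        X, Y = feats[r], data.envelopes[task][r]
        if seq_mode == "1seq":
            out.append((X, Y))
        else:
            for lo, hi in data.segmentations[task][r].segments:
                if hi - lo >= 2:
                    out.append((X[lo:hi], Y[lo:hi]))
    return out


def _predict_trial(trained, data: SubjectData, task: str, rep: int, seq_mode: str, elbow: str):
    """Predict one trial; under nseq the segment predictions are concatenated
    and scored over the active interval they partition."""
    X = data.features(elbow)[task][rep]
    Y = data.envelopes[task][rep]
    if seq_mode == "1seq":
        return Y, model_mod.predict(trained, X)
    seg = data.segmentations[task][rep]
    preds = [model_mod.predict(trained, X[lo:hi]) for lo, hi in seg.segments]
    return Y[seg.covered_frames()], np.vstack(preds)


def run_single_model(
    data: SubjectData,
    split: protocol.SplitSpec,
    seq_mode: str,
    elbow: str,
    model_section: ModelSection,
    run_seed: int,
    eval_tasks: dict | None = None,
) -> tuple:
    """Train one model for one (split, condition) cell and score its trials.

    ``eval_tasks`` maps dataset label -> {task: [rep indices]}; by default
    the split's test repetitions (dataset "test") and the left-out task's
    repetitions (dataset "new_motion") are scored. Returns (rows, trained).
    """
    train_seqs, val_seqs = [], []
    for task, roles in split.assignment.items():
        train_seqs += _sequences(data, task, roles["train"], seq_mode, elbow)
        val_seqs += _sequences(data, task, roles["val"], seq_mode, elbow)
    cfg = model_mod.ModelConfig(
        input_width=8 if elbow == "1elbow" else 7,
        hidden_sizes=tuple(model_section.hidden_sizes),
        dropout_rate=model_section.dropout_rate,
        batch_size=model_section.batch_size,
        learning_rate=model_section.learning_rate,
        max_epochs=model_section.max_epochs,
        patience=model_section.patience,
        seed=run_seed,
    )
    trained = model_mod.train(model_mod.build_model(cfg), train_seqs, val_seqs, cfg)

    if eval_tasks is None:
        eval_tasks = {
            "test": {t: roles["test"] for t, roles in split.assignment.items()},
        }
        if split.left_out is not None:
            eval_tasks["new_motion"] = {split.left_out: split.new_motion}
    rows = []
    for dataset, task_reps in eval_tasks.items():
        for task, reps in task_reps.items():
            for rep in reps:
                y, x = _predict_trial(trained, data, task, rep, seq_mode, elbow)
                scores = evaluation.score_trial(y, x)
                for metric, value in scores.items():
                    rows.append(
                        {
                            "subject": data.subject,
                            "condition": f"{seq_mode}_{elbow}",
                            "dataset": dataset,
                            "movement": task,
                            "left_out": split.left_out,
                            "run": run_seed,
                            "metric": metric,
                            "value": value,
                        }
                    )
    return rows, trained


def _run_seed(base_seed: int, *key) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


def run_condition_grid(config: ExperimentConfig, seed: int = 0) -> tuple:
    """The main grid: conditions x leave-one-movement-out x runs.

    Returns ``(tidy, summary)``: a tidy per-trial score table and the
    median/MAD summary per (condition, dataset, metric). Deterministic
    given ``seed``.
    """
    manifest = generate_study(study_config_from(config.simulation), seed)
    subjects = {
        s: prepare_subject(manifest, s, config.preprocessing.window)
        for s in manifest.subject_ids
    }
    rows = []
    for s, data in subjects.items():
        for lo_idx, left_out in enumerate(config.protocol.left_out_tasks):
            if left_out not in data.tasks:
                continue
            split = protocol.make_splits(
                manifest,
                s,
                left_out=left_out,
                n_val=config.protocol.n_val,
                n_test=config.protocol.n_test,
            )
            for c_idx, (seq_mode, elbow) in enumerate(config.protocol.conditions):
                for run in range(config.protocol.n_runs):
                    rs = _run_seed(seed, s, lo_idx, c_idx, run)
                    r, _ = run_single_model(
                        data, split, seq_mode, elbow, config.model, rs
                    )
                    rows += r
    tidy = pd.DataFrame(rows)
    summary = evaluation.aggregate(tidy, level=config.evaluation.level)
    return tidy, summary


def summary_to_grid(summary: pd.DataFrame, metric: str = "Zs") -> dict:
    """Nested {condition: {dataset: {"median", "mad"}}} view of a summary."""
    sel = summary[summary["metric"] == metric]
    out = {}
    for _, row in sel.iterrows():
        out.setdefault(row["condition"], {})[row["dataset"]] = {
            "median": float(row["median"]),
            "mad": float(row["mad"]),
        }
    return out


def run_swivel_grouping(
    tidy: pd.DataFrame,
    crucial_tasks=CRUCIAL_ELBOW_TASKS,
    non_crucial_tasks=NON_CRUCIAL_ELBOW_TASKS,
    seq_mode: str = "1seq",
) -> dict:
    """Compare elbow conditions within swivel-relevant movement groups.

    New-motion zero-line scores are split into movements likely to benefit
    from the swivel angle and movements unlikely to; within each group the
    0elbow and 1elbow conditions are compared pairwise across subjects.
    """
    if set(crucial_tasks) & set(non_crucial_tasks):
        raise ValueError("groups must be disjoint")
    nm = tidy[(tidy["dataset"] == "new_motion") & (tidy["metric"] == "Zs")]
    out = {}
    for label, group in (
        ("crucial", tuple(crucial_tasks)),
        ("non_crucial", tuple(non_crucial_tasks)),
    ):
        sub = nm[nm["movement"].isin(group)]
        if sub.empty:
            raise ValueError(f"no new-motion scores for group {label!r}")
        per_subject = {}
        for elbow in ("0elbow", "1elbow"):
            cond = f"{seq_mode}_{elbow}"
            agg = (
                sub[sub["condition"] == cond]
                .groupby("subject")["value"]
                .median()
                .sort_index()
            )
            per_subject[elbow] = agg
        a, b = per_subject["0elbow"], per_subject["1elbow"]
        common = a.index.intersection(b.index)
        result = {
            "movements": list(group),
            "median_0elbow": float(a.loc[common].median()),
            "median_1elbow": float(b.loc[common].median()),
        }
        if len(common) >= 3:
            try:
                st = stats_mod.paired_compare(
                    a.loc[common].values,
                    b.loc[common].values,
                    comparison=f"{label}:0elbow_vs_1elbow",
                )
                result["stat"] = st
            except stats_mod.DegenerateComparisonError:
                result["stat"] = None
        out[label] = result
    return out


def run_complexity_experiment(config: ExperimentConfig, seed: int = 0) -> tuple:
    """Three training pools (all / simple / complex) on the exclusive test sets.

    Each model trains on one pool's tasks and is scored on both the
    simple-exclusive and complex-exclusive test sets. For a specialist
    model the opposite category's test set consists of movement types never
    seen in training — the cross-category generalization cells.
    """
    manifest = generate_study(study_config_from(config.simulation), seed)
    subjects = {
        s: prepare_subject(manifest, s, config.preprocessing.window)
        for s in manifest.subject_ids
    }
    rows = []
    for s, data in subjects.items():
        for m_idx, mode in enumerate(("all", "simple", "complex")):
            subsets = protocol.complexity_subsets(manifest, mode)
            full = protocol.make_splits(
                manifest,
                s,
                left_out=None,
                n_val=config.protocol.n_val,
                n_test=config.protocol.n_test,
            )
            # restrict training/validation to the mode's pool
            split = protocol.SplitSpec(
                subject=s,
                left_out=None,
                assignment={
                    t: r for t, r in full.assignment.items() if t in subsets.train_tasks
                },
                new_motion=[],
            )
            eval_tasks = {
                "simple_exclusive_test": {
                    t: full.assignment[t]["test"] for t in subsets.simple_test_tasks
                },
                "complex_exclusive_test": {
                    t: full.assignment[t]["test"] for t in subsets.complex_test_tasks
                },
            }
            for run in range(config.protocol.n_runs):
                rs = _run_seed(seed, 1000 + s, m_idx, run)
                r, _ = run_single_model(
                    data,
                    split,
                    "1seq",
                    "0elbow",
                    config.model,
                    rs,
                    eval_tasks=eval_tasks,
                )
                for row in r:
                    row["condition"] = f"train_{mode}"
                rows += r
    tidy = pd.DataFrame(rows)
    summary = evaluation.aggregate(tidy, level="condition")
    return tidy, summary


def save_outputs(out_dir, tidy: pd.DataFrame, summary: pd.DataFrame, config=None, seed=None):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tidy.to_csv(out / "reports.csv", index=False)
    summary.to_csv(out / "summary.csv", index=False)
    meta = {"seed": seed}
    if config is not None:
        meta["config"] = config.to_dict()
    with open(out / "run.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True, default=str)
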