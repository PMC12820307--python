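"""Data splits: per-movement repetition split, leave-one-movement-out, and
complexity-based training subsets.

Each subject is modelled separately. Within every included task the
repetitions split 14 / 2 / 2 (train / validation / test) for the full
18-repetition protocol, with the four validation+test repetitions taken
from the middle of the recording order to avoid the earliest and latest
executions; smaller studies split proportionally. Under leave-one-movement-
out (LOO), one movement is excluded entirely from training, validation and
test and all its repetitions form the "new motion" generalization set.
Only movements available for every subject enter the LOO rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field


from .synthetic_data import SessionManifest, common_tasks


class NoCommonMovementError(ValueError):
    """No movement is available for every subject."""


@dataclass
class SplitSpec:
    """Repetition assignment for one (subject, left-out movement) model."""

    subject: int
    left_out: str | None
    assignment: dict  # task -> {"train": [...], "val": [...], "test": [...], "unused": [...]}
    new_motion: list  # repetition indices of the left-out task
    condition: dict = field(default_factory=dict)  # e.g. {"seq": "1seq", "elbow": "0elbow"}
    seed: int | None = None

    def reps(self, task: str, role: str) -> list:
        return self.assignment[task][role]


def _rep_split(n: int, n_val: int, n_test: int) -> dict:
    """Centered-middle-block split of ``n`` repetitions."""
    block = n_val + n_test
    start = (n - block) // 2
    middle = list(range(start, start + block))
    val = middle[:n_val]
    test = middle[n_val:]
    train = [i for i in range(n) if i not in middle]
    return {"train": train, "val": val, "test": test, "unused": []}


def make_splits(
    manifest: SessionManifest,
    subject: int,
    left_out: str | None = None,
    n_val: int = 2,
    n_test: int = 2,
    seed: int | None = None,
) -> SplitSpec:
    """Build one subject's split, optionally leaving a movement out.

    Tasks with at least 17 repetitions use the requested ``n_val``/``n_test``
    (default 2 + 2 from the middle, leaving 14 of 18 for training); smaller
    tasks fall back to a proportional split with a warning. The left-out
    task contributes nothing to train/val/test; all its repetitions become
    the new-motion set. The assignment is deterministic — ``seed`` is
    recorded for provenance only.
    """
    available = manifest.available_tasks(subject)
    if left_out is not None and left_out not in available:
        raise ValueError(f"left-out task {left_out!r} not available for subject {subject}")
    assignment = {}
    for task in available:
        if task == left_out:
            continue
        n = manifest.rep_count(subject, task)
        if n >= 17:
            assignment[task] = _rep_split(n, n_val, n_test)
        else:
            pv = max(1, int(round(n * 2 / 18)))
            pt = max(1, int(round(n * 2 / 18)))
            warnings.warn(
                f"task {task!r} has {n} repetitions; using proportional split "
                f"{n - pv - pt}/{pv}/{pt}",
                stacklevel=2,
            )
            assignment[task] = _rep_split(n, pv, pt)
    new_motion = (
        list(range(manifest.rep_count(subject, left_out))) if left_out else []
    )
    return SplitSpec(
        subject=subject,
        left_out=left_out,
        assignment=assignment,
        new_motion=new_motion,
        seed=seed,
    )


def enumerate_loo(manifest: SessionManifest, n_val: int = 2, n_test: int = 2) -> dict:
    """One split per (subject, commonly available movement).

    A movement enters the rotation only if every subject performed it, so
    all subjects see the same set of new motions. Returns
    ``{subject: [SplitSpec, ...]}``.
    """
    common = common_tasks(manifest.availability)
    if not common:
        raise NoCommonMovementError("no movement is available for all subjects")
    return {
        s: [
            make_splits(manifest, s, left_out=t, n_val=n_val, n_test=n_test)
            for t in common
        ]
        for s in manifest.subject_ids
    }


@dataclass
class ComplexitySubsets:
    """Training pool restricted by movement category + the two exclusive test sets."""

    mode: str  # "all" | "simple" | "complex"
    train_tasks: list
    simple_test_tasks: list
    complex_test_tasks: list


def complexity_subsets(manifest: SessionManifest, mode: str) -> ComplexitySubsets:
    """Restrict the training pool to one movement category.

    ``mode="all"`` keeps the full catalog. The simple- and complex-exclusive
    test sets are always emitted so every model can be evaluated within and
    across categories.
    """
    if mode not in ("all", "simple", "complex"):
        raise ValueError(f"bad mode {mode!r}")
    cats = manifest.categories
    simple = [t for t in manifest.tasks if cats[t] == "simple"]
    complex_ = [t for t in manifest.tasks if cats[t] == "complex"]
    if not simple or not complex_:
        raise ValueError("both movement categories must be present")
    pool = {"all": list(manifest.tasks), "simple": simple, "complex": complex_}[mode]
    return ComplexitySubsets(
        mode=mode,
        train_tasks=pool,
        simple_test_tasks=simple,
        complex_test_tasks=complex_,
    )


def check_no_leakage(split: SplitSpec) -> bool:
    """Verify the split invariants (disjoint roles, excluded left-out task)."""
    for task, roles in split.assignment.items():
        if task == split.left_out:
            return False
        sets = [set(roles[r]) for r in ("train", "val", "test", "unused")]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            return False
    return True
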