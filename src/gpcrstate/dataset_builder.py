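"""Labeled frame datasets and leakage-free trajectory-stratified splits.

Frames sampled from a trajectory inherit the conformational-state label of
its starting structure, every trajectory becomes exactly one fold, and the
train/test partition is drawn at the fold level so that no frames of one
trajectory can ever reach both sides of a split.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .descriptor import PairList, TrajectoryFeaturizer
from .errors import DatasetError, SplitError, TrajectoryError
from .generic_numbering import ResidueMapping, load_mapping
from .structure import Trajectory

__all__ = [
    "FrameSamplingPlan",
    "TrajectoryEntry",
    "LabeledFrameDataset",
    "FoldAssignment",
    "extract_frames",
    "build_dataset",
    "assign_folds",
    "load_manifest",
]

STATES = ("active", "inactive")


@dataclass(frozen=True)
class FrameSamplingPlan:
    """Fixed-interval snapshot plan: trajectory length and sampling spacing."""

    length_ns: float = 20.0
    interval_ps: float = 100.0

    def __post_init__(self) -> None:
        if self.length_ns <= 0 or self.interval_ps <= 0:
            raise TrajectoryError("plan length and interval must be positive")

    @property
    def length_ps(self) -> float:
        return self.length_ns * 1000.0

    @property
    def expected_frames(self) -> int:
        """floor(length / interval): 200 for the default 20 ns / 100 ps plan."""
        return int(math.floor(self.length_ps / self.interval_ps + 1e-9))


def extract_frames(trajectory: Trajectory, plan: FrameSamplingPlan) -> np.ndarray:
    """Indices of evenly spaced frames matching the sampling plan.

    Snapshots are taken at t0, t0+interval, ..., i.e. ``expected_frames``
    frames starting from the first stored frame.  The trajectory must cover
    the plan length (its nominal span, frames x dt) and be stored at least
    as finely as the sampling interval.
    """
    dt = trajectory.dt_ps
    n = trajectory.n_frames
    available_ps = n * dt
    if available_ps + 1e-6 < plan.length_ps:
        raise TrajectoryError(
            f"trajectory {trajectory.name!r} spans {available_ps:.1f} ps "
            f"({n} frames x {dt:g} ps) but the plan requires {plan.length_ps:.1f} ps"
        )
    if plan.interval_ps + 1e-6 < dt:
        raise TrajectoryError(
            f"sampling interval {plan.interval_ps:g} ps is finer than the "
            f"trajectory time step {dt:g} ps"
        )
    targets = np.arange(plan.expected_frames) * plan.interval_ps
    indices = np.rint(targets / dt).astype(int)
    if indices[-1] >= n:
        raise TrajectoryError(
            f"trajectory {trajectory.name!r}: last snapshot time {targets[-1]:.1f} ps "
            f"falls outside the stored {n} frames"
        )
    return indices


@dataclass(frozen=True)
class TrajectoryEntry:
    """One trajectory to be folded into a dataset."""

    trajectory: Trajectory
    mapping: ResidueMapping
    state: str
    traj_id: int

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise DatasetError(f"trajectory {self.traj_id}: state {self.state!r} not in {STATES}")


@dataclass
class LabeledFrameDataset:
    """Descriptor matrix with per-frame state labels and trajectory ids."""

    X: np.ndarray
    labels: np.ndarray
    traj_ids: np.ndarray
    frame_indices: np.ndarray
    pair_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.traj_ids = np.asarray(self.traj_ids, dtype=int)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        n = self.X.shape[0]
        if self.X.ndim != 2 or self.X.shape[1] != len(self.pair_labels):
            raise DatasetError(
                f"matrix shape {self.X.shape} does not match {len(self.pair_labels)} pairs"
            )
        if not (len(self.labels) == len(self.traj_ids) == len(self.frame_indices) == n):
            raise DatasetError("per-frame arrays must all have one entry per matrix row")
        if not np.all(np.isfinite(self.X)):
            raise DatasetError("descriptor matrix contains non-finite values")
        bad = set(self.labels) - set(STATES)
        if bad:
            raise DatasetError(f"unknown state labels {sorted(bad)}")
        for tid in np.unique(self.traj_ids):
            states = set(self.labels[self.traj_ids == tid])
            if len(states) != 1:
                raise DatasetError(f"trajectory {tid} carries multiple labels {sorted(states)}")

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def trajectory_ids(self) -> np.ndarray:
        return np.unique(self.traj_ids)

    def trajectory_states(self) -> dict[int, str]:
        return {
            int(tid): str(self.labels[self.traj_ids == tid][0])
            for tid in self.trajectory_ids()
        }

    def to_csv(self, descriptor_path: Union[str, Path], sidecar_path: Union[str, Path]) -> None:
        """Write the descriptor CSV plus a label/trajectory sidecar CSV."""
        df = pd.DataFrame(self.X, columns=list(self.pair_labels))
        df.insert(0, "frame", self.frame_indices)
        df.to_csv(descriptor_path, index=False)
        side = pd.DataFrame(
            {"traj_id": self.traj_ids, "frame": self.frame_indices, "state": self.labels}
        )
        side.to_csv(sidecar_path, index=False)

    @classmethod
    def from_csv(
        cls, descriptor_path: Union[str, Path], sidecar_path: Union[str, Path]
    ) -> "LabeledFrameDataset":
        df = pd.read_csv(descriptor_path)
        side = pd.read_csv(sidecar_path)
        if len(df) != len(side):
            raise DatasetError("descriptor and sidecar CSVs have different row counts")
        pair_labels = tuple(c for c in df.columns if c != "frame")
        return cls(
            X=df[list(pair_labels)].to_numpy(),
            labels=side["state"].to_numpy(dtype=object),
            traj_ids=side["traj_id"].to_numpy(dtype=int),
            frame_indices=df["frame"].to_numpy(dtype=int),
            pair_labels=pair_labels,
        )


def build_dataset(
    entries: Sequence[TrajectoryEntry],
    pairs: PairList,
    plan: Optional[FrameSamplingPlan] = None,
) -> LabeledFrameDataset:
    """Featurize every trajectory under the sampling plan into one dataset.

    With 38 trajectories under the default 20 ns / 100 ps plan this yields
    the canonical 7,600-row matrix (200 frames each).
    """
    plan = plan or FrameSamplingPlan()
    ids = [e.traj_id for e in entries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DatasetError(f"duplicate trajectory ids {dupes}")
    blocks, labels, tids, fidx = [], [], [], []
    for entry in entries:
        frames = extract_frames(entry.trajectory, plan)
        feat = TrajectoryFeaturizer(entry.trajectory, entry.mapping, pairs)
        block = feat.featurize_frames(frames)
        blocks.append(block)
        labels.extend([entry.state] * len(frames))
        tids.extend([entry.traj_id] * len(frames))
        fidx.extend(frames.tolist())
    return LabeledFrameDataset(
        X=np.vstack(blocks),
        labels=np.array(labels, dtype=object),
        traj_ids=np.array(tids),
        frame_indices=np.array(fidx),
        pair_labels=tuple(pairs.labels),
    )


@dataclass
class FoldAssignment:
    """One fold per trajectory, and a train/test tag per fold."""

    fold_of_trajectory: dict[int, int]
    partition_of_fold: dict[int, str]

    def __post_init__(self) -> None:
        folds = set(self.fold_of_trajectory.values())
        if folds != set(self.partition_of_fold):
            raise SplitError("fold ids of trajectories and partitions disagree")
        if not set(self.partition_of_fold.values()) <= {"train", "test"}:
            raise SplitError("partition tags must be 'train' or 'test'")

    @property
    def n_folds(self) -> int:
        return len(self.partition_of_fold)

    def trajectories_in(self, partition: str) -> set[int]:
        return {
            tid
            for tid, fold in self.fold_of_trajectory.items()
            if self.partition_of_fold[fold] == partition
        }

    def partition_mask(self, dataset: LabeledFrameDataset, partition: str) -> np.ndarray:
        wanted = self.trajectories_in(partition)
        return np.isin(dataset.traj_ids, sorted(wanted))

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "fold_of_trajectory": {str(k): v for k, v in self.fold_of_trajectory.items()},
            "partition_of_fold": {str(k): v for k, v in self.partition_of_fold.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FoldAssignment":
        payload = json.loads(Path(path).read_text())
        return cls(
            fold_of_trajectory={int(k): int(v) for k, v in payload["fold_of_trajectory"].items()},
            partition_of_fold={int(k): str(v) for k, v in payload["partition_of_fold"].items()},
        )


def assign_folds(
    dataset: LabeledFrameDataset,
    n_train_folds: int = 28,
    n_test_folds: int = 10,
    seed: int = 0,
) -> FoldAssignment:
    """Assign one fold per trajectory and draw a stratified train/test split.

    The split is random but seeded and stratified by state: both partitions
    must receive at least one trajectory of each state present in the
    dataset, otherwise a :class:`SplitError` is raised.
    """
    traj_states = dataset.trajectory_states()
    traj_ids = sorted(traj_states)
    n_traj = len(traj_ids)
    if n_train_folds < 1 or n_test_folds < 1:
        raise SplitError("both partitions need at least one fold")
    if n_train_folds + n_test_folds != n_traj:
        raise SplitError(
            f"{n_train_folds} train + {n_test_folds} test folds != {n_traj} trajectories"
        )
    fold_of_trajectory = {tid: i for i, tid in enumerate(traj_ids)}

    by_state: dict[str, list[int]] = {}
    for tid in traj_ids:
        by_state.setdefault(traj_states[tid], []).append(tid)
    for state, members in by_state.items():
        if len(members) < 2:
            raise SplitError(
                f"state {state!r} has only {len(members)} trajectory; "
                "stratification needs at least one per partition"
            )

    # Per-state train quotas: proportional, clamped to leave >=1 on each side,
    # then adjusted to hit the requested total exactly.
    states = sorted(by_state)
    quotas = {}
    for state in states:
        m = len(by_state[state])
        quotas[state] = min(max(int(round(n_train_folds * m / n_traj)), 1), m - 1)
    diff = n_train_folds - sum(quotas.values())
    for state in sorted(states, key=lambda s: -len(by_state[s])):
        while diff > 0 and quotas[state] < len(by_state[state]) - 1:
            quotas[state] += 1
            diff -= 1
        while diff < 0 and quotas[state] > 1:
            quotas[state] -= 1
            diff += 1
    if diff != 0:
        raise SplitError(
            f"cannot stratify {n_traj} trajectories into {n_train_folds}/{n_test_folds} "
            "while keeping every state on both sides"
        )

    rng = np.random.default_rng(seed)
    partition_of_fold: dict[int, str] = {}
    for state in states:
        members = np.array(by_state[state])
        rng.shuffle(members)
        train_ids = set(members[: quotas[state]].tolist())
        for tid in members.tolist():
            tag = "train" if tid in train_ids else "test"
            partition_of_fold[fold_of_trajectory[tid]] = tag
    return FoldAssignment(
        fold_of_trajectory=fold_of_trajectory, partition_of_fold=partition_of_fold
    )


def load_manifest(path: Union[str, Path]) -> list[TrajectoryEntry]:
    """Load dataset entries from a manifest.

    CSV columns (or a JSON list of objects with the same keys):
    ``traj_id, state, topology, trajectory, mapping[, dt_ps]``.  Relative
    paths are taken relative to the manifest location.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    base = path.parent
    entries = []
    for row in rows:
        dt = row.get("dt_ps")
        dt = float(dt) if dt not in (None, "") and not pd.isna(dt) else None
        traj = Trajectory(
            base / str(row["topology"]),
            base / str(row["trajectory"]) if row.get("trajectory") else None,
            dt_ps=dt,
            name=str(row["traj_id"]),
        )
        entries.append(
            TrajectoryEntry(
                trajectory=traj,
                mapping=load_mapping(base / str(row["mapping"])),
                state=str(row["state"]),
                traj_id=int(row["traj_id"]),
            )
        )
    return entries
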