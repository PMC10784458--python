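"""Fixed-length pairwise-distance descriptors of receptor conformations.

A conformation is represented by the ordered vector of Euclidean distances
(in Å) between the side-chain geometric centers of configured residue
pairs.  "Geometric center" means the unweighted centroid of the side-chain
heavy atoms (backbone N/CA/C/O/OXT and all hydrogens excluded); glycine,
which has no side-chain heavy atom, falls back to its CA position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    DegenerateResidueError,
    FeaturizationError,
    GPCRStateError,
    MappingError,
)
from .generic_numbering import GenericLabel, ResidueMapping, parse_generic_label, resolve_residue
from .structure import ResidueRef, Structure, Trajectory, is_hydrogen

__all__ = [
    "PairList",
    "ConformationDescriptor",
    "sidechain_center",
    "pair_distance",
    "extract_descriptor",
    "TrajectoryFeaturizer",
    "descriptors_to_frame",
    "load_default_pairs",
]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

Pair = tuple[GenericLabel, GenericLabel]


def _pair_key(pair: Pair) -> frozenset:
    return frozenset(pair)


def format_pair(pair: Pair) -> str:
    return f"{pair[0]}:{pair[1]}"


@dataclass(frozen=True)
class PairList:
    """Ordered residue-pair configuration defining the descriptor layout."""

    pairs: tuple[Pair, ...]
    name: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for pair in self.pairs:
            key = _pair_key(pair)
            if len(key) < 2:
                raise MappingError(f"pair {format_pair(pair)} repeats a residue")
            if key in seen:
                raise MappingError(f"duplicate residue pair {format_pair(pair)} in pair list")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def labels(self) -> list[str]:
        """Per-component names, e.g. ``["5x62:6x37", ...]``."""
        return [format_pair(p) for p in self.pairs]

    def residues(self) -> list[GenericLabel]:
        """Distinct residue labels, in first-appearance order."""
        out: list[GenericLabel] = []
        for a, b in self.pairs:
            for lab in (a, b):
                if lab not in out:
                    out.append(lab)
        return out

    @classmethod
    def from_strings(cls, rows: Iterable[tuple[str, str]], name: str = "") -> "PairList":
        pairs = tuple((parse_generic_label(a), parse_generic_label(b)) for a, b in rows)
        return cls(pairs=pairs, name=name)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PairList":
        """Read a pair list file: one "labelA labelB" per line, "#" comments."""
        path = Path(path)
        rows: list[tuple[str, str]] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                fields = line.split()
                if len(fields) != 2:
                    raise MappingError(f"{path}:{lineno}: expected two labels, got {len(fields)}")
                rows.append((fields[0], fields[1]))
        return cls.from_strings(rows, name=path.name)

    def save(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for a, b in self.pairs:
                fh.write(f"{a} {b}\n")


def load_default_pairs() -> PairList:
    """The packaged default activation-pathway pair list."""
    ref = resources.files("gpcrstate.data") / "activation_pairs_default.txt"
    with resources.as_file(ref) as path:
        pl = PairList.load(path)
    return PairList(pairs=pl.pairs, name="activation-pathway-default")


@dataclass(frozen=True)
class ConformationDescriptor:
    """One frame's descriptor: distances in Å in pair-list order."""

    values: np.ndarray
    pair_labels: tuple[str, ...]
    frame_index: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != len(self.pair_labels):
            raise FeaturizationError(
                f"descriptor has {values.size} values for {len(self.pair_labels)} pairs"
            )
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise FeaturizationError("descriptor values must be finite and non-negative")
        if self.frame_index < 0:
            raise FeaturizationError("frame index must be >= 0")

    def __len__(self) -> int:
        return len(self.values)


def _sidechain_atoms(atoms) -> list:
    heavy = [a for a in atoms if not is_hydrogen(a)]
    return [a for a in heavy if a.name not in _BACKBONE]


def sidechain_center(structure: Structure, residue: ResidueRef) -> np.ndarray:
    """Unweighted centroid (Å) of a residue's side-chain heavy atoms.

    Glycine (or any residue whose only heavy atoms are backbone) falls back
    to the CA position; a residue with neither raises
    :class:`DegenerateResidueError`.
    """
    atoms = structure.residue_atoms(residue)
    if len(atoms) == 0:
        raise DegenerateResidueError(f"residue {residue} has no atoms")
    side = _sidechain_atoms(atoms)
    if side:
        return np.mean([a.position for a in side], axis=0)
    ca = [a for a in atoms if a.name == "CA" and not is_hydrogen(a)]
    if ca:
        return ca[0].position.astype(float).copy()
    raise DegenerateResidueError(
        f"residue {residue} has no side-chain heavy atoms and no CA fallback"
    )


def pair_distance(
    structure: Structure,
    mapping: ResidueMapping,
    pair: Union[Pair, tuple[str, str]],
) -> float:
    """Distance (Å) between the side-chain centers of a residue pair."""
    a, b = (parse_generic_label(x) for x in pair)
    try:
        ref_a = resolve_residue(mapping, a, structure)
        ref_b = resolve_residue(mapping, b, structure)
        center_a = sidechain_center(structure, ref_a)
        center_b = sidechain_center(structure, ref_b)
    except GPCRStateError as exc:
        raise FeaturizationError(f"pair {a}:{b}: {exc}") from exc
    return float(np.linalg.norm(center_a - center_b))


def extract_descriptor(
    structure: Structure,
    mapping: ResidueMapping,
    pairs: PairList,
    frame_index: int = 0,
) -> ConformationDescriptor:
    """Featurize one structure into its pair-distance vector.

    All unresolvable pairs are collected and reported together rather than
    failing on the first.
    """
    centers: dict[GenericLabel, np.ndarray] = {}
    failures: dict[GenericLabel, str] = {}
    for label in pairs.residues():
        try:
            ref = resolve_residue(mapping, label, structure)
            centers[label] = sidechain_center(structure, ref)
        except GPCRStateError as exc:
            failures[label] = str(exc)
    if failures:
        bad = [format_pair(p) for p in pairs if p[0] in failures or p[1] in failures]
        details = "; ".join(f"{lab}: {msg}" for lab, msg in failures.items())
        raise FeaturizationError(
            f"cannot featurize {structure.name!r}: unresolvable pairs {bad} ({details})"
        )
    values = np.array(
        [np.linalg.norm(centers[a] - centers[b]) for a, b in pairs], dtype=float
    )
    return ConformationDescriptor(
        values=values,
        pair_labels=tuple(pairs.labels),
        frame_index=frame_index,
        source=structure.name,
    )


class TrajectoryFeaturizer:
    """Precompiled per-frame featurizer for one trajectory.

    Residue lookups and atom selections are done once at construction;
    per-frame work is pure NumPy on the frame's coordinate array, which
    keeps whole-trajectory featurization streaming and fast.
    """

    def __init__(self, trajectory: Trajectory, mapping: ResidueMapping, pairs: PairList):
        self.trajectory = trajectory
        self.pairs = pairs
        structure = Structure(trajectory.universe, name=trajectory.name)
        residues = pairs.residues()
        index_of: dict[GenericLabel, int] = {}
        atom_indices: list[np.ndarray] = []
        failures: dict[GenericLabel, str] = {}
        for label in residues:
            try:
                ref = resolve_residue(mapping, label, structure)
                atoms = structure.residue_atoms(ref)
                side = _sidechain_atoms(atoms)
                if not side:
                    side = [a for a in atoms if a.name == "CA" and not is_hydrogen(a)]
                if not side:
                    raise DegenerateResidueError(
                        f"residue {ref} has no side-chain heavy atoms and no CA fallback"
                    )
                index_of[label] = len(atom_indices)
                atom_indices.append(np.array([a.index for a in side], dtype=np.intp))
            except GPCRStateError as exc:
                failures[label] = str(exc)
        if failures:
            bad = [format_pair(p) for p in pairs if p[0] in failures or p[1] in failures]
            details = "; ".join(f"{lab}: {msg}" for lab, msg in failures.items())
            raise FeaturizationError(
                f"cannot featurize trajectory {trajectory.name!r}: "
                f"unresolvable pairs {bad} ({details})"
            )
        self._atom_indices = atom_indices
        self._pair_i = np.array([index_of[a] for a, _ in pairs], dtype=np.intp)
        self._pair_j = np.array([index_of[b] for _, b in pairs], dtype=np.intp)

    def descriptor_from_positions(self, positions: np.ndarray) -> np.ndarray:
        """Distances (Å) for one frame's full coordinate array."""
        centers = np.stack(
            [positions[idx].mean(axis=0) for idx in self._atom_indices]
        ).astype(float)
        delta = centers[self._pair_i] - centers[self._pair_j]
        return np.linalg.norm(delta, axis=1)

    def featurize_frames(self, frames: Optional[np.ndarray] = None) -> np.ndarray:
        """Descriptor matrix (n_frames, n_pairs) over selected frame indices."""
        rows = []
        for i, positions in self.trajectory.iter_positions(frames):
            try:
                rows.append(self.descriptor_from_positions(positions))
            except Exception as exc:  # attach the frame index to any failure
                raise FeaturizationError(
                    f"trajectory {self.trajectory.name!r} frame {i}: {exc}"
                ) from exc
        return np.asarray(rows, dtype=float)


def descriptors_to_frame(
    matrix: np.ndarray,
    pairs: PairList,
    frame_indices: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Tabulate a descriptor matrix: frame-index column + one column per pair."""
    matrix = np.asarray(matrix, dtype=float)
    if frame_indices is None:
        frame_indices = np.arange(matrix.shape[0])
    df = pd.DataFrame(matrix, columns=pairs.labels)
    df.insert(0, "frame", np.asarray(frame_indices, dtype=int))
    return df
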