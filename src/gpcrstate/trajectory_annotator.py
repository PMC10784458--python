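"""Whole-trajectory scoring, frame/trajectory classification, site RMSD.

Frames are called active when their raw score exceeds the frame threshold
θ (default 0.375, strict inequality); a trajectory is called active when
its active-frame ratio exceeds the trajectory threshold δ (strict again).
Smoothing exists for reporting only and never feeds classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from MDAnalysis.analysis import rms as mda_rms
from MDAnalysis.lib.distances import distance_array

from .descriptor import PairList, TrajectoryFeaturizer
from .errors import BindingSiteError, GPCRStateError, TrajectoryError
from .generic_numbering import ResidueMapping, resolve_residue
from .state_model import NEGATIVE_CLASS, POSITIVE_CLASS, StateModel
from .structure import Structure, Trajectory, is_hydrogen

__all__ = [
    "DEFAULT_FRAME_THRESHOLD",
    "ScoreSeries",
    "TrajectoryVerdict",
    "SiteResidue",
    "BindingSiteDefinition",
    "score_trajectory",
    "smooth",
    "classify_frames",
    "classify_trajectory",
    "define_binding_site",
    "binding_site_rmsd",
    "compare_rmsd_groups",
]

DEFAULT_FRAME_THRESHOLD = 0.375


@dataclass(frozen=True)
class ScoreSeries:
    """Per-frame active-state scores, with an optional smoothed companion."""

    times: np.ndarray
    scores: np.ndarray
    window: int = 1
    smoothed: np.ndarray = None  # filled from scores when omitted

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        scores = np.asarray(self.scores, dtype=float)
        smoothed = self.smoothed if self.smoothed is not None else scores
        smoothed = np.asarray(smoothed, dtype=float)
        if not (len(times) == len(scores) == len(smoothed)):
            raise TrajectoryError("times, scores and smoothed series must have equal length")
        if len(scores) and (scores.min() < 0 or scores.max() > 1):
            raise TrajectoryError("scores must lie in [0, 1]")
        if self.window < 1:
            raise TrajectoryError("smoothing window must be >= 1")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "smoothed", smoothed)

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ps": self.times, "score": self.scores, "smoothed": self.smoothed}
        )


@dataclass(frozen=True)
class TrajectoryVerdict:
    """Trajectory-level classification from the active-frame ratio."""

    active_ratio: float
    delta: float
    verdict: str
    theta: Optional[float] = None
    n_frames: int = 0

    def as_dict(self) -> dict:
        return {
            "active_ratio": self.active_ratio,
            "delta": self.delta,
            "theta": self.theta,
            "verdict": self.verdict,
            "n_frames": self.n_frames,
        }


def score_trajectory(
    model: StateModel,
    trajectory: Trajectory,
    mapping: ResidueMapping,
    pairs: Optional[PairList] = None,
    chunk_size: int = 256,
) -> ScoreSeries:
    """Score every frame of a trajectory in file order, streaming.

    ``pairs`` defaults to the model's own pair layout reparsed from its
    stored labels; passing a list with a different order raises.
    """
    if pairs is None:
        pairs = PairList.from_strings(
            [tuple(lab.split(":")) for lab in model.pair_labels], name="model"
        )
    if tuple(pairs.labels) != tuple(model.pair_labels):
        model._check_layout(pairs.labels)  # raises with a precise message
    featurizer = TrajectoryFeaturizer(trajectory, mapping, pairs)
    dt = trajectory.dt_ps
    scores: list[np.ndarray] = []
    chunk: list[np.ndarray] = []
    for i, positions in trajectory.iter_positions():
        try:
            chunk.append(featurizer.descriptor_from_positions(positions))
        except GPCRStateError as exc:
            raise TrajectoryError(f"frame {i}: {exc}") from exc
        if len(chunk) >= chunk_size:
            scores.append(model.score_matrix(np.asarray(chunk)))
            chunk = []
    if chunk:
        scores.append(model.score_matrix(np.asarray(chunk)))
    all_scores = np.concatenate(scores) if scores else np.empty(0)
    times = np.arange(len(all_scores)) * dt
    return ScoreSeries(times=times, scores=all_scores, window=1, smoothed=all_scores)


def smooth(series: ScoreSeries, window: int = 5) -> ScoreSeries:
    """Centered moving average over ``window`` frames; truncated at edges.

    The window must be odd so the average is centered; the raw scores are
    kept untouched alongside the smoothed curve.
    """
    if window < 1:
        raise TrajectoryError("smoothing window must be >= 1")
    if window % 2 == 0:
        raise TrajectoryError(f"smoothing window must be odd, got {window}")
    smoothed = (
        pd.Series(series.scores)
        .rolling(window=window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return ScoreSeries(times=series.times, scores=series.scores, window=window, smoothed=smoothed)


def classify_frames(series: ScoreSeries, theta: float = DEFAULT_FRAME_THRESHOLD) -> np.ndarray:
    """Per-frame labels: active iff raw score > θ (strict; smoothing ignored)."""
    if not 0.0 <= theta <= 1.0:
        raise TrajectoryError(f"frame threshold must be in [0, 1], got {theta}")
    return np.where(series.scores > theta, POSITIVE_CLASS, NEGATIVE_CLASS).astype(object)


def classify_trajectory(
    frame_labels: Sequence[str],
    delta: float,
    theta: Optional[float] = None,
) -> TrajectoryVerdict:
    """Trajectory verdict: active iff the active-frame ratio exceeds δ (strict)."""
    labels = np.asarray(frame_labels, dtype=object)
    if len(labels) == 0:
        raise TrajectoryError("cannot classify a trajectory with no frames")
    if not 0.0 <= delta <= 1.0:
        raise TrajectoryError(f"trajectory threshold must be in [0, 1], got {delta}")
    ratio = float(np.mean(labels == POSITIVE_CLASS))
    verdict = POSITIVE_CLASS if ratio > delta else NEGATIVE_CLASS
    return TrajectoryVerdict(
        active_ratio=ratio, delta=delta, verdict=verdict, theta=theta, n_frames=len(labels)
    )


# ---------------------------------------------------------------------------
# binding sites


@dataclass(frozen=True)
class SiteResidue:
    """A site member: concrete residue plus its generic label when known."""

    chain: str
    resnum: int
    label: Optional[str] = None

    @property
    def key(self) -> str:
        return self.label if self.label is not None else f"{self.chain}:{self.resnum}"


@dataclass
class BindingSiteDefinition:
    """A residue set within a distance cutoff of a reference entity."""

    kind: str  # "ligand" or "g-protein"
    cutoff: float
    references: list[str]
    residues: list[SiteResidue]

    def __post_init__(self) -> None:
        if self.kind not in ("ligand", "g-protein"):
            raise BindingSiteError(f"site kind must be 'ligand' or 'g-protein', got {self.kind!r}")
        if not self.residues:
            raise BindingSiteError("empty site: no residue lies within the cutoff")

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "kind": self.kind,
            "cutoff": self.cutoff,
            "references": self.references,
            "residues": [
                {"chain": r.chain, "resnum": r.resnum, "label": r.label} for r in self.residues
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "BindingSiteDefinition":
        payload = json.loads(Path(path).read_text())
        return cls(
            kind=payload["kind"],
            cutoff=float(payload["cutoff"]),
            references=list(payload["references"]),
            residues=[SiteResidue(r["chain"], int(r["resnum"]), r.get("label")) for r in payload["residues"]],
        )


def define_binding_site(
    references: Sequence[tuple[Structure, str]],
    cutoff: float = 8.0,
    kind: str = "ligand",
    mappings: Optional[Sequence[Optional[ResidueMapping]]] = None,
) -> BindingSiteDefinition:
    """Union of receptor residues within ``cutoff`` of a reference entity.

    ``references`` is a sequence of (structure, entity selection string);
    the selection picks the ligand or Gα-helix atoms inside each structure.
    A residue joins the site when any of its heavy atoms lies strictly
    within the cutoff of any entity heavy atom in at least one reference.
    Residues are reported by generic label where the matching mapping (one
    per reference, optional) covers them, by chain:resnum otherwise.
    """
    if mappings is None:
        mappings = [None] * len(references)
    if len(mappings) != len(references):
        raise BindingSiteError("one mapping (or None) is required per reference structure")
    members: dict[str, SiteResidue] = {}
    for (structure, selection), mapping in zip(references, mappings):
        entity = structure.universe.select_atoms(selection)
        entity_heavy = [a for a in entity if not is_hydrogen(a)]
        if not entity_heavy:
            raise BindingSiteError(
                f"entity selection {selection!r} matches nothing in {structure.name!r}"
            )
        entity_pos = np.array([a.position for a in entity_heavy])
        entity_idx = set(int(a.index) for a in entity)
        receptor = structure.universe.select_atoms("protein")
        receptor_heavy = [
            a for a in receptor if not is_hydrogen(a) and int(a.index) not in entity_idx
        ]
        if not receptor_heavy:
            raise BindingSiteError(f"no receptor atoms in {structure.name!r}")
        rec_pos = np.array([a.position for a in receptor_heavy])
        dmat = distance_array(rec_pos, entity_pos)
        near = dmat.min(axis=1) < cutoff  # strictly within
        reverse = mapping.reverse() if mapping is not None else {}
        chain_ids = structure._chain_ids(structure.universe.atoms)
        for atom, is_near in zip(receptor_heavy, near):
            if not is_near:
                continue
            chain = str(chain_ids[atom.index])
            resnum = int(atom.resnum)
            label = reverse.get((chain, resnum)) or reverse.get((None, resnum))
            res = SiteResidue(chain=chain, resnum=resnum, label=str(label) if label else None)
            members.setdefault(res.key, res)
    if not members:
        raise BindingSiteError(f"empty site: no residue within {cutoff} Å of the entity")
    residues = sorted(members.values(), key=lambda r: (r.chain, r.resnum))
    return BindingSiteDefinition(
        kind=kind,
        cutoff=cutoff,
        references=[s.name for s, _ in references],
        residues=residues,
    )


def _site_ca_coords(
    structure: Structure,
    site: BindingSiteDefinition,
    mapping: Optional[ResidueMapping],
) -> np.ndarray:
    coords = []
    missing = []
    for res in site.residues:
        ref = None
        if res.label is not None and mapping is not None and res.label in mapping:
            try:
                ref = resolve_residue(mapping, res.label, structure)
            except GPCRStateError:
                ref = None
        if ref is None:
            ref = structure.find_residue(res.chain, res.resnum)
        if ref is None:
            missing.append(res.key)
            continue
        atoms = structure.residue_atoms(ref)
        ca = [a for a in atoms if a.name == "CA" and not is_hydrogen(a)]
        if not ca:
            missing.append(res.key)
            continue
        coords.append(ca[0].position)
    if missing:
        raise BindingSiteError(
            f"site residues unresolvable in {structure.name!r}: {missing}"
        )
    return np.asarray(coords, dtype=float)


def binding_site_rmsd(
    frame: Structure,
    reference: Structure,
    site: BindingSiteDefinition,
    frame_mapping: Optional[ResidueMapping] = None,
    reference_mapping: Optional[ResidueMapping] = None,
) -> float:
    """Cα RMSD (Å) over the site residues after least-squares superposition."""
    a = _site_ca_coords(frame, site, frame_mapping)
    b = _site_ca_coords(reference, site, reference_mapping)
    if a.shape != b.shape:
        raise BindingSiteError(
            f"site resolves to {len(a)} residues in {frame.name!r} but "
            f"{len(b)} in {reference.name!r}"
        )
    return float(mda_rms.rmsd(a, b, center=True, superposition=True))


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Mann-Whitney comparison of two RMSD groups."""

    p_value: float
    u_statistic: float
    median_a: float
    median_b: float


def compare_rmsd_groups(
    active_rmsds: Sequence[float],
    inactive_rmsds: Sequence[float],
) -> GroupComparison:
    """Mann-Whitney U (two-sided) p-value plus group medians."""
    a = np.asarray(active_rmsds, dtype=float)
    b = np.asarray(inactive_rmsds, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise BindingSiteError("both RMSD groups must be non-empty")
    result = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        p_value=float(result.pvalue),
        u_statistic=float(result.statistic),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )
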