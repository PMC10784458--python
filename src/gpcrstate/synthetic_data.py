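"""Synthetic receptor-like ensembles with known ground truth.

The generator builds a roster of pseudo-residues (1-5 dummy heavy atoms
each, including glycines that exercise the CA fallback) covering a pair
list's labels, places them so that every pair with exactly one helix-6
member separates the two state templates by a configurable margin, and
interpolates/noises the templates into trajectories written as standard
PDB + DCD files with a mapping table and a ground-truth CSV.  Everything
is seeded and reproducible at the descriptor level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

import MDAnalysis as mda

from .descriptor import PairList, format_pair
from .errors import GPCRStateError
from .generic_numbering import GenericLabel
from .structure import Trajectory

__all__ = [
    "PseudoResidue",
    "ConformationTemplate",
    "EnsembleSpec",
    "EnsembleFiles",
    "make_templates",
    "generate_ensemble",
]

# Atom layouts: (resname, atom names, offsets from the residue center).
# Side-chain heavy atoms are placed symmetrically so their centroid is the
# residue center exactly; GLY has CA at the center (the fallback rule);
# SER carries a hydrogen that must be excluded from the centroid.
_LAYOUTS: list[tuple[str, tuple[str, ...], np.ndarray]] = [
    (
        "GLY",
        ("N", "CA", "C", "O"),
        np.array([[1.2, 0.0, 0.8], [0.0, 0.0, 0.0], [-1.2, 0.0, 0.8], [-1.4, 0.0, 2.0]]),
    ),
    (
        "ALA",
        ("N", "CA", "C", "O", "CB"),
        np.array(
            [[-1.2, 0.0, 1.0], [0.0, 0.0, 1.0], [1.2, 0.0, 1.0], [1.8, 0.0, 2.0], [0.0, 0.0, 0.0]]
        ),
    ),
    (
        "SER",
        ("N", "CA", "C", "O", "CB", "OG", "HG"),
        np.array(
            [
                [-1.2, 0.0, 1.0], [0.0, 0.0, 1.0], [1.2, 0.0, 1.0], [1.8, 0.0, 2.0],
                [0.6, 0.0, 0.0], [-0.6, 0.0, 0.0], [0.0, 0.0, 2.5],
            ]
        ),
    ),
    (
        "LEU",
        ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"),
        np.array(
            [
                [-1.2, 0.0, 1.0], [0.0, 0.0, 1.0], [1.2, 0.0, 1.0], [1.8, 0.0, 2.0],
                [0.5, 0.0, 0.0], [-0.5, 0.0, 0.0], [0.0, 0.5, 0.0], [0.0, -0.5, 0.0],
            ]
        ),
    ),
    (
        "LYS",
        ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"),
        np.array(
            [
                [-1.2, 0.0, 1.0], [0.0, 0.0, 1.0], [1.2, 0.0, 1.0], [1.8, 0.0, 2.0],
                [0.5, 0.0, 0.0], [-0.5, 0.0, 0.0], [0.0, 0.5, 0.0], [0.0, -0.5, 0.0],
                [0.0, 0.0, 0.0],
            ]
        ),
    ),
]

_HELIX6_X_ACTIVE = 6.0
_SEPARATION_MARGIN = 0.25


@dataclass(frozen=True)
class PseudoResidue:
    """One synthetic residue: identity plus its rigid atom layout."""

    label: GenericLabel
    resnum: int
    resname: str
    atom_names: tuple[str, ...]
    offsets: np.ndarray  # (n_atoms, 3), relative to the residue center


@dataclass(frozen=True)
class ConformationTemplate:
    """A noise-free conformation: a roster and one center per residue."""

    roster: tuple[PseudoResidue, ...]
    centers: np.ndarray  # (n_residues, 3)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atom_names) for r in self.roster)

    def atom_coordinates(self, centers: Optional[np.ndarray] = None) -> np.ndarray:
        """Expand residue centers into a full (n_atoms, 3) coordinate array."""
        centers = self.centers if centers is None else centers
        return np.vstack([centers[i] + r.offsets for i, r in enumerate(self.roster)])

    def pair_distances(self, pairs: PairList) -> np.ndarray:
        """Exact descriptor of this template (centers are exact by layout)."""
        index = {r.label: i for i, r in enumerate(self.roster)}
        return np.array(
            [np.linalg.norm(self.centers[index[a]] - self.centers[index[b]]) for a, b in pairs]
        )


def _build_roster(pairs: PairList) -> tuple[PseudoResidue, ...]:
    labels = sorted(pairs.residues())
    roster = []
    for i, label in enumerate(labels):
        resname, names, offsets = _LAYOUTS[i % len(_LAYOUTS)]
        roster.append(
            PseudoResidue(
                label=label, resnum=i + 1, resname=resname, atom_names=names, offsets=offsets
            )
        )
    return tuple(roster)


def make_templates(
    pairs: PairList, separation: float
) -> tuple[ConformationTemplate, ConformationTemplate]:
    """Build active/inactive templates whose helix-6 pairs differ by >= separation.

    Pairs with exactly one helix-6 member are the discriminative ones: in
    the active template they sit near 6 Å, in the inactive template near
    6 Å + separation (imitating the TM6 outward swing).  All other pairs
    are identical between the two templates.
    """
    if separation <= 0:
        raise GPCRStateError("separation must be positive")
    roster = _build_roster(pairs)
    centers_active = np.zeros((len(roster), 3))
    for i, residue in enumerate(roster):
        centers_active[i] = (0.0, 0.15 * (i % 6), 0.15 * (i // 6))
        if residue.label.segment == 6:
            centers_active[i, 0] = _HELIX6_X_ACTIVE
    centers_inactive = centers_active.copy()
    shift = separation + _SEPARATION_MARGIN
    for i, residue in enumerate(roster):
        if residue.label.segment == 6:
            centers_inactive[i, 0] += shift

    active = ConformationTemplate(roster=roster, centers=centers_active)
    inactive = ConformationTemplate(roster=roster, centers=centers_inactive)

    # Construction guard: verify the advertised geometry actually holds.
    d_act = active.pair_distances(pairs)
    d_inact = inactive.pair_distances(pairs)
    for k, (a, b) in enumerate(pairs):
        n_h6 = (a.segment == 6) + (b.segment == 6)
        if n_h6 == 1 and abs(d_inact[k] - d_act[k]) < separation:
            raise GPCRStateError(
                f"template construction failed for pair {format_pair((a, b))}: "
                f"|{d_inact[k]:.3f} - {d_act[k]:.3f}| < {separation}"
            )
    if np.allclose(d_act, d_inact):
        raise GPCRStateError("templates have identical descriptors; no helix-6 pair in list")
    return active, inactive


@dataclass
class EnsembleSpec:
    """Recipe for one synthetic trajectory.

    ``lambdas`` is the per-frame state coordinate (1 = active template,
    0 = inactive template); its length is the frame count.  The ground
    truth labels a frame active when its lambda is >= 0.5.
    """

    active: ConformationTemplate
    inactive: ConformationTemplate
    lambdas: np.ndarray
    sigma: float
    seed: int
    frame_interval_ps: float = 100.0

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if tuple(r.label for r in self.active.roster) != tuple(r.label for r in self.inactive.roster):
            raise GPCRStateError("active and inactive templates must share one residue roster")
        if self.lambdas.ndim != 1 or len(self.lambdas) == 0:
            raise GPCRStateError("lambda schedule must be a non-empty 1-D array")
        if np.any((self.lambdas < 0) | (self.lambdas > 1)):
            raise GPCRStateError("lambda values must lie in [0, 1]")
        if self.sigma < 0:
            raise GPCRStateError("noise sigma must be >= 0")
        if self.frame_interval_ps <= 0:
            raise GPCRStateError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.lambdas)

    @classmethod
    def constant(
        cls,
        active: ConformationTemplate,
        inactive: ConformationTemplate,
        state: str,
        n_frames: int,
        sigma: float,
        seed: int,
        frame_interval_ps: float = 100.0,
    ) -> "EnsembleSpec":
        lam = 1.0 if state == "active" else 0.0
        return cls(
            active=active,
            inactive=inactive,
            lambdas=np.full(n_frames, lam),
            sigma=sigma,
            seed=seed,
            frame_interval_ps=frame_interval_ps,
        )


@dataclass(frozen=True)
class EnsembleFiles:
    """Paths of one generated ensemble plus how to read it back."""

    topology: Path
    trajectory: Path
    mapping: Path
    ground_truth: Path
    dt_ps: float
    n_frames: int

    def open(self, name: str = "") -> Trajectory:
        return Trajectory(self.topology, self.trajectory, dt_ps=self.dt_ps, name=name or self.trajectory.stem)

    def truth(self) -> pd.DataFrame:
        return pd.read_csv(self.ground_truth)


def _element_of(name: str) -> str:
    return name.lstrip("0123456789")[0]


def _build_universe(template: ConformationTemplate) -> "mda.Universe":
    roster = template.roster
    n_atoms = template.n_atoms
    resindex = np.concatenate(
        [np.full(len(r.atom_names), i, dtype=int) for i, r in enumerate(roster)]
    )
    u = mda.Universe.empty(
        n_atoms=n_atoms,
        n_residues=len(roster),
        n_segments=1,
        atom_resindex=resindex,
        residue_segindex=np.zeros(len(roster), dtype=int),
        trajectory=True,
    )
    names = [n for r in roster for n in r.atom_names]
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("elements", [_element_of(n) for n in names])
    u.add_TopologyAttr("resnames", [r.resname for r in roster])
    u.add_TopologyAttr("resids", [r.resnum for r in roster])
    u.add_TopologyAttr("chainIDs", ["A"] * n_atoms)
    u.add_TopologyAttr("segids", ["A"])
    u.add_TopologyAttr("occupancies", np.ones(n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(n_atoms))
    u.add_TopologyAttr("altLocs", [""] * n_atoms)
    u.atoms.positions = template.atom_coordinates()
    return u


def generate_ensemble(
    spec: EnsembleSpec,
    outdir: Union[str, Path],
    basename: str = "ensemble",
) -> EnsembleFiles:
    """Write one synthetic ensemble: PDB topology, DCD trajectory, mapping, truth.

    Frame coordinates are ``lambda * active + (1 - lambda) * inactive``
    plus i.i.d. Gaussian noise of width sigma on every atom, drawn from a
    generator seeded with ``spec.seed`` — the same spec always produces
    descriptor-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    top_path = outdir / f"{basename}_top.pdb"
    traj_path = outdir / f"{basename}.dcd"
    map_path = outdir / f"{basename}_mapping.txt"
    truth_path = outdir / f"{basename}_truth.csv"

    u = _build_universe(spec.active)
    u.atoms.write(str(top_path))

    rng = np.random.default_rng(spec.seed)
    n_atoms = spec.active.n_atoms
    with mda.Writer(str(traj_path), n_atoms=n_atoms) as writer:
        for lam in spec.lambdas:
            centers = lam * spec.active.centers + (1.0 - lam) * spec.inactive.centers
            coords = spec.active.atom_coordinates(centers)
            if spec.sigma > 0:
                coords = coords + rng.normal(0.0, spec.sigma, size=coords.shape)
            u.atoms.positions = coords
            writer.write(u.atoms)

    with open(map_path, "w") as fh:
        fh.write("# generic_label resnum chain resname\n")
        for r in spec.active.roster:
            fh.write(f"{r.label} {r.resnum} A {r.resname}\n")

    states = np.where(spec.lambdas >= 0.5, "active", "inactive")
    truth = pd.DataFrame(
        {
            "frame": np.arange(spec.n_frames),
            "time_ps": np.arange(spec.n_frames) * spec.frame_interval_ps,
            "lambda": spec.lambdas,
            "state": states,
        }
    )
    truth.to_csv(truth_path, index=False)

    return EnsembleFiles(
        topology=top_path,
        trajectory=traj_path,
        mapping=map_path,
        ground_truth=truth_path,
        dt_ps=spec.frame_interval_ps,
        n_frames=spec.n_frames,
    )
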