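"""Thin wrappers over MDAnalysis for structures and trajectories.

These wrappers isolate the rest of the package from MDAnalysis topology
details: residue lookup by (chain, author residue number, insertion code),
alternate-location resolution, hydrogen detection, and frame access with an
explicit time step for trajectory formats that do not store times.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np

import MDAnalysis as mda

__all__ = ["ResidueRef", "Structure", "Trajectory", "is_hydrogen", "resolve_altlocs"]

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def is_hydrogen(atom) -> bool:
    """True if the atom is a hydrogen, by element when present, else by name."""
    element = getattr(atom, "element", "") or ""
    if element:
        return element.upper() == "H"
    name = atom.name.lstrip("0123456789")
    return name[:1].upper() == "H"


def resolve_altlocs(atoms: "mda.AtomGroup") -> "mda.AtomGroup":
    """Collapse alternate locations: one atom per name, highest occupancy.

    Ties are broken toward the lexicographically smallest altloc ("A"
    before "B"), matching the usual deposition convention.
    """
    if len(atoms) == 0 or not hasattr(atoms, "altLocs"):
        return atoms
    if all(a == "" or a == " " for a in atoms.altLocs):
        return atoms
    best: dict[str, int] = {}
    occupancies = getattr(atoms, "occupancies", np.ones(len(atoms)))
    for i, atom in enumerate(atoms):
        name = atom.name
        if name not in best:
            best[name] = i
            continue
        j = best[name]
        key_i = (-float(occupancies[i]), str(atoms.altLocs[i]))
        key_j = (-float(occupancies[j]), str(atoms.altLocs[j]))
        if key_i < key_j:
            best[name] = i
    idx = sorted(best.values())
    return atoms[idx]


@dataclass(frozen=True)
class ResidueRef:
    """Reference to one residue of a structure, by author identifiers."""

    chain: str
    resnum: int
    resname: str
    icode: str = ""

    def __str__(self) -> str:
        icode = self.icode.strip()
        return f"{self.chain}/{self.resname}{self.resnum}{icode}"


class Structure:
    """A single-conformation view of a coordinate file (or trajectory frame)."""

    def __init__(self, universe: "mda.Universe", name: str = "", frame: Optional[int] = None):
        self.universe = universe
        self.name = name or getattr(universe, "filename", "") or "structure"
        self._frame = frame

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "Structure":
        """Load a structure from a PDB file."""
        path = Path(path)
        universe = mda.Universe(str(path))
        return cls(universe, name=path.name)

    @property
    def atoms(self) -> "mda.AtomGroup":
        self._activate_frame()
        return self.universe.atoms

    def _activate_frame(self) -> None:
        if self._frame is not None and self.universe.trajectory.frame != self._frame:
            self.universe.trajectory[self._frame]

    def _chain_ids(self, atoms) -> np.ndarray:
        if hasattr(atoms, "chainIDs"):
            return np.asarray(atoms.chainIDs)
        return np.asarray(atoms.segids)

    def protein_chains(self) -> set[str]:
        """Chain identifiers that carry protein atoms."""
        protein = self.universe.select_atoms("protein")
        return set(self._chain_ids(protein))

    def find_residue(self, chain: str, resnum: int, icode: str = "") -> Optional[ResidueRef]:
        """Locate a residue by chain and author number; None if absent.

        If the file distinguishes residues by insertion code, the blank
        icode (or the requested one) must match exactly.
        """
        atoms = self.universe.atoms
        mask = (self._chain_ids(atoms) == chain) & (atoms.resnums == resnum)
        if hasattr(atoms, "icodes"):
            mask &= np.char.strip(atoms.icodes.astype(str)) == icode.strip()
        if not mask.any():
            return None
        sub = atoms[mask]
        return ResidueRef(
            chain=chain,
            resnum=resnum,
            resname=str(sub.resnames[0]),
            icode=icode,
        )

    def residue_atoms(self, ref: ResidueRef) -> "mda.AtomGroup":
        """All atoms of the referenced residue, altlocs resolved."""
        self._activate_frame()
        atoms = self.universe.atoms
        mask = (self._chain_ids(atoms) == ref.chain) & (atoms.resnums == ref.resnum)
        if hasattr(atoms, "icodes"):
            mask &= np.char.strip(atoms.icodes.astype(str)) == ref.icode.strip()
        return resolve_altlocs(atoms[mask])


class Trajectory:
    """A topology + coordinate series, with an explicit frame time step.

    ``dt_ps`` overrides the time step recorded in the file; trajectory
    formats routinely lose the physical time base, so callers generating
    or documenting their data pass it explicitly.
    """

    def __init__(
        self,
        topology: Union[str, Path],
        trajectory: Optional[Union[str, Path, Sequence[Union[str, Path]]]] = None,
        dt_ps: Optional[float] = None,
        name: str = "",
    ):
        kwargs = {}
        if dt_ps is not None:
            kwargs["dt"] = float(dt_ps)
        if trajectory is None:
            self.universe = mda.Universe(str(topology), **kwargs)
            self.name = name or Path(topology).name
        else:
            if isinstance(trajectory, (str, Path)):
                paths = [str(trajectory)]
            else:  # several files are chained into one continuous trajectory
                paths = [str(p) for p in trajectory]
            self.universe = mda.Universe(str(topology), paths, **kwargs)
            self.name = name or Path(paths[0]).name

    @property
    def n_frames(self) -> int:
        return len(self.universe.trajectory)

    @property
    def dt_ps(self) -> float:
        return float(self.universe.trajectory.dt)

    @property
    def n_atoms(self) -> int:
        return len(self.universe.atoms)

    def positions_at(self, frame: int) -> np.ndarray:
        """Coordinates (n_atoms, 3) of one frame, copied."""
        self.universe.trajectory[frame]
        return self.universe.atoms.positions.copy()

    def iter_positions(self, frames: Optional[np.ndarray] = None) -> Iterator[tuple[int, np.ndarray]]:
        """Stream (frame index, positions) without materializing all frames."""
        if frames is None:
            frames = np.arange(self.n_frames)
        for i in frames:
            yield int(i), self.positions_at(int(i))

    def structure_at(self, frame: int) -> Structure:
        """A Structure view pinned to one frame of this trajectory."""
        return Structure(self.universe, name=f"{self.name}[{frame}]", frame=frame)
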