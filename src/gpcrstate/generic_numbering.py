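"""Generic residue numbering: "SxNN" labels and label-to-residue mappings.

Class A GPCR residues are addressed with structure-aware generic labels of
the form ``"5x62"`` (helix 5, position 62), where position 50 of each helix
is the most conserved residue.  This module parses such labels and resolves
them to concrete residues of a loaded structure through a user-supplied
mapping table; no external numbering service is ever queried.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .errors import MappingError, MissingResidueError, LabelParseError, UnmappedLabelError
from .structure import ResidueRef, Structure

__all__ = [
    "GenericLabel",
    "MappingEntry",
    "ResidueMapping",
    "parse_generic_label",
    "load_mapping",
    "resolve_residue",
]

#: Both the plain "x" and the typographic multiplication sign are accepted.
_LABEL_RE = re.compile(r"^\s*(\d+)\s*[x×]\s*(\d+)\s*$")


@dataclass(frozen=True, order=True)
class GenericLabel:
    """A generic residue label: helix/segment index plus in-segment position.

    The canonical string form is ``"SxNN"`` (e.g. ``"5x62"``); the position
    is the raw number printed after the separator, so the x50 anchor of
    helix 3 is ``GenericLabel(3, 50)``.
    """

    segment: int
    position: int

    def __post_init__(self) -> None:
        if not 1 <= self.segment <= 8:
            raise LabelParseError(f"segment {self.segment!r} outside 1-8")
        if not 1 <= self.position <= 99:
            raise LabelParseError(f"position {self.position!r} outside 1-99")

    def __str__(self) -> str:
        return f"{self.segment}x{self.position}"

    def __repr__(self) -> str:  # compact, round-trippable through parse
        return f"GenericLabel({self.segment}, {self.position})"


def parse_generic_label(text: Union[str, GenericLabel]) -> GenericLabel:
    """Parse ``"5x62"`` / ``"5×62"`` into a :class:`GenericLabel`.

    Raises
    ------
    LabelParseError
        If the text has no separator, non-numeric parts, or a segment
        outside 1-8 / position outside 1-99.
    """
    if isinstance(text, GenericLabel):
        return text
    if not isinstance(text, str):
        raise LabelParseError(f"expected a label string, got {type(text).__name__}")
    m = _LABEL_RE.match(text)
    if m is None:
        raise LabelParseError(
            f"malformed generic label {text!r}: expected 'SxNN' with numeric "
            "segment and position separated by 'x' or '×'"
        )
    return GenericLabel(int(m.group(1)), int(m.group(2)))


@dataclass(frozen=True)
class MappingEntry:
    """One mapping row: where a generic label lives in a coordinate file."""

    resnum: int
    chain: Optional[str] = None
    resname: Optional[str] = None


@dataclass
class ResidueMapping:
    """Association from generic labels to (chain, author residue number).

    ``chain`` may be omitted per entry; resolution then requires the target
    structure to contain exactly one protein chain.
    """

    entries: dict[GenericLabel, MappingEntry] = field(default_factory=dict)
    receptor: str = ""
    source: str = "user"

    def __contains__(self, label: Union[str, GenericLabel]) -> bool:
        return parse_generic_label(label) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, label: Union[str, GenericLabel]) -> MappingEntry:
        key = parse_generic_label(label)
        try:
            return self.entries[key]
        except KeyError:
            raise UnmappedLabelError(f"label {key} not present in mapping {self.source!r}") from None

    def labels(self) -> list[GenericLabel]:
        return list(self.entries)

    def reverse(self) -> dict[tuple[Optional[str], int], GenericLabel]:
        """(chain, resnum) -> label lookup, used to report site residues."""
        return {(e.chain, e.resnum): lab for lab, e in self.entries.items()}

    @classmethod
    def from_items(
        cls,
        items: Iterable[tuple[Union[str, GenericLabel], MappingEntry]],
        receptor: str = "",
        source: str = "user",
    ) -> "ResidueMapping":
        entries: dict[GenericLabel, MappingEntry] = {}
        for label, entry in items:
            key = parse_generic_label(label)
            if key in entries:
                raise MappingError(f"duplicate generic label {key} in mapping {source!r}")
            entries[key] = entry
        return cls(entries=entries, receptor=receptor, source=source)


def load_mapping(path: Union[str, Path], receptor: str = "") -> ResidueMapping:
    """Load a mapping table from a plain-text file.

    Format: whitespace- or tab-separated columns
    ``generic_label  resnum  [chain]  [resname]``, one entry per line;
    ``#`` starts a comment.  Duplicate labels are rejected.
    """
    path = Path(path)
    items: list[tuple[GenericLabel, MappingEntry]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise MappingError(f"{path}:{lineno}: expected at least 2 columns, got {len(fields)}")
            try:
                label = parse_generic_label(fields[0])
            except LabelParseError as exc:
                raise MappingError(f"{path}:{lineno}: {exc}") from exc
            try:
                resnum = int(fields[1])
            except ValueError:
                raise MappingError(f"{path}:{lineno}: residue number {fields[1]!r} is not an integer") from None
            chain = fields[2] if len(fields) >= 3 else None
            resname = fields[3] if len(fields) >= 4 else None
            items.append((label, MappingEntry(resnum=resnum, chain=chain, resname=resname)))
    try:
        return ResidueMapping.from_items(items, receptor=receptor, source=str(path))
    except MappingError as exc:
        raise MappingError(f"{path}: {exc}") from exc


def resolve_residue(
    mapping: ResidueMapping,
    label: Union[str, GenericLabel],
    structure: Structure,
) -> ResidueRef:
    """Resolve a generic label to a residue of ``structure``.

    When the mapping entry carries no chain, the structure must contain
    exactly one protein chain, which is then used implicitly.

    Raises
    ------
    UnmappedLabelError
        If the label is absent from the mapping.
    MissingResidueError
        If the mapped (chain, residue number) does not exist in the
        structure or has no atoms.
    """
    key = parse_generic_label(label)
    entry = mapping[key]
    chain = entry.chain
    if chain is None:
        chains = structure.protein_chains()
        if len(chains) != 1:
            raise MissingResidueError(
                f"label {key}: mapping has no chain column and structure "
                f"{structure.name!r} has {len(chains)} protein chains {sorted(chains)}; "
                "an explicit chain is required"
            )
        chain = next(iter(chains))
    ref = structure.find_residue(chain, entry.resnum)
    if ref is None:
        raise MissingResidueError(
            f"label {key}: residue {entry.resnum} on chain {chain!r} not found in "
            f"structure {structure.name!r}"
        )
    return ref
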