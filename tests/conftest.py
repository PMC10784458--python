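"""Shared fixtures: toy PDB structures and seeded synthetic ensembles."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from gpcrstate import (
    FrameSamplingPlan,
    PairList,
    TrajectoryEntry,
    assign_folds,
    build_dataset,
    load_default_pairs,
    load_mapping,
    train,
)
from gpcrstate.synthetic_data import EnsembleSpec, generate_ensemble, make_templates

# ---------------------------------------------------------------------------
# raw PDB construction (full control over names/altlocs for edge cases)

_PDB_ATOM = (
    "{record:<6}{serial:>5} {name:<4}{altloc:1}{resname:<3} {chain:1}"
    "{resnum:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2}\n"
)


def write_pdb(path: Path, atoms: list[dict]) -> Path:
    """Write a PDB from dicts: name, resname, chain, resnum, xyz + optionals."""
    with open(path, "w") as fh:
        for i, a in enumerate(atoms, start=1):
            name = a["name"]
            fh.write(
                _PDB_ATOM.format(
                    record=a.get("record", "ATOM"),
                    serial=i,
                    name=name if len(name) >= 4 else f" {name}",
                    altloc=a.get("altloc", " "),
                    resname=a["resname"],
                    chain=a.get("chain", "A"),
                    resnum=a["resnum"],
                    icode=a.get("icode", " "),
                    x=a["xyz"][0],
                    y=a["xyz"][1],
                    z=a["xyz"][2],
                    occ=a.get("occ", 1.0),
                    b=0.0,
                    element=a.get("element", name.lstrip("0123456789")[0]),
                )
            )
        fh.write("END\n")
    return path


@pytest.fixture
def pdb_writer(tmp_path):
    def _write(atoms, filename="toy.pdb"):
        return write_pdb(tmp_path / filename, atoms)

    return _write


# ---------------------------------------------------------------------------
# pair lists and templates

@pytest.fixture(scope="session")
def default_pairs() -> PairList:
    return load_default_pairs()


@pytest.fixture(scope="session")
def small_pairs() -> PairList:
    return PairList.from_strings(
        [("5x62", "6x37"), ("2x50", "3x39"), ("7x45", "7x49")], name="small"
    )


@pytest.fixture(scope="session")
def templates(default_pairs):
    return make_templates(default_pairs, separation=9.0)


@pytest.fixture(scope="session")
def small_templates(small_pairs):
    return make_templates(small_pairs, separation=9.0)


# ---------------------------------------------------------------------------
# synthetic ensembles (session-scoped: generation dominates test runtime)


def generate_labeled_set(
    templates,
    outdir: Path,
    n_per_class: int,
    n_frames: int,
    sigma: float,
    seed: int,
    interval_ps: float = 100.0,
):
    """Generate n active + n inactive trajectories; returns (files, states)."""
    active, inactive = templates
    out = []
    for i in range(2 * n_per_class):
        state = "active" if i < n_per_class else "inactive"
        spec = EnsembleSpec.constant(
            active, inactive, state, n_frames, sigma, seed=seed + i, frame_interval_ps=interval_ps
        )
        files = generate_ensemble(spec, outdir, basename=f"traj{i:02d}")
        out.append((files, state))
    return out


def entries_from(generated, start_id: int = 0) -> list[TrajectoryEntry]:
    return [
        TrajectoryEntry(
            trajectory=files.open(name=f"traj{start_id + i}"),
            mapping=load_mapping(files.mapping),
            state=state,
            traj_id=start_id + i,
        )
        for i, (files, state) in enumerate(generated)
    ]


@pytest.fixture(scope="session")
def labeled_set10(templates, tmp_path_factory):
    """10 trajectories (5 active / 5 inactive), 30 frames each, sigma 0.3."""
    outdir = tmp_path_factory.mktemp("labeled10")
    return generate_labeled_set(templates, outdir, n_per_class=5, n_frames=30, sigma=0.3, seed=100)


@pytest.fixture(scope="session")
def dataset10(labeled_set10, default_pairs):
    plan = FrameSamplingPlan(length_ns=3.0, interval_ps=100.0)  # 30 frames
    return build_dataset(entries_from(labeled_set10), default_pairs, plan)


@pytest.fixture(scope="session")
def folds10(dataset10):
    return assign_folds(dataset10, n_train_folds=7, n_test_folds=3, seed=7)


@pytest.fixture(scope="session")
def model10(dataset10, folds10):
    return train(dataset10, folds10, family="random-forest", seed=42)
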