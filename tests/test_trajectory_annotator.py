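import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation
from scipy.stats import rankdata

from gpcrstate import (
    binding_site_rmsd,
    classify_frames,
    classify_trajectory,
    compare_rmsd_groups,
    define_binding_site,
    load_mapping,
    score_trajectory,
    smooth,
)
from gpcrstate.errors import BindingSiteError, TrajectoryError
from gpcrstate.structure import Structure, Trajectory
from gpcrstate.synthetic_data import EnsembleSpec, generate_ensemble
from gpcrstate.trajectory_annotator import (
    BindingSiteDefinition,
    ScoreSeries,
    SiteResidue,
)


def make_series(scores, times=None):
    scores = np.asarray(scores, dtype=float)
    times = np.arange(len(scores), dtype=float) if times is None else times
    return ScoreSeries(times=times, scores=scores)


# ---------------------------------------------------------------------------
# oracles


def kabsch_rmsd_oracle(P, Q):
    """Brute-force Kabsch: center, SVD rotation, explicit RMSD."""
    P = np.asarray(P, float) - np.mean(P, axis=0)
    Q = np.asarray(Q, float) - np.mean(Q, axis=0)
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    return float(np.sqrt(np.mean(np.sum((P @ R - Q) ** 2, axis=1))))


def mannwhitney_permutation_oracle(a, b, n_perm=4000, seed=0):
    """Monte-Carlo permutation p-value for the rank-sum statistic."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n = len(a)
    mu = n * (len(pooled) + 1) / 2.0
    observed = abs(ranks[:n].sum() - mu)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        if abs(ranks[perm[:n]].sum() - mu) >= observed - 1e-9:
            count += 1
    return (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# smoothing


class TestSmooth:
    def test_constant_series_unchanged(self):
        series = smooth(make_series([0.4] * 7), window=5)
        assert np.allclose(series.smoothed, 0.4)

    def test_hand_checked_center_value(self):
        series = smooth(make_series([0, 0, 1, 0, 0]), window=5)
        assert series.smoothed[2] == pytest.approx(0.2)
        # truncated edges: mean over the available neighbors only
        assert series.smoothed[0] == pytest.approx(1 / 3)
        assert series.smoothed[1] == pytest.approx(1 / 4)

    def test_window_one_is_identity(self):
        raw = [0.1, 0.9, 0.3]
        series = smooth(make_series(raw), window=1)
        assert np.array_equal(series.smoothed, raw)

    def test_even_window_rejected(self):
        with pytest.raises(TrajectoryError, match="odd"):
            smooth(make_series([0.1, 0.2]), window=4)

    def test_raw_scores_untouched(self):
        raw = [0.0, 1.0, 0.0]
        series = smooth(make_series(raw), window=3)
        assert np.array_equal(series.scores, raw)

    @settings(max_examples=100, deadline=None)
    @given(
        scores=st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40),
        window=st.sampled_from([1, 3, 5, 7]),
    )
    def test_smoothed_bounded_by_raw_range(self, scores, window):
        series = smooth(make_series(scores), window=window)
        assert np.all(series.smoothed >= min(scores) - 1e-12)
        assert np.all(series.smoothed <= max(scores) + 1e-12)


# ---------------------------------------------------------------------------
# frame / trajectory classification


class TestClassifyFrames:
    def test_printed_score_pair(self):
        labels = classify_frames(make_series([0.0, 0.65]), theta=0.375)
        assert list(labels) == ["inactive", "active"]

    def test_score_exactly_theta_is_inactive(self):
        labels = classify_frames(make_series([0.375]), theta=0.375)
        assert list(labels) == ["inactive"]

    def test_theta_zero(self):
        labels = classify_frames(make_series([0.0, 1e-9, 0.7]), theta=0.0)
        assert list(labels) == ["inactive", "active", "active"]

    def test_smoothing_does_not_affect_classification(self):
        raw = [0.0, 0.0, 1.0, 0.0, 0.0]
        smoothed = smooth(make_series(raw), window=5)
        assert list(classify_frames(smoothed, 0.375)) == list(
            classify_frames(make_series(raw), 0.375)
        )

    def test_invalid_theta(self):
        with pytest.raises(TrajectoryError):
            classify_frames(make_series([0.5]), theta=1.5)


class TestClassifyTrajectory:
    def test_ratio_04_with_delta_0375_is_active(self):
        labels = ["active"] * 4 + ["inactive"] * 6
        verdict = classify_trajectory(labels, delta=0.375)
        assert verdict.active_ratio == pytest.approx(0.4)
        assert verdict.verdict == "active"

    def test_all_active_high_delta(self):
        verdict = classify_trajectory(["active"] * 10, delta=0.999)
        assert verdict.verdict == "active"

    def test_ratio_exactly_delta_is_inactive(self):
        labels = ["active"] * 4 + ["inactive"] * 6
        assert classify_trajectory(labels, delta=0.4).verdict == "inactive"

    def test_empty_rejected(self):
        with pytest.raises(TrajectoryError):
            classify_trajectory([], delta=0.5)

    @settings(max_examples=100, deadline=None)
    @given(
        n_active=st.integers(min_value=0, max_value=20),
        n_inactive=st.integers(min_value=0, max_value=20),
        deltas=st.tuples(
            st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1)
        ),
    )
    def test_monotone_in_delta(self, n_active, n_inactive, deltas):
        if n_active + n_inactive == 0:
            return
        labels = ["active"] * n_active + ["inactive"] * n_inactive
        lo, hi = min(deltas), max(deltas)
        # raising delta never flips inactive -> active
        if classify_trajectory(labels, delta=lo).verdict == "inactive":
            assert classify_trajectory(labels, delta=hi).verdict == "inactive"


# ---------------------------------------------------------------------------
# trajectory scoring


@pytest.fixture(scope="module")
def scoring_setup(templates, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("scoring")
    active, inactive = templates
    inactive_files = generate_ensemble(
        EnsembleSpec.constant(active, inactive, "inactive", 25, 0.2, seed=21), outdir, "allinact"
    )
    lambdas = np.concatenate([np.zeros(20), np.ones(20)])
    switch_files = generate_ensemble(
        EnsembleSpec(active=active, inactive=inactive, lambdas=lambdas, sigma=0.1, seed=22),
        outdir,
        "switch",
    )
    single_files = generate_ensemble(
        EnsembleSpec.constant(active, inactive, "active", 1, 0.0, seed=23), outdir, "single"
    )
    return {"inactive": inactive_files, "switch": switch_files, "single": single_files}


class TestScoreTrajectory:
    def test_all_inactive_scores_below_theta(self, model10, default_pairs, scoring_setup, templates):
        files = scoring_setup["inactive"]
        series = score_trajectory(model10, files.open(), load_mapping(files.mapping))
        assert len(series) == 25
        assert np.all(series.scores < 0.375)
        # centroid oracle agrees frame by frame
        active, inactive = templates
        d_act = active.pair_distances(default_pairs)
        d_inact = inactive.pair_distances(default_pairs)
        from gpcrstate.descriptor import TrajectoryFeaturizer

        X = TrajectoryFeaturizer(files.open(), load_mapping(files.mapping), default_pairs).featurize_frames()
        for x in X:
            assert np.linalg.norm(x - d_inact) < np.linalg.norm(x - d_act)

    def test_single_frame_series(self, model10, scoring_setup):
        files = scoring_setup["single"]
        series = score_trajectory(model10, files.open(), load_mapping(files.mapping))
        assert len(series) == 1
        assert series.scores[0] > 0.5

    def test_switch_crossing_near_known_frame(self, model10, scoring_setup):
        files = scoring_setup["switch"]
        series = score_trajectory(model10, files.open(), load_mapping(files.mapping))
        labels = classify_frames(series, theta=0.375)
        truth = files.truth()["state"].to_numpy()
        assert list(labels) == list(truth)  # instant switch, well separated
        assert int(np.argmax(labels == "active")) == 20

    def test_concatenation_equals_concatenated_series(self, model10, scoring_setup):
        inact, switch = scoring_setup["inactive"], scoring_setup["switch"]
        mapping = load_mapping(inact.mapping)
        s1 = score_trajectory(model10, inact.open(), mapping)
        s2 = score_trajectory(model10, switch.open(), mapping)
        chained = Trajectory(
            inact.topology, [inact.trajectory, switch.trajectory], dt_ps=100.0, name="chained"
        )
        s12 = score_trajectory(model10, chained, mapping)
        assert np.array_equal(s12.scores, np.concatenate([s1.scores, s2.scores]))

    def test_deterministic(self, model10, scoring_setup):
        files = scoring_setup["switch"]
        mapping = load_mapping(files.mapping)
        a = score_trajectory(model10, files.open(), mapping)
        b = score_trajectory(model10, files.open(), mapping)
        assert np.array_equal(a.scores, b.scores)


# ---------------------------------------------------------------------------
# binding sites


def _site_toy_atoms():
    atoms = [
        {"name": "C1", "resname": "LIG", "resnum": 900, "record": "HETATM", "xyz": (0, 0, 0)},
    ]
    for i, dist in enumerate((5.0, 7.9, 8.1), start=1):
        atoms.append({"name": "CA", "resname": "ALA", "resnum": i, "xyz": (dist, 0, 0)})
        atoms.append({"name": "CB", "resname": "ALA", "resnum": i, "xyz": (dist + 1.0, 0, 0)})
    return atoms


class TestDefineBindingSite:
    def test_cutoff_boundary_strictly_within(self, pdb_writer):
        structure = Structure.from_file(pdb_writer(_site_toy_atoms()))
        site = define_binding_site([(structure, "resname LIG")], cutoff=8.0, kind="ligand")
        assert sorted(r.resnum for r in site.residues) == [1, 2]

    def test_union_over_references(self, pdb_writer):
        s1 = Structure.from_file(pdb_writer(_site_toy_atoms(), "ref1.pdb"))
        atoms2 = [
            {"name": "C1", "resname": "LIG", "resnum": 900, "record": "HETATM", "xyz": (100, 0, 0)},
            {"name": "CA", "resname": "ALA", "resnum": 50, "xyz": (103, 0, 0)},
        ]
        s2 = Structure.from_file(pdb_writer(atoms2, "ref2.pdb"))
        site = define_binding_site(
            [(s1, "resname LIG"), (s2, "resname LIG")], cutoff=8.0, kind="ligand"
        )
        assert sorted(r.resnum for r in site.residues) == [1, 2, 50]

    def test_empty_selector_errors(self, pdb_writer):
        structure = Structure.from_file(pdb_writer(_site_toy_atoms()))
        with pytest.raises(BindingSiteError, match="matches nothing"):
            define_binding_site([(structure, "resname XYZ")], cutoff=8.0)

    def test_zero_cutoff_empty_site_errors(self, pdb_writer):
        structure = Structure.from_file(pdb_writer(_site_toy_atoms()))
        with pytest.raises(BindingSiteError, match="empty site"):
            define_binding_site([(structure, "resname LIG")], cutoff=0.0)

    def test_generic_labels_reported_when_mapped(self, pdb_writer, tmp_path):
        structure = Structure.from_file(pdb_writer(_site_toy_atoms()))
        mpath = tmp_path / "map.txt"
        mpath.write_text("3x32 1 A ALA\n")
        mapping = load_mapping(mpath)
        site = define_binding_site(
            [(structure, "resname LIG")], cutoff=8.0, mappings=[mapping]
        )
        labels = {r.resnum: r.label for r in site.residues}
        assert labels[1] == "3x32"
        assert labels[2] is None

    def test_json_roundtrip(self, pdb_writer, tmp_path):
        structure = Structure.from_file(pdb_writer(_site_toy_atoms()))
        site = define_binding_site([(structure, "resname LIG")], cutoff=8.0)
        path = tmp_path / "site.json"
        site.to_json(path)
        back = BindingSiteDefinition.from_json(path)
        assert [r.resnum for r in back.residues] == [r.resnum for r in site.residues]
        assert back.cutoff == 8.0


def _ca_structure(pdb_writer, coords, filename):
    atoms = [
        {"name": "CA", "resname": "ALA", "resnum": i + 1, "xyz": tuple(c)}
        for i, c in enumerate(coords)
    ]
    return Structure.from_file(pdb_writer(atoms, filename))


def _site_for(n):
    return BindingSiteDefinition(
        kind="g-protein",
        cutoff=8.0,
        references=["toy"],
        residues=[SiteResidue(chain="A", resnum=i + 1) for i in range(n)],
    )


class TestBindingSiteRMSD:
    def _coords(self, seed=0, n=9):
        rng = np.random.default_rng(seed)
        return rng.uniform(-10, 10, size=(n, 3))

    def test_identical_structures_zero(self, pdb_writer):
        coords = self._coords()
        a = _ca_structure(pdb_writer, coords, "a.pdb")
        b = _ca_structure(pdb_writer, coords, "b.pdb")
        assert binding_site_rmsd(a, b, _site_for(9)) == pytest.approx(0.0, abs=1e-6)

    def test_rigid_rotation_removed(self, pdb_writer):
        # rotate in memory: PDB files quantize coordinates to 1e-3 A
        coords = self._coords(seed=1)
        rot = Rotation.from_euler("xyz", [30, -45, 60], degrees=True).as_matrix()
        a = _ca_structure(pdb_writer, coords, "a.pdb")
        b = _ca_structure(pdb_writer, coords, "b.pdb")
        b.universe.atoms.positions = a.universe.atoms.positions @ rot.T + np.array([5, -3, 12])
        assert binding_site_rmsd(a, b, _site_for(9)) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_agrees_with_kabsch_oracle(self, pdb_writer, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        P = rng.uniform(-10, 10, size=(n, 3))
        Q = P + rng.normal(0, 2.0, size=(n, 3))
        a = _ca_structure(pdb_writer, P, f"p{seed}.pdb")
        b = _ca_structure(pdb_writer, Q, f"q{seed}.pdb")
        got = binding_site_rmsd(a, b, _site_for(n))
        # PDB storage quantizes coordinates to 1e-3 A
        assert got == pytest.approx(kabsch_rmsd_oracle(P, Q), abs=1e-3)

    def test_single_displaced_ca(self, pdb_writer):
        P = self._coords(seed=5, n=9)
        Q = P.copy()
        Q[0] += np.array([3.0, 0, 0])
        a = _ca_structure(pdb_writer, P, "a.pdb")
        b = _ca_structure(pdb_writer, Q, "b.pdb")
        got = binding_site_rmsd(a, b, _site_for(9))
        assert got == pytest.approx(kabsch_rmsd_oracle(P, Q), abs=1e-3)
        assert got > 0

    def test_symmetric_under_swap(self, pdb_writer):
        P = self._coords(seed=6)
        Q = P + np.random.default_rng(7).normal(0, 1, size=P.shape)
        a = _ca_structure(pdb_writer, P, "a.pdb")
        b = _ca_structure(pdb_writer, Q, "b.pdb")
        assert binding_site_rmsd(a, b, _site_for(9)) == pytest.approx(
            binding_site_rmsd(b, a, _site_for(9)), abs=1e-9
        )

    def test_unresolvable_site_residue_listed(self, pdb_writer):
        a = _ca_structure(pdb_writer, self._coords(), "a.pdb")
        b = _ca_structure(pdb_writer, self._coords(), "b.pdb")
        site = BindingSiteDefinition(
            kind="g-protein",
            cutoff=8.0,
            references=["toy"],
            residues=[SiteResidue(chain="A", resnum=999)],
        )
        with pytest.raises(BindingSiteError, match="999"):
            binding_site_rmsd(a, b, site)

    def test_active_frames_closer_to_active_template(self, scoring_setup, templates):
        # the two-state switch ensemble reproduces the expected pattern:
        # active-labeled frames have smaller site RMSD to the active template
        files = scoring_setup["switch"]
        traj = files.open()
        mapping = load_mapping(files.mapping)
        truth = files.truth()["state"].to_numpy()
        reference = Structure.from_file(files.topology)  # active-template coordinates
        site_labels = ["5x62", "6x37", "6x40", "3x50", "7x53", "5x58", "6x41", "2x50", "3x39"]
        residues = [
            SiteResidue(chain="A", resnum=mapping[lab].resnum, label=lab) for lab in site_labels
        ]
        site = BindingSiteDefinition(
            kind="g-protein", cutoff=8.0, references=["template"], residues=residues
        )
        rmsds = np.array(
            [binding_site_rmsd(traj.structure_at(i), reference, site) for i in range(traj.n_frames)]
        )
        active_mean = rmsds[truth == "active"].mean()
        inactive_mean = rmsds[truth == "inactive"].mean()
        assert active_mean < inactive_mean


# ---------------------------------------------------------------------------
# group comparison


class TestCompareRmsdGroups:
    def test_identical_groups(self):
        group = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        result = compare_rmsd_groups(group, group)
        assert result.p_value > 0.9
        assert result.median_a == result.median_b == 3.0

    def test_shifted_groups_tiny_pvalue_vs_permutation_oracle(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0.0, 1.0, size=100)
        b = rng.normal(3.0, 1.0, size=100)  # 3 sigma shift
        result = compare_rmsd_groups(a, b)
        assert result.p_value < 1e-6
        perm_p = mannwhitney_permutation_oracle(a, b, n_perm=2000, seed=1)
        assert perm_p <= 5 / 2000  # saturated at the Monte-Carlo floor

    def test_moderate_case_matches_permutation_within_mc_error(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, size=40)
        b = rng.normal(0.45, 1.0, size=40)
        result = compare_rmsd_groups(a, b)
        n_perm = 4000
        perm_p = mannwhitney_permutation_oracle(a, b, n_perm=n_perm, seed=2)
        se = np.sqrt(result.p_value * (1 - result.p_value) / n_perm)
        assert abs(result.p_value - perm_p) < 5 * se + 2 / n_perm

    def test_medians_match_direct_sort(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 5, size=31)
        b = rng.uniform(1, 6, size=17)
        result = compare_rmsd_groups(a, b)
        assert result.median_a == sorted(a)[15]
        assert result.median_b == sorted(b)[8]

    def test_empty_group_rejected(self):
        with pytest.raises(BindingSiteError):
            compare_rmsd_groups([], [1.0])
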