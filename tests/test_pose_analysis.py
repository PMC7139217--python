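import itertools
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from densedock import (
    LigandPose,
    cluster_by_centroid,
    consensus,
    deduplicate,
    pose_rmsd,
)
from densedock.errors import CorrespondenceError, ScoreOrientationError
from densedock.pose_analysis import graph_automorphisms, infer_bonds

from tests.conftest import make_fragment_pose, random_rigid_copy


def hexagon_pose(pose_id="ring"):
    """A benzene-like six-carbon ring in the xy-plane."""
    coords = np.array(
        [
            [1.4 * np.cos(np.deg2rad(60 * k)), 1.4 * np.sin(np.deg2rad(60 * k)), 0.0]
            for k in range(6)
        ]
    )
    return LigandPose(
        names=[f"C{k + 1}" for k in range(6)],
        elements=["C"] * 6,
        coords=coords,
        pose_id=pose_id,
    )


class TestPoseRMSD:
    def test_identity_is_zero(self):
        p = make_fragment_pose("a")
        assert pose_rmsd(p, p) == 0.0

    def test_rigid_translation_is_exact(self):
        p = make_fragment_pose("a")
        q = replace(p, coords=p.coords + np.array([2.0, 0.0, 0.0]), pose_id="b")
        assert pose_rmsd(p, q, symmetry=False) == pytest.approx(2.0, abs=1e-12)
        assert pose_rmsd(p, q, symmetry=True) == pytest.approx(2.0, abs=1e-9)

    def test_ring_flip_with_symmetry_matches_bruteforce(self):
        # flip the ring 180 degrees about the x-axis: geometrically identical
        p = hexagon_pose("p")
        flip = np.diag([1.0, -1.0, -1.0])
        q = replace(p, coords=p.coords @ flip.T, pose_id="q")
        assert pose_rmsd(p, q, symmetry=False) > 1.0

        # oracle: minimum over ALL adjacency-preserving atom permutations
        bonds = set(map(frozenset, infer_bonds(p.elements, p.coords)))
        best = np.inf
        for perm in itertools.permutations(range(6)):
            mapped = {frozenset((perm[i], perm[j])) for i, j in map(tuple, bonds)}
            if mapped == bonds:
                r = np.sqrt(np.mean(np.sum((p.coords[list(perm)] - q.coords) ** 2,
                                           axis=-1)))
                best = min(best, r)
        assert pose_rmsd(p, q, symmetry=True) == pytest.approx(best, abs=1e-10)
        assert best == pytest.approx(0.0, abs=1e-10)

    def test_automorphism_count_of_benzene_ring(self):
        p = hexagon_pose()
        autos = graph_automorphisms(p.elements, p.coords)
        assert len(autos) == 12  # dihedral group of the hexagon

    def test_atom_mismatch_raises(self):
        p = make_fragment_pose("a")
        q = hexagon_pose("b")
        with pytest.raises(CorrespondenceError):
            pose_rmsd(p, q)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_pseudometric_properties_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        base = make_fragment_pose()
        a, b, c = (random_rigid_copy(base, rng) for _ in range(3))
        dab = pose_rmsd(a, b, symmetry=False)
        dba = pose_rmsd(b, a, symmetry=False)
        dac = pose_rmsd(a, c, symmetry=False)
        dbc = pose_rmsd(b, c, symmetry=False)
        assert dab == pytest.approx(dba, abs=1e-10)
        assert dac <= dab + dbc + 1e-9


def brute_check_dedup(poses, clusters, threshold):
    """Exhaustive verification of the two dedup coverage/separation rules."""
    reps = [c.representative for c in clusters]
    for p, q in itertools.combinations(reps, 2):
        assert pose_rmsd(p, q, symmetry=False) > threshold
    by_id = {p.pose_id: p for p in poses}
    for c in clusters:
        for member_id in c.members:
            assert pose_rmsd(c.representative, by_id[member_id],
                             symmetry=False) <= threshold


class TestDeduplicate:
    def test_copies_collapse_to_one_cluster(self):
        p = make_fragment_pose("p0", score=-9.0)
        copies = [replace(p, pose_id=f"p{i}", engine_score=-9.0 + 0.1 * i)
                  for i in range(10)]
        clusters = deduplicate(copies, threshold=2.0)
        assert len(clusters) == 1
        assert clusters[0].size == 10
        assert clusters[0].representative.pose_id == "p0"  # best (lowest) score

    def test_distant_poses_stay_singletons(self):
        base = make_fragment_pose()
        poses = [
            replace(base, coords=base.coords + np.array([5.0 * i, 0, 0]),
                    pose_id=f"p{i}", engine_score=float(i),
                    lower_is_better=True)
            for i in range(6)
        ]
        clusters = deduplicate(poses, threshold=2.0)
        assert len(clusters) == 6

    def test_random_sets_satisfy_coverage_and_separation(self):
        rng = np.random.default_rng(11)
        base = make_fragment_pose()
        poses = []
        for i in range(30):
            p = random_rigid_copy(base, rng, max_shift=6.0)
            poses.append(replace(p, pose_id=f"p{i:02d}",
                                 engine_score=float(rng.normal()),
                                 lower_is_better=True))
        clusters = deduplicate(poses, threshold=2.0, symmetry=False)
        brute_check_dedup(poses, clusters, threshold=2.0)

    def test_result_is_input_order_independent(self):
        rng = np.random.default_rng(12)
        base = make_fragment_pose()
        poses = []
        for i in range(15):
            p = random_rigid_copy(base, rng, max_shift=5.0)
            poses.append(replace(p, pose_id=f"p{i:02d}",
                                 engine_score=float(rng.normal()),
                                 lower_is_better=True))
        ref = deduplicate(poses, threshold=2.0, symmetry=False)
        shuffled = [poses[i] for i in rng.permutation(len(poses))]
        alt = deduplicate(shuffled, threshold=2.0, symmetry=False)
        assert [c.representative.pose_id for c in ref] == \
               [c.representative.pose_id for c in alt]

    def test_mixed_score_orientations_rejected(self):
        a = make_fragment_pose("a", score=-9.0, lower=True)
        b = make_fragment_pose("b", score=40.0, lower=False)
        with pytest.raises(ScoreOrientationError):
            deduplicate([a, b])

    def test_missing_scores_fall_back_to_input_order(self):
        a = make_fragment_pose("a")
        b = replace(make_fragment_pose("b"),
                    coords=make_fragment_pose("b").coords + 5.0)
        with pytest.warns(UserWarning, match="input order"):
            clusters = deduplicate([a, b], threshold=2.0)
        assert len(clusters) == 2


class TestClusterByCentroid:
    def test_two_separated_groups(self):
        base = make_fragment_pose()
        rng = np.random.default_rng(13)
        poses = []
        for i in range(4):
            poses.append(replace(base, coords=base.coords + rng.normal(0, 0.3, 3),
                                 pose_id=f"a{i}"))
        for i in range(4):
            poses.append(replace(base,
                                 coords=base.coords + np.array([20.0, 0, 0])
                                 + rng.normal(0, 0.3, 3),
                                 pose_id=f"b{i}"))
        clusters = cluster_by_centroid(poses, link_threshold=5.0)
        assert len(clusters) == 2

    def test_infinite_threshold_gives_one_cluster(self):
        rng = np.random.default_rng(14)
        base = make_fragment_pose()
        poses = [replace(random_rigid_copy(base, rng, 30.0), pose_id=f"p{i}")
                 for i in range(8)]
        clusters = cluster_by_centroid(poses, link_threshold=np.inf)
        assert len(clusters) == 1
        assert clusters[0].size == 8

    def test_three_planted_sites_recovered(self):
        base = make_fragment_pose()
        rng = np.random.default_rng(15)
        sites = [np.zeros(3), np.array([25.0, 0, 0]), np.array([0, 25.0, 0])]
        poses = []
        for s_idx, site in enumerate(sites):
            for i in range(5):
                poses.append(
                    replace(base, coords=base.coords + site + rng.normal(0, 0.5, 3),
                            pose_id=f"s{s_idx}_{i}")
                )
        clusters = cluster_by_centroid(poses, link_threshold=5.0)
        assert len(clusters) == 3
        centers = sorted(tuple(np.round(c.centroid)) for c in clusters)
        expected = sorted(tuple(np.round(base.centroid + s)) for s in sites)
        for got, want in zip(centers, expected):
            assert np.linalg.norm(np.array(got) - np.array(want)) <= 2.0


def brute_consensus_ids(pose_sets, threshold):
    """Independent all-pairs enumeration of the cross-engine consensus."""
    engines = sorted(pose_sets)
    supported = []
    for engine in engines:
        for pose in pose_sets[engine]:
            if all(
                any(
                    pose_rmsd(pose, q, symmetry=False) <= threshold
                    for q in pose_sets[other]
                )
                for other in engines
                if other != engine
            ):
                supported.append(pose)
    supported.sort(key=lambda p: p.pose_id)
    kept = []
    for pose in supported:
        if all(pose_rmsd(k, pose, symmetry=False) > threshold for k in kept):
            kept.append(pose)
    return [p.pose_id for p in kept]


class TestConsensus:
    def test_identical_pose_in_all_engines(self):
        base = make_fragment_pose()
        sets = {
            e: [replace(base, engine=e, pose_id=f"{e}_0")]
            for e in ("vina", "chemscore", "goldscore")
        }
        result = consensus(sets, threshold=2.0)
        assert len(result) == 1
        assert set(result.support[result.poses[0].pose_id]) == set(sets)

    def test_pose_in_two_of_three_engines_excluded(self):
        base = make_fragment_pose()
        far = replace(base, coords=base.coords + np.array([30.0, 0, 0]))
        sets = {
            "e1": [replace(base, pose_id="e1_0")],
            "e2": [replace(base, pose_id="e2_0")],
            "e3": [replace(far, pose_id="e3_0")],
        }
        result = consensus(sets, threshold=2.0)
        assert len(result) == 0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(16)
        base = make_fragment_pose()
        for trial in range(10):
            sets = {}
            for e in range(int(rng.integers(2, 5))):
                label = f"eng{e}"
                sets[label] = [
                    replace(random_rigid_copy(base, rng, max_shift=4.0),
                            engine=label, pose_id=f"{label}_p{i}")
                    for i in range(int(rng.integers(1, 11)))
                ]
            result = consensus(sets, threshold=2.0, symmetry=False)
            assert [p.pose_id for p in result.poses] == \
                   brute_consensus_ids(sets, 2.0)

    def test_invariant_to_engine_relabeling(self):
        rng = np.random.default_rng(17)
        base = make_fragment_pose()
        sets = {
            label: [
                replace(random_rigid_copy(base, rng, max_shift=3.0),
                        pose_id=f"{label}_p{i}")
                for i in range(6)
            ]
            for label in ("alpha", "beta", "gamma")
        }
        a = consensus(sets, threshold=2.0, symmetry=False)
        relabeled = {"zeta": sets["alpha"], "eta": sets["beta"],
                     "theta": sets["gamma"]}
        b = consensus(relabeled, threshold=2.0, symmetry=False)
        assert [p.pose_id for p in a.poses] == [p.pose_id for p in b.poses]

    def test_empty_engine_yields_empty_consensus_with_warning(self):
        base = make_fragment_pose()
        sets = {"e1": [replace(base, pose_id="e1_0")], "e2": []}
        with pytest.warns(UserWarning, match="no poses"):
            result = consensus(sets, threshold=2.0)
        assert len(result) == 0
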