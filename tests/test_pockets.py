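"""Pocket model construction and B/F/O pose assignment."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hlapocket import (
    PocketModel,
    assign_pockets,
    build_pocket_model,
    cluster_poses,
    label_clusters,
    make_groove,
    make_pose_set,
)
from hlapocket.model import Atom, LigandPose, Structure


def _point_pose(xyz, run_id=1, score=-3.0, space="PBG"):
    atom = Atom(
        serial=9000 + run_id, name="C1", element="C", residue_name="LIG",
        residue_number=1, chain="L", position=np.asarray(xyz, dtype=float),
    )
    return LigandPose(atoms=[atom], score=score, run_id=run_id, search_space=space)


def _model(b=(0.0, 0, 0), f=(15.0, 0, 0), radius=12.0):
    return PocketModel(
        pockets={
            "B": (frozenset({9}), np.asarray(b, dtype=float)),
            "F": (frozenset({80}), np.asarray(f, dtype=float)),
        },
        groove_radius=radius,
    )


class TestBuildPocketModel:
    def test_centroids_sit_at_pocket_centres(self, groove, config):
        model = build_pocket_model(groove)
        np.testing.assert_allclose(
            model.centroid("B"), config.pocket_center_B, atol=1.0
        )
        np.testing.assert_allclose(
            model.centroid("F"), config.pocket_center_F, atol=1.0
        )

    def test_f_pocket_residue_list_resolves(self, groove):
        f_def = {"F": frozenset({77, 80, 81, 84, 95, 116, 123, 143, 147}),
                 "B": frozenset({9, 45, 63})}
        model = build_pocket_model(groove, definitions=f_def)
        assert np.all(np.isfinite(model.centroid("F")))

    def test_unresolvable_pocket_errors(self, groove):
        with pytest.raises(ValueError, match="pocket A"):
            build_pocket_model(groove, definitions={"A": frozenset({999})})


class TestClusterPoses:
    def test_two_separated_clouds_recovered_exactly(self, rng):
        poses = [_point_pose(rng.normal(scale=1.0, size=3), run_id=i + 1) for i in range(10)]
        poses += [
            _point_pose((15, 0, 0) + rng.normal(scale=1.0, size=3), run_id=i + 11)
            for i in range(10)
        ]
        labels = cluster_poses(poses, k=2)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_degenerate_identical_points_tolerated(self):
        poses = [_point_pose((1.0, 2.0, 3.0), run_id=i + 1) for i in range(5)]
        labels = cluster_poses(poses, k=2)
        assert len(labels) == 5

    def test_k1_single_cluster(self, rng):
        poses = [_point_pose(rng.normal(size=3), run_id=i + 1) for i in range(6)]
        assert set(cluster_poses(poses, k=1)) == {0}

    def test_fewer_poses_than_k_errors(self):
        with pytest.raises(ValueError, match="at least k"):
            cluster_poses([_point_pose((0, 0, 0))], k=2)

    def test_pose_order_permutation_never_changes_labels(self, rng):
        poses = [_point_pose(rng.normal(scale=1.5, size=3), run_id=i + 1) for i in range(8)]
        poses += [
            _point_pose((15, 0, 0) + rng.normal(scale=1.5, size=3), run_id=i + 9)
            for i in range(8)
        ]
        base = dict(zip([p.run_id for p in poses],
                        label_clusters(poses, cluster_poses(poses), _model())))
        for _ in range(10):
            perm = rng.permutation(len(poses))
            shuffled = [poses[i] for i in perm]
            asg = label_clusters(shuffled, cluster_poses(shuffled), _model())
            for pose, a in zip(shuffled, asg):
                assert a.label == base[pose.run_id].label


class TestLabelClusters:
    def test_nearest_centroid_rule(self):
        near_f = [_point_pose((13, 1, 0), run_id=1), _point_pose((14, -1, 0), run_id=2)]
        asg = label_clusters(near_f, [0, 0], _model())
        assert [a.label for a in asg] == ["F", "F"]

    def test_outside_groove_threshold(self):
        pose = _point_pose((7.5, 25, 0), run_id=1)
        asg = label_clusters([pose], [0], _model(radius=12.0))
        assert asg[0].label == "O"

    def test_missing_f_pocket_errors(self):
        model = PocketModel(pockets={"B": (frozenset({9}), np.zeros(3))})
        with pytest.raises(ValueError, match="F pocket"):
            label_clusters([_point_pose((0, 0, 0))], [0], model)

    def test_risk_like_pose_set_mostly_f(self, groove, config):
        poses, truth = make_pose_set(config, n_B=2, n_F=8)
        asg = assign_pockets(poses, build_pocket_model(groove))
        assert sum(a.label == "F" for a in asg) >= 8

    def test_joint_rigid_transform_invariance(self, config, rng):
        groove = make_groove(config)
        poses, _ = make_pose_set(config, n_B=5, n_F=5)
        base = [a.label for a in assign_pockets(poses, build_pocket_model(groove))]

        rot = Rotation.random(rng=rng)
        shift = rng.normal(scale=30, size=3)

        def move_atom(a):
            return Atom(
                serial=a.serial, name=a.name, element=a.element,
                residue_name=a.residue_name, residue_number=a.residue_number,
                chain=a.chain, position=rot.apply(a.position) + shift,
            )

        groove2 = Structure(atoms=[move_atom(a) for a in groove.atoms], label="moved")
        poses2 = [
            LigandPose(
                atoms=[move_atom(a) for a in p.atoms], score=p.score,
                run_id=p.run_id, search_space=p.search_space, ligand_id=p.ligand_id,
            )
            for p in poses
        ]
        moved = [a.label for a in assign_pockets(poses2, build_pocket_model(groove2))]
        assert moved == base
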