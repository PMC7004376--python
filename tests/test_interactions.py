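"""Contact detection, thiocarbonyl pattern, and the Thr80 taxonomy."""

import numpy as np
import pytest

from hlapocket import (
    ContactParams,
    Thr80Class,
    classify_thr80,
    detect_contacts,
    find_thiocarbonyl_sulfur,
    make_groove,
    make_pose_set,
    make_thr80_pose_set,
    tabulate_thr80,
)
from hlapocket.model import Atom, LigandPose, Structure


def _atom(serial, name, element, xyz, resname="ALA", resnum=1, chain="A"):
    return Atom(
        serial=serial, name=name, element=element, residue_name=resname,
        residue_number=resnum, chain=chain, position=np.asarray(xyz, dtype=float),
    )


def _ligand(atoms, score=-3.0, run_id=1):
    return LigandPose(atoms=atoms, score=score, run_id=run_id, search_space="PBG")


class TestThiocarbonylFinder:
    def test_methimazole_like_sulfur_found(self, config):
        poses, _ = make_pose_set(config, n_B=1, n_F=0, thiocarbonyl=True)
        assert find_thiocarbonyl_sulfur(poses[0]) == "S1"

    def test_ligand_without_sulfur_gives_none(self, config):
        poses, _ = make_pose_set(config, n_B=1, n_F=0, thiocarbonyl=False)
        assert find_thiocarbonyl_sulfur(poses[0]) is None

    def test_thioether_fails_pattern(self):
        # C-S-C with two ~1.81 A bonds: sulfur is not terminal
        lig = _ligand([
            _atom(9001, "C1", "C", (-1.81, 0, 0), chain="L"),
            _atom(9002, "S1", "S", (0, 0, 0), chain="L"),
            _atom(9003, "C2", "C", (1.81, 0, 0), chain="L"),
        ])
        assert find_thiocarbonyl_sulfur(lig) is None

    def test_isolated_cs_pair_fails_neighbour_test(self):
        # C=S where the carbon has no further neighbours
        lig = _ligand([
            _atom(9001, "C1", "C", (0, 0, 0), chain="L"),
            _atom(9002, "S1", "S", (1.68, 0, 0), chain="L"),
        ])
        assert find_thiocarbonyl_sulfur(lig) is None


class TestDetectContacts:
    def test_hydrophobic_contact_inside_window(self):
        prot = Structure([_atom(1, "CB", "C", (0, 0, 0))])
        lig = _ligand([_atom(9001, "C1", "C", (3.5, 0, 0), chain="L")])
        recs = detect_contacts(prot, lig)
        assert len(recs) == 1
        assert recs[0].kind == "hydrophobic"
        assert recs[0].distance == pytest.approx(3.5)

    def test_hbond_donor_to_backbone_oxygen(self):
        prot = Structure([_atom(1, "O", "O", (0, 0, 0))])  # backbone O accepts
        lig = _ligand([_atom(9001, "N1", "N", (2.9, 0, 0), chain="L")])
        recs = detect_contacts(prot, lig)
        assert [r.kind for r in recs] == ["hbond"]

    def test_nonpolar_carbon_pair_makes_no_hbond(self):
        prot = Structure([_atom(1, "CB", "C", (0, 0, 0))])
        lig = _ligand([_atom(9001, "C1", "C", (3.0, 0, 0), chain="L")])
        assert all(r.kind == "hydrophobic" for r in detect_contacts(prot, lig))

    def test_far_ligand_gives_no_records(self):
        prot = Structure([_atom(1, "CB", "C", (0, 0, 0))])
        lig = _ligand([_atom(9001, "C1", "C", (5.0, 0, 0), chain="L")])
        assert detect_contacts(prot, lig) == []

    def test_overlapping_serials_error(self):
        prot = Structure([_atom(1, "CB", "C", (0, 0, 0))])
        lig = _ligand([_atom(1, "C1", "C", (3.5, 0, 0), chain="L")])
        with pytest.raises(ValueError, match="serial"):
            detect_contacts(prot, lig)

    def test_matches_all_pairs_brute_force(self, config, rng):
        """KD-tree pruning must change nothing vs. an exhaustive scan."""
        from hlapocket.interactions import (
            _ligand_polar_roles,
            _protein_is_acceptor,
            _protein_is_donor,
        )

        params = ContactParams()
        groove = make_groove(config)
        for rep in range(10):
            poses, _ = make_pose_set(
                config, n_B=1, n_F=1,
                rng=np.random.default_rng(rng.integers(2**31)),
            )
            for pose in poses:
                got = detect_contacts(groove, pose, params)
                expected = []
                for pa in groove.atoms:
                    for la in pose.atoms:
                        d = float(np.linalg.norm(pa.position - la.position))
                        if (pa.element in "CS" and la.element in "CS"
                                and params.hphob_min <= d <= params.hphob_max):
                            expected.append((pa.name, la.name, "hydrophobic", round(d, 9)))
                        if (pa.element in "NOS" and la.element in "NOS"
                                and d <= params.hbond_max):
                            ld, la_acc = _ligand_polar_roles(la, None)
                            if (_protein_is_donor(pa) and la_acc) or (
                                    _protein_is_acceptor(pa) and ld):
                                expected.append((pa.name, la.name, "hbond", round(d, 9)))
                got_set = {(r.protein_atom, r.ligand_atom, r.kind, round(r.distance, 9))
                           for r in got}
                assert got_set == set(expected)
                assert [r.distance for r in got] == sorted(r.distance for r in got)

    def test_shrinking_hphob_max_never_adds_records(self, config):
        groove = make_groove(config)
        poses, _ = make_pose_set(config, n_B=2, n_F=2)
        for pose in poses:
            wide = {(r.protein_atom, r.ligand_atom)
                    for r in detect_contacts(groove, pose, ContactParams(hphob_max=3.9))
                    if r.kind == "hydrophobic"}
            for hmax in (3.7, 3.5, 3.3, 3.1):
                narrow = {(r.protein_atom, r.ligand_atom)
                          for r in detect_contacts(groove, pose, ContactParams(hphob_max=hmax))
                          if r.kind == "hydrophobic"}
                assert narrow <= wide
                wide = narrow


class TestClassifyThr80:
    def test_thiocarbonyl_contact_is_thr80_s(self, config):
        groove = make_groove(config)
        poses, truth = make_thr80_pose_set(config, groove, n_contact=3, n_away=3)
        for pose, label in zip(poses, truth):
            cls = classify_thr80(detect_contacts(groove, pose), pose, 80, groove)
            if label == "thr80_contact":
                assert cls is Thr80Class.THR80_S
            else:
                assert cls is Thr80Class.NO_THR80

    def test_non_sulfur_contact_is_other_thr80(self, config):
        groove = make_groove(config)
        # ligand nitrogen near the THR 80 side chain, no thiocarbonyl present
        poses, _ = make_thr80_pose_set(config, groove, n_contact=1, n_away=0,
                                       thiocarbonyl=False)
        pose = poses[0]
        recs = detect_contacts(groove, pose)
        assert any(r.residue_position == 80 for r in recs)
        assert classify_thr80(recs, pose, 80, groove) is Thr80Class.OTHER_THR80

    def test_position_absent_from_structure_errors(self, config):
        prot = Structure([_atom(1, "CB", "C", (0, 0, 0), resnum=5)])
        lig = _ligand([_atom(9001, "C1", "C", (3.5, 0, 0), chain="L")])
        with pytest.raises(ValueError, match="absent"):
            classify_thr80([], lig, 80, prot)


class TestTabulate:
    def test_fixture_counts_and_most_favourable(self):
        classes = ([Thr80Class.NO_THR80] * 5 + [Thr80Class.THR80_S] * 4
                   + [Thr80Class.OTHER_THR80])
        scores = [-3.0] * 5 + [-4.5, -3.1, -3.2, -3.3] + [-3.4]
        summary = tabulate_thr80(classes, scores)
        assert (summary.n_no_thr80, summary.n_thr80_s, summary.n_other_thr80) == (5, 4, 1)
        assert summary.most_favourable is Thr80Class.THR80_S

    def test_single_pose(self):
        summary = tabulate_thr80([Thr80Class.NO_THR80], [-2.0])
        assert (summary.n_no_thr80, summary.n_thr80_s, summary.n_other_thr80) == (1, 0, 0)
        assert summary.most_favourable is Thr80Class.NO_THR80

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            tabulate_thr80([], [])

    def test_counts_match_brute_force_tally(self, rng):
        values = list(Thr80Class)
        for _ in range(50):
            n = int(rng.integers(1, 40))
            classes = [values[i] for i in rng.integers(0, 3, size=n)]
            scores = rng.normal(size=n).tolist()
            summary = tabulate_thr80(classes, scores)
            assert summary.n_no_thr80 == classes.count(Thr80Class.NO_THR80)
            assert summary.n_thr80_s == classes.count(Thr80Class.THR80_S)
            assert summary.n_other_thr80 == classes.count(Thr80Class.OTHER_THR80)
            assert summary.total == n
            assert summary.most_favourable is classes[int(np.argmin(scores))]
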