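"""Docking summary rows, rendering, and multi-run score distributions."""

import numpy as np
import pytest

from hlapocket import (
    FiveNumberSummary,
    PocketAssignment,
    render_row,
    render_table,
    score_distribution,
    summarize,
)
from hlapocket.model import Atom, LigandPose


def _pose(score, run_id, ligand="MMZ", space="PBG"):
    atom = Atom(
        serial=9000 + run_id, name="C1", element="C", residue_name="LIG",
        residue_number=1, chain="L", position=np.zeros(3),
    )
    return LigandPose(atoms=[atom], score=score, run_id=run_id,
                      search_space=space, ligand_id=ligand)


def _group(labels, scores, allele="B*38:02_M", ligand="MMZ", space="PBG", start=1):
    poses = [_pose(s, start + i, ligand, space) for i, s in enumerate(scores)]
    assignments = [
        PocketAssignment(pose_index=start + i - 1, cluster_id=0, label=l)
        for i, l in enumerate(labels)
    ]
    alleles = [allele] * len(scores)
    return assignments, poses, alleles


def test_one_b_nine_f_row_shape_and_rendering():
    """1 B pose at -3.10 and 9 F poses with median -4.39, minimum in F:
    the row renders 'F 1 -3.10 9 -4.39'."""
    f_scores = [-4.39, -4.50, -4.10, -4.39, -4.60, -4.20, -4.39, -4.80, -4.00]
    asg, poses, alleles = _group(["B"] + ["F"] * 9, [-3.10] + f_scores)
    rows = summarize(asg, poses, alleles)
    assert len(rows) == 1
    row = rows[0]
    assert (row.lowest_pocket, row.count_B, row.count_F) == ("F", 1, 9)
    assert row.median_B == pytest.approx(-3.10)
    assert row.median_F == pytest.approx(-4.39)
    assert render_row(row) == "F 1 -3.10 9 -4.39"


def test_empty_pocket_renders_na():
    asg, poses, alleles = _group(["F"] * 10, [-3.66] * 10, allele="B*38:01_M")
    row = summarize(asg, poses, alleles)[0]
    assert row.count_B == 0 and row.median_B is None
    assert render_row(row) == "F 0 N/A 10 -3.66"


def test_top3_rows_include_outside_columns():
    asg, poses, alleles = _group(["B", "F", "O", "O"], [-3.2, -3.4, -3.9, -3.7],
                                 space="Top3")
    row = summarize(asg, poses, alleles)[0]
    assert render_row(row) == "O 1 -3.20 1 -3.40 2 -3.80"


def test_render_table_column_order():
    asg, poses, alleles = _group(["B"] + ["F"] * 9,
                                 [-3.10, -4.39, -4.5, -4.1, -4.39, -4.6, -4.2,
                                  -4.39, -4.8, -4.0])
    text = render_table(summarize(asg, poses, alleles),
                        status={"B*38:02_M": "Risk"},
                        mutation={"B*38:02_M": "N80T"})
    lines = text.splitlines()
    assert lines[0].split("\t")[:4] == ["Status", "Allele", "Mutation", "Lowest"]
    assert lines[1].split("\t")[:6] == ["Risk", "B*38:02_M", "N80T", "F", "1", "-3.10"]


def test_counts_sum_and_lowest_tie_break(rng):
    asg, poses, alleles = _group(["B", "F"], [-5.0, -5.0])
    row = summarize(asg, poses, alleles)[0]
    assert row.lowest_pocket == "B"  # tie on score -> lowest pose index
    assert row.count_B + row.count_F + row.count_O == 2


def test_groups_keyed_by_allele_ligand_space():
    asg1, poses1, alleles1 = _group(["B"] * 2, [-3.0, -3.1], ligand="MMZ")
    asg2, poses2, alleles2 = _group(["F"] * 3, [-5.0, -5.1, -5.2], ligand="PTU", start=3)
    rows = summarize(asg1 + asg2, poses1 + poses2, alleles1 + alleles2)
    assert [(r.ligand_id, r.count_B, r.count_F) for r in rows] == [
        ("MMZ", 2, 0), ("PTU", 0, 3)]


def test_matches_brute_force_grouping_oracle(rng):
    """Counts, medians and lowest pocket equal an independent tally on
    random groups (statistics module median as the second opinion)."""
    import statistics

    labels3 = ["B", "F", "O"]
    for _ in range(200):
        n = int(rng.integers(1, 25))
        labels = [labels3[i] for i in rng.integers(0, 3, size=n)]
        scores = np.round(rng.normal(-4, 1, size=n), 3).tolist()
        asg, poses, alleles = _group(labels, scores)
        row = summarize(asg, poses, alleles)[0]
        for pocket in labels3:
            members = [s for s, l in zip(scores, labels) if l == pocket]
            assert row.count(pocket) == len(members)
            if members:
                assert row.median(pocket) == pytest.approx(statistics.median(members))
            else:
                assert row.median(pocket) is None
        assert row.lowest_pocket == labels[int(np.argmin(scores))]


class TestScoreDistribution:
    def test_constant_scores(self):
        _, poses, alleles = _group(["F"] * 4, [-5.0] * 4)
        summary = score_distribution(poses, alleles)[("B*38:02_M", "MMZ")]
        assert summary == FiveNumberSummary(-5.0, -5.0, -5.0, -5.0, -5.0)

    def test_1_to_100_quartiles(self):
        scores = [float(i) for i in range(1, 101)]
        _, poses, alleles = _group(["F"] * 100, scores)
        s = score_distribution(poses, alleles)[("B*38:02_M", "MMZ")]
        assert s.median == pytest.approx(50.5)
        assert s.q1 == pytest.approx(25.75)   # linear interpolation rule
        assert s.q3 == pytest.approx(75.25)
        assert (s.minimum, s.maximum) == (1.0, 100.0)

    def test_group_order_stable(self):
        _, p1, a1 = _group(["F"], [-1.0], allele="Z")
        _, p2, a2 = _group(["F"], [-2.0], allele="A", start=2)
        keys = list(score_distribution(p1 + p2, a1 + a2))
        assert keys == [("Z", "MMZ"), ("A", "MMZ")]
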