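"""Per-group docking summaries: pocket counts, per-pocket median scores,
the pocket of the lowest-scoring pose, and boxplot-ready five-number score
summaries for multi-run analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import LigandPose
from .pockets import PocketAssignment

__all__ = [
    "PoseSummaryRow",
    "FiveNumberSummary",
    "summarize",
    "score_distribution",
    "render_row",
    "render_table",
]

_POCKETS = ("B", "F", "O")


@dataclass(frozen=True)
class PoseSummaryRow:
    """One allele x drug x search-space row: lowest-pose pocket, per-pocket
    pose counts, and per-pocket median scores (None when the pocket holds
    no poses)."""

    allele: str
    ligand_id: str
    search_space: str
    lowest_pocket: str
    count_B: int
    count_F: int
    count_O: int
    median_B: float | None
    median_F: float | None
    median_O: float | None

    def count(self, pocket: str) -> int:
        return getattr(self, f"count_{pocket}")

    def median(self, pocket: str) -> float | None:
        return getattr(self, f"median_{pocket}")


def summarize(
    assignments: list[PocketAssignment],
    poses: list[LigandPose],
    alleles: list[str],
) -> list[PoseSummaryRow]:
    """One summary row per (allele, ligand, search_space) group.

    ``assignments``, ``poses`` and ``alleles`` are aligned 1:1 per pose.
    The median of an even-sized pocket is the mean of the two central
    scores; an empty pocket has no median. The lowest pocket is the label
    of the minimum-score pose, ties broken by lowest pose index. Groups are
    emitted in first-appearance order.
    """
    if not (len(assignments) == len(poses) == len(alleles)):
        raise ValueError("assignments, poses and alleles must be aligned 1:1")
    groups: dict[tuple[str, str, str], list[int]] = {}
    for i, (pose, allele) in enumerate(zip(poses, alleles)):
        groups.setdefault((allele, pose.ligand_id, pose.search_space), []).append(i)

    rows = []
    for (allele, ligand_id, space), indices in groups.items():
        scores_by_pocket: dict[str, list[float]] = {p: [] for p in _POCKETS}
        for i in indices:
            scores_by_pocket[assignments[i].label].append(poses[i].score)
        best = min(indices, key=lambda i: (poses[i].score, i))
        counts = {p: len(scores_by_pocket[p]) for p in _POCKETS}
        medians = {
            p: (float(np.median(scores_by_pocket[p])) if scores_by_pocket[p] else None)
            for p in _POCKETS
        }
        rows.append(
            PoseSummaryRow(
                allele=allele,
                ligand_id=ligand_id,
                search_space=space,
                lowest_pocket=assignments[best].label,
                count_B=counts["B"],
                count_F=counts["F"],
                count_O=counts["O"],
                median_B=medians["B"],
                median_F=medians["F"],
                median_O=medians["O"],
            )
        )
    return rows


@dataclass(frozen=True)
class FiveNumberSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float


def score_distribution(
    poses: list[LigandPose], alleles: list[str]
) -> dict[tuple[str, str], FiveNumberSummary]:
    """Five-number score summaries per (allele, ligand) group, suitable for
    boxplot rendering of multi-run docking (e.g. 100 runs per combination).

    Quartiles use linear interpolation between closest ranks. Groups keep
    first-appearance order; empty groups cannot arise (a group exists only
    if a pose created it).
    """
    if len(poses) != len(alleles):
        raise ValueError("poses and alleles must be aligned 1:1")
    groups: dict[tuple[str, str], list[float]] = {}
    for pose, allele in zip(poses, alleles):
        groups.setdefault((allele, pose.ligand_id), []).append(pose.score)
    out = {}
    for key, scores in groups.items():
        arr = np.asarray(scores, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
        out[key] = FiveNumberSummary(
            minimum=float(arr.min()),
            q1=float(q1),
            median=float(med),
            q3=float(q3),
            maximum=float(arr.max()),
        )
    return out


def _fmt(median: float | None) -> str:
    return "N/A" if median is None else f"{median:.2f}"


def render_row(row: PoseSummaryRow, include_outside: bool | None = None) -> str:
    """Render the pocket columns of a summary row, e.g. ``F 1 -3.10 9 -4.39``.

    Column order: Lowest, B count, B median, F count, F median, and (for
    the extended Top3 search space, or when forced) O count and O median.
    Medians print to 2 decimals, empty pockets as ``N/A``.
    """
    if include_outside is None:
        include_outside = row.search_space == "Top3"
    fields = [
        row.lowest_pocket,
        str(row.count_B),
        _fmt(row.median_B),
        str(row.count_F),
        _fmt(row.median_F),
    ]
    if include_outside:
        fields += [str(row.count_O), _fmt(row.median_O)]
    return " ".join(fields)


def render_table(
    rows: list[PoseSummaryRow],
    status: dict[str, str] | None = None,
    mutation: dict[str, str] | None = None,
    sep: str = "\t",
) -> str:
    """Render rows as a TSV table with the standard column order
    (Status, Allele, Mutation, Lowest, B, Median, F, Median, O, Median)."""
    include_outside = any(r.search_space == "Top3" or r.count_O for r in rows)
    header = ["Status", "Allele", "Mutation", "Lowest", "B", "Median", "F", "Median"]
    if include_outside:
        header += ["O", "Median"]
    lines = [sep.join(header)]
    for row in rows:
        cells = [
            (status or {}).get(row.allele, ""),
            row.allele,
            (mutation or {}).get(row.allele, ""),
        ] + render_row(row, include_outside=include_outside).split(" ")
        lines.append(sep.join(cells))
    return "\n".join(lines) + "\n"
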