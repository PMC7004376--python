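"""Groove pocket modelling and docking-pose pocket assignment.

The class I peptide-binding groove contains six subsites (pockets A-F).
Docked ligand poses are assigned to the B pocket, the F pocket, or O
(outside the groove) by k-means clustering (k=2) of each pose's reference
atom (C1 by default), labelling each cluster by its nearest pocket
centroid, then relabelling any pose lying farther than ``groove_radius``
from both centroids as O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import get_reference_atom
from .model import LigandPose, Structure

__all__ = [
    "DEFAULT_POCKET_DEFINITIONS",
    "PocketModel",
    "PocketAssignment",
    "build_pocket_model",
    "cluster_poses",
    "label_clusters",
    "assign_pockets",
]

#: Residue positions (mature HLA-B numbering) defining the two pockets used
#: for labelling. The F-pocket set is the residues observed lining/
#: surrounding that pocket (77, 80, 81, 84, 95, 116, 123, 124, 143, 147)
#: plus canonical 146; the B-pocket set is the canonical literature set.
DEFAULT_POCKET_DEFINITIONS: dict[str, frozenset[int]] = {
    "B": frozenset({7, 9, 24, 25, 34, 45, 63, 66, 67, 70, 99}),
    "F": frozenset({77, 80, 81, 84, 95, 116, 123, 124, 143, 146, 147}),
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class PocketModel:
    """Named groove subsites as residue-position sets with 3-D centroids."""

    pockets: dict[str, tuple[frozenset[int], np.ndarray]]
    groove_radius: float = 12.0

    def __post_init__(self) -> None:
        if self.groove_radius <= 0:
            raise ValueError("groove_radius must be positive")
        allowed = set("ABCDEF")
        for label, (_, centroid) in self.pockets.items():
            if label not in allowed:
                raise ValueError(f"unknown pocket label {label!r}")
            if not np.all(np.isfinite(centroid)):
                raise ValueError(f"pocket {label}: non-finite centroid")

    def centroid(self, label: str) -> np.ndarray:
        return self.pockets[label][1]


@dataclass(frozen=True)
class PocketAssignment:
    """Final per-pose assignment: k-means cluster id plus B/F/O label."""

    pose_index: int
    cluster_id: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in ("B", "F", "O"):
            raise ValueError(f"label must be B, F or O, got {self.label!r}")


def build_pocket_model(
    structure: Structure,
    definitions: dict[str, frozenset[int]] | None = None,
    groove_radius: float = 12.0,
) -> PocketModel:
    """Build a pocket model from a structure.

    Each pocket centroid is the mean position of the side-chain atoms of
    its defining residues that are present in the structure. A pocket with
    no resolvable residue is an error.
    """
    definitions = definitions or DEFAULT_POCKET_DEFINITIONS
    pockets = {}
    for label, positions in definitions.items():
        coords = [
            atom.position
            for atom in structure.atoms
            if atom.residue_number in positions and atom.name not in BACKBONE_ATOMS
        ]
        if not coords:
            raise ValueError(
                f"pocket {label}: no side-chain atoms for residues "
                f"{sorted(positions)} in structure {structure.label!r}"
            )
        pockets[label] = (frozenset(positions), np.mean(coords, axis=0))
    return PocketModel(pockets=pockets, groove_radius=groove_radius)


def _lex_argmin(points: np.ndarray, keys: np.ndarray) -> int:
    """Index of the minimum of ``keys``; ties broken by lexicographically
    smallest coordinates, so the choice is independent of input order."""
    best = np.min(keys)
    candidates = np.flatnonzero(keys == best)
    if len(candidates) == 1:
        return int(candidates[0])
    tuples = [tuple(points[i]) for i in candidates]
    return int(candidates[min(range(len(tuples)), key=tuples.__getitem__)])


def cluster_poses(
    poses: list[LigandPose], k: int = 2, seed: int = 0
) -> np.ndarray:
    """k-means clustering of pose reference-atom coordinates.

    Initialisation is deterministic farthest-point seeding (first centre =
    point farthest from the data centroid, later centres maximise distance
    to the chosen set; exact ties broken by lexicographic coordinates), so
    the result is identical for any pose ordering and any seed. The
    ``seed`` argument is accepted for interface stability. Coincident
    points are tolerated: an emptied cluster keeps its previous centre.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(poses) < k:
        raise ValueError(f"need at least k={k} poses, got {len(poses)}")
    points = np.array([get_reference_atom(p).position for p in poses])

    centres = np.empty((k, 3))
    dist_to_mean = np.linalg.norm(points - points.mean(axis=0), axis=1)
    centres[0] = points[_lex_argmin(points, -dist_to_mean)]
    for j in range(1, k):
        dmin = np.min(
            np.linalg.norm(points[:, None, :] - centres[None, :j, :], axis=2), axis=1
        )
        centres[j] = points[_lex_argmin(points, -dmin)]

    labels = np.zeros(len(points), dtype=int)
    for _ in range(100):
        dists = np.linalg.norm(points[:, None, :] - centres[None, :, :], axis=2)
        new_labels = np.argmin(dists, axis=1)  # ties -> lowest cluster id
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for j in range(k):
            members = points[labels == j]
            if len(members):
                centres[j] = members.mean(axis=0)
    return labels


def label_clusters(
    poses: list[LigandPose],
    cluster_ids: np.ndarray,
    model: PocketModel,
) -> list[PocketAssignment]:
    """Label each cluster by the nearest of the B/F pocket centroids to the
    cluster mean, then relabel as O every pose whose reference atom lies
    farther than ``groove_radius`` from both centroids."""
    for needed in ("B", "F"):
        if needed not in model.pockets:
            raise ValueError(f"pocket model lacks the {needed} pocket")
    points = np.array([get_reference_atom(p).position for p in poses])
    cluster_ids = np.asarray(cluster_ids)
    cb, cf = model.centroid("B"), model.centroid("F")

    cluster_label: dict[int, str] = {}
    for cid in np.unique(cluster_ids):
        mean = points[cluster_ids == cid].mean(axis=0)
        cluster_label[int(cid)] = (
            "B" if np.linalg.norm(mean - cb) <= np.linalg.norm(mean - cf) else "F"
        )

    assignments = []
    for i, (point, cid) in enumerate(zip(points, cluster_ids)):
        label = cluster_label[int(cid)]
        if min(np.linalg.norm(point - cb), np.linalg.norm(point - cf)) > model.groove_radius:
            label = "O"
        assignments.append(PocketAssignment(pose_index=i, cluster_id=int(cid), label=label))
    return assignments


def assign_pockets(
    poses: list[LigandPose],
    model: PocketModel,
    k: int = 2,
    seed: int = 0,
) -> list[PocketAssignment]:
    """Cluster then label in one call (the usual entry point)."""
    return label_clusters(poses, cluster_poses(poses, k=k, seed=seed), model)
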