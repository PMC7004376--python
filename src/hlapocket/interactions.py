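"""Ligand-residue contact detection and the Thr80 interaction taxonomy.

Contacts follow LigPlot-style heavy-atom conventions: a hydrophobic
contact is a nonpolar (C or S) protein atom within a distance window of a
nonpolar ligand atom; a hydrogen bond is a donor-capable and an
acceptor-capable N/O/S pair within a cutoff (no explicit hydrogens, no
angle term). Each pose is then classified against a residue of interest
(position 80, threonine in the risk alleles):

* ``THR80_S``     - some contact at the position involves the ligand's
                    thiocarbonyl sulfur (the C=S group shared by
                    methimazole, propylthiouracil, MZY and TUL);
* ``OTHER_THR80`` - contacts at the position exist but none involve that
                    sulfur;
* ``NO_THR80``    - no contact at the position at all.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import Atom, LigandPose, Structure

__all__ = [
    "ContactParams",
    "InteractionRecord",
    "Thr80Class",
    "Thr80Summary",
    "find_thiocarbonyl_sulfur",
    "detect_contacts",
    "classify_thr80",
    "tabulate_thr80",
]


@dataclass(frozen=True)
class ContactParams:
    """Distance cutoffs (Angstrom). Defaults follow common LigPlot usage."""

    hphob_min: float = 2.9
    hphob_max: float = 3.9
    hbond_max: float = 3.35
    #: max S-C distance for the thiocarbonyl pattern (C=S is ~1.68 A)
    thio_bond_max: float = 1.85
    #: generic heavy-atom bond cutoff used when counting neighbours
    bond_max: float = 1.75

    def __post_init__(self) -> None:
        if not 0 < self.hphob_min <= self.hphob_max:
            raise ValueError("need 0 < hphob_min <= hphob_max")
        if self.hbond_max <= 0:
            raise ValueError("hbond_max must be positive")


@dataclass(frozen=True)
class InteractionRecord:
    residue_position: int
    residue_name: str
    protein_atom: str
    ligand_atom: str
    kind: str  # "hydrophobic" | "hbond"
    distance: float

    def __post_init__(self) -> None:
        if self.kind not in ("hydrophobic", "hbond"):
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


class Thr80Class(enum.Enum):
    NO_THR80 = "No Thr80"
    THR80_S = "Thr80-S"
    OTHER_THR80 = "Other Thr80"


# Donor/acceptor capability of protein heavy atoms. Backbone N donates,
# backbone O accepts, for every residue; side-chain rules per residue type.
_SIDECHAIN_DONORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"}, "TRP": {"NE1"},
    "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"},
}
_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"OD1"}, "GLN": {"OE1"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}


def _protein_is_donor(atom: Atom) -> bool:
    if atom.name == "N":
        return True
    return atom.name in _SIDECHAIN_DONORS.get(atom.residue_name, set())


def _protein_is_acceptor(atom: Atom) -> bool:
    if atom.name in ("O", "OXT"):
        return True
    return atom.name in _SIDECHAIN_ACCEPTORS.get(atom.residue_name, set())


def _ligand_polar_roles(
    atom: Atom, annotations: dict[str, tuple[bool, bool]] | None
) -> tuple[bool, bool]:
    """(donor, acceptor) capability of a ligand heavy atom.

    Per-ligand annotations (atom name -> (donor, acceptor)) override the
    element default: N and O are treated as both donor- and
    acceptor-capable, S as acceptor only.
    """
    if annotations and atom.name in annotations:
        return annotations[atom.name]
    if atom.element in ("N", "O"):
        return True, True
    if atom.element == "S":
        return False, True
    return False, False


def find_thiocarbonyl_sulfur(
    pose: LigandPose, params: ContactParams = ContactParams()
) -> str | None:
    """Name of the pose's thiocarbonyl (C=S) sulfur atom, or None.

    The pattern is a terminal sulfur (exactly one bonded heavy atom within
    ``thio_bond_max``) whose partner is a carbon with at least two further
    neighbours (a ring or chain carbon). A thioether sulfur (C-S-C) has two
    bonded partners and fails the pattern; absence is a valid outcome.
    """
    coords = pose.coordinates()
    for i, atom in enumerate(pose.atoms):
        if atom.element != "S":
            continue
        dists = np.linalg.norm(coords - coords[i], axis=1)
        partners = [
            j for j in range(len(pose.atoms))
            if j != i and dists[j] <= params.thio_bond_max
            and pose.atoms[j].element != "H"
        ]
        if len(partners) != 1:
            continue
        j = partners[0]
        if pose.atoms[j].element != "C":
            continue
        cd = np.linalg.norm(coords - coords[j], axis=1)
        neighbours = sum(
            1 for m in range(len(pose.atoms))
            if m not in (i, j) and cd[m] <= params.bond_max
            and pose.atoms[m].element != "H"
        )
        if neighbours >= 2:
            return atom.name
    return None


def detect_contacts(
    structure: Structure,
    pose: LigandPose,
    params: ContactParams = ContactParams(),
    ligand_annotations: dict[str, tuple[bool, bool]] | None = None,
) -> list[InteractionRecord]:
    """All hydrophobic contacts and hydrogen bonds between a protein
    structure and one ligand pose, sorted by distance.

    Hydrophobic: protein C/S atom and ligand C/S atom with separation in
    [hphob_min, hphob_max]. Hydrogen bond: N/O/S pair within hbond_max
    where one side can donate and the other accept (either direction).
    """
    overlap = {a.serial for a in structure.atoms} & {a.serial for a in pose.atoms}
    if overlap:
        raise ValueError(
            f"structure and pose share atom serials (e.g. {sorted(overlap)[:3]}); "
            "renumber one of them"
        )
    prot_atoms = [a for a in structure.atoms if a.element != "H"]
    lig_atoms = [a for a in pose.atoms if a.element != "H"]
    prot_xyz = np.array([a.position for a in prot_atoms])
    lig_xyz = np.array([a.position for a in lig_atoms])

    cutoff = max(params.hphob_max, params.hbond_max)
    pairs = cKDTree(prot_xyz).query_ball_tree(cKDTree(lig_xyz), r=cutoff)

    records: list[InteractionRecord] = []
    for pi, lig_indices in enumerate(pairs):
        pa = prot_atoms[pi]
        for li in lig_indices:
            la = lig_atoms[li]
            d = float(np.linalg.norm(pa.position - la.position))
            if (
                pa.element in ("C", "S")
                and la.element in ("C", "S")
                and params.hphob_min <= d <= params.hphob_max
            ):
                records.append(
                    InteractionRecord(
                        residue_position=pa.residue_number,
                        residue_name=pa.residue_name,
                        protein_atom=pa.name,
                        ligand_atom=la.name,
                        kind="hydrophobic",
                        distance=d,
                    )
                )
            if (
                pa.element in ("N", "O", "S")
                and la.element in ("N", "O", "S")
                and d <= params.hbond_max
            ):
                lig_donor, lig_acceptor = _ligand_polar_roles(la, ligand_annotations)
                if (_protein_is_donor(pa) and lig_acceptor) or (
                    _protein_is_acceptor(pa) and lig_donor
                ):
                    records.append(
                        InteractionRecord(
                            residue_position=pa.residue_number,
                            residue_name=pa.residue_name,
                            protein_atom=pa.name,
                            ligand_atom=la.name,
                            kind="hbond",
                            distance=d,
                        )
                    )
    records.sort(key=lambda r: (r.distance, r.residue_position, r.protein_atom, r.ligand_atom))
    return records


def classify_thr80(
    records: list[InteractionRecord],
    pose: LigandPose,
    position: int = 80,
    structure: Structure | None = None,
    params: ContactParams = ContactParams(),
) -> Thr80Class:
    """Classify one pose's relationship to the residue of interest.

    If ``structure`` is given, the position must exist in it. The
    thiocarbonyl sulfur is located on the pose; any contact at the position
    involving that sulfur gives THR80_S, any other contact at the position
    gives OTHER_THR80, otherwise NO_THR80.
    """
    if structure is not None and not structure.atoms_of_residue(position):
        raise ValueError(f"position {position} absent from structure {structure.label!r}")
    at_position = [r for r in records if r.residue_position == position]
    if not at_position:
        return Thr80Class.NO_THR80
    s_name = find_thiocarbonyl_sulfur(pose, params)
    if s_name is not None and any(r.ligand_atom == s_name for r in at_position):
        return Thr80Class.THR80_S
    return Thr80Class.OTHER_THR80


@dataclass(frozen=True)
class Thr80Summary:
    """Per allele x drug tally of pose classes plus the class of the
    lowest-scoring (most favourable) pose."""

    n_no_thr80: int
    n_thr80_s: int
    n_other_thr80: int
    most_favourable: Thr80Class

    @property
    def total(self) -> int:
        return self.n_no_thr80 + self.n_thr80_s + self.n_other_thr80


def tabulate_thr80(
    classes: list[Thr80Class], scores: list[float]
) -> Thr80Summary:
    """Tally pose classes and pick the class of the minimum-score pose
    (ties broken by lowest pose index)."""
    if not classes:
        raise ValueError("cannot tabulate an empty pose set")
    if len(classes) != len(scores):
        raise ValueError("classes and scores must have equal length")
    best = min(range(len(scores)), key=lambda i: (scores[i], i))
    return Thr80Summary(
        n_no_thr80=sum(c is Thr80Class.NO_THR80 for c in classes),
        n_thr80_s=sum(c is Thr80Class.THR80_S for c in classes),
        n_other_thr80=sum(c is Thr80Class.OTHER_THR80 for c in classes),
        most_favourable=classes[best],
    )
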