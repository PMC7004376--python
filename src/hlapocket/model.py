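"""Core in-memory containers shared across the analysis modules.

Coordinates are in Angstrom, docking scores in kcal/mol (lower = more
favourable), residue numbers are taken verbatim from the source file
(author numbering); mapping to mature HLA numbering is an explicit,
separate step (see :mod:`hlapocket.msa`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "LigandPose",
    "PSSM",
    "SEARCH_SPACES",
    "AMINO_ACIDS",
]

#: Docking search-space tags: the peptide-binding groove box, or the box
#: covering the three largest cavities found on the protein surface.
SEARCH_SPACES = ("PBG", "Top3")

#: Canonical 20 amino acids, the column order of a binding-motif matrix.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Atom:
    """One atom record.

    ``position`` is a length-3 float array (Angstrom). ``residue_number``
    is whatever the source file said; no renumbering happens at parse time.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"atom position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial} {self.name!r} has non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name!r} has an empty element symbol")
        object.__setattr__(self, "position", pos)


@dataclass
class Structure:
    """An ordered collection of atoms with a free-text label.

    Labels follow the convention of suffixing crystal structures with
    ``_S`` and homology models with ``_M`` (e.g. ``B*27:05_S``), but any
    label is accepted.
    """

    atoms: list[Atom]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"structure {self.label!r} has no atoms")
        keys = [(a.chain, a.residue_number, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(
                f"structure {self.label!r}: duplicate atom (chain, residue, name) = {dup}"
            )

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def atoms_of_residue(self, residue_number: int, chain: str | None = None) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.residue_number == residue_number and (chain is None or a.chain == chain)
        ]

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class LigandPose:
    """One docked ligand conformation.

    The designated reference atom (default name ``C1``) is the single
    atom used for pose clustering, so chemically dissimilar ligands with
    different atom counts can be clustered together.
    """

    atoms: list[Atom]
    score: float
    run_id: int
    search_space: str
    ligand_id: str = ""
    reference_atom_name: str = "C1"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("ligand pose has no atoms")
        if not np.isfinite(self.score):
            raise ValueError(f"pose run_id={self.run_id}: score is not finite")
        if self.search_space not in SEARCH_SPACES:
            raise ValueError(
                f"pose run_id={self.run_id}: search_space {self.search_space!r} "
                f"not in {SEARCH_SPACES}"
            )

    def reference_atom(self) -> Atom:
        """The clustering reference atom; see :func:`hlapocket.io.get_reference_atom`."""
        from .io import get_reference_atom

        return get_reference_atom(self)

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


@dataclass
class PSSM:
    """A 9x20 position-specific score matrix summarising an allele's
    peptide-binding motif (9-mer positions x 20 amino acids)."""

    allele: str
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (9, 20):
            raise ValueError(
                f"PSSM for {self.allele}: expected shape (9, 20), got {scores.shape}"
            )
        if not np.all(np.isfinite(scores)):
            raise ValueError(f"PSSM for {self.allele}: non-finite entries")
        self.scores = scores
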