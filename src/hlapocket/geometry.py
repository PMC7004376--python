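"""Rigid-body structure comparison (Kabsch superposition RMSD)."""

from __future__ import annotations

import warnings
from collections.abc import Callable, Iterable

import numpy as np
from scipy.spatial.transform import Rotation

from .model import Atom, Structure

__all__ = ["superpose_rmsd", "kabsch_rmsd", "match_atoms"]


def match_atoms(
    a: Structure,
    b: Structure,
    selection: Callable[[Atom], bool] | Iterable[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair atoms between two structures by (chain, residue_number, name).

    ``selection`` restricts the match: either a predicate over atoms or an
    iterable of atom names (e.g. ``("CA",)`` for an alpha-carbon fit).
    Returns the two matched coordinate arrays in a deterministic order.
    """
    if selection is None:
        pred = lambda atom: True  # noqa: E731
    elif callable(selection):
        pred = selection
    else:
        names = set(selection)
        pred = lambda atom: atom.name in names  # noqa: E731

    index_b = {
        (atom.chain, atom.residue_number, atom.name): atom
        for atom in b.atoms
        if pred(atom)
    }
    xs, ys = [], []
    for atom in a.atoms:
        if not pred(atom):
            continue
        key = (atom.chain, atom.residue_number, atom.name)
        if key in index_b:
            xs.append(atom.position)
            ys.append(index_b[key].position)
    if not xs:
        raise ValueError(
            f"no matched atoms between {a.label!r} and {b.label!r} under the selection"
        )
    return np.array(xs), np.array(ys)


def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares RMSD between paired coordinate sets after optimal
    rigid superposition (translation + proper rotation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"coordinate sets must both be (n, 3); got {x.shape} vs {y.shape}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # align_vectors minimises sum |R a_i - b_i|^2 and reports the residual
    # sqrt(sum of squared distances) directly. Collinear/planar sets make
    # the optimal rotation non-unique (the RMSD is still well defined).
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="Optimal rotation is not uniquely"
        )
        _, rssd = Rotation.align_vectors(yc, xc)
    return float(rssd) / np.sqrt(len(x))


def superpose_rmsd(
    a: Structure,
    b: Structure,
    selection: Callable[[Atom], bool] | Iterable[str] | None = None,
) -> float:
    """RMSD between two structures after optimal rigid superposition.

    Atoms are paired by (chain, residue_number, name); ``selection``
    optionally restricts the paired set. Symmetric in its arguments.
    """
    x, y = match_atoms(a, b, selection)
    return kabsch_rmsd(x, y)
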