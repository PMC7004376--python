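"""Scanning aligned allele sequences for residues unique to risk alleles.

Positions are reported in mature-protein, 1-based numbering (signal peptide
removed); a column index is mapped to a mature position via the ungapped
index of a designated reference row plus a caller-supplied offset. The
known risk-discriminating positions in the anti-thyroid-drug setting are
Cys67 and Thr80 of HLA-B, and the motivating near-pair is B*38:02 vs
B*38:01, which differ only by Thr80Ile.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "STATUSES",
    "AlleleAlignment",
    "DiscriminatingPosition",
    "map_numbering",
    "scan_unique_residues",
    "mutation_label",
]

#: Allowed row statuses. ``possible_risk`` marks alleles (like B*38:01)
#: whose association is plausible but unconfirmed; they are excluded from
#: both sides of the scan unless explicitly listed.
STATUSES = ("risk", "possible_risk", "control", "common")

GAP_CHARS = set("-.")


@dataclass
class AlleleAlignment:
    """Aligned allele protein sequences with status labels.

    rows: (allele name, status, aligned residue string), equal lengths.
    numbering_offset: added to the reference row's ungapped 1-based index
    to obtain the mature-protein position (0 for pre-trimmed sequences).
    reference: name of the numbering reference row (default: first row).
    """

    rows: list[tuple[str, str, str]]
    numbering_offset: int = 0
    reference: str | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        width = len(self.rows[0][2])
        for name, status, seq in self.rows:
            if status not in STATUSES:
                raise ValueError(f"row {name!r}: unknown status {status!r}")
            if len(seq) != width:
                raise ValueError(
                    f"row {name!r}: length {len(seq)} != alignment width {width}"
                )
        names = [name for name, _, _ in self.rows]
        if len(set(names)) != len(names):
            raise ValueError("duplicate allele names in alignment")
        if self.reference is None:
            self.reference = self.rows[0][0]
        elif self.reference not in names:
            raise ValueError(f"reference row {self.reference!r} not in alignment")

    @property
    def width(self) -> int:
        return len(self.rows[0][2])

    def row(self, allele: str) -> tuple[str, str, str]:
        for item in self.rows:
            if item[0] == allele:
                return item
        raise KeyError(f"allele {allele!r} not in alignment")

    def by_status(self, statuses) -> list[tuple[str, str, str]]:
        statuses = set(statuses)
        return [r for r in self.rows if r[1] in statuses]


@dataclass(frozen=True)
class DiscriminatingPosition:
    """A mature position where every risk allele carries one residue that
    no control allele carries."""

    position: int
    risk_residue: str
    control_residues: frozenset[str]

    def __post_init__(self) -> None:
        if self.risk_residue in self.control_residues:
            raise ValueError("risk residue cannot appear among control residues")


def map_numbering(column: int, alignment: AlleleAlignment) -> int:
    """Map a 0-based alignment column to a mature-protein position.

    The position is the 1-based ungapped index of the reference row at that
    column, plus ``numbering_offset``. A column where the reference row has
    a gap carries no reference position and raises.
    """
    if not 0 <= column < alignment.width:
        raise IndexError(f"column {column} outside alignment width {alignment.width}")
    _, _, ref_seq = alignment.row(alignment.reference)
    if ref_seq[column] in GAP_CHARS:
        raise ValueError(
            f"column {column} falls on a gap in reference row {alignment.reference!r}"
        )
    ungapped = sum(1 for ch in ref_seq[: column + 1] if ch not in GAP_CHARS)
    return ungapped + alignment.numbering_offset


def _column_to_position(alignment: AlleleAlignment) -> dict[int, int]:
    _, _, ref_seq = alignment.row(alignment.reference)
    mapping = {}
    ungapped = 0
    for col, ch in enumerate(ref_seq):
        if ch not in GAP_CHARS:
            ungapped += 1
            mapping[col] = ungapped + alignment.numbering_offset
    return mapping


def scan_unique_residues(
    alignment: AlleleAlignment,
    risk_statuses=("risk",),
    control_statuses=("control",),
) -> list[DiscriminatingPosition]:
    """Positions where all risk rows share one residue absent from every
    control row.

    Gaps never match a residue: a column with a gap in any risk row is
    skipped, and a control gap does not count as carrying the risk residue.
    Columns where the reference row is gapped have no mature position and
    are skipped. ``possible_risk`` rows take part only if their status is
    explicitly listed in one of the groups.
    """
    risk_rows = alignment.by_status(risk_statuses)
    control_rows = alignment.by_status(control_statuses)
    if not risk_rows or not control_rows:
        raise ValueError("scan requires at least one risk row and one control row")
    col_to_pos = _column_to_position(alignment)
    hits = []
    for col in range(alignment.width):
        if col not in col_to_pos:
            continue
        risk_res = {seq[col] for _, _, seq in risk_rows}
        if len(risk_res) != 1:
            continue
        residue = next(iter(risk_res))
        if residue in GAP_CHARS:
            continue
        control_res = {seq[col] for _, _, seq in control_rows} - GAP_CHARS
        if residue in control_res:
            continue
        hits.append(
            DiscriminatingPosition(
                position=col_to_pos[col],
                risk_residue=residue,
                control_residues=frozenset(control_res),
            )
        )
    return hits


def mutation_label(
    alignment: AlleleAlignment,
    allele: str,
    position: int,
    reference_residue: str,
) -> str:
    """Reference-relative residue label for an allele at a mature position.

    Returns e.g. ``"N80T"`` when the allele carries T where the reference
    residue is N, or ``"N80"`` when they agree — the convention used when
    tabulating per-allele position-80 states.
    """
    _, _, seq = alignment.row(allele)
    col_to_pos = _column_to_position(alignment)
    cols = [c for c, p in col_to_pos.items() if p == position]
    if not cols:
        raise ValueError(f"position {position} not resolvable in the reference row")
    observed = seq[cols[0]]
    if observed in GAP_CHARS:
        raise ValueError(f"allele {allele!r} has a gap at position {position}")
    if observed == reference_residue:
        return f"{reference_residue}{position}"
    return f"{reference_residue}{position}{observed}"
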