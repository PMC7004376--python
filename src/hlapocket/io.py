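"""Readers and writers for the external formats the pipeline consumes.

Structures and poses arrive as PDB or PDBQT (the AutoDock dialect: same
fixed-width coordinate columns, with partial-charge and atom-type columns
appended; both extras are tolerated and ignored beyond element recovery).
Sequences and alignments are FASTA (via Biopython), tables are CSV (via
pandas), binding-motif matrices are whitespace-delimited 9x20 text.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import AMINO_ACIDS, Atom, LigandPose, PSSM, Structure

__all__ = [
    "ParseError",
    "read_structure",
    "write_structure",
    "read_pose_set",
    "write_pose_set",
    "get_reference_atom",
    "read_alignment",
    "write_alignment",
    "read_pssm",
    "write_pssm",
    "read_frequency_table",
    "write_frequency_table",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


# AutoDock atom types that are not plain element symbols.
_AUTODOCK_TYPES = {
    "A": "C",   # aromatic carbon
    "OA": "O",  # H-bond accepting oxygen
    "NA": "N",  # H-bond accepting nitrogen
    "SA": "S",  # H-bond accepting sulfur
    "HD": "H",  # polar hydrogen
    "HS": "H",
    "NS": "N",
    "OS": "O",
}


def _element_from_fields(name: str, tail: str, fmt: str) -> str:
    """Recover the element symbol from the columns after z (PDB element
    column, or AutoDock type column in PDBQT), falling back to the atom name."""
    tail = tail.strip()
    if tail:
        token = tail.split()[-1].upper()
        if fmt == "pdbqt" and token in _AUTODOCK_TYPES:
            return _AUTODOCK_TYPES[token]
        if token.isalpha() and len(token) <= 2:
            return token.capitalize()
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ParseError(f"cannot derive element for atom name {name!r}")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int, fmt: str, serial_fallback: int) -> Atom:
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed coordinate field: {line.rstrip()!r}") from exc
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = serial_fallback
    name = line[12:16].strip()
    residue_name = line[17:20].strip()
    chain = line[21:22].strip() or "A"
    try:
        residue_number = int(line[22:26])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed residue number: {line.rstrip()!r}") from exc
    element = _element_from_fields(name, line[66:] if len(line) > 66 else "", fmt)
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_number=residue_number,
        chain=chain,
        position=np.array([x, y, z]),
    )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("pdb", "pdbqt"):
            raise ValueError(f"unknown structure format {fmt!r}")
        return fmt
    return "pdbqt" if path.suffix.lower() == ".pdbqt" else "pdb"


def read_structure(path: str | Path, format: str | None = None, label: str | None = None) -> Structure:
    """Read ATOM/HETATM records from a PDB or PDBQT file into a Structure.

    PDBQT partial-charge and atom-type columns are tolerated; the type
    column is consulted only to recover the element symbol.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                atoms.append(_parse_atom_line(line, lineno, fmt, len(atoms) + 1))
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms=atoms, label=label if label is not None else path.stem)


_PDB_ATOM_FMT = (
    "{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
    "{resnum:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2s}\n"
)


def _format_atom(atom: Atom, hetatm: bool = False) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    return _PDB_ATOM_FMT.format(
        record="HETATM" if hetatm else "ATOM",
        serial=atom.serial,
        name=name,
        altloc=" ",
        resname=atom.residue_name,
        chain=atom.chain,
        resnum=atom.residue_number,
        icode=" ",
        x=atom.position[0],
        y=atom.position[1],
        z=atom.position[2],
        occ=1.0,
        b=0.0,
        element=atom.element.upper(),
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as standard PDB ATOM records (3-decimal coordinates)."""
    with open(path, "w") as fh:
        for atom in structure.atoms:
            fh.write(_format_atom(atom))
        fh.write("END\n")


# --- pose sets -------------------------------------------------------------

_SCORE_RE = re.compile(
    r"^REMARK\s+(?:SCORE|VINA RESULT:?|ADFR RESULT:?)\s+(-?\d+(?:\.\d+)?)", re.IGNORECASE
)


def read_pose_set(
    path: str | Path,
    scores: str | Path | dict[int, float] | None = None,
    search_space: str = "PBG",
    ligand_id: str = "",
    reference_atom_name: str = "C1",
) -> list[LigandPose]:
    """Read a multi-model PDB/PDBQT pose file into LigandPose objects.

    Scores come from per-model ``REMARK SCORE <x>`` lines (AutoDock-style
    result remarks are also accepted), or from a sidecar keyed by run_id
    (CSV path with ``run_id,score`` columns, or a mapping). If both are
    present for a pose they must agree exactly; a pose with no resolvable
    score is an error.
    """
    path = Path(path)
    fmt = _infer_format(path, None)
    sidecar: dict[int, float] | None = None
    if scores is not None:
        if isinstance(scores, dict):
            sidecar = {int(k): float(v) for k, v in scores.items()}
        else:
            df = pd.read_csv(scores)
            if not {"run_id", "score"}.issubset(df.columns):
                raise ParseError(f"{scores}: score sidecar needs run_id and score columns")
            if df["run_id"].duplicated().any():
                raise ParseError(f"{scores}: duplicate run_id in score sidecar")
            sidecar = dict(zip(df["run_id"].astype(int), df["score"].astype(float)))

    poses: list[LigandPose] = []
    seen_runs: set[int] = set()
    model_id: int | None = None
    model_atoms: list[Atom] = []
    embedded: float | None = None
    next_auto_id = 1

    def flush(lineno: int) -> None:
        nonlocal model_id, model_atoms, embedded, next_auto_id
        if not model_atoms:
            model_id, embedded = None, None
            return
        run_id = model_id if model_id is not None else next_auto_id
        next_auto_id = max(next_auto_id, run_id) + 1
        if run_id in seen_runs:
            raise ParseError(f"{path}: duplicate run_id {run_id}")
        seen_runs.add(run_id)
        score = embedded
        if sidecar is not None and run_id in sidecar:
            if score is not None and abs(score - sidecar[run_id]) > 1e-9:
                raise ParseError(
                    f"{path}: run_id {run_id}: embedded score {score} disagrees "
                    f"with sidecar score {sidecar[run_id]}"
                )
            score = sidecar[run_id] if score is None else score
        if score is None:
            raise ParseError(f"{path}: pose run_id {run_id} has no resolvable score")
        poses.append(
            LigandPose(
                atoms=list(model_atoms),
                score=score,
                run_id=run_id,
                search_space=search_space,
                ligand_id=ligand_id,
                reference_atom_name=reference_atom_name,
            )
        )
        model_id, model_atoms, embedded = None, [], None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                flush(lineno)
                try:
                    model_id = int(line.split()[1])
                except (IndexError, ValueError):
                    model_id = None
            elif line.startswith("ENDMDL"):
                flush(lineno)
            elif line.startswith(("ATOM", "HETATM")):
                model_atoms.append(_parse_atom_line(line, lineno, fmt, len(model_atoms) + 1))
            else:
                m = _SCORE_RE.match(line)
                if m:
                    embedded = float(m.group(1))
    flush(-1)
    if not poses:
        raise ParseError(f"{path}: no poses found")
    return poses


def write_pose_set(poses: list[LigandPose], path: str | Path) -> None:
    """Write poses as a multi-model PDB file with embedded REMARK SCORE lines."""
    with open(path, "w") as fh:
        for pose in poses:
            fh.write(f"MODEL {pose.run_id:>8d}\n")
            fh.write(f"REMARK SCORE {pose.score:.4f}\n")
            for atom in pose.atoms:
                fh.write(_format_atom(atom, hetatm=True))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def get_reference_atom(pose: LigandPose) -> Atom:
    """Return the pose's designated clustering reference atom (default C1)."""
    for atom in pose.atoms:
        if atom.name == pose.reference_atom_name:
            return atom
    available = sorted({a.name for a in pose.atoms})
    raise ValueError(
        f"pose run_id={pose.run_id}: no atom named {pose.reference_atom_name!r}; "
        f"available names: {available}"
    )


# --- alignments ------------------------------------------------------------

def read_alignment(
    path: str | Path,
    labels: str | Path | dict[str, str] | None = None,
    numbering_offset: int = 0,
    reference: str | None = None,
):
    """Read an aligned FASTA into an AlleleAlignment.

    Row statuses come from ``labels`` (a CSV with ``allele,status`` columns
    or a mapping), or from a ``name|status`` suffix convention in the FASTA
    headers. All records must share one aligned length.
    """
    from .msa import AlleleAlignment

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    label_map: dict[str, str] = {}
    if labels is not None:
        if isinstance(labels, dict):
            label_map = dict(labels)
        else:
            df = pd.read_csv(labels)
            label_map = dict(zip(df["allele"], df["status"]))
    rows = []
    seen = set()
    for rec in records:
        name = rec.id
        status = None
        if "|" in name:
            name, status = name.split("|", 1)
        if name in seen:
            raise ParseError(f"{path}: duplicate allele name {name!r}")
        seen.add(name)
        status = label_map.get(name, status)
        if status is None:
            raise ParseError(f"{path}: no status label for allele {name!r}")
        rows.append((name, status, str(rec.seq).upper()))
    lengths = {len(seq) for _, _, seq in rows}
    if len(lengths) != 1:
        raise ParseError(f"{path}: ragged alignment, lengths {sorted(lengths)}")
    return AlleleAlignment(rows=rows, numbering_offset=numbering_offset, reference=reference)


def write_alignment(alignment, path: str | Path, embed_status: bool = False) -> None:
    with open(path, "w") as fh:
        for name, status, seq in alignment.rows:
            header = f"{name}|{status}" if embed_status else name
            fh.write(f">{header}\n{seq}\n")


# --- PSSMs -----------------------------------------------------------------

def read_pssm(path: str | Path, allele: str | None = None) -> PSSM:
    """Read a whitespace-delimited 9x20 motif matrix.

    The first row is a header of 20 one-letter amino-acid codes (any order;
    columns are re-ordered to the canonical ACDE... order). Each data row
    may start with a position index, which is ignored.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty PSSM file")
    header = [t.upper() for t in lines[0]]
    if sorted(header) != sorted(AMINO_ACIDS):
        raise ParseError(f"{path}: header must list the 20 amino acids, got {header}")
    order = [header.index(aa) for aa in AMINO_ACIDS]
    rows = []
    for tokens in lines[1:]:
        if len(tokens) == 21:
            tokens = tokens[1:]
        if len(tokens) != 20:
            raise ParseError(f"{path}: expected 20 scores per row, got {len(tokens)}")
        vals = np.array([float(t) for t in tokens])
        rows.append(vals[order])
    if len(rows) != 9:
        raise ParseError(f"{path}: expected 9 positions, got {len(rows)}")
    return PSSM(allele=allele or path.stem, scores=np.array(rows))


def write_pssm(pssm: PSSM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(AMINO_ACIDS) + "\n")
        for i in range(9):
            fh.write(f"{i + 1} " + " ".join(f"{v:.6f}" for v in pssm.scores[i]) + "\n")


# --- frequency tables ------------------------------------------------------

_CORE_FREQ_COLS = ["allele", "case_freq", "study_control_freq", "case_n", "control_n"]


def read_frequency_table(path: str | Path):
    """Read a case/control/healthy allele-frequency CSV.

    Required columns: allele, case_freq, study_control_freq, case_n,
    control_n. Every other column is treated as a healthy-population
    frequency column named after the population; NaN entries mean the
    allele was not typed in that population.
    """
    from .alleles import FrequencyRecord

    df = pd.read_csv(path)
    missing = [c for c in _CORE_FREQ_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    pop_cols = [c for c in df.columns if c not in _CORE_FREQ_COLS]
    records = []
    for _, row in df.iterrows():
        healthy = [
            (pop, float(row[pop])) for pop in pop_cols if pd.notna(row[pop])
        ]
        records.append(
            FrequencyRecord(
                allele=str(row["allele"]),
                case_freq=float(row["case_freq"]),
                study_control_freq=float(row["study_control_freq"]),
                healthy_freqs=healthy,
                case_n=int(row["case_n"]),
                control_n=int(row["control_n"]),
            )
        )
    return records


def write_frequency_table(records, path: str | Path) -> None:
    pops: list[str] = []
    for rec in records:
        for pop, _ in rec.healthy_freqs:
            if pop not in pops:
                pops.append(pop)
    rows = []
    for rec in records:
        row = {
            "allele": rec.allele,
            "case_freq": rec.case_freq,
            "study_control_freq": rec.study_control_freq,
            "case_n": rec.case_n,
            "control_n": rec.control_n,
        }
        row.update({pop: freq for pop, freq in rec.healthy_freqs})
        rows.append(row)
    pd.DataFrame(rows, columns=_CORE_FREQ_COLS + pops).to_csv(path, index=False)
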