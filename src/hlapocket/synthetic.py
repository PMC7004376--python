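"""Synthetic inputs with planted ground truth for every pipeline stage.

Real inputs to this kind of analysis come from a docking engine (pose
clouds with scores), curated allele sequence databases, published
case/control frequency tables, and binding-motif predictors. None of those
are needed to exercise the analysis logic: this module generates

* a pseudo-protein "groove" whose B- and F-pocket residues ring two
  centres a configurable distance apart (default 15 A),
* ligand pose sets whose reference atoms scatter around planted pockets,
  with pocket-specific score distributions and an optional thiocarbonyl
  (C=S) group on the ligand template,
* allele sequence panels sharing planted residues in all risk alleles
  (Cys67/Thr80-style), with a single-residue possible-risk pair emulating
  B*38:02 vs B*38:01 (Thr80Ile),
* case/control/healthy frequency tables realising a planted odds ratio,
* PSSM panels with planted cluster structure and a near-duplicate pair.

A single root seed drives independent named substreams, so adding a call
on one stream never perturbs another stream's output, and a fixed config
reproduces byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from . import io as hio
from .alleles import FrequencyRecord
from .model import AMINO_ACIDS, Atom, LigandPose, PSSM, Structure
from .msa import AlleleAlignment
from .pockets import DEFAULT_POCKET_DEFINITIONS

__all__ = [
    "SimulationConfig",
    "AllelePanel",
    "stream_rng",
    "make_groove",
    "make_pose_set",
    "make_thr80_pose_set",
    "make_allele_panel",
    "make_pssm_panel",
    "write_bundle",
]

_STREAMS = {"structure": 0, "poses": 1, "sequences": 2, "frequencies": 3, "pssms": 4}

# Ligand atom serial numbers start here so a generated structure + pose
# pair never shares serials (contact detection rejects overlap).
_LIGAND_SERIAL_BASE = 9001


@dataclass
class SimulationConfig:
    """All knobs of the generator, chosen to emulate the study conditions.

    Pockets sit 15 A apart with a 1.5 A pose spread; 10 poses per
    allele/drug/search-space group; F-pocket scores for risk alleles are
    lower (more favourable) than B-pocket scores, matching the reported
    medians (about -4.4 vs -3.2 kcal/mol for methimazole). Cohorts default
    to 60 cases / 1200 controls and a planted odds ratio of 20, the
    magnitudes of the source association studies.
    """

    seed: int = 0
    # groove / poses
    pocket_center_B: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pocket_center_F: tuple[float, float, float] = (15.0, 0.0, 0.0)
    pocket_spread: float = 1.5
    groove_radius: float = 12.0
    n_poses_per_group: int = 10
    score_mean_B: float = -3.3
    score_sd_B: float = 0.3
    score_mean_F: float = -4.2
    score_sd_F: float = 0.4
    score_mean_O: float = -3.6
    score_sd_O: float = 0.4
    # allele panel
    n_risk: int = 2
    n_possible_risk: int = 1
    n_control: int = 5
    n_common: int = 4
    seq_length: int = 182
    planted_positions: tuple[tuple[int, str], ...] = ((67, "C"), (80, "T"))
    n_extra_polymorphisms: int = 12
    # frequencies
    planted_or: float = 20.0
    case_n: int = 60
    control_n: int = 1200
    n_healthy_pops: int = 6
    healthy_n: int = 2000
    healthy_log_sd: float = 0.5
    base_freq_range: tuple[float, float] = (0.05, 0.15)
    # PSSMs
    pssm_clusters: int = 2
    pssm_per_cluster: int = 4
    pssm_noise_frac: float = 0.05
    pssm_near_dup_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.pocket_spread <= 0:
            raise ValueError("pocket_spread must be positive")
        if self.planted_or < 1:
            raise ValueError("planted_or must be >= 1")
        for pos, res in self.planted_positions:
            if not 1 <= pos <= self.seq_length:
                raise ValueError(
                    f"planted position {pos} beyond sequence length {self.seq_length}"
                )
            if res not in AMINO_ACIDS:
                raise ValueError(f"planted residue {res!r} is not an amino acid")


def stream_rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible RNG for one named generator stream."""
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[stream],))
    )


def _random_rotation(rng: np.random.Generator) -> Rotation:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q))


# --- groove ------------------------------------------------------------------

# Side-chain atom offsets (relative to CB, in the residue's local frame)
# for the residue types placed in the pseudo-groove.
_RESIDUE_TYPES: dict[int, tuple[str, list[tuple[str, str, np.ndarray]]]] = {}


def _residue_type(position: int) -> tuple[str, list[tuple[str, str]]]:
    """(residue_name, extra side-chain atoms beyond CB) for a position.

    Position 80 is THR (OG1 donor/acceptor + CG2 carbon), 67 is CYS (SG),
    everything else ALA (CB only) — enough chemistry for distance-based
    contact logic without pretending to model real side chains.
    """
    if position == 80:
        return "THR", [("OG1", "O"), ("CG2", "C")]
    if position == 67:
        return "CYS", [("SG", "S")]
    return "ALA", []


def make_groove(
    config: SimulationConfig,
    definitions: dict[str, frozenset[int]] | None = None,
) -> Structure:
    """Pseudo-protein with side-chain atoms for the configured B- and
    F-pocket residues ringing the two pocket centres.

    Residues of each pocket are placed on a circle of radius 3.5 A around
    the pocket centre (evenly spaced directions sum to zero, so each
    pocket's side-chain centroid sits essentially at its centre). Residue
    numbering is mature 1-based; coordinates are deterministic for a fixed
    config.
    """
    definitions = definitions or DEFAULT_POCKET_DEFINITIONS
    centers = {
        "B": np.array(config.pocket_center_B),
        "F": np.array(config.pocket_center_F),
    }
    separation = np.linalg.norm(centers["F"] - centers["B"])
    if separation < 2 * config.pocket_spread:
        warnings.warn(
            f"pocket centres only {separation:.2f} A apart "
            f"(< 2 sigma = {2 * config.pocket_spread:.2f} A); pose clouds will overlap",
            stacklevel=2,
        )
    atoms: list[Atom] = []
    serial = 1
    for label in sorted(definitions):
        if label not in centers:
            continue
        center = centers[label]
        positions = sorted(definitions[label])
        n = len(positions)
        for idx, pos in enumerate(positions):
            theta = 2 * np.pi * idx / n
            u = np.array([np.cos(theta), np.sin(theta), 0.0])
            tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
            cb = center + 3.5 * u
            ca = center + 5.0 * u
            resname, extras = _residue_type(pos)
            residue_atoms = [
                ("N", "N", ca + np.array([0.0, 0.0, 1.45])),
                ("CA", "C", ca),
                ("C", "C", ca + 1.5 * tangent),
                ("O", "O", ca + 1.5 * tangent + np.array([0.0, 0.0, 1.23])),
                ("CB", "C", cb),
            ]
            for k, (name, element) in enumerate(extras):
                offset = 1.45 * tangent if k == 0 else -1.5 * tangent
                residue_atoms.append((name, element, cb + offset))
            for name, element, xyz in residue_atoms:
                atoms.append(
                    Atom(
                        serial=serial,
                        name=name,
                        element=element,
                        residue_name=resname,
                        residue_number=pos,
                        chain="A",
                        position=xyz,
                    )
                )
                serial += 1
    return Structure(atoms=atoms, label="synthetic_groove")


# --- ligand poses ------------------------------------------------------------

# Methimazole-like template: a five-membered C/N ring with an exocyclic
# C=S at the canonical 1.68 A bond length and an N-methyl tail. C1 is the
# thiocarbonyl carbon and the clustering reference atom.
_RING_TEMPLATE: list[tuple[str, str, tuple[float, float, float]]] = [
    ("C1", "C", (0.00, 0.00, 0.0)),
    ("N1", "N", (1.37, 0.00, 0.0)),
    ("C2", "C", (1.79, 1.30, 0.0)),
    ("C3", "C", (0.68, 2.10, 0.0)),
    ("N2", "N", (-0.42, 1.30, 0.0)),
    ("C4", "C", (-1.82, 1.76, 0.0)),
]
_THIO_S: tuple[str, str, tuple[float, float, float]] = ("S1", "S", (-0.98, -1.36, 0.0))


def _ligand_template(thiocarbonyl: bool) -> list[tuple[str, str, np.ndarray]]:
    atoms = [(n, e, np.array(p)) for n, e, p in _RING_TEMPLATE]
    if thiocarbonyl:
        n, e, p = _THIO_S
        atoms.append((n, e, np.array(p)))
    return atoms


def _instantiate_pose(
    template: list[tuple[str, str, np.ndarray]],
    rotation: Rotation,
    anchor_local: np.ndarray,
    anchor_world: np.ndarray,
    score: float,
    run_id: int,
    search_space: str,
    ligand_id: str,
) -> LigandPose:
    """Rigidly place the template so the chosen local anchor point lands at
    ``anchor_world``."""
    atoms = []
    for k, (name, element, local) in enumerate(template):
        xyz = anchor_world + rotation.apply(local - anchor_local)
        atoms.append(
            Atom(
                serial=_LIGAND_SERIAL_BASE + k,
                name=name,
                element=element,
                residue_name=ligand_id[:3] if ligand_id else "LIG",
                residue_number=1,
                chain="L",
                position=xyz,
            )
        )
    return LigandPose(
        atoms=atoms,
        score=score,
        run_id=run_id,
        search_space=search_space,
        ligand_id=ligand_id,
    )


def make_pose_set(
    config: SimulationConfig,
    n_B: int = 5,
    n_F: int = 5,
    n_O: int = 0,
    thiocarbonyl: bool = True,
    ligand_id: str = "MMZ",
    search_space: str = "PBG",
    rng: np.random.Generator | None = None,
    run_id_start: int = 1,
) -> tuple[list[LigandPose], list[str]]:
    """Pose set with planted pocket labels.

    Reference atoms (C1) are drawn from isotropic Gaussians around the
    planted pocket centres (sigma = ``pocket_spread``); O poses sit well
    outside the groove, beyond ``groove_radius`` from both centres. Scores
    are drawn from the pocket's score distribution. Returns the poses and
    the planted label list, which is never embedded in the poses.
    """
    rng = rng if rng is not None else stream_rng(config, "poses")
    cb = np.array(config.pocket_center_B)
    cf = np.array(config.pocket_center_F)
    midpoint = (cb + cf) / 2
    o_center = midpoint + np.array([0.0, config.groove_radius + 14.0, 0.0])
    template = _ligand_template(thiocarbonyl)
    c1_local = np.zeros(3)

    plan = [("B", cb, config.score_mean_B, config.score_sd_B)] * n_B
    plan += [("F", cf, config.score_mean_F, config.score_sd_F)] * n_F
    plan += [("O", o_center, config.score_mean_O, config.score_sd_O)] * n_O
    poses, truth = [], []
    for offset, (label, center, mu, sd) in enumerate(plan):
        target = center + rng.normal(scale=config.pocket_spread, size=3)
        poses.append(
            _instantiate_pose(
                template,
                _random_rotation(rng),
                c1_local,
                target,
                score=float(rng.normal(mu, sd)),
                run_id=run_id_start + offset,
                search_space=search_space,
                ligand_id=ligand_id,
            )
        )
        truth.append(label)
    return poses, truth


def make_thr80_pose_set(
    config: SimulationConfig,
    groove: Structure,
    n_contact: int = 4,
    n_away: int = 6,
    thiocarbonyl: bool = True,
    ligand_id: str = "MMZ",
    search_space: str = "PBG",
    rng: np.random.Generator | None = None,
    contact_distance: float = 3.4,
) -> tuple[list[LigandPose], list[str]]:
    """Pose set planted for the Thr80 taxonomy.

    ``n_contact`` poses place the ligand's thiocarbonyl sulfur (or, without
    a thiocarbonyl, the C1 carbon) exactly ``contact_distance`` from the
    CB carbon of residue 80 — inside the default hydrophobic window — and
    ``n_away`` poses sit in the B pocket, too far from residue 80 for any
    contact. Returns poses plus planted truth labels
    ``{"thr80_contact", "no_thr80"}``.
    """
    rng = rng if rng is not None else stream_rng(config, "poses")
    res80 = [a for a in groove.atoms_of_residue(80) if a.name == "CB"]
    if not res80:
        raise ValueError("groove has no CB atom at residue 80")
    cb80 = res80[0].position
    cf = np.array(config.pocket_center_F)
    outward = cb80 - cf
    outward = outward / np.linalg.norm(outward)
    anchor_world = cb80 + contact_distance * outward

    template = _ligand_template(thiocarbonyl)
    anchor_name = "S1" if thiocarbonyl else "C1"
    anchor_local = next(p for n, _, p in template if n == anchor_name)

    poses, truth = [], []
    for i in range(n_contact):
        poses.append(
            _instantiate_pose(
                template,
                _random_rotation(rng),
                anchor_local,
                anchor_world,
                score=float(rng.normal(config.score_mean_F, config.score_sd_F)),
                run_id=i + 1,
                search_space=search_space,
                ligand_id=ligand_id,
            )
        )
        truth.append("thr80_contact")
    away_sets, _ = make_pose_set(
        config,
        n_B=n_away,
        n_F=0,
        thiocarbonyl=thiocarbonyl,
        ligand_id=ligand_id,
        search_space=search_space,
        rng=rng,
        run_id_start=n_contact + 1,
    )
    poses.extend(away_sets)
    truth.extend(["no_thr80"] * n_away)
    return poses, truth


# --- allele panel ------------------------------------------------------------

_DEFAULT_RISK = ["B*27:05", "B*38:02"]
_DEFAULT_POSSIBLE = ["B*38:01"]
_DEFAULT_CONTROL = ["B*15:01", "B*40:06", "B*46:01", "B*51:01", "B*54:01"]
_DEFAULT_COMMON = ["B*07:02", "B*08:01", "B*35:01", "B*44:02"]


def _names(defaults: list[str], n: int, prefix: str) -> list[str]:
    names = defaults[:n]
    names += [f"B*{prefix}{i:02d}:01" for i in range(len(names) + 1, n + 1)]
    return names


@dataclass
class AllelePanel:
    """Everything make_allele_panel produces, plus the planted truth."""

    alignment: AlleleAlignment
    frequencies: list[FrequencyRecord]
    pssms: list[PSSM]
    truth: dict = field(default_factory=dict)


def make_allele_panel(config: SimulationConfig) -> AllelePanel:
    """Sequence alignment + frequency table + PSSM set with planted truth.

    Sequences: all alleles share a random background; risk alleles carry
    the planted residues at the planted positions, controls and commons
    carry the (different) background residue there, and extra polymorphism
    is injected only in ways that cannot create further risk-unique
    positions (either one risk row deviates, so the risk group disagrees,
    or a proper subset of controls deviates, so at least one control still
    matches the risk residue). One possible-risk allele copies the last
    risk allele except at the last planted position (the Thr80Ile analog).

    Frequencies: risk alleles are enriched in cases at the planted odds
    ratio; all other alleles are null. Counts are binomially sampled at the
    configured cohort sizes; healthy-population frequencies vary
    log-normally around each allele's base frequency.

    PSSMs: drawn from ``pssm_clusters`` random prototypes plus noise, with
    the B*38:02/B*38:01 analog pair generated as near-duplicates.
    """
    if config.n_risk < 1 or config.n_control < 2:
        raise ValueError("panel needs >= 1 risk and >= 2 control alleles")
    rng = stream_rng(config, "sequences")
    aas = list(AMINO_ACIDS)
    L = config.seq_length

    risk_names = _names(_DEFAULT_RISK, config.n_risk, "R")
    possible_names = _names(_DEFAULT_POSSIBLE, config.n_possible_risk, "P")
    control_names = _names(_DEFAULT_CONTROL, config.n_control, "C")
    common_names = _names(_DEFAULT_COMMON, config.n_common, "N")

    background = [aas[i] for i in rng.integers(0, 20, size=L)]
    planted = dict(config.planted_positions)
    for pos, res in planted.items():
        if background[pos - 1] == res:  # background must differ from the risk residue
            background[pos - 1] = aas[(aas.index(res) + 1) % 20]

    def with_planted(seq: list[str]) -> list[str]:
        out = list(seq)
        for pos, res in planted.items():
            out[pos - 1] = res
        return out

    seqs: dict[str, list[str]] = {}
    for name in risk_names:
        seqs[name] = with_planted(background)
    for name in control_names + common_names:
        seqs[name] = list(background)

    # Thr80Ile-style possible-risk pair: copy the last risk allele, change
    # exactly the last planted position to a residue nobody else carries there.
    source_risk = risk_names[-1]
    pair_pos, pair_res = config.planted_positions[-1]
    alt = "I" if pair_res != "I" else "V"
    if alt == background[pair_pos - 1]:
        alt = next(a for a in aas if a not in (pair_res, background[pair_pos - 1]))
    for name in possible_names:
        seqs[name] = list(seqs[source_risk])
        seqs[name][pair_pos - 1] = alt

    # Extra polymorphism that can never add a risk-unique position.
    mutable_risks = risk_names[:-1]  # keep the pair source pristine
    candidates = [p for p in range(1, L + 1) if p not in planted]
    extra_positions = sorted(
        rng.choice(candidates, size=min(config.n_extra_polymorphisms, len(candidates)),
                   replace=False).tolist()
    )
    for pos in extra_positions:
        mutate_risk = bool(mutable_risks) and rng.random() < 0.5
        if mutate_risk:
            target = mutable_risks[int(rng.integers(0, len(mutable_risks)))]
            victims = [target]
        else:
            k = int(rng.integers(1, config.n_control))  # proper subset
            victims = list(rng.choice(control_names, size=k, replace=False))
            if config.n_common and rng.random() < 0.5:
                victims += list(
                    rng.choice(common_names, size=int(rng.integers(1, config.n_common + 1)),
                               replace=False)
                )
        new = aas[int(rng.integers(0, 20))]
        while new == background[pos - 1]:
            new = aas[int(rng.integers(0, 20))]
        for name in victims:
            seqs[name][pos - 1] = new

    rows = (
        [(n, "risk", "".join(seqs[n])) for n in risk_names]
        + [(n, "possible_risk", "".join(seqs[n])) for n in possible_names]
        + [(n, "control", "".join(seqs[n])) for n in control_names]
        + [(n, "common", "".join(seqs[n])) for n in common_names]
    )
    alignment = AlleleAlignment(rows=rows, numbering_offset=0, reference=risk_names[0])

    # frequencies
    frng = stream_rng(config, "frequencies")
    records = []
    enriched = set(risk_names)
    lo, hi = config.base_freq_range
    for name, status, _ in rows:
        p0 = float(frng.uniform(lo, hi))
        if name in enriched:
            odds1 = config.planted_or * p0 / (1 - p0)
            p1 = odds1 / (1 + odds1)
        else:
            p1 = p0
        case_chr = 2 * config.case_n
        ctrl_chr = 2 * config.control_n
        case_freq = frng.binomial(case_chr, p1) / case_chr
        control_freq = frng.binomial(ctrl_chr, p0) / ctrl_chr
        healthy = []
        for pop in range(config.n_healthy_pops):
            p_pop = min(0.5, p0 * float(np.exp(config.healthy_log_sd * frng.normal())))
            healthy_chr = 2 * config.healthy_n
            healthy.append(
                (f"POP{pop + 1}", frng.binomial(healthy_chr, p_pop) / healthy_chr)
            )
        records.append(
            FrequencyRecord(
                allele=name,
                case_freq=case_freq,
                study_control_freq=control_freq,
                healthy_freqs=healthy,
                case_n=config.case_n,
                control_n=config.control_n,
            )
        )

    # PSSMs: the near-duplicate pair is (source risk, its possible-risk copy)
    allele_names = [name for name, _, _ in rows]
    dup_pair = (source_risk, possible_names[0]) if possible_names else None
    pssms, pssm_truth = make_pssm_panel(config, allele_names=allele_names, dup_pair=dup_pair)

    truth = {
        "planted_positions": [list(p) for p in config.planted_positions],
        "enriched_alleles": sorted(enriched),
        "null_alleles": sorted(set(allele_names) - enriched),
        "possible_risk_pair": list(dup_pair) if dup_pair else None,
        "pair_position": pair_pos,
        "pssm_clusters": pssm_truth,
    }
    return AllelePanel(alignment=alignment, frequencies=records, pssms=pssms, truth=truth)


def make_pssm_panel(
    config: SimulationConfig,
    allele_names: list[str] | None = None,
    dup_pair: tuple[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[PSSM], dict[str, int]]:
    """PSSM set with planted cluster structure.

    Cluster prototypes are independent N(0,1) 9x20 matrices; each member is
    its prototype plus Gaussian noise with sd ``pssm_noise_frac`` times the
    prototype's score range. If ``dup_pair`` names two alleles, the second
    is generated as a near-duplicate of the first (noise scaled down by
    ``pssm_near_dup_frac``), and both land in cluster 0. Returns the PSSMs
    and the planted allele -> cluster map.
    """
    rng = rng if rng is not None else stream_rng(config, "pssms")
    k = config.pssm_clusters
    if allele_names is None:
        allele_names = [
            f"B*{c + 1:02d}:{i + 1:02d}"
            for c in range(k)
            for i in range(config.pssm_per_cluster)
        ]
    n = len(allele_names)
    prototypes = [rng.normal(size=(9, 20)) for _ in range(k)]
    noise_sd = [config.pssm_noise_frac * float(np.ptp(p)) for p in prototypes]

    # Round-robin-free assignment: contiguous blocks as equal as possible.
    assignment: dict[str, int] = {}
    block = int(np.ceil(n / k))
    for i, name in enumerate(allele_names):
        assignment[name] = min(i // block, k - 1)
    if dup_pair is not None:
        a, b = dup_pair
        if a not in allele_names or b not in allele_names:
            raise ValueError(f"dup_pair {dup_pair} not among allele names")
        if allele_names.index(a) > allele_names.index(b):
            raise ValueError("dup_pair source must precede its near-duplicate")
        assignment[a] = 0
        assignment[b] = 0

    pssms = []
    base_scores: dict[str, np.ndarray] = {}
    for name in allele_names:
        c = assignment[name]
        if dup_pair is not None and name == dup_pair[1]:
            src = base_scores[dup_pair[0]]
            scores = src + rng.normal(
                scale=config.pssm_near_dup_frac * noise_sd[0], size=(9, 20)
            )
        else:
            scores = prototypes[c] + rng.normal(scale=noise_sd[c], size=(9, 20))
        base_scores[name] = scores
        pssms.append(PSSM(allele=name, scores=scores))
    return pssms, assignment


# --- bundle emission ---------------------------------------------------------

def _safe_name(allele: str) -> str:
    return allele.replace("*", "").replace(":", "_")


def write_bundle(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Generate one full input bundle and write it to ``outdir``.

    Emits groove PDB, a 10-pose PBG + 10-pose Top3 pose file pair per drug
    (scores embedded and mirrored in a CSV sidecar), the aligned FASTA with
    a status label CSV, the frequency table CSV, one PSSM text file per
    allele, and a JSON sidecar holding every planted truth. Byte-identical
    across runs for a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    groove = make_groove(config)
    paths["groove"] = str(outdir / "groove.pdb")
    hio.write_structure(groove, paths["groove"])

    rng = stream_rng(config, "poses")
    pose_truth: dict[str, list[str]] = {}
    for ligand_id, thio in (("MMZ", True), ("DMI", False)):
        for space, (n_b, n_f, n_o) in (("PBG", (1, 9, 0)), ("Top3", (1, 7, 2))):
            poses, truth = make_pose_set(
                config, n_B=n_b, n_F=n_f, n_O=n_o, thiocarbonyl=thio,
                ligand_id=ligand_id, search_space=space, rng=rng,
            )
            key = f"poses_{ligand_id}_{space}"
            paths[key] = str(outdir / f"{key}.pdb")
            hio.write_pose_set(poses, paths[key])
            with open(outdir / f"{key}_scores.csv", "w") as fh:
                fh.write("run_id,score\n")
                for p in poses:
                    fh.write(f"{p.run_id},{p.score:.4f}\n")
            pose_truth[key] = truth

    panel = make_allele_panel(config)
    paths["alignment"] = str(outdir / "alignment.fasta")
    hio.write_alignment(panel.alignment, paths["alignment"])
    with open(outdir / "labels.csv", "w") as fh:
        fh.write("allele,status\n")
        for name, status, _ in panel.alignment.rows:
            fh.write(f"{name},{status}\n")
    paths["labels"] = str(outdir / "labels.csv")
    paths["frequencies"] = str(outdir / "frequencies.csv")
    hio.write_frequency_table(panel.frequencies, paths["frequencies"])
    for pssm in panel.pssms:
        hio.write_pssm(pssm, outdir / f"pssm_{_safe_name(pssm.allele)}.txt")

    truth = dict(panel.truth)
    truth["pose_labels"] = pose_truth
    truth["config"] = asdict(config)
    paths["truth"] = str(outdir / "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
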