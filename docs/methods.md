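# Methods

This note documents the models and procedures `hlapocket` implements, the
defaults it ships with and why, what the synthetic-data generator does and
does not emulate, and the numerical choices that make results
deterministic.

## Scientific setting

Class I HLA molecules present 8–11-mer peptides in a groove formed between
two α-helices and a β-sheet platform; the groove contains six subsites
(pockets A–F) whose shape is set by polymorphic residues. Under the
altered-peptide-repertoire model of HLA-mediated adverse drug reactions, a
drug binds non-covalently inside this groove and changes which
self-peptides are presented. For the anti-thyroid drugs — thioamides
sharing a thiocarbonyl (C=S) group — the risk alleles B*27:05 and B*38:02
carry Cys67 and Thr80, and docked drug poses concentrate in the F pocket
next to residue 80. The package provides each analysis step of that
argument as a separately testable operation.

## Control-allele selection (`alleles`)

Candidate controls must be common enough to be informative: the screen
keeps alleles with study-control frequency strictly over 3% (strict
inequality, reflecting "over 3%"). An allele is then accepted as a control
when its study-control frequency **or** any healthy-population reference
frequency is *similar to or greater than* its case frequency. "Similar to"
is quantified as a relative margin: accepted iff

```
max(study_control_freq, healthy_freqs…) ≥ case_freq × (1 − tolerance)
```

with `tolerance = 0.1` by default (10% relative slack; exposed as a
parameter because any fixed quantification of "similar" is a judgement
call). A record with no healthy frequencies is judged on its study-control
frequency alone. The selection is by construction a subset of the screen.

Odds ratios are reporting support only: OR = ad/bc over carrier counts
with the Haldane–Anscombe 0.5 correction when any cell is zero and a
Woolf-type 95% CI (`exp(log OR ± 1.96·SE)`, `SE = sqrt(1/a+1/b+1/c+1/d)`).
Two zero cells sharing a margin leave the OR undefined and raise.

## Risk-unique residue scan (`msa`)

Positions are mature-protein, 1-based: an alignment column maps to the
ungapped index of a designated reference row plus a caller-supplied offset
(default 0 for pre-trimmed mature sequences; signal-peptide handling is
deliberately the caller's responsibility). A position is *discriminating*
when all risk rows share one residue and no control row carries it. Gaps
never match anything: a gap in any risk row skips the column, and control
gaps do not count as carrying the risk residue. `possible_risk` rows (the
B*38:01 situation — plausible but unconfirmed) are excluded from both
groups unless explicitly listed, so an unconfirmed allele can never dilute
the risk consensus.

## Pocket assignment (`pockets`)

Pocket centroids are means of side-chain atom positions (non-backbone
atoms) of the defining residues present in the structure. The shipped
residue sets are, in mature numbering,

- F pocket: 77, 80, 81, 84, 95, 116, 123, 124, 143, 146, 147 — the
  residues observed lining and surrounding the pocket, plus canonical 146;
- B pocket: 7, 9, 24, 25, 34, 45, 63, 66, 67, 70, 99 — the canonical
  literature set;

both overridable, since pocket definitions vary by author.

Poses are clustered with k-means, k = 2 (two visually distinct pose groups
motivate the choice), on the coordinates of one designated reference atom
per pose (default name `C1`), which lets chemically different ligands with
different atom counts be clustered together. Initialisation is
deterministic farthest-point seeding — first centre is the point farthest
from the data centroid, subsequent centres maximise distance to the chosen
set, exact ties broken by lexicographic coordinates — followed by Lloyd
iteration (assignment ties to the lowest cluster id; a cluster that
empties keeps its previous centre, so coincident points are tolerated).
This makes the result independent of pose order and of the seed argument,
which is retained in the API for interface stability. A randomised
initialisation with restarts was rejected because it cannot guarantee
order-independence, which we treat as a correctness property.

Each cluster is labelled B or F by the pocket centroid nearest its mean;
any individual pose whose reference atom lies farther than
`groove_radius` (default 12 Å) from *both* centroids is relabelled O
(outside the groove). The threshold is a reproducible surrogate for the
visual "other pockets" judgement; 12 Å comfortably separates groove poses
(≤ ~8 Å from a centroid at the default geometry) from surface pockets.

## Interactions and the Thr80 taxonomy (`interactions`)

Heavy-atom-only contact detection in the LigPlot style:

- hydrophobic contact: protein C/S atom and ligand C/S atom at 2.9–3.9 Å;
- hydrogen bond: N/O/S pair within 3.35 Å where one side can donate and
  the other accept. Protein capability comes from small residue templates
  (backbone N donates, backbone O accepts; side-chain rules per residue
  type, e.g. Thr OG1 is both donor and acceptor). Ligand capability
  defaults to element rules (N/O both roles, S acceptor) and can be
  overridden per ligand.

No explicit hydrogens and no angle term — the classification is
distance-based, as in the figure-level analyses it supports. All cutoffs
sit in a `ContactParams` object and are overridable.

The thiocarbonyl sulfur is identified geometrically: a terminal sulfur
(exactly one heavy-atom neighbour within 1.85 Å) bonded to a carbon with at
least two further neighbours. A thioether (C–S–C) fails terminality; an
isolated C–S fragment fails the neighbour test. Pose classification at a
position of interest (default 80) is residue-level: *Thr80-S* if any
contact at the position involves the thiocarbonyl sulfur, *Other Thr80* if
contacts exist but none involve it, *No Thr80* otherwise. Tabulation
reports the three counts plus the class of the minimum-score pose (ties by
lowest pose index).

## Summaries (`summary`)

One row per allele × ligand × search-space group: per-pocket counts,
per-pocket median scores (even-count median = mean of the two central
values), and the pocket label of the minimum-score pose (ties by pose
index). Medians render to 2 decimals and empty pockets as `N/A`, matching
the conventional table format; O columns appear for the extended (Top3)
search space. Five-number summaries for multi-run boxplots use linear
interpolation between closest ranks, fixed so outputs are deterministic.

## Motif comparison (`motifs`)

Binding motifs arrive as 9×20 position-specific score matrices from any
external predictor. The distance is `d = (1 − r)/2` with `r` the Pearson
correlation of the flattened matrices, mapping identical motifs to 0 and
anti-correlated ones to 1 — the same 0→1 similarity scale used in
motif-similarity heat maps. A constant matrix has no defined correlation
and is rejected. The triangle inequality is *not* guaranteed and not
asserted; trees are descriptive. Clustering is UPGMA
(`scipy.cluster.hierarchy`, average linkage) after sorting alleles
lexicographically, which resolves equal-distance merges to the
lexicographically smallest pair and makes tree output deterministic. The
Newick writer quotes labels containing reserved characters (HLA names
contain `:` and `*`) and emits ultrametric branch lengths.

## Superposition RMSD (`geometry`)

Atoms are paired by (chain, residue number, atom name), optionally
restricted by a selection; RMSD is computed after optimal rigid
superposition (Kabsch, via `scipy.spatial.transform.Rotation.align_vectors`).
Collinear or planar selections make the optimal rotation non-unique; the
RMSD is still well defined and the library warning is suppressed. A useful
analytic anchor used in the tests: a displacement field orthogonal to all
rigid modes (zero net translation and zero net torque, e.g. the collinear
3-atom toy displaced by `(a, −2a, a)` with `a = 1/√6`) cannot be reduced by
superposition and has RMSD exactly `√(1/3)`, whereas displacing a single
atom of three by 1 Å reduces to `√(2/9)` once the centroid shift is
absorbed.

## Synthetic data (`synthetic`)

The generator's defaults define the test-bed conditions:

- **Groove**: B- and F-pocket residues on 3.5 Å circles around two centres
  15 Å apart (evenly spaced directions, so each pocket's side-chain
  centroid sits at its centre). Residue 80 is THR (CB/OG1/CG2), 67 CYS
  (CB/SG), all others ALA — enough chemistry for distance-based contact
  logic, not a real fold.
- **Poses**: reference atoms drawn from isotropic Gaussians (σ = 1.5 Å)
  around the planted pocket; O poses placed ~26 Å from both centres.
  Ten poses per group. Scores are Gaussian per pocket (F −4.2 ± 0.4, B
  −3.3 ± 0.3, O −3.6 ± 0.4 kcal/mol), giving risk-like groups more
  favourable F medians. The ligand template is a five-membered C/N ring
  with an optional exocyclic C=S at 1.68 Å and a methyl tail —
  methimazole-like connectivity, not a force-field geometry.
- **Allele panels**: 182-residue mature sequences; two risk alleles share
  planted Cys67/Thr80; one possible-risk allele copies the second risk
  allele except for a single Thr80Ile-style change; controls and commons
  carry the background residue at planted positions. Extra polymorphism is
  injected only in ways that cannot create additional risk-unique
  positions (either one risk row deviates, or a proper subset of controls
  does), so the planted positions are exactly the discriminating set by
  construction.
- **Frequencies**: planted odds ratio 20 for the risk alleles (the
  replicated Asian-cohort HLA-B associations report ORs of roughly 21–66;
  the Caucasian B*27:05 association is weaker at ~3), cohorts of 60 cases
  and 1200 controls (within the 21–234 / 81–5170 ranges of the source
  studies), allele base frequencies uniform on 5–15%, and six healthy
  reference populations whose true frequencies vary log-normally
  (σ_log = 0.5) around the base — emulating the order-of-magnitude
  between-population spread HLA-B alleles show in reference databases.
  Counts are binomial over 2N chromosomes. The reported false-exclusion
  rate counts every null allele not selected, whether it failed the 3%
  screen or the similarity rule.
- **PSSMs**: cluster prototypes are independent N(0,1) 9×20 matrices;
  members add Gaussian noise with sd 5% of the prototype's range;
  near-duplicate pairs scale that noise by a further 0.2.

A single root seed feeds independent named substreams (structure, poses,
sequences, frequencies, PSSMs) via `SeedSequence` spawn keys, so adding a
call on one stream never changes another stream's output and a fixed
config yields byte-identical files. Planted truth is written only to a
JSON sidecar, never into analysis-facing files.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: docking energetics and pose geometry beyond
Gaussian clouds, linkage between alleles and realistic HLA sequence
diversity, ascertainment and typing-resolution artefacts in frequency
tables, and the shape of real predictor score matrices. Recovery rates on
this test-bed certify the *logic* of each stage (clustering, labelling,
set algebra, thresholds, tallies), not the accuracy of any upstream
docking or prediction engine.

## Problem sizes and determinism

The verification script and test suite run 100 pocket-assignment
replicates (1,000 poses), 1,000 random summary groups, 50 contact-oracle
complexes plus 40 Thr80 taxonomy pose sets, 100 alignment panels, 200
frequency tables (2,000 null alleles), 100 motif panels, 100 rigid-motion
RMSD copies and a duplicated full-bundle generation — sizes chosen so the
whole battery completes in seconds while keeping binomial/Gaussian
sampling noise far from the decision thresholds. All randomness flows from
explicit seeds; reruns with the same seed reproduce every number exactly.

## Known limitations

- PDB/PDBQT parsing covers ATOM/HETATM/MODEL/REMARK records only; no
  mmCIF, no altloc/insertion-code handling beyond ignoring the columns.
- Contact detection has no angle terms, explicit hydrogens, π-stacking or
  halogen bonds; it reproduces residue-level contact tables, not binding
  energetics.
- The motif distance is a correlation on externally supplied matrices; it
  is not the internal metric of any particular prediction server, whose
  peptide sampling is not reproducible from matrices alone.
- The 3% screen and the 10% similarity tolerance are policy defaults;
  published control sets cannot be re-derived exactly without the
  underlying per-study tables.
- O-classification uses a fixed radial threshold; qualitatively assigned
  "outside the groove" calls in the literature have no stated threshold,
  so agreement is by construction of the surrogate, not by calibration.
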