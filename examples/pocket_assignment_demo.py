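"""Assign docked ligand poses to the B pocket, F pocket, or outside the groove.

Builds a synthetic groove whose B- and F-pocket residues ring two centres
15 A apart, generates a 10-pose methimazole-like set (1 planted in B, 9 in
F — the shape a risk allele shows), clusters the pose reference atoms with
k-means (k=2), and labels each cluster by its nearest pocket centroid.
"""

from hlapocket import (
    SimulationConfig,
    assign_pockets,
    build_pocket_model,
    make_groove,
    make_pose_set,
)

config = SimulationConfig(seed=7)
groove = make_groove(config)
model = build_pocket_model(groove)  # centroids from pocket residue side chains
poses, planted = make_pose_set(config, n_B=1, n_F=9, ligand_id="MMZ")

assignments = assign_pockets(poses, model, k=2)

print("pose  run  score    cluster  label  planted")
for pose, asg, truth in zip(poses, assignments, planted):
    print(
        f"{asg.pose_index:>4}  {pose.run_id:>3}  {pose.score:>6.2f}  "
        f"{asg.cluster_id:>7}  {asg.label:>5}  {truth:>7}"
    )
recovered = sum(a.label == t for a, t in zip(assignments, planted))
print(f"\n{recovered}/10 poses received their planted pocket label.")
print("A risk-allele-like pose cloud concentrates in the F pocket, the")
print("subsite next to residue 80 of the peptide-binding groove.")
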