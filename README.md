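# restgraph

Graph-theoretical analysis of whole-brain resting-state functional
connectivity, built for case–control fMRI studies: head-motion quality
control, temporal preprocessing, voxel-level degree-centrality mapping,
data-driven refinement of an anatomical atlas into functionally homogeneous
network nodes, binary-graph network metrics with rewired null models, and
nonparametric group inference. A seeded synthetic-cohort generator with
planted network structure makes every stage testable end to end without any
imaging data download.

It is aimed at researchers who want a transparent, scriptable alternative to
GUI neuroimaging toolchains for the *network* half of a resting-state
analysis — the pipeline consumes already-aligned 4D BOLD volumes plus
rigid-body motion parameter files, and takes it from there.

## The analysis

**Motion QC.** From the six rigid-body parameters d_j(i) (three translations
in mm, three rotations in degrees, relative to the first frame), framewise
displacement is

    FD(i) = Σ_j |d_j(i) − d_j(i−1)|,

with rotation differences converted to arc length on a 50 mm sphere.
Subjects are excluded when any per-parameter min-to-max range exceeds 3.0 mm
(translations) or 3.0° (rotations), or when max FD > 2.5 mm. Four scalar
summaries (D_max, D_RMS, FD_max, FD_RMS) feed a confound audit that
correlates motion with the group-discriminating edges.

**Degree maps.** Every in-mask voxel is Pearson-correlated with every other
voxel; the voxel degree D_i counts correlations r > 0.25, and maps are
z-scored within the mask, z_i = (D_i − ⟨D⟩)/σ_D, for averaging and group
contrasts. Voxelwise two-sample t-maps are assessed by cluster-extent
inference (cluster-defining p = 0.005, permutation null of the maximum
cluster size, BH-FDR across clusters).

**Nodes.** Each anatomical region of a label atlas is refined by community
detection: the region's voxel×voxel Fisher-z correlation matrix (averaged
over the control group) is proportionally thresholded (top 30 % of weights)
and partitioned with Newman's spectral modularity algorithm. The detected
voxel communities become the network nodes and raise ROI homogeneity (mean
pairwise voxel Fisher z) relative to the parent atlas.

**Graphs and metrics.** ROI mean time courses give a Fisher-z connectivity
matrix per subject, binarised over a sparsity grid S ∈ [0.10, 0.35]. On each
binary graph: degree and z-degree, Watts–Strogatz clustering C, characteristic
path length L, and the small-world ratios γ = C/⟨C_rand⟩ and λ = L/⟨L_rand⟩
against degree-preserving Maslov–Sneppen rewired references. Module structure
is detected on the control-group mean matrix (S = 0.2) and applied unchanged
to every subject; per-module mean z-degree and participation coefficient
P_i = 1 − Σ_m (k_im/D_i)² quantify module-level group differences.

**Inference.** Group differences in graph metrics use two-sample permutation
tests (exact enumeration when feasible) with Benjamini–Hochberg FDR across
nodes/modules; edge-level differences use two-sample t-tests on Fisher-z
values with a ranked top-edge report.

## Worked example

The built-in demo generates a two-group synthetic cohort (12 controls vs
12 "patients", 16³ voxel grid, 168 frames at TR = 2 s) with two planted
effects in the patient group: the sensorimotor-analogue module couples more
strongly within itself, and the visual-analogue module couples less strongly
to the rest of the network.

```bash
restgraph demo --seed 1 --out-dir demo_out
```

prints

```json
{
 "seed": 1,
 "sensorimotor_module": 3,
 "visual_module": 2,
 "sensorimotor_degree_diff_case_minus_ref": 0.5159314839170928,
 "sensorimotor_degree_p": 0.03796203796203796,
 "sensorimotor_direction_recovered": true,
 "visual_participation_diff_case_minus_ref": -0.15637996556647354,
 "visual_participation_p": 0.001998001998001998,
 "visual_direction_recovered": true,
 "both_directions_recovered": true
}
```

Reading this: community detection on the control-group mean matrix found the
four planted network modules exactly (modularity Q = 0.75 over 16 nodes);
the sensorimotor-analogue module shows a *higher* mean z-degree in patients
(+0.52, permutation p = 0.038) and the visual-analogue module a *lower*
participation coefficient (−0.156, p = 0.002) — both planted directions
recovered. Atlas refinement raised mean ROI homogeneity from 0.30 to 0.41
(Fisher z), and per-subject small-world ratios at the minimum connected
sparsity came out at γ ≈ 2.3–2.9 with λ ≈ 1.2. `demo_out/` contains the full
stage-by-stage TSV/JSON reports (QC, homogeneity, community structure, node
and global metrics, module and node tests, top edges, voxel clusters,
motion audit, effective config).

The same pipeline runs on real data from a cohort manifest:

```bash
restgraph run --manifest cohort.tsv --atlas atlas.nii.gz --out-dir out --seed 7
```

where `cohort.tsv` has columns `subject_id  group  bold_path  motion_path`.
Single stages are exposed as `simulate`, `qc`, `prep`, `degree`,
`parcellate`, `graph`, and `stats` subcommands.

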