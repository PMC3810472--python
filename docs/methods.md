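# Methods

This note documents the models, conventions and numerical choices behind
`restgraph`, and what the synthetic cohort does and does not emulate.

## Motion quality control

The six realignment parameters are taken relative to the first frame
(traces read from disk are rebased). Rotations are converted from degrees to
millimetres as arc length θ(rad)·R on a sphere of radius R = 50 mm, a
standard approximation of the mean cortex-to-head-centre distance; the same
conversion enters FD, D_max and D_RMS.

Framewise displacement is the L1 norm of the parameter differences between
consecutive frames (length N−1 for N frames). Exclusion acts on three
criteria, each a strict inequality: per-parameter min-to-max range > 3.0 mm
(translations) or > 3.0° (rotations), and FD_max > 2.5 mm. All violated
criteria are reported, not just the first. Frame censoring ("scrubbing") is
deliberately not implemented — the QC model excludes subjects, not frames.

D_RMS is defined as sqrt((1/N) Σ_i Σ_j d̃_j(i)²) over the radius-converted
parameters (the "pooled" variant). A per-frame-Euclidean variant is
selectable; the two differ only by a fixed pooling convention, and the
confound audit only requires a monotone summary of overall motion. D_max is
the largest absolute converted parameter value over frames; a per-parameter
range reading of "maximum displacement" would differ by at most a factor 2
and is equally monotone — the instantaneous reading is implemented.

The motion confound audit Pearson-correlates each of the four summaries
with each candidate edge's Fisher-z connectivity across subjects and
compares the count of significant correlations at α against the α·n_tests
expected under the null. Zero-variance columns are flagged undefined and
excluded from both counts.

## Temporal preprocessing

Nuisance regression is per-voxel OLS on [intercept + regressors]; regressor
columns are centred so the intercept absorbs means, and the output is the
residual series (mean ≈ 0 per voxel). Rank deficiency is an error that names
the collinear columns rather than silently dropping one. Regression runs
before filtering, matching the order in which these steps are conventionally
applied to already-aligned data.

The bandpass (0.01–0.08 Hz default) is a zero-phase forward–backward
Butterworth, order 2 per pass. Zero phase matters because every downstream
connectivity estimate is a zero-lag Pearson correlation; a causal filter
would shift phases and distort it. The high cutoff must be strictly below
Nyquist = 1/(2·TR). Measured on a 168-frame, TR = 2 s series: a 0.04 Hz
sinusoid passes with < 1 % amplitude error; a 0.2 Hz sinusoid is attenuated
by more than 99 %. The filter is linear to float precision, and regression
is idempotent (residuals are orthogonal to the design).

## Voxel degree maps

Degree counts correlations **r > threshold on signed r** (default 0.25):
anti-correlations do not count. The correlation matrix is never
materialised; unit-normalised series make correlation a dot product,
computed in row blocks (float32 GEMM — ample precision for comparing
against a threshold), so peak memory is O(block · n_voxels) and the result
is exactly independent of the block partition. Zero-variance in-mask voxels
either raise (default) or are dropped from the mask, configurable.

The z-transform uses the population SD over in-mask voxels. The convention
(population vs sample) cancels in group contrasts; it is fixed for
reproducibility. Group hub maps are voxelwise one-sample t statistics of
z-degree across subjects, thresholded at a configurable t cutoff.

## Atlas refinement (sub-parcellation)

Per region: per-subject voxel Pearson matrices → Fisher z → element-wise
mean over the **reference (control) cohort only** — case subjects never
influence node definitions, which prevents circularity in the group
comparison. Fisher z of r = ±1 is infinite, so |r| is capped at 1 − 1e-7
(z ≈ 8.1) before atanh; the cap only binds for degenerate or synthetic
data. The mean matrix is proportionally thresholded (top 30 % of
off-diagonal weights) and partitioned by spectral modularity maximisation;
a region with no positive-modularity split stays whole.

Proportional thresholding keeps exactly round(S·n(n−1)/2) edges, ranking by
weight with ties broken by lexicographic node-pair order. This makes
thresholding deterministic across runs and platforms and makes the retained
edge set monotone (nested) in S. Note one consequence: a matrix with all
weights *equal* thresholds to the lexicographically first k pairs, which is
a structured graph — only at S = 1 (complete graph) is "no sub-structure"
guaranteed to return a single module.

Sub-regions are not forced to be spatially contiguous; community detection
sees only correlation. The node lookup table reports a connected-component
fragment count per sub-region so fragmentation is visible. Homogeneity is
the mean off-diagonal Fisher z among a region's voxels, reported for the
parent and refined parcellations.

## Network metrics

All metrics operate on undirected binary graphs; weighted variants are out
of scope. Conventions:

- **Degree/z-degree**: row sums; z with population mean/SD over nodes. A
  uniform degree distribution makes z undefined — the library call raises,
  and the pipeline records z = 0 for all nodes of such a graph.
- **Clustering**: Watts–Strogatz binary form; C_i = 0 for degree < 2, and
  such nodes are included in the mean.
- **Path length**: mean shortest hop count over ordered pairs, BFS with
  unit edges. Disconnected graphs are an error — never a silent ∞ or
  harmonic mean. The pipeline computes small-world metrics at each
  subject's minimum connected sparsity within the grid and records the
  sparsity used.
- **Rewired null**: Maslov–Sneppen double-edge swaps; proposals creating
  self-loops or multi-edges are rejected, so the degree sequence is
  conserved exactly. Defaults: 10 swaps per edge, 20 reference networks
  (both configurable and recorded). References that come out disconnected
  are skipped in the γ/λ means; all-disconnected is an error.
- **Community detection**: Newman's spectral algorithm — recursive
  bisection by the sign of the leading eigenvector of the generalised
  modularity matrix B(g) = B[g,g] − diag(row sums), with Kernighan–Lin-style
  fine-tuning after each division (each pass moves every node once, keeps
  the best intermediate state, repeats while the objective improves).
  Division stops when no split increases Q. Numerical care: the pass
  objective is recomputed exactly at pass end — incremental gains
  accumulate round-off, and accepting that noise as improvement cycles
  forever. The leading eigenpair uses dense `eigh` below 128 nodes and
  Lanczos above, with a dense fallback. Module labels are ordered by each
  module's smallest node index, making the partition deterministic.
- **Participation**: P_i = 1 − Σ_m (k_im/D_i)²; P_i = 0 for isolated nodes.
  The partition is always the control-derived one, applied per subject.

## Group inference

Permutation tests use the difference of group means; with C(n_a+n_b, n_a)
splits below the requested n_perm the null is enumerated exactly
(p = proportion of splits at least as extreme), otherwise Monte-Carlo with
p = (1 + hits)/(n_perm + 1). Comparisons use an absolute tolerance of 1e-12
so exact ties count as extreme. FDR is Benjamini–Hochberg step-up.

Edge tests are pooled-variance two-sample t on Fisher-z values (Welch by
flag); edges with degenerate variance are flagged and excluded. The
top-edge report ranks by p with a deterministic (p, node_i, node_j)
tie-break.

Voxelwise contrasts use cluster-extent inference with a permutation null:
both one-sided t-maps are thresholded at the t quantile of the
cluster-forming p (default 0.005), supra-threshold clusters are
6-connected components (18/26 configurable), and each observed cluster's p
is the exceedance probability of its size under a group-relabelling null of
the *maximum* cluster size (both directions pooled). BH-FDR is then applied
across observed clusters and the smallest surviving size is reported as the
critical cluster size. This permutation construction replaces random-field
topological FDR, which is out of scope; it controls the same quantity
empirically. Practical note: the Monte-Carlo p floor 1/(n_perm+1) must
undercut q/m for m observed clusters, so cluster nulls need generous
permutation counts (pipeline default 500; calibration tests use more).

Module-level tests are run both at the community sparsity and on the
per-subject mean over the sparsity grid. The grid mean exists because a
single sparsity bin can be degenerate at toy scale: if the edge budget
S·n(n−1)/2 exceeds the total number of within-module pairs, every
within-module edge is retained in both groups and the degree effect
saturates; if it falls below, no between-module edge survives and
participation starves. Averaging over the grid sees both regimes; module
effects worth reporting should in any case be stable across sparsity.

## The synthetic cohort

Voxel series follow a latent-factor construction (module, sub-region,
optional global and shared cross-module latents plus i.i.d. Gaussian
noise), which guarantees a positive semi-definite implied correlation and
gives the nested ordering corr(within sub-region) > corr(within module) >
corr(between modules) whenever c_s > c_w > c_b. Defaults: 168 frames at
TR = 2 s (a 6-minute run minus equilibration discards), 8 block regions in
a 16³ grid, 4 network modules of 2 regions, c_s = 0.60, c_w = 0.30,
c_b = 0.10, noise SD 1. The patient group raises sensorimotor within-module
coupling to 0.45 and lowers visual between-module coupling to 0.02 — effect
sizes chosen once as plausibly large disease effects detectable at n = 12
per group, and kept. Motion traces are Gaussian random walks (step SD
0.01 mm/° per frame in the cohort default) with optional transient spikes.
The global-signal component defaults to off, matching a pipeline that does
no global-signal regression; a coupling flag enables it for sensitivity
studies.

What the generator does **not** emulate: hemodynamics, physiological noise,
scanner drift, spatial autocorrelation from smoothing, realistic brain
geometry, or partial-volume effects. Passing tests therefore demonstrate
that the *machinery* is correct and calibrated under its stated
assumptions — not that effect sizes or p-values transfer to any real
cohort.

Problem sizes used in the test and acceptance runs (demo: 12+12 subjects on
a 16³ grid; recovery rates over 20–100 seeds; permutation calibration at
199 permutations × 1000 replicates; cluster nulls at 100–1500 permutations)
were chosen to give stable rates on a single CPU; all are configurable.

## Known limitations

- Community detection is the classic spectral + fine-tuning scheme; it is
  deterministic but, like all modularity maximisation, subject to the
  resolution limit on very small modules.
- Proportional thresholding of constant matrices is lexicographic by
  contract, hence arbitrary-but-reproducible.
- The pipeline assumes exactly two groups and a designated reference group.
- NIfTI affines are treated as identity (voxel indices, not mm, in all
  coordinate reports); the pipeline consumes already-normalised volumes.
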