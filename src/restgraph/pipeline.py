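"""End-to-end orchestration: QC -> prep -> degree -> parcellation -> graphs -> stats.

``run_pipeline`` sequences the full analysis on a cohort (in memory or loaded
from a manifest) and writes every stage's tables; ``run_demo`` generates the
default synthetic two-group cohort, runs the pipeline, and reports whether
the planted module-level effect directions were recovered.

All randomness flows from a single root seed, deterministically forked per
stage, so identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import degree as deg
from . import graph as gr
from . import motion as mo
from . import parcellation as parc
from . import prep as pp
from . import stats as st
from . import synthetic as syn
from .datasets import BoldDataset, load_bold, read_manifest

__all__ = ["PipelineConfig", "run_pipeline", "run_demo"]


@dataclass
class PipelineConfig:
    """Effective parameter set of one pipeline run (echoed to disk)."""

    out_dir: str | None = None
    manifest: str | None = None
    atlas: str | None = None
    # thresholds
    r_threshold: float = 0.25
    parcellation_sparsity: float = 0.3
    community_sparsity: float = 0.2
    sparsity_grid: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35)
    cluster_forming_p: float = 0.005
    fdr_q: float = 0.05
    alpha: float = 0.05
    edge_alpha: float = 0.001
    audit_alpha: float = 0.01
    # motion rule
    max_translation: float = 3.0
    max_rotation: float = 3.0
    max_fd: float = 2.5
    sphere_radius: float = 50.0
    # filtering
    filter_low_hz: float = 0.01
    filter_high_hz: float = 0.08
    filter_order: int = 2
    # reproducibility / budgets
    seed: int = 0
    n_perm: int = 1000
    n_cluster_perm: int = 500
    n_random_refs: int = 8
    n_swaps_per_edge: int = 10
    reference_group: str = "control"
    run_voxel_stage: bool = True

    def exclusion_rule(self) -> mo.ExclusionRule:
        return mo.ExclusionRule(
            max_translation=self.max_translation,
            max_rotation=self.max_rotation,
            max_fd=self.max_fd,
            sphere_radius=self.sphere_radius,
        )


def _load_cohort(config: PipelineConfig) -> tuple[list[dict], np.ndarray]:
    if config.manifest is None or config.atlas is None:
        raise ValueError("run_pipeline needs either an in-memory cohort or "
                         "manifest + atlas paths in the config")
    import nibabel as nib

    manifest = read_manifest(config.manifest)
    atlas = np.asarray(nib.load(config.atlas).dataobj).astype(int)
    cohort = []
    for _, row in manifest.iterrows():
        for col in ("bold_path", "motion_path"):
            if not Path(row[col]).exists():
                raise FileNotFoundError(
                    f"subject {row['subject_id']}: missing file {row[col]}"
                )
        ds = load_bold(row["bold_path"], subject_id=row["subject_id"],
                       group=row["group"])
        trace = mo.read_motion_file(row["motion_path"])
        cohort.append({"dataset": ds, "motion": trace,
                       "subject_id": row["subject_id"], "group": row["group"]})
    return cohort, atlas


def _write_tsv(df: pd.DataFrame, out_dir: Path | None, name: str) -> None:
    if out_dir is not None:
        df.to_csv(out_dir / name, sep="\t", index=False, float_format="%.6g")


def run_pipeline(
    config: PipelineConfig,
    cohort: list[dict] | None = None,
    atlas: np.ndarray | None = None,
) -> dict:
    """Run the full analysis; returns the result bundle as a dict.

    ``cohort`` is a list of records with keys ``dataset`` (BoldDataset),
    ``motion`` (MotionTrace), ``subject_id`` and ``group``; when omitted it
    is loaded from ``config.manifest`` / ``config.atlas``.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    if cohort is None or atlas is None:
        cohort, atlas = _load_cohort(config)
    groups = sorted({rec["group"] for rec in cohort})
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    ref_group = config.reference_group
    if ref_group not in groups:
        raise ValueError(f"reference group {ref_group!r} not among {groups}")
    other_group = [g for g in groups if g != ref_group][0]
    rule = config.exclusion_rule()

    # --- stage 1: motion QC -------------------------------------------------
    qc_rows = []
    included = []
    for rec in cohort:
        summary = mo.motion_summaries(rec["motion"], rule.sphere_radius)
        decision, reasons = mo.apply_exclusion(summary, rec["motion"], rule)
        qc_rows.append({
            "subject_id": rec["subject_id"], "group": rec["group"],
            **summary.as_dict(), "decision": decision,
            "reasons": "; ".join(reasons),
        })
        if decision == "include":
            included.append({**rec, "summary": summary})
    qc = pd.DataFrame(qc_rows)
    _write_tsv(qc, out_dir, "qc_report.tsv")
    if not included:
        raise ValueError("motion QC excluded every subject")

    # --- stage 2: temporal preprocessing ------------------------------------
    for rec in included:
        nuis = pp.NuisanceSet.from_parts(motion=rec["motion"])
        rec["prepped"] = pp.preprocess(
            rec["dataset"], nuis,
            low_hz=config.filter_low_hz, high_hz=config.filter_high_hz,
            order=config.filter_order,
        )
    ref_sets = [r["prepped"] for r in included if r["group"] == ref_group]
    other_sets = [r["prepped"] for r in included if r["group"] == other_group]
    if len(ref_sets) < 2 or len(other_sets) < 2:
        raise ValueError("need at least 2 included subjects per group")

    bundle: dict = {"config": asdict(config), "qc": qc, "groups": groups,
                    "reference_group": ref_group, "case_group": other_group}
    root_seed = np.random.SeedSequence(config.seed)
    stage_seeds = {name: s for name, s in zip(
        ("voxel", "module", "node", "edge"), root_seed.spawn(4))}

    # --- stage 3: voxel degree maps + group cluster test ---------------------
    if config.run_voxel_stage:
        zmaps = {}
        for rec in included:
            dm = deg.voxel_degree_map(rec["prepped"], r_threshold=config.r_threshold)
            rec["zmap"] = deg.z_transform_map(dm)
        zmaps_ref = [r["zmap"].z_degree for r in included if r["group"] == ref_group]
        zmaps_other = [r["zmap"].z_degree for r in included
                       if r["group"] == other_group]
        mask = included[0]["prepped"].mask
        t_vol, cluster_res = st.voxel_degree_group_test(
            zmaps_ref, zmaps_other, mask,
            cluster_forming_p=config.cluster_forming_p,
            cluster_alpha=config.fdr_q,
            n_perm=config.n_cluster_perm,
            seed=np.random.default_rng(stage_seeds["voxel"]).integers(2**31),
        )
        hub_t, hub_vol = deg.hub_map(
            [r["zmap"] for r in included if r["group"] == ref_group], t_cutoff=6.0
        )
        bundle["voxel"] = {"t_map": t_vol, "clusters": cluster_res,
                           "hub_t": hub_t, "hub_map": hub_vol}
        _write_tsv(cluster_res.clusters, out_dir, "voxel_clusters.tsv")

    # --- stage 4: parcellation from the reference group ----------------------
    parcellation, homogeneity = parc.build_subparcellation(
        ref_sets, atlas, proportional_threshold=config.parcellation_sparsity
    )
    _write_tsv(homogeneity, out_dir, "homogeneity.tsv")
    _write_tsv(parcellation.lookup_table(), out_dir, "parcellation_nodes.tsv")
    bundle["parcellation"] = parcellation
    bundle["homogeneity"] = homogeneity

    # --- stage 5: connectivity matrices and community structure --------------
    for rec in included:
        ts = gr.extract_roi_timeseries(rec["prepped"], parcellation)
        rec["conn"] = gr.connectivity_matrix(ts)
    ref_mats = [r["conn"] for r in included if r["group"] == ref_group]
    mean_ref = gr.ConnectivityMatrix(
        z=np.mean([m.z for m in ref_mats], axis=0),
        node_ids=ref_mats[0].node_ids,
    )
    partition = gr.detect_communities(mean_ref, sparsity=config.community_sparsity)
    bundle["partition"] = partition
    _write_tsv(
        pd.DataFrame({"node": np.arange(parcellation.n_nodes),
                      "name": [parcellation.names[i + 1]
                               for i in range(parcellation.n_nodes)],
                      "module": partition.assignment}),
        out_dir, "community_structure.tsv",
    )

    # --- stage 6: per-subject graph metrics over the sparsity grid -----------
    node_rows, global_rows = [], []
    for rec in included:
        for S in config.sparsity_grid:
            g = gr.threshold_proportional(rec["conn"], S)
            D = g.degrees()
            sd = D.std()
            # uniform degree distribution: every node sits at the mean
            z = (D - D.mean()) / sd if sd > 0 else np.zeros(len(D))
            C_i, C = gr.clustering_coefficients(g)
            P = gr.participation_coefficients(g, partition)
            connected = g.is_connected()
            for node in range(g.n_nodes):
                node_rows.append({
                    "subject_id": rec["subject_id"], "group": rec["group"],
                    "sparsity": S, "node": node, "degree": int(D[node]),
                    "z_degree": z[node], "clustering": C_i[node],
                    "participation": P[node],
                })
            global_rows.append({
                "subject_id": rec["subject_id"], "group": rec["group"],
                "sparsity": S, "mean_clustering": C,
                "path_length": gr.characteristic_path_length(g) if connected else np.nan,
                "connected": connected,
            })
    node_metrics = pd.DataFrame(node_rows)
    global_metrics = pd.DataFrame(global_rows)

    # small-world normalisation at each subject's minimum connected sparsity
    # (at or above the community sparsity); the sparsity used is recorded
    sw_rows = []
    sw_seed_root = np.random.SeedSequence(config.seed + 1_000_003)
    sw_seeds = sw_seed_root.spawn(len(included))
    for rec, ss in zip(included, sw_seeds):
        s_used, g = None, None
        for S in sorted(config.sparsity_grid):
            if S < config.community_sparsity - 1e-9:
                continue
            cand = gr.threshold_proportional(rec["conn"], S)
            if cand.is_connected():
                s_used, g = S, cand
                break
        if g is None:
            continue
        gm = gr.normalized_global_metrics(
            g, n_random=config.n_random_refs,
            n_swaps_per_edge=config.n_swaps_per_edge,
            seed=np.random.default_rng(ss).integers(2**31),
        )
        sw_rows.append({
            "subject_id": rec["subject_id"], "group": rec["group"],
            "sparsity": s_used,
            "gamma": gm.gamma, "lambda": gm.lam, "sigma": gm.sigma,
        })
    smallworld = pd.DataFrame(sw_rows)
    _write_tsv(node_metrics, out_dir, "node_metrics.tsv")
    _write_tsv(global_metrics, out_dir, "global_metrics.tsv")
    _write_tsv(smallworld, out_dir, "smallworld.tsv")
    bundle["node_metrics"] = node_metrics
    bundle["global_metrics"] = global_metrics
    bundle["smallworld"] = smallworld

    # --- stage 7: group statistics -------------------------------------------
    module_df = gr.module_summaries(node_metrics, partition)
    module_df = module_df.merge(
        node_metrics[["subject_id", "group"]].drop_duplicates(), on="subject_id"
    ) if "group" not in module_df.columns else module_df
    bundle["module_summaries"] = module_df
    _write_tsv(module_df, out_dir, "module_summaries.tsv")

    # module tests at the community sparsity and on the grid mean: a single
    # sparsity bin can saturate (every within-module edge retained) or starve
    # (no between-module edge retained) one of the two module metrics, so the
    # per-subject mean over the whole sparsity grid is tested as well
    mod_seed = np.random.default_rng(stage_seeds["module"])
    S0 = config.community_sparsity
    grid_mean = module_df.groupby(
        ["subject_id", "group", "module"], as_index=False
    )[["z_degree", "participation"]].mean()
    test_rows = []
    for slice_name, frame in (
        (f"S={S0:g}", module_df[np.isclose(module_df["sparsity"], S0)]),
        ("grid_mean", grid_mean),
    ):
        for metric in ("z_degree", "participation"):
            for module in sorted(frame["module"].unique()):
                sub = frame[frame["module"] == module]
                va = sub.loc[sub["group"] == ref_group, metric].to_numpy()
                vb = sub.loc[sub["group"] == other_group, metric].to_numpy()
                res = st.permutation_test(
                    va, vb, n_perm=config.n_perm,
                    seed=int(mod_seed.integers(2**31)),
                )
                test_rows.append({
                    "metric": metric, "module": module, "sparsity": slice_name,
                    f"mean_{ref_group}": va.mean(),
                    f"mean_{other_group}": vb.mean(),
                    "statistic": res.statistic, "p": res.p,
                    "direction": f"{ref_group}>{other_group}" if res.statistic > 0
                                 else f"{other_group}>{ref_group}",
                })
    module_tests = pd.DataFrame(test_rows)
    for slice_name in module_tests["sparsity"].unique():
        for metric in ("z_degree", "participation"):
            sel = (module_tests["metric"] == metric) & (
                module_tests["sparsity"] == slice_name)
            p_adj, _ = st.fdr_adjust(module_tests.loc[sel, "p"].to_numpy(),
                                     q=config.fdr_q)
            module_tests.loc[sel, "p_adjusted"] = p_adj
    bundle["module_tests"] = module_tests
    _write_tsv(module_tests, out_dir, "module_tests.tsv")

    # node-level z-degree tests at S0, FDR corrected
    node_seed = np.random.default_rng(stage_seeds["node"])
    at_s_nodes = node_metrics[np.isclose(node_metrics["sparsity"], S0)]
    nrows = []
    for node in range(parcellation.n_nodes):
        sub = at_s_nodes[at_s_nodes["node"] == node]
        va = sub.loc[sub["group"] == ref_group, "z_degree"].to_numpy()
        vb = sub.loc[sub["group"] == other_group, "z_degree"].to_numpy()
        res = st.permutation_test(va, vb, n_perm=config.n_perm,
                                  seed=int(node_seed.integers(2**31)))
        nrows.append({"node": node, "name": parcellation.names[node + 1],
                      f"mean_{ref_group}": va.mean(),
                      f"mean_{other_group}": vb.mean(),
                      "statistic": res.statistic, "p": res.p})
    node_tests = pd.DataFrame(nrows)
    node_tests["p_adjusted"], node_tests["significant"] = st.fdr_adjust(
        node_tests["p"].to_numpy(), q=config.fdr_q
    )
    bundle["node_tests"] = node_tests
    _write_tsv(node_tests, out_dir, "node_degree_tests.tsv")

    # edge-level tests + top-edge report
    ref_conn = [r["conn"] for r in included if r["group"] == ref_group]
    other_conn = [r["conn"] for r in included if r["group"] == other_group]
    edge_df = st.edge_group_test(ref_conn, other_conn, alpha=config.edge_alpha)
    names0 = {i: parcellation.names[i + 1] for i in range(parcellation.n_nodes)}
    top = st.top_edges(edge_df, k=min(10, int(edge_df["defined"].sum())),
                       node_names=names0)
    bundle["edge_tests"] = edge_df
    bundle["top_edges"] = top
    _write_tsv(top, out_dir, "top_edges.tsv")

    # --- stage 8: motion confound audit --------------------------------------
    sig_edges = edge_df[edge_df["significant"]]
    audit_counts = None
    if len(sig_edges) and len(included) >= 4:
        edge_table = pd.DataFrame({
            f"{int(r.node_i)}-{int(r.node_j)}": [
                rec["conn"].z[int(r.node_i), int(r.node_j)] for rec in included
            ]
            for r in sig_edges.itertuples()
        })
        audit_table, audit_counts = mo.motion_confound_audit(
            edge_table, [rec["summary"] for rec in included],
            alpha=config.audit_alpha,
        )
        _write_tsv(audit_table, out_dir, "motion_audit.tsv")
    bundle["motion_audit_counts"] = audit_counts

    bundle["wall_time_s"] = time.time() - t0
    if out_dir is not None:
        with open(out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(config), fh, sort_keys=True)
        summary = {
            "n_subjects_included": len(included),
            "n_nodes": parcellation.n_nodes,
            "n_modules": partition.n_modules,
            "modularity_q": partition.q,
            "seed": config.seed,
            "wall_time_s": bundle["wall_time_s"],
        }
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return bundle


# ---------------------------------------------------------------------------
# demo

def _match_module(partition, parcellation, syn_config, planted_module: str) -> int:
    """Detected module label best overlapping a planted network module."""
    planted_regions = set(syn_config.module_assignment[planted_module])
    node_planted = np.array([
        parcellation.parent[i + 1] in planted_regions
        for i in range(parcellation.n_nodes)
    ])
    best, best_j = None, -1.0
    for mod, nodes in partition.module_nodes().items():
        in_mod = np.zeros(parcellation.n_nodes, dtype=bool)
        in_mod[nodes] = True
        inter = (in_mod & node_planted).sum()
        union = (in_mod | node_planted).sum()
        j = inter / union if union else 0.0
        if j > best_j:
            best, best_j = mod, j
    return int(best)


def run_demo(
    seed: int = 0,
    out_dir: str | None = None,
    config: PipelineConfig | None = None,
    syn_config: syn.SyntheticConfig | None = None,
) -> dict:
    """Generate the default synthetic cohort, run the pipeline, check recovery.

    The demo plants two effects in the patient group: raised within-module
    coupling in the sensorimotor analogue (expected: higher module mean
    z-degree in patients) and lowered between-module coupling in the visual
    analogue (expected: lower module mean participation in patients).  The
    returned bundle's ``demo_report`` states for each effect whether its
    direction was recovered, with the permutation p-value.
    """
    if syn_config is None:
        syn_config = syn.default_demo_config(seed=seed)
    if config is None:
        config = PipelineConfig(seed=seed, out_dir=out_dir)
    atlas = syn.generate_toy_atlas(syn_config)
    cohort = syn.generate_cohort(syn_config, atlas=atlas)
    bundle = run_pipeline(config, cohort=cohort, atlas=atlas)

    parcellation = bundle["parcellation"]
    partition = bundle["partition"]
    tests = bundle["module_tests"]
    ref, case = bundle["reference_group"], bundle["case_group"]

    report = {"seed": seed}
    sm_mod = _match_module(partition, parcellation, syn_config, "sensorimotor")
    vis_mod = _match_module(partition, parcellation, syn_config, "visual")
    tests = tests[tests["sparsity"] == "grid_mean"]
    row_sm = tests[(tests["metric"] == "z_degree") & (tests["module"] == sm_mod)]
    row_vis = tests[(tests["metric"] == "participation") & (tests["module"] == vis_mod)]
    sm_diff = float(row_sm[f"mean_{case}"].iloc[0] - row_sm[f"mean_{ref}"].iloc[0])
    vis_diff = float(row_vis[f"mean_{case}"].iloc[0] - row_vis[f"mean_{ref}"].iloc[0])
    report["sensorimotor_module"] = sm_mod
    report["visual_module"] = vis_mod
    report["sensorimotor_degree_diff_case_minus_ref"] = sm_diff
    report["sensorimotor_degree_p"] = float(row_sm["p"].iloc[0])
    report["sensorimotor_direction_recovered"] = bool(sm_diff > 0)
    report["visual_participation_diff_case_minus_ref"] = vis_diff
    report["visual_participation_p"] = float(row_vis["p"].iloc[0])
    report["visual_direction_recovered"] = bool(vis_diff < 0)
    report["both_directions_recovered"] = bool(sm_diff > 0 and vis_diff < 0)
    bundle["demo_report"] = report
    if config.out_dir:
        with open(Path(config.out_dir) / "demo_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return bundle
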