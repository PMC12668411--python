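"""End-to-end pipeline: simulate -> position -> qc -> trajectory ->
mi_genes -> cross_species -> trends -> field.

Each stage reads the previous stage's in-memory products, writes its
declared outputs under ``out_dir``, and contributes a block to the run
report (input/output counts, parameters, wall time, warnings). One global
seed fans out to per-stage seeds derived from the stage name, so any stage
can be re-run in isolation reproducibly.

For synthetic runs the pseudotime root cell is taken from the generator's
ground truth (the most peripheral cell), mirroring the practice of rooting
the trajectory at an undifferentiated cell chosen from biological
knowledge; on real inputs the root must be supplied.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cross_species as xs
from . import field as fld
from . import mi_genes, positioning, qc, simulate, trajectory, trends
from .config import PipelineConfig, derive_seed

logger = logging.getLogger("spatime")
STAGE_ORDER = (
    "simulate",
    "position",
    "qc",
    "trajectory",
    "mi_genes",
    "cross_species",
    "trends",
    "field",
)


def validate_config(path: str | Path | None) -> PipelineConfig:
    """Load, validate and normalize a YAML pipeline config.

    Unknown keys, type mismatches and out-of-range values raise with a
    descriptive message; an empty (or absent) file yields the full-default
    configuration.
    """
    data = {}
    if path is not None:
        raw = Path(path).read_text()
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return PipelineConfig(**data)


def _stage_logger(report: dict, name: str):
    t0 = time.time()
    block = {"warnings": []}

    def finish(**outputs):
        block.update(outputs)
        block["wall_time_s"] = round(time.time() - t0, 3)
        report["stages"][name] = block

    return block, finish


def run_pipeline(config: PipelineConfig, only_stage: str | None = None) -> dict:
    """Execute the enabled stages in order and return the run report.

    ``only_stage`` restricts execution to one stage and its required
    upstream stages. Fails fast on stage errors, naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "stages": {},
    }
    enabled = {s: getattr(config.stages, s) for s in STAGE_ORDER}
    if only_stage is not None:
        if only_stage not in STAGE_ORDER:
            raise ValueError(f"unknown stage {only_stage!r}")
        cutoff = STAGE_ORDER.index(only_stage)
        for i, s in enumerate(STAGE_ORDER):
            enabled[s] = enabled[s] and i <= cutoff

    state: dict = {}
    for stage in STAGE_ORDER:
        if not enabled[stage]:
            continue
        logger.info("stage=%s status=start", stage)
        try:
            _STAGES[stage](config, state, report, out)
        except Exception as exc:
            logger.error("stage=%s status=failed error=%s", stage, exc)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage=%s status=done", stage)

    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, default=str))
    return report


# ------------------------------------------------------------------ stages


def _stage_simulate(config: PipelineConfig, state, report, out: Path):
    block, finish = _stage_logger(report, "simulate")
    sim = config.sim.model_copy(
        update={"seed": derive_seed(config.seed, "simulate")}
    )
    truth = simulate.generate_truth(sim)
    whitelist = simulate.generate_bead_array(sim)
    counts_a, counts_b = simulate.generate_expression(sim, truth)
    reads = simulate.generate_spatial_reads(sim, truth, whitelist)
    homology = simulate.generate_ortholog_table(sim, truth)

    simulate.write_whitelist(whitelist, out / "whitelist.csv")
    reads.write(out / "reads_R1.fastq", out / "reads_R2.fastq")
    simulate.write_counts_10x(counts_a, out / "counts_mouse")
    simulate.write_counts_10x(counts_b, out / "counts_human")
    homology.to_csv(out / "homology.tsv", sep="\t", index=False)
    for name, frame in truth.to_frames().items():
        frame.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)

    state.update(
        truth=truth, whitelist=whitelist, counts_a=counts_a, counts_b=counts_b,
        reads=reads, homology=homology,
    )
    finish(
        n_beads=len(whitelist),
        n_cells_a=counts_a.n_obs,
        n_cells_b=counts_b.n_obs,
        n_genes=counts_a.n_vars,
        n_reads=len(reads.r1),
        n_homology_rows=len(homology),
    )


def _stage_position(config: PipelineConfig, state, report, out: Path):
    block, finish = _stage_logger(report, "position")
    if "reads" in state:
        r1, r2 = state["reads"].r1, state["reads"].r2
        whitelist = state["whitelist"]
        called = list(state["truth"].species_a.barcodes)
    else:
        r1, r2 = config.input_fastq_r1, config.input_fastq_r2
        whitelist = pd.read_csv(config.input_whitelist)
        called = state.get("called_cells") or []
    matrix = positioning.parse_spatial_reads(
        r1, r2, whitelist, called, chimera=config.chimera
    )
    positions = positioning.assign_positions(matrix, whitelist, config.dbscan)
    positions.to_csv(out / "positions.tsv", sep="\t", index=False)
    (out / "read_filter_report.json").write_text(json.dumps(matrix.provenance))
    state.update(positions=positions, barcode_matrix=matrix)
    finish(
        reads_in=matrix.provenance["total"],
        reads_pass=matrix.provenance["pass"],
        n_cells_placed=int(positions["placed"].sum()),
        dbscan_eps=positions.attrs["eps"],
        dbscan_min_pts=positions.attrs["min_pts"],
    )


def _stage_qc(config: PipelineConfig, state, report, out: Path):
    block, finish = _stage_logger(report, "qc")
    if "counts_a" not in state:
        if config.input_counts_dir is None:
            raise ValueError("qc stage requires counts (enable simulate or set input_counts_dir)")
        state["counts_a"] = simulate.read_counts_10x(config.input_counts_dir)
    counts = {}
    for tag in ("a", "b"):
        key = f"counts_{tag}"
        if key not in state:
            continue
        adata = state[key]
        keep, qrep = qc.filter_cells(adata, config.qc)
        kept = adata[keep].copy()
        dparams = config.doublets.model_copy(
            update={"seed": derive_seed(config.seed, f"doublets_{tag}")}
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            is_doub, tally = qc.detect_doublets(kept, dparams)
            block["warnings"] += [str(w.message) for w in caught]
        final = kept[~is_doub].copy()
        counts[tag] = final
        mask = pd.DataFrame(
            {"cell": adata.obs_names, "kept": keep}
        )
        mask.to_csv(out / f"qc_mask_{tag}.tsv", sep="\t", index=False)
        payload = qrep.to_dict()
        payload["n_doublets_removed"] = int(is_doub.sum())
        payload["doublet_tally"] = tally.to_dict(orient="list")
        (out / f"qc_report_{tag}.json").write_text(json.dumps(payload))
        block[f"n_kept_{tag}"] = final.n_obs
    state["qc_a"] = counts.get("a")
    state["qc_b"] = counts.get("b")
    finish()


def _pseudotime_for(config: PipelineConfig, adata, root: int):
    tp = config.trajectory
    norm = trajectory.normalize_log(adata, tp.target_sum)
    hvgs = trajectory.select_hvgs(adata, n=min(tp.n_hvgs, adata.n_vars))
    emb = trajectory.embed(norm, d=min(tp.n_components, len(hvgs) - 1), hvgs=hvgs)
    pt = trajectory.diffusion_pseudotime(
        emb, root=root, k=tp.k_neighbors, n_comps=tp.n_diffusion_comps
    )
    return norm, emb, pt


def _root_from_truth(adata, truth_sp) -> int:
    """Most peripheral (least differentiated) retained cell."""
    t_true = adata.obs["true_pseudotime"].to_numpy(np.float64)
    if np.isnan(t_true).all():
        return 0
    return int(np.nanargmin(t_true))


def _stage_trajectory(config: PipelineConfig, state, report, out: Path):
    block, finish = _stage_logger(report, "trajectory")
    for tag in ("a", "b"):
        adata = state.get(f"qc_{tag}")
        if adata is None:
            continue
        root = (
            _root_from_truth(adata, None)
            if "true_pseudotime" in adata.obs
            else 0
        )
        norm, emb, pt = _pseudotime_for(config, adata, root)
        state[f"norm_{tag}"] = norm
        state[f"emb_{tag}"] = emb
        state[f"pt_{tag}"] = pt
        df = pd.DataFrame(
            {
                "cell": adata.obs_names,
                "t": pt.t,
                "root": adata.obs_names[pt.root],
                "n_comps": pt.n_diffusion_comps,
            }
        )
        df.to_csv(out / f"pseudotime_{tag}.tsv", sep="\t", index=False)
        np.savetxt(out / f"embedding_{tag}.tsv", emb.coords, delimiter="\t")
        block[f"n_cells_{tag}"] = adata.n_obs
    finish()


def _stage_mi(config: PipelineConfig, state, report, out: Path):
    block, finish = _stage_logger(report, "mi_genes")
    for tag in ("a", "b"):
        norm = state.get(f"norm_{tag}")
        if norm is None:
            continue
        pconf = config.permutation.model_copy(
            update={"seed": derive_seed(config.seed, f"mi_{tag}")}
        )
        results = mi_genes.permutation_fdr(norm, state[f"pt_{tag}"].t, pconf)
        results.to_csv(out / f"mi_results_{tag}.tsv", sep="\t", index=False)
        state[f"mi_{tag}"] = results
        summary = results.attrs.get("summary")
        block[f"n_significant_{tag}"] = summary.n_significant if summary else 0
        block[f"n_top_hits_{tag}"] = summary.n_top_hits if summary else 0
    finish()


def _stage_cross_species(config: PipelineConfig, state, report, out: Path):
    block, finish = _stage_logger(report, "cross_species")
    pairs = xs.one_to_one_orthologs(state["homology"])
    background = xs.build_background(
        pairs,
        state["qc_a"],
        state["qc_b"],
        state["mi_a"],
        state["mi_b"],
        min_expr_frac=config.permutation.min_expr_frac,
    )
    top_a = set(state["mi_a"].loc[state["mi_a"]["top_hit"], "gene"])
    top_b = set(state["mi_b"].loc[state["mi_b"]["top_hit"], "gene"])
    test = xs.overlap_from_sets(background.pairs, top_a, top_b)
    shared = [
        p for p in background.pairs if p[0] in top_a and p[1] in top_b
    ]
    pd.DataFrame(shared, columns=["gene_a", "gene_b"]).to_csv(
        out / "shared_top_pairs.tsv", sep="\t", index=False
    )
    (out / "overlap_test.json").write_text(json.dumps(test.to_dict()))
    state["overlap"] = test
    state["background"] = background
    finish(
        n_one_to_one=len(pairs),
        background_size=background.size,
        **test.to_dict(),
    )


def _stage_trends(config: PipelineConfig, state, report, out: Path):
    block, finish = _stage_logger(report, "trends")
    mi_a = state["mi_a"]
    genes = mi_a.loc[mi_a["top_hit"], "gene"].tolist()
    if not genes:  # fall back to best significant genes for the heatmap
        genes = mi_a.sort_values("mi", ascending=False)["gene"].head(5).tolist()
    traj = trends.smooth_gene_panel(
        state["norm_a"], state["pt_a"].t, genes, config.gam
    )
    np.savetxt(out / "trend_heatmap.tsv", traj.matrix, delimiter="\t")
    pd.DataFrame(
        {"gene": traj.genes, "peak_index": traj.peak_index}
    ).to_csv(out / "trend_gene_order.tsv", sep="\t", index=False)
    state["trends"] = traj
    finish(n_genes_smoothed=len(traj.genes))


def _stage_field(config: PipelineConfig, state, report, out: Path):
    block, finish = _stage_logger(report, "field")
    positions = state["positions"]
    adata = state["qc_a"]
    pt = pd.DataFrame({"cell": adata.obs_names, "t": state["pt_a"].t})
    placed = positions.loc[positions["placed"], ["cell", "x", "y"]]
    pts = placed.merge(pt, on="cell", how="inner")
    filtered = fld.remove_spatial_outliers(pts, config.outliers)
    grid = fld.fit_pseudotime_surface(filtered, config.field)
    result = fld.gradient_field(grid, config.field)
    np.savetxt(out / "field_surface.tsv", result.surface, delimiter="\t")
    np.savetxt(out / "field_du.tsv", result.du, delimiter="\t")
    np.savetxt(out / "field_dv.tsv", result.dv, delimiter="\t")
    np.savetxt(out / "field_mask.tsv", result.mask.astype(int), delimiter="\t", fmt="%d")
    state["field"] = result
    finish(
        n_points_in=len(pts),
        n_points_used=len(filtered),
        n_outliers_removed=len(pts) - len(filtered),
        grid_shape=list(result.surface.shape),
    )


_STAGES = {
    "simulate": _stage_simulate,
    "position": _stage_position,
    "qc": _stage_qc,
    "trajectory": _stage_trajectory,
    "mi_genes": _stage_mi,
    "cross_species": _stage_cross_species,
    "trends": _stage_trends,
    "field": _stage_field,
}
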