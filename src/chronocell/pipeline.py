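"""End-to-end orchestration: counts -> QC -> scores -> phases -> report.

Stages run in a fixed order (simulate/load, QC, filter, normalize,
HVG, scale, PCA, cluster, module scores, phase bins/scores/calls,
trajectory, DE, phase shift), each writing a TSV artifact that can be
re-loaded independently, plus a structured JSON run log. The whole
run is deterministic from the single seed in the config.
"""
from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .clustering import cluster_graph, knn_graph
from .de import wilcoxon_de
from .io import (
    CountMatrix,
    GeneSet,
    PhaseTable,
    QCThresholds,
    read_10x_dir,
    read_gene_sets,
    read_phase_table,
)
from .phase import aggregate_by_cluster, build_phase_bins, call_phase, phase_scores, phase_shift
from .preprocess import (
    DEFAULT_SCALE_FACTOR,
    filter_cells,
    normalize_log,
    pca,
    qc_metrics,
    scale_center,
    select_variable_genes,
)
from .score import mixture_bimodality, positive_fraction, score
from .simulate import SimConfig, make_gene_sets, make_phase_table, simulate
from .trajectory import circular_pseudotime, pseudotime_heatmap_data


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for actionable messages."""

    def __init__(self, stage, original):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {original}")


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults follow the published analysis
    (QC 100 genes / 300 UMIs, scale factor 10,000, 20 PCs, clustering
    resolution 0.5, adjusted P < 0.05)."""

    counts_dir: str | None = None
    gene_sets_path: str | None = None
    phase_table_path: str | None = None
    sim: SimConfig | None = None

    qc: QCThresholds = field(default_factory=QCThresholds)
    scale_factor: float = DEFAULT_SCALE_FACTOR
    n_top_hvg: int = 2000
    n_pcs: int = 20
    k_neighbors: int = 20
    resolution: float = 0.5
    n_score_bins: int = 24
    n_ctrl: int = 100
    phase_method: str = "timetable"
    n_perm: int = 1000
    compare_samples: tuple | None = None  # (A, B) for DE and phase shift
    trajectory_sample: str | None = None
    division_set: str = "division"
    bimodality_set: str | None = None
    seed: int = 0


def demo_config(seed: int = 0, n_cells: int = 300, n_genes: int = 1500) -> PipelineConfig:
    """Small simulated Fe+/Fe-/Mix design exercising every stage."""
    sim = SimConfig(
        n_cells_per_sample=n_cells,
        n_genes=n_genes,
        sample_names=("Fe+", "Fe-"),
        frac_rhythmic=0.25,
        amplitude=1.0,
        cell_phase_kappa=2.0,
        phase_delay=2.0,
        delay_sample="Fe-",
        regulons={"Fe-": (GeneSet("iron", [f"iron{i}" for i in range(60)]), 2.0)},
        division_frac_outside_window={"Fe+": 0.07, "Fe-": 0.30, "Mix": 0.07},
        mixture_of={"Mix": ("Fe+", "Fe-")},
        mean_umis_per_cell=1500.0,
        nb_dispersion=0.5,
        seed=seed,
    )
    return PipelineConfig(
        sim=sim,
        compare_samples=("Fe+", "Fe-"),
        trajectory_sample="Fe+",
        bimodality_set="iron",
        seed=seed,
    )


def run_all(config: PipelineConfig, outdir) -> dict:
    """Execute every stage, write artifacts under `outdir`, return the bundle."""
    import os

    os.makedirs(outdir, exist_ok=True)
    bundle: dict = {"config": config, "outdir": str(outdir)}
    log: dict = {
        "chronocell_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": [],
    }
    t_start = time.perf_counter()

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise PipelineStageError(name, exc) from exc
        log["stages"].append({"stage": name, "elapsed_s": round(time.perf_counter() - t0, 3)})
        return out

    # --- inputs
    def load():
        if config.sim is not None:
            matrix, truth = simulate(config.sim)
            gene_sets = make_gene_sets(truth)
            phase_table = make_phase_table(truth)
            truth.cells.to_csv(os.path.join(outdir, "truth_cells.tsv"), sep="\t")
            truth.genes.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t")
            bundle["truth"] = truth
        elif config.counts_dir is not None:
            matrix = read_10x_dir(config.counts_dir)
            gene_sets = read_gene_sets(config.gene_sets_path) if config.gene_sets_path else []
            phase_table = (
                read_phase_table(config.phase_table_path) if config.phase_table_path else None
            )
        else:
            raise ValueError("config must provide either sim or counts_dir")
        return matrix, gene_sets, phase_table

    matrix, gene_sets, phase_table = stage("load", load)
    bundle["gene_sets"] = gene_sets
    bundle["phase_table"] = phase_table

    qc = stage("qc", lambda: qc_metrics(matrix))
    qc.per_cell.to_csv(os.path.join(outdir, "qc_cells.tsv"), sep="\t")
    qc.per_sample.to_csv(os.path.join(outdir, "qc_samples.tsv"), sep="\t")
    bundle["qc"] = qc

    filtered = stage("filter", lambda: filter_cells(matrix, config.qc))
    norm = stage("normalize", lambda: normalize_log(filtered, config.scale_factor))
    bundle["norm"] = norm

    hvg = stage("hvg", lambda: select_variable_genes(norm, config.n_top_hvg))
    scaled, kept = stage("scale", lambda: scale_center(norm, hvg))
    embedding = stage("pca", lambda: pca(scaled, min(config.n_pcs, min(scaled.shape))))
    pd.DataFrame(
        embedding,
        index=pd.Index(norm.barcodes, name="barcode"),
        columns=[f"PC{i + 1}" for i in range(embedding.shape[1])],
    ).to_csv(os.path.join(outdir, "embedding.tsv"), sep="\t")
    bundle["embedding"] = embedding

    def do_cluster():
        graph = knn_graph(embedding, k=min(config.k_neighbors, embedding.shape[0] - 1))
        return cluster_graph(graph, resolution=config.resolution, seed=config.seed)

    clusters = stage("cluster", do_cluster)
    pd.Series(
        clusters.labels, index=pd.Index(norm.barcodes, name="barcode"), name="cluster"
    ).to_csv(os.path.join(outdir, "clusters.tsv"), sep="\t")
    bundle["clusters"] = clusters

    # --- module scores for every supplied gene set
    def do_scores():
        cols = {}
        for gs in gene_sets:
            present = [g for g in gs.members if g in set(norm.genes)]
            if not present:
                continue
            cols[gs.name] = score(
                norm, GeneSet(gs.name, present),
                n_bins=config.n_score_bins, n_ctrl=config.n_ctrl, seed=config.seed,
            ).scores
        return pd.DataFrame(cols, index=pd.Index(norm.barcodes, name="barcode"))

    scores_df = stage("module_scores", do_scores)
    scores_df.to_csv(os.path.join(outdir, "module_scores.tsv"), sep="\t")
    bundle["module_scores"] = scores_df

    if config.division_set in scores_df.columns:
        frac = positive_fraction(scores_df[config.division_set].to_numpy(), norm.sample)
        frac.to_csv(os.path.join(outdir, "division_fractions.tsv"), sep="\t")
        bundle["division_fractions"] = frac

    bim_set = config.bimodality_set
    if bim_set and bim_set in scores_df.columns:
        rows = []
        for name in pd.unique(norm.sample):
            vals = scores_df.loc[norm.sample == name, bim_set].to_numpy()
            if vals.size >= 50:
                fit = mixture_bimodality(vals)
                rows.append({"sample": name, "set": bim_set,
                             "ashman_d": fit["ashman_d"], "bimodal": fit["bimodal"]})
        bim = pd.DataFrame(rows)
        bim.to_csv(os.path.join(outdir, "bimodality.tsv"), sep="\t", index=False)
        bundle["bimodality"] = bim

    # --- diurnal phase
    if phase_table is not None and len(phase_table):
        bins = stage("phase_bins", lambda: build_phase_bins(phase_table))
        psm = stage(
            "phase_scores",
            lambda: phase_scores(norm, bins, n_bins=config.n_score_bins,
                                 n_ctrl=config.n_ctrl, seed=config.seed),
        )
        psm.to_csv(os.path.join(outdir, "phase_scores.tsv"), sep="\t")
        bundle["phase_scores"] = psm

        cluster_means = aggregate_by_cluster(psm, clusters)
        cluster_means.to_csv(os.path.join(outdir, "cluster_phase_means.tsv"), sep="\t")
        bundle["cluster_phase_means"] = cluster_means

        calls = stage("phase_calls", lambda: call_phase(psm, method=config.phase_method))
        calls.to_csv(os.path.join(outdir, "phase_calls.tsv"), sep="\t")
        bundle["phase_calls"] = calls

        traj_name = config.trajectory_sample or norm.sample[0]
        traj_mask = norm.sample == traj_name

        def do_trajectory():
            return circular_pseudotime(psm.loc[traj_mask]) if traj_mask.sum() >= 100 else None

        pt = stage("trajectory", do_trajectory)
        if pt is not None:
            pt.to_series().to_csv(os.path.join(outdir, "pseudotime.tsv"), sep="\t")
            heat = pseudotime_heatmap_data(psm.loc[traj_mask], pt)
            heat.to_csv(os.path.join(outdir, "pseudotime_heatmap.tsv"), sep="\t")
            bundle["pseudotime"] = pt
            bundle["pseudotime_heatmap"] = heat

        pair = config.compare_samples or _default_pair(norm.sample)
        if pair is not None:
            a, b = pair
            shift = stage(
                "phase_shift",
                lambda: phase_shift(
                    calls.loc[norm.sample == a, "phase_hat"].to_numpy(dtype=float),
                    calls.loc[norm.sample == b, "phase_hat"].to_numpy(dtype=float),
                    n_perm=config.n_perm,
                    seed=config.seed,
                ),
            )
            shift_row = {"sample_a": a, "sample_b": b, **shift}
            pd.DataFrame([shift_row]).to_csv(
                os.path.join(outdir, "phase_shift.tsv"), sep="\t", index=False
            )
            bundle["phase_shift"] = shift_row

    # --- differential expression
    pair = config.compare_samples or _default_pair(norm.sample)
    if pair is not None:
        a, b = pair
        de = stage("de", lambda: wilcoxon_de(norm, norm.sample == a, norm.sample == b))
        de.to_csv(os.path.join(outdir, "de.tsv"), sep="\t")
        bundle["de"] = de

    log["total_elapsed_s"] = round(time.perf_counter() - t_start, 3)
    log["n_cells_raw"] = int(matrix.n_cells)
    log["n_cells_kept"] = int(norm.n_cells)
    log["n_genes"] = int(norm.n_genes)
    log["params"] = asdict(config)
    with open(os.path.join(outdir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    bundle["log"] = log
    return bundle


def _default_pair(sample_labels):
    names = list(pd.unique(sample_labels))
    return tuple(names[:2]) if len(names) >= 2 else None


def report(bundle: dict) -> str:
    """Human-readable run summary (QC, scores, fractions, phases, shift)."""
    lines = ["chronocell run report", "=" * 21, ""]
    qc = bundle.get("qc")
    if qc is not None:
        lines.append("Per-sample QC means:")
        lines.append(qc.per_sample.round(2).to_string())
        lines.append("")
    scores = bundle.get("module_scores")
    if scores is not None and not scores.empty:
        norm = bundle["norm"]
        summary = scores.groupby(pd.Series(norm.sample, index=scores.index)).mean()
        lines.append("Per-sample module-score means:")
        lines.append(summary.round(3).to_string())
        lines.append("")
    frac = bundle.get("division_fractions")
    if frac is not None:
        lines.append("Division-positive fraction per sample:")
        lines.append(frac.round(3).to_string())
        lines.append("")
    bim = bundle.get("bimodality")
    if bim is not None and len(bim):
        lines.append("Score bimodality (Ashman's D; > 2 = bimodal):")
        lines.append(bim.round(2).to_string(index=False))
        lines.append("")
    cm = bundle.get("cluster_phase_means")
    if cm is not None:
        lines.append(f"Cluster x phase-bin score matrix ({cm.shape[0]} clusters x "
                     f"{cm.shape[1]} bins):")
        lines.append(cm.round(3).to_string())
        lines.append("")
    if "pseudotime" not in bundle:
        lines.append("Trajectory stage skipped (too few cells in the target sample).")
        lines.append("")
    shift = bundle.get("phase_shift")
    if shift is not None:
        lines.append(
            f"Phase shift {shift['sample_b']} - {shift['sample_a']}: "
            f"{shift['delta_hours']:+.2f} h (permutation p = {shift['p_value']:.4g}, "
            f"n = {shift['n_a']}/{shift['n_b']})"
        )
        lines.append("")
    de = bundle.get("de")
    if de is not None:
        lines.append(f"Differential expression: {int(de['significant'].sum())} genes at "
                     f"adjusted P < 0.05 (of {len(de)} tested)")
    return "\n".join(lines)
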