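"""End-to-end orchestration: QC -> cluster/annotate -> pseudotime ->
mixed model -> trajectory screen -> signatures, with manifests.

`run_pipeline_data` drives the analysis on in-memory inputs and is what
the tests and examples call; `run_pipeline` is the file-facing wrapper
reading a config (YAML/dict) of paths and stage parameters;
`simulate_and_run` chains the synthetic generator in front and appends a
truth-vs-inferred recovery report. Identical config + seed reproduce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from . import __version__
from .containers import CountMatrix, read_mtx_dir, validate_meta
from .clustering import (
    annotate_clusters,
    build_knn_graph,
    cluster_flow_table,
    cluster_sweep,
    connected_components,
    wilcoxon_markers,
)
from .datagen import (
    DEFAULT_MARKER_PANELS,
    HOMEOSTATIC_PANEL,
    SimulationConfig,
    simulate_dataset,
    truth_signature,
    write_dataset,
)
from .mixed_model import fit_random_intercept_lmm
from .pseudotime import diffusion_map, diffusion_pseudotime, root_axis, select_root
from .qc import filter_genes_min_nuclei, filter_nuclei_gene_count, knn_smooth, normalize_log
from .screen import (
    ScreenConfig,
    classify_dysregulated,
    gene_trajectory_regression,
    ma_table,
    rank_uniform,
    refine_trajectory,
)

__all__ = [
    "PipelineParams",
    "PipelineError",
    "PipelineResult",
    "run_pipeline",
    "run_pipeline_data",
    "simulate_and_run",
]

log = logging.getLogger("astrotraj")


class PipelineError(RuntimeError):
    """A stage failed; the failing stage is named and partial outputs kept."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineParams:
    """Stage parameters of a run (paths live in the file-facing config)."""

    min_nuclei: int = 30
    max_genes: int = 2500
    target_sum: float | None = None
    denoise: str = "knn"           # none | knn
    denoise_k: int = 30            # smoothing for markers / screened expression
    embed_k: int = 60              # heavier smoothing for embedding & pseudotime
    denoise_n_pcs: int = 50
    cluster_n_pcs: int = 50
    cluster_k: int = 30
    resolutions: list[float] = field(default_factory=lambda: [0.1, 0.25, 0.5, 1.0])
    target_n_clusters: int = 4
    marker_q: float = 0.05
    panels: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MARKER_PANELS.items()}
    )
    homeostatic_panel: list[str] = field(default_factory=lambda: list(HOMEOSTATIC_PANEL))
    dpt_n_comps: int = 15
    # principal-curve-style refinement passes applied to the diffusion
    # pseudotime of the analysis population before the mixed model and
    # the screen (0 disables)
    refine_iterations: int = 2
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    # split-half reproducibility gate: the screen only calls genes when
    # independently inferred half-cohort trajectories agree on the gene
    # slope vector (|r| above the threshold); guards against trajectories
    # built from noise
    gate_threshold: float = 0.2
    gate_min_nuclei: int = 200
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        d = dict(d)
        if "screen" in d and isinstance(d["screen"], dict):
            d["screen"] = ScreenConfig(**d["screen"])
        return cls(**d)


@dataclass
class PipelineResult:
    expr_gene_ids: np.ndarray
    cluster_assignments: pd.DataFrame
    analysis_resolution: float
    markers: pd.DataFrame
    cluster_labels: pd.DataFrame
    nucleus_labels: pd.Series           # per retained nucleus, population label
    flow_table: pd.DataFrame
    pseudotime: pd.DataFrame            # nucleus_id, t, is_root, population
    lmm: dict[str, object]
    screen_records: pd.DataFrame
    signature: object
    ma: pd.DataFrame
    n_nuclei: int
    n_genes: int
    reproducibility: float = float("nan")
    outdir: Path | None = None


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, exc) from exc
            log.info("stage %s: done", name)
            return out
        return wrapped
    return deco


def _infer_pseudotime(
    expr, params: PipelineParams, homeostatic_panel: list[str], candidate_ids=None
):
    """Embed, root and order one expression matrix (helper shared by the
    main pseudotime stage and the split-half reproducibility gate).

    ``candidate_ids`` restricts root selection (e.g. to protoplasmic
    nuclei); the graph is restricted to its largest connected component.
    """
    k = min(params.cluster_k, expr.n_nuclei - 1)
    graph = build_knn_graph(expr, params.cluster_n_pcs, k)
    comps = connected_components(graph)
    largest = np.argmax(np.bincount(comps))
    keep = comps == largest
    if not keep.all():
        log.info("pseudotime: restricting to largest component (%d of %d nuclei)",
                 int(keep.sum()), expr.n_nuclei)
        expr = expr.subset_nuclei(keep)
        graph = build_knn_graph(expr, params.cluster_n_pcs, min(k, expr.n_nuclei - 1))
    dmap = diffusion_map(graph, params.dpt_n_comps)
    panel = [g for g in homeostatic_panel if g in expr.gene_ids]
    if panel:
        score = expr.values[:, [expr.gene_index(g) for g in panel]].mean(axis=1)
    else:
        log.warning("no homeostatic panel genes present; axis sign unanchored")
        score = np.zeros(expr.n_nuclei)
    axis = root_axis(dmap, score)
    candidates = np.arange(expr.n_nuclei)
    if candidate_ids is not None:
        restricted = np.flatnonzero(pd.Index(expr.nucleus_ids).isin(candidate_ids))
        if restricted.size:
            candidates = restricted
    root = select_root(axis, candidates, score, expr.nucleus_ids)
    result = diffusion_pseudotime(dmap, root, expr.nucleus_ids)
    return expr, result


def trajectory_reproducibility(
    raw_expr, params: PipelineParams
) -> float:
    """|Pearson r| between per-gene slopes of two half-cohort trajectories.

    Nuclei are split at random (seeded); each half gets its own smoothed
    embedding, root and diffusion pseudotime, and the raw expression of
    each half is regressed on its own ranked pseudotime. A genuine
    trajectory yields strongly correlated slope vectors; an axis fit to
    noise does not reproduce across halves.
    """
    from .screen import _ols_columns  # local import to avoid cycle noise

    n = raw_expr.n_nuclei
    perm = np.random.default_rng(params.seed).permutation(n)
    betas = []
    for half in (perm[: n // 2], perm[n // 2 :]):
        mask = np.zeros(n, dtype=bool)
        mask[half] = True
        sub = raw_expr.subset_nuclei(mask)
        k_e = min(params.embed_k, sub.n_nuclei - 1)
        emb = knn_smooth(sub, k_e, params.denoise_n_pcs) if k_e > 0 else sub
        emb, result = _infer_pseudotime(emb, params, params.homeostatic_panel)
        sub = sub.subset_nuclei(pd.Index(sub.nucleus_ids).isin(result.nucleus_ids))
        ranked = rank_uniform(result.t)
        beta, _, _ = _ols_columns(sub.values, ranked)
        betas.append(beta)
    r = np.corrcoef(betas[0], betas[1])[0, 1]
    return float(abs(r)) if np.isfinite(r) else 0.0


def run_pipeline_data(
    counts: CountMatrix,
    meta: pd.DataFrame,
    params: PipelineParams | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory counts + metadata."""
    params = params or PipelineParams()
    meta = validate_meta(meta)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    @_stage("qc")
    def qc_stage():
        filtered = filter_genes_min_nuclei(counts, params.min_nuclei)
        filtered = filter_nuclei_gene_count(filtered, params.max_genes)
        raw = normalize_log(filtered, params.target_sum)
        if params.denoise == "knn":
            k_d = min(params.denoise_k, raw.n_nuclei - 1)
            k_e = min(params.embed_k, raw.n_nuclei - 1)
            denoised = knn_smooth(raw, k_d, params.denoise_n_pcs) if k_d > 0 else raw
            embed = knn_smooth(raw, k_e, params.denoise_n_pcs) if k_e > 0 else raw
        elif params.denoise == "none":
            denoised = embed = raw
        else:
            raise ValueError(f"unknown denoise mode {params.denoise!r}")
        return raw, denoised, embed

    raw_expr, expr, embed_expr = qc_stage()
    kept = pd.Index(expr.nucleus_ids, name="nucleus_id")
    meta_kept = meta.set_index("nucleus_id").loc[kept].reset_index()

    @_stage("cluster")
    def cluster_stage():
        graph = build_knn_graph(embed_expr, params.cluster_n_pcs, params.cluster_k)
        assignments = cluster_sweep(graph, params.resolutions, params.seed)
        n_clusters = assignments.nunique()
        usable = n_clusters[n_clusters >= 2]
        if len(usable):
            pick = (usable - params.target_n_clusters).abs().idxmin()
            labels = assignments[pick].to_numpy()
            markers = wilcoxon_markers(expr, labels)
            cluster_labels = annotate_clusters(markers, params.panels, params.marker_q)
            label_of = dict(zip(cluster_labels["cluster"], cluster_labels["label"]))
            nucleus_labels = pd.Series(
                [label_of[c] for c in labels], index=kept, name="population"
            )
        else:
            # one cluster at every resolution: nothing to annotate
            log.warning("single cluster at every resolution; skipping annotation")
            pick = assignments.columns[0]
            markers = pd.DataFrame(
                columns=["cluster", "gene", "logfc", "statistic", "p", "q"]
            )
            cluster_labels = pd.DataFrame({"cluster": [0], "label": ["unassigned"]})
            nucleus_labels = pd.Series("unassigned", index=kept, name="population")
        flow = cluster_flow_table(assignments) if assignments.shape[1] > 1 else pd.DataFrame()
        return graph, assignments, pick, markers, cluster_labels, nucleus_labels, flow

    graph, assignments, pick, markers, cluster_labels, nucleus_labels, flow = cluster_stage()

    # when no cluster matches an astrocyte panel (e.g. a pre-subset
    # second cell type fed through the same pipeline), analyze all
    # nuclei as a single trajectory population
    if not nucleus_labels.isin(["protoplasmic", "fibrous"]).any():
        log.warning(
            "no cluster matched an astrocyte marker panel; "
            "treating all nuclei as one analysis population"
        )
        nucleus_labels = pd.Series("protoplasmic", index=kept, name="population")

    @_stage("pseudotime")
    def pseudotime_stage():
        astro_mask = nucleus_labels.isin(["protoplasmic", "fibrous"]).to_numpy()
        if astro_mask.sum() < 10:
            raise ValueError("too few astrocyte nuclei after annotation")
        sub = embed_expr.subset_nuclei(astro_mask)
        proto_ids = nucleus_labels.index[nucleus_labels == "protoplasmic"]
        sub, result = _infer_pseudotime(
            sub, params, params.homeostatic_panel, candidate_ids=proto_ids
        )
        sub_labels = nucleus_labels.loc[sub.nucleus_ids]
        frame = result.to_frame()
        frame["population"] = sub_labels.to_numpy()
        frame["t_dpt"] = frame["t"]
        if params.refine_iterations > 0:
            proto = (sub_labels == "protoplasmic").to_numpy()
            if proto.sum() >= 10:
                ids = frame.loc[proto, "nucleus_id"]
                mask = pd.Index(expr.nucleus_ids).isin(ids)
                t_ref = refine_trajectory(
                    expr.subset_nuclei(mask),
                    frame.loc[proto, "t"].to_numpy(),
                    params.screen,
                    raw_expr=raw_expr.subset_nuclei(mask) if expr.smoothed else None,
                    n_iter=params.refine_iterations,
                )
                frame.loc[proto, "t"] = t_ref
        return frame

    pt = pseudotime_stage()

    @_stage("mixed_model")
    def lmm_stage():
        out: dict[str, object] = {}
        meta_idx = meta_kept.set_index("nucleus_id")
        for pop in ("protoplasmic", "fibrous"):
            rows = pt[pt["population"] == pop]
            if len(rows) < 10:
                continue
            sub_meta = meta_idx.loc[rows["nucleus_id"]].reset_index()
            if sub_meta["sample"].nunique() < 2:
                continue
            try:
                out[pop] = fit_random_intercept_lmm(rows["t"].to_numpy(), sub_meta)
            except ValueError as exc:
                log.warning("mixed model for %s skipped: %s", pop, exc)
        return out

    lmm = lmm_stage()

    @_stage("screen")
    def screen_stage():
        rows = pt[pt["population"] == "protoplasmic"]
        mask = pd.Index(expr.nucleus_ids).isin(rows["nucleus_id"])
        sub = expr.subset_nuclei(mask)
        raw_sub = raw_expr.subset_nuclei(mask)
        order = pd.Index(sub.nucleus_ids)
        t_vals = rows.set_index("nucleus_id").loc[order, "t"].to_numpy()
        ranked = rank_uniform(t_vals, rescale=params.screen.rescale_ranks)
        records = gene_trajectory_regression(
            sub, ranked, params.screen, raw_expr=raw_sub if sub.smoothed else None
        )
        gate = float("nan")
        if params.gate_threshold > 0 and sub.n_nuclei >= params.gate_min_nuclei:
            gate = trajectory_reproducibility(raw_sub, params)
            if gate < params.gate_threshold:
                log.warning(
                    "trajectory reproducibility %.3f below %.2f: no genes called",
                    gate, params.gate_threshold,
                )
                records["status"] = "ns"
        signature = classify_dysregulated(records)
        ma = ma_table(records, params.screen)
        return records, signature, ma, gate

    records, signature, ma, gate = screen_stage()

    result = PipelineResult(
        expr_gene_ids=expr.gene_ids,
        cluster_assignments=assignments,
        analysis_resolution=pick,
        markers=markers,
        cluster_labels=cluster_labels,
        nucleus_labels=nucleus_labels,
        flow_table=flow,
        pseudotime=pt,
        lmm=lmm,
        screen_records=records,
        signature=signature,
        ma=ma,
        n_nuclei=expr.n_nuclei,
        n_genes=expr.n_genes,
        reproducibility=gate,
        outdir=outdir,
    )
    if outdir is not None:
        _persist(result, params, outdir)
    return result


def _persist(result: PipelineResult, params: PipelineParams, outdir: Path) -> None:
    result.cluster_assignments.to_csv(outdir / "cluster_assignments.tsv", sep="\t", index=False)
    result.markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
    result.cluster_labels.to_csv(outdir / "cluster_labels.tsv", sep="\t", index=False)
    if len(result.flow_table):
        result.flow_table.to_csv(outdir / "cluster_flow.tsv", sep="\t", index=False)
    result.pseudotime.to_csv(outdir / "pseudotime.tsv", sep="\t", index=False)
    for pop, fit in result.lmm.items():
        fit.coefficients.to_csv(outdir / f"lmm_{pop}.tsv", sep="\t", index=False)
    result.screen_records.to_csv(outdir / "screen_records.tsv", sep="\t", index=False)
    result.ma.to_csv(outdir / "ma_table.tsv", sep="\t", index=False)
    sig = result.signature
    pd.DataFrame(
        {"gene": sig.genes, "direction": [sig.directions[g] for g in sig.genes]}
    ).to_csv(outdir / "signature.tsv", sep="\t", index=False)
    params_dict = dataclasses.asdict(params)
    blob = json.dumps(params_dict, sort_keys=True, default=str)
    manifest = {
        "package_version": __version__,
        "seed": params.seed,
        "params": params_dict,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
        "n_nuclei": result.n_nuclei,
        "n_genes": result.n_genes,
        "analysis_resolution": float(result.analysis_resolution),
        "trajectory_reproducibility": result.reproducibility,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> PipelineResult:
    """File-facing entry point: config holds paths + stage parameters.

    Expected keys: ``paths: {counts_dir, metadata?}``, optional ``params``
    (see :class:`PipelineParams`), ``seed``, ``outdir``. All referenced
    paths are validated before any stage runs.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    paths = config.get("paths", {})
    counts_dir = paths.get("counts_dir")
    if counts_dir is None:
        raise ValueError("config paths.counts_dir is required")
    counts_dir = Path(counts_dir)
    if not counts_dir.exists():
        raise FileNotFoundError(f"counts directory not found: {counts_dir}")
    meta_path = paths.get("metadata")
    if meta_path is not None and not Path(meta_path).exists():
        raise FileNotFoundError(f"metadata file not found: {meta_path}")
    params = PipelineParams.from_dict(config.get("params", {}))
    if "seed" in config:
        params.seed = int(config["seed"])
    counts, meta = read_mtx_dir(counts_dir)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t")
    if meta is None:
        raise ValueError("no metadata found (counts_dir/metadata.tsv or paths.metadata)")
    outdir = outdir or config.get("outdir")
    return run_pipeline_data(counts, meta, params, outdir)


def recovery_report(result: PipelineResult, truth) -> dict:
    """Compare pipeline output against the generator's ground truth."""
    truth_nuclei = truth.nuclei.set_index("nucleus_id")
    pt = result.pseudotime
    proto = pt[pt["population"] == "protoplasmic"]
    joined = proto.join(truth_nuclei[["r", "population"]], on="nucleus_id", rsuffix="_true")
    with_r = joined.dropna(subset=["r"])
    spearman = (
        float(scipy.stats.spearmanr(with_r["r"], with_r["t"]).statistic)
        if len(with_r) > 2
        else float("nan")
    )
    planted = truth_signature(truth)
    called = result.signature
    report = {"pseudotime_spearman_r": spearman}
    n_correct = 0
    for direction in ("up", "down"):
        true_set = set(planted.subset(direction))
        called_set = set(called.subset(direction))
        tp = len(true_set & called_set)
        n_correct += tp
        report[f"n_planted_{direction}"] = len(true_set)
        report[f"n_called_{direction}"] = len(called_set)
        report[f"sensitivity_{direction}"] = tp / len(true_set) if true_set else float("nan")
    n_called = len(called.genes)
    report["false_discovery_proportion"] = (
        (n_called - n_correct) / n_called if n_called else 0.0
    )
    report["down_dominated"] = report["n_called_down"] > report["n_called_up"]
    # doublet capture: truth-flagged doublets landing in doublet-labeled clusters
    is_doublet_true = truth_nuclei["population"].str.startswith("doublet")
    labels = result.nucleus_labels
    captured = labels[labels.index.isin(truth_nuclei.index[is_doublet_true])]
    if len(captured):
        report["doublet_capture"] = float(captured.str.startswith("doublet").mean())
    return report


def simulate_and_run(
    sim_config: SimulationConfig,
    params: PipelineParams | None = None,
    outdir: str | Path | None = None,
    persist_dataset: bool = False,
) -> tuple[PipelineResult, dict]:
    """Generate a synthetic cohort, run the pipeline, score recovery."""
    dataset = simulate_dataset(sim_config)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None and persist_dataset:
        write_dataset(dataset, outdir / "dataset", sim_config)
    if params is None:
        params = PipelineParams(seed=sim_config.seed)
    result = run_pipeline_data(dataset.counts, dataset.meta, params, outdir)
    report = recovery_report(result, dataset.truth)
    if outdir is not None:
        (Path(outdir) / "recovery_report.json").write_text(
            json.dumps(report, indent=2, default=float)
        )
    return result, report
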