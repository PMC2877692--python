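"""End-to-end orchestration: prefilter -> graph -> sparsify -> rank -> output.

`rank_samples` is the in-memory entry point; `run_pipeline` wraps it with
file IO, artifact dumps, and a machine-readable run manifest (parameters,
seed, input checksums) so every run is reproducible from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .graph import (
    AffinityGraph,
    build_affinity,
    estimate_sigma,
    normalize,
    pairwise_distances,
    write_edge_list,
)
from .io import (
    FeatureTable,
    LabelAssignment,
    read_feature_table,
    read_labels,
    write_ranking,
)
from .prefilter import FilterReport, filter_bottom_k
from .ranking import RankingParams, RankingResult, rank
from .sparsify import apply_sparsification, default_budget, solve_bmatching

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineOutput", "rank_samples", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    features_path: str
    labels_path: str
    out_dir: str = "."
    top_n: int | None = None
    filter_k: int = 0
    sparsify: bool = False
    sparsify_b: int | None = None  # None -> default_budget(n)
    sigma: float | None = None  # None -> mean pairwise distance
    zscore: bool = False
    alpha: float = 0.5
    gamma: float = 0.5
    mode: str = "positive_only"
    solver: str = "closed_form"
    tol: float = 1e-9
    max_iter: int = 10_000
    seed: int = 0
    delimiter: str = "\t"
    header: bool = False
    dump_graph: bool = False

    def ranking_params(self) -> RankingParams:
        return RankingParams(
            alpha=self.alpha,
            gamma=self.gamma,
            tol=self.tol,
            max_iter=self.max_iter,
            mode=self.mode,
            solver=self.solver,
        )


@dataclass
class PipelineOutput:
    table: FeatureTable
    labels: LabelAssignment
    result: RankingResult
    graph: AffinityGraph
    filter_report: FilterReport | None = None
    artifacts: dict = field(default_factory=dict)


def rank_samples(
    table: FeatureTable,
    labels: LabelAssignment,
    params: RankingParams | None = None,
    filter_k: int = 0,
    sparsify: bool = False,
    sparsify_b: int | None = None,
    sigma: float | None = None,
    zscore: bool = False,
) -> PipelineOutput:
    """Run the full ranking pipeline on in-memory data.

    Stages, in order: optional z-scoring of features, optional
    nearest-positive prefilter dropping ``filter_k`` unlabeled samples,
    affinity-graph construction (distances recomputed on the retained
    subset, so sigma reflects the set actually ranked), optional b-matching
    sparsification, then manifold ranking.
    """
    params = params or RankingParams()
    if zscore:
        mu, sd = table.X.mean(axis=0), table.X.std(axis=0)
        sd[sd == 0] = 1.0
        table = FeatureTable(table.ids, (table.X - mu) / sd)

    report = None
    if filter_k > 0:
        table, labels, report = filter_bottom_k(table, labels, filter_k)
        logger.info("prefilter: dropped %d, retained %d", filter_k, table.n)

    D = pairwise_distances(table)
    sig = sigma if sigma is not None else estimate_sigma(D)
    graph = build_affinity(D, sig)

    if sparsify:
        b = sparsify_b if sparsify_b is not None else default_budget(table.n)
        pattern = solve_bmatching(graph, b)
        graph = apply_sparsification(graph, pattern)
        logger.info("sparsified to %d edges (b=%d)", len(pattern.edges()), b)

    result = rank(normalize(graph), labels, params)
    return PipelineOutput(table, labels, result, graph, report)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineOutput:
    """File-to-file pipeline run with artifacts and a JSON manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    table = read_feature_table(
        config.features_path, delimiter=config.delimiter, header=config.header
    )
    labels = read_labels(config.labels_path, table)
    if config.filter_k > int(labels.unlabeled.sum()):
        raise ValueError(
            f"filter_k={config.filter_k} exceeds the "
            f"{int(labels.unlabeled.sum())} unlabeled samples"
        )

    out = rank_samples(
        table,
        labels,
        params=config.ranking_params(),
        filter_k=config.filter_k,
        sparsify=config.sparsify,
        sparsify_b=config.sparsify_b,
        sigma=config.sigma,
        zscore=config.zscore,
    )

    ranking_path = out_dir / "ranking.tsv"
    top_n = config.top_n if config.top_n is not None else out.table.n
    write_ranking(out.table.ids, out.result.scores, ranking_path, top_n)
    out.artifacts["ranking"] = str(ranking_path)

    if out.filter_report is not None:
        fr_path = out_dir / "filter_report.tsv"
        out.filter_report.write(fr_path)
        out.artifacts["filter_report"] = str(fr_path)
    if config.dump_graph:
        g_path = out_dir / "graph_edges.tsv"
        write_edge_list(out.graph, g_path)
        out.artifacts["graph_edges"] = str(g_path)

    manifest = {
        "serorank_version": __version__,
        "config": asdict(config),
        "inputs": {
            "features_sha256": _sha256(config.features_path),
            "labels_sha256": _sha256(config.labels_path),
        },
        "n_input": table.n,
        "n_ranked": out.table.n,
        "converged": bool(out.result.converged),
        "iterations": int(out.result.iterations),
        "artifacts": out.artifacts,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    out.artifacts["manifest"] = str(manifest_path)
    return out
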