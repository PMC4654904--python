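"""End-to-end orchestration: screen, normalize, cluster, tree, marker search.

``run_pipeline`` executes the full staging analysis on a long-format dataset
and writes all stage outputs plus a run manifest.  Stages:

1. ANOVA screen across time points with Holm correction (the Welch 0 h vs
   6 h test is reported alongside but does not gate the subset);
2. normalization of the significant factors (grand mean 0, range 1);
3. pairwise YS3 similarity on the significant subset;
4. complete-linkage clustering (cluster count automatic or fixed);
5. regression tree on per-sample cluster means with leave-one-out
   evaluation;
6. marker-combination search: all single-factor panels scored exactly, a
   random sample of two-factor panels.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    ClusterSet,
    cluster_factors,
    dendrogram_newick,
    select_cluster_count,
    write_mean_courses_csv,
)
from .dataset import TimeCourseDataset, normalize_factors, read_dataset
from .markers import (
    count_single_combinations,
    sample_double_combinations,
    score_all_single_combinations,
    score_combination,
)
from .phase_tree import build_sample_table, fit_tree, loo_evaluate
from .screening import anova_screen, significant_ids, welch_initial_test
from .similarity import DEFAULT_WEIGHTS, similarity_matrix

logger = logging.getLogger("cholestage")


@dataclass
class PipelineConfig:
    """Settings of one pipeline run; defaults follow the study's analysis."""

    input_path: str | None = None
    output_dir: str = "cholestage_out"
    alpha: float = 0.05
    weights: tuple = DEFAULT_WEIGHTS
    n_clusters: int | str = 6  # or 'auto': largest cut with no singleton
    minsplit: int = 6
    minbucket: int = 2
    cp: float = 0.01
    n_doubles: int = 10000
    top_k: int = 20
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weights"] = list(self.weights)
        return d


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    config: PipelineConfig
    screening: list
    welch: list
    clusters: ClusterSet
    tree: object
    loo: object
    single_scores: pd.DataFrame
    double_scores: pd.DataFrame
    manifest: dict


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers = [
        h
        for h in logger.handlers
        if not isinstance(h, (logging.StreamHandler, logging.FileHandler))
    ]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(outdir / "pipeline.log"),
    ):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def run_pipeline(
    config: PipelineConfig,
    data: TimeCourseDataset | None = None,
) -> PipelineResult:
    """Run the full analysis; ``data`` overrides ``config.input_path``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    manifest: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def _stage(name, fn):
        logger.info("stage %s ...", name)
        try:
            return fn()
        except Exception as exc:  # keep partial artifacts, name the stage
            manifest["failed_stage"] = name
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=2, default=str)
            )
            raise PipelineStageError(name, exc) from exc

    if data is None:
        if config.input_path is None:
            raise ValueError("config.input_path or data required")
        data = _stage("read", lambda: read_dataset(config.input_path))
    manifest["n_factors_in"] = data.n_factors
    manifest["n_times"] = data.n_times
    manifest["n_replicates"] = data.n_replicates

    screening = _stage(
        "screen", lambda: anova_screen(data, alpha=config.alpha)
    )
    _screen_csv(screening, outdir / "screening_anova.csv")
    welch = _stage(
        "welch",
        lambda: welch_initial_test(data, alpha=config.alpha)
        if 6.0 in data.times
        else [],
    )
    if welch:
        _screen_csv(welch, outdir / "screening_welch_0h_6h.csv")
    keep = significant_ids(screening)
    manifest["n_significant"] = len(keep)
    logger.info("%d/%d factors significant", len(keep), data.n_factors)

    normalized = _stage(
        "normalize", lambda: normalize_factors(data.subset(keep))
    )
    sim = _stage(
        "similarity",
        lambda: similarity_matrix(normalized, weights=config.weights),
    )
    sim.write_csv(outdir / "similarity_ys3.csv")

    def _cluster():
        k = (
            select_cluster_count(sim)
            if config.n_clusters == "auto"
            else int(config.n_clusters)
        )
        return cluster_factors(sim, k, normalized, config.weights)

    clusters = _stage("cluster", _cluster)
    manifest["n_clusters"] = clusters.n_clusters
    manifest["cluster_sizes"] = {
        str(c): s for c, s in sorted(clusters.sizes.items())
    }
    clusters.to_frame().to_csv(outdir / "clusters.csv", index=False)
    write_mean_courses_csv(
        clusters, normalized.times, outdir / "cluster_mean_courses.csv"
    )
    (outdir / "dendrogram.nwk").write_text(dendrogram_newick(sim))

    table = _stage(
        "sample_table", lambda: build_sample_table(clusters, normalized)
    )
    manifest["n_samples"] = table.n_samples
    tree = _stage(
        "tree",
        lambda: fit_tree(
            table, config.minsplit, config.minbucket, config.cp
        ),
    )
    tree.to_json(outdir / "tree.json")
    (outdir / "tree.txt").write_text(tree.render() + "\n")
    manifest["tree_n_leaves"] = tree.n_leaves
    manifest["tree_predictors_used"] = tree.used_predictors()

    loo = _stage(
        "loo",
        lambda: loo_evaluate(
            table, config.minsplit, config.minbucket, config.cp
        ),
    )
    loo.records.to_csv(outdir / "loo_predictions.csv", index=False)
    manifest["loo_d"] = loo.d

    single = _stage(
        "search_single",
        lambda: score_all_single_combinations(tree, normalized, clusters, table),
    )
    manifest["n_single_combinations"] = len(single)
    assert manifest["n_single_combinations"] == count_single_combinations(
        clusters.sizes.values()
    )
    single.head(config.top_k).to_csv(
        outdir / "combinations_single_top.csv", index=False
    )
    manifest["best_single_d"] = float(single["d"].iloc[0])

    def _doubles():
        sizes = clusters.sizes.values()
        if min(sizes) < 2:
            logger.info("a cluster has <2 members; skipping double panels")
            return pd.DataFrame()
        combos = sample_double_combinations(
            clusters, n=config.n_doubles, seed=config.seed
        )
        rows = []
        for combo in combos:
            score = score_combination(tree, normalized, table, combo)
            rows.append(
                {
                    **{
                        f"c{c}": "+".join(slot)
                        for c, slot in zip(clusters.cluster_labels, combo)
                    },
                    "d": score.d,
                }
            )
        df = pd.DataFrame(rows)
        return df.sort_values("d", kind="stable").reset_index(drop=True)

    doubles = _stage("search_double", _doubles)
    if len(doubles):
        manifest["n_double_combinations"] = len(doubles)
        manifest["best_double_d"] = float(doubles["d"].iloc[0])
        doubles.head(config.top_k).to_csv(
            outdir / "combinations_double_top.csv", index=False
        )

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
    logger.info("pipeline complete: %s", outdir)
    return PipelineResult(
        config, screening, welch, clusters, tree, loo, single, doubles, manifest
    )


def _screen_csv(results, path) -> None:
    pd.DataFrame(
        [
            {
                "factor_id": r.factor_id,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in results
        ]
    ).to_csv(path, index=False)
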