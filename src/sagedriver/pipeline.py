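"""End-to-end orchestration: preprocess -> train (K-fold CV) -> rank ->
evaluate, plus the 8-way component ablation harness.

Cross-validation follows the held-out-sample protocol: samples are split
into k folds; for each fold the model trains with that fold's columns
masked out of both the loss and the message-passing adjacency, candidate
lists are built only for the fold's test samples, and the fold's test
lists are aggregated with EPV. Cohort-level metrics are reported per fold
and as the mean across folds; a pooled ranking aggregates every sample's
test-fold candidate list (each sample contributes from the fold where it
was held out, so no training leakage enters the final list).
"""

from __future__ import annotations

import dataclasses
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import FoldSplit, kfold_split, topk_metrics
from .model import DriverGeneModel
from .preprocess import (
    CohortDataset,
    load_driver_genes,
    load_expression,
    load_mutation,
    load_ppi_edges,
)
from .ranking import (
    ALPHA_DEFAULTS,
    ALPHA_FALLBACK,
    EPVResult,
    SampleRanking,
    condorcet_rank,
    epv_scores,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "CVResult", "cross_validate", "run_pipeline", "run_ablation"]

DEFAULT_K_GRID = tuple(range(10, 201, 10))


@dataclass
class RunConfig:
    """Everything one reproducible end-to-end run needs."""

    expression_path: str
    mutation_path: str
    ppi_path: str
    drivers_path: str
    output_dir: str = "sagedriver_run"
    # preprocessing
    min_confidence: float = 0.5
    strict_greater: bool = False
    zscore_threshold: float = 2.0
    two_sided: bool = False
    # architecture
    hidden_dim: int = 64
    attention_dim: int = 64
    projection_dim: int = 32
    n_layers: int = 2
    use_attention: bool = True
    sampling_size: Optional[int] = None
    adjacency_source: str = "association"
    # optimization
    beta: Optional[float] = None
    epochs: int = 200
    learning_rate: float = 1e-3
    # ranking / evaluation
    alpha: Optional[float] = None
    dataset_tag: Optional[str] = None
    keep_fraction: float = 0.5
    ranking_method: str = "epv"
    k_folds: int = 5
    k_grid: Sequence[int] = DEFAULT_K_GRID
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved_alpha(self) -> float:
        if self.alpha is not None:
            return self.alpha
        return ALPHA_DEFAULTS.get(self.dataset_tag, ALPHA_FALLBACK)

    def validate_paths(self) -> None:
        for name in ("expression_path", "mutation_path", "ppi_path", "drivers_path"):
            p = getattr(self, name)
            if not p:
                raise ValueError(f"configuration error: {name} is not set")
            if not Path(p).is_file():
                raise ValueError(f"configuration error: {name} does not exist: {p}")


@dataclass
class CVResult:
    """Cross-validated run: per-fold and pooled rankings plus metrics."""

    folds: FoldSplit
    fold_rankings: list[EPVResult]
    pooled_ranking: EPVResult
    fold_lists: list[list[SampleRanking]]
    metrics: pd.DataFrame  # tidy: fold, K, precision, recall, f1
    fold_scores: list  # per-fold ScoreMatrix

    def mean_metrics(self) -> pd.DataFrame:
        return (
            self.metrics.groupby("K")[["precision", "recall", "f1"]]
            .mean()
            .reset_index()
        )


def _rank_lists(
    lists: list[SampleRanking], method: str, alpha: float
) -> EPVResult:
    if method == "condorcet":
        genes = condorcet_rank(lists)
        return EPVResult(
            table=pd.DataFrame(
                {"gene": genes, "p": np.nan, "win": np.nan, "loss": np.nan}
            )
        )
    return epv_scores(lists, alpha=alpha)


def cross_validate(
    dataset: CohortDataset,
    config: RunConfig,
    truth: Optional[set[str]] = None,
) -> CVResult:
    """Run the K-fold protocol on an already-built cohort."""
    truth = truth if truth is not None else set(dataset.known_drivers)
    folds = kfold_split(dataset.samples, k=config.k_folds, seed=config.seed)
    alpha = config.resolved_alpha()

    model = DriverGeneModel(
        dataset,
        hidden_dim=config.hidden_dim,
        attention_dim=config.attention_dim,
        projection_dim=config.projection_dim,
        n_layers=config.n_layers,
        use_attention=config.use_attention,
        adjacency_source=config.adjacency_source,
        sampling_size=config.sampling_size,
    )

    fold_rankings: list[EPVResult] = []
    fold_lists: list[list[SampleRanking]] = []
    fold_scores = []
    rows = []
    truth_in_universe = truth & set(dataset.genes)
    for fold_no, test_samples in enumerate(folds):
        t0 = time.perf_counter()
        train_samples = [s for s in dataset.samples if s not in set(test_samples)]
        res = model.fit(
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            beta=config.beta,
            seed=config.seed + fold_no,
            train_samples=train_samples,
        )
        lists = res.sample_rankings(
            keep_fraction=config.keep_fraction, samples=test_samples
        )
        lists = [r for r in lists if r.genes]
        ranking = _rank_lists(lists, config.ranking_method, alpha)
        fold_rankings.append(ranking)
        fold_lists.append(lists)
        fold_scores.append(res.scores)
        if truth_in_universe:
            for K in config.k_grid:
                with warnings.catch_warnings():
                    # short per-fold rankings evaluate on the full list
                    warnings.simplefilter("ignore")
                    m = topk_metrics(ranking.genes, truth_in_universe, K)
                rows.append(
                    {
                        "fold": fold_no,
                        "K": K,
                        "precision": m.precision,
                        "recall": m.recall,
                        "f1": m.f1,
                    }
                )
        logger.info(
            "fold %d/%d: %d test samples, %.2fs",
            fold_no + 1,
            len(folds),
            len(test_samples),
            time.perf_counter() - t0,
        )

    pooled_lists = [r for lists in fold_lists for r in lists]
    pooled_ranking = _rank_lists(pooled_lists, config.ranking_method, alpha)
    metrics = pd.DataFrame(rows, columns=["fold", "K", "precision", "recall", "f1"])
    return CVResult(
        folds=folds,
        fold_rankings=fold_rankings,
        pooled_ranking=pooled_ranking,
        fold_lists=fold_lists,
        metrics=metrics,
        fold_scores=fold_scores,
    )


def load_and_preprocess(config: RunConfig) -> CohortDataset:
    from .preprocess import preprocess_cohort

    expr = load_expression(config.expression_path)
    mut = load_mutation(config.mutation_path)
    ppi = load_ppi_edges(
        config.ppi_path,
        min_confidence=config.min_confidence,
        strict_greater=config.strict_greater,
    )
    drivers = load_driver_genes(config.drivers_path)
    dataset = preprocess_cohort(
        expr,
        mut,
        ppi,
        drivers,
        zscore_threshold=config.zscore_threshold,
        two_sided=config.two_sided,
    )
    logger.info(
        "preprocess: %d genes x %d samples retained (%d known drivers in universe)",
        dataset.n_genes,
        dataset.n_samples,
        len(dataset.known_drivers & set(dataset.genes)),
    )
    return dataset


def run_pipeline(config: RunConfig) -> CVResult:
    """Full run: load, preprocess, cross-validate, write all outputs."""
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    dataset = _stage("preprocess", load_and_preprocess, config)
    result = _stage("cross_validate", cross_validate, dataset, config)

    for fold_no, scores in enumerate(result.fold_scores):
        scores.write_tsv(out / f"scores_fold{fold_no}.tsv")
    with open(out / "candidate_lists.tsv", "w") as fh:
        fh.write("sample\trank\tgene\tscore\n")
        for lists in result.fold_lists:
            for r in lists:
                for rank, (g, s) in enumerate(zip(r.genes, r.scores), start=1):
                    fh.write(f"{r.sample}\t{rank}\t{g}\t{s}\n")
    result.pooled_ranking.write_tsv(out / "epv_ranking.tsv")
    result.metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
    result.mean_metrics().to_csv(out / "metrics_mean.tsv", sep="\t", index=False)
    manifest = dataclasses.asdict(config)
    manifest["k_grid"] = list(config.k_grid)
    manifest["software_version"] = __version__
    manifest["n_genes_retained"] = dataset.n_genes
    manifest["n_samples"] = dataset.n_samples
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return result


ABLATION_GRID = tuple(
    {"n_layers": layers, "use_attention": att, "ranking_method": method}
    for layers in (2, 1)
    for att in (True, False)
    for method in ("epv", "condorcet")
)


def run_ablation(
    config: RunConfig,
    dataset: Optional[CohortDataset] = None,
    k_eval: int = 20,
    truth: Optional[set[str]] = None,
) -> pd.DataFrame:
    """Run all 8 component configurations on one dataset.

    Axes: GraphSAGE depth (2 vs 1 layer), bidirectional attention (on vs
    off) and ranking strategy (EPV vs Condorcet). Returns one row per
    configuration with the mean across folds of F1 at ``k_eval``.
    """
    if dataset is None:
        config.validate_paths()
        dataset = load_and_preprocess(config)
    rows = []
    for axes in ABLATION_GRID:
        cfg = dataclasses.replace(config, k_grid=(k_eval,), **axes)
        result = cross_validate(dataset, cfg, truth=truth)
        mean = result.mean_metrics()
        f1 = float(mean.loc[mean["K"] == k_eval, "f1"].iloc[0]) if len(mean) else np.nan
        rows.append(
            {
                "n_layers": axes["n_layers"],
                "bwfa": "on" if axes["use_attention"] else "off",
                "ranking": axes["ranking_method"],
                "f1": f1,
            }
        )
        logger.info("ablation %s -> F1=%.4f", axes, f1)
    return pd.DataFrame(rows)
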