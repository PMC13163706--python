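"""Model/Results facade over the full prioritization pipeline.

:class:`DriverGeneModel` is constructed from a :class:`CohortDataset` (or
directly from the raw data frames via :meth:`from_dataframes`) and holds the
architecture configuration; :meth:`fit` trains the encoder + attention +
decoder stack and returns a :class:`DriverGeneResults` carrying the fitted
parameters, the gene-sample driver probability matrix, the training loss
trace, and the rank-aggregation entry points.

Example
-------
>>> from sagedriver.synthetic import SyntheticSpec, generate_cohort
>>> from sagedriver.preprocess import preprocess_cohort
>>> from sagedriver.model import DriverGeneModel
>>> cohort = generate_cohort(SyntheticSpec(seed=1))
>>> data = preprocess_cohort(cohort.expression, cohort.mutation,
...                          cohort.ppi, cohort.drivers)
>>> res = DriverGeneModel(data, hidden_dim=32).fit(epochs=50, seed=1)
>>> ranking = res.rank_genes(alpha=0.5)
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .decoder import ScoreMatrix
from .preprocess import (
    CohortDataset,
    PPINetwork,
    preprocess_cohort,
)
from .ranking import (
    ALPHA_DEFAULTS,
    ALPHA_FALLBACK,
    EPVResult,
    SampleRanking,
    build_sample_rankings,
    condorcet_rank,
    epv_scores,
)
from .training import ModelConfig, ModelParams, TrainConfig, train

__all__ = ["DriverGeneModel", "DriverGeneResults"]


class DriverGeneModel:
    """Gene-sample driver probability model on a bipartite cohort graph.

    Parameters mirror :class:`~sagedriver.training.ModelConfig`:
    ``hidden_dim`` (embedding width d), ``attention_dim`` (dk),
    ``projection_dim`` (decoding width k), ``n_layers`` (GraphSAGE depth,
    1 or 2), ``use_attention`` (bidirectional cross-attention on/off),
    ``adjacency_source`` ('association' or 'mutation'), and
    ``sampling_size`` (fixed-size neighbor sampling; None = dense).
    """

    def __init__(
        self,
        dataset: CohortDataset,
        hidden_dim: int = 64,
        attention_dim: int = 64,
        projection_dim: int = 32,
        n_layers: int = 2,
        use_attention: bool = True,
        share_qkv: bool = False,
        adjacency_source: str = "association",
        sampling_size: Optional[int] = None,
    ):
        self.dataset = dataset
        self.config = ModelConfig(
            hidden_dim=hidden_dim,
            attention_dim=attention_dim,
            projection_dim=projection_dim,
            n_layers=n_layers,
            use_attention=use_attention,
            share_qkv=share_qkv,
            adjacency_source=adjacency_source,
            sampling_size=sampling_size,
        )

    @classmethod
    def from_dataframes(
        cls,
        expression: pd.DataFrame,
        mutation: pd.DataFrame,
        ppi: PPINetwork,
        known_drivers: Iterable[str],
        zscore_threshold: float = 2.0,
        two_sided: bool = False,
        **model_kwargs,
    ) -> "DriverGeneModel":
        """Run the preprocessing chain and build the model in one step."""
        dataset = preprocess_cohort(
            expression,
            mutation,
            ppi,
            known_drivers,
            zscore_threshold=zscore_threshold,
            two_sided=two_sided,
        )
        return cls(dataset, **model_kwargs)

    def fit(
        self,
        epochs: int = 200,
        learning_rate: float = 1e-3,
        beta: Optional[float] = None,
        seed: int = 0,
        train_samples: Optional[Iterable[str]] = None,
    ) -> "DriverGeneResults":
        """Train end to end and return the results object.

        ``train_samples`` restricts the loss (and the message-passing
        adjacency) to those sample columns, the cross-validation masking
        protocol; by default all samples train.
        """
        mask = None
        if train_samples is not None:
            cols = np.isin(np.array(self.dataset.samples), list(train_samples))
            if not cols.any():
                raise ValueError("train_samples matches no dataset sample")
            mask = np.broadcast_to(
                cols[None, :], (self.dataset.n_genes, self.dataset.n_samples)
            ).copy()
        cfg = TrainConfig(
            beta=beta, epochs=epochs, learning_rate=learning_rate, seed=seed, mask=mask
        )
        params, scores, losses = train(self.dataset, cfg, self.config)
        return DriverGeneResults(
            model=self, params=params, scores=scores, loss_history=losses,
            train_config=cfg,
        )


class DriverGeneResults:
    """Fitted model: probability matrix, parameters, and rankings."""

    def __init__(
        self,
        model: DriverGeneModel,
        params: ModelParams,
        scores: ScoreMatrix,
        loss_history: list[float],
        train_config: TrainConfig,
    ):
        self.model = model
        self.params = params
        self.scores = scores
        self.loss_history = loss_history
        self.train_config = train_config

    @property
    def score_frame(self) -> pd.DataFrame:
        """Gene x sample driver probabilities as a DataFrame."""
        return self.scores.to_frame()

    def sample_rankings(
        self,
        keep_fraction: float = 0.5,
        samples: Optional[Iterable[str]] = None,
    ) -> list[SampleRanking]:
        """Per-sample candidate driver lists (top half of mutated genes).

        ``samples`` restricts the output, e.g. to a test fold.
        """
        rankings = build_sample_rankings(
            self.scores, self.model.dataset.Xg, keep_fraction=keep_fraction
        )
        if samples is not None:
            wanted = set(samples)
            rankings = [r for r in rankings if r.sample in wanted]
        return rankings

    def rank_genes(
        self,
        alpha: Optional[float] = None,
        dataset_tag: Optional[str] = None,
        keep_fraction: float = 0.5,
        samples: Optional[Iterable[str]] = None,
        method: str = "epv",
        universe: Optional[Iterable[str]] = None,
    ) -> EPVResult:
        """Aggregate per-sample lists into the cohort driver ranking.

        ``alpha`` defaults to the cancer-specific calibration when a
        ``dataset_tag`` (BRCA/LUAD/PRAD) is given, else 0.5.
        ``method`` is 'epv' or 'condorcet'.
        """
        if alpha is None:
            alpha = ALPHA_DEFAULTS.get(dataset_tag, ALPHA_FALLBACK)
        rankings = self.sample_rankings(keep_fraction=keep_fraction, samples=samples)
        if method == "epv":
            return epv_scores(rankings, alpha=alpha, universe=universe)
        if method == "condorcet":
            genes = condorcet_rank(rankings, universe=universe)
            table = pd.DataFrame(
                {"gene": genes, "p": np.nan, "win": np.nan, "loss": np.nan}
            )
            return EPVResult(table=table)
        raise ValueError(f"unknown ranking method {method!r}")

    def summary(self, top: int = 10, alpha: Optional[float] = None) -> str:
        """Human-readable fit summary with the leading cohort-level genes."""
        d = self.model.dataset
        ranking = self.rank_genes(alpha=alpha)
        lines = [
            "Driver gene prioritization results",
            "==================================",
            f"genes: {d.n_genes}   samples: {d.n_samples}   "
            f"known drivers in universe: {len(d.known_drivers & set(d.genes))}",
            f"layers: {self.model.config.n_layers}   "
            f"attention: {'on' if self.model.config.use_attention else 'off'}   "
            f"hidden_dim: {self.model.config.hidden_dim}",
            f"epochs: {len(self.loss_history)}   "
            f"final loss: {self.loss_history[-1]:.6f}",
            "",
            f"{'rank':>4}  {'gene':<12} {'P':>8} {'win':>10} {'loss':>10}",
        ]
        for i, row in ranking.table.head(top).iterrows():
            lines.append(
                f"{i + 1:>4}  {row['gene']:<12} {row['p']:>8.4f} "
                f"{row['win']:>10.3f} {row['loss']:>10.3f}"
            )
        return "\n".join(lines)
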