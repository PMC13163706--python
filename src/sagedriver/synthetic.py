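"""Planted-driver cohort simulator.

Generates the four inputs the pipeline consumes — expression matrix,
binary mutation matrix, confidence-weighted PPI edge list, and a known
driver list — with the causal structure the preprocessing filter assumes:
driver genes mutate more often than passengers, and a driver mutation in a
sample shifts the expression of the driver's network neighbors in that
same sample. Shifts are expressed in units of the per-gene baseline
standard deviation, so they are directly comparable to the z-score
aberrance threshold.

Baseline expression is per-gene Gaussian noise; shifts from multiple
mutated driver neighbors add. The network is Erdős–Rényi by default with a
minimum-degree-1 repair (every gene participates in the interactome — an
isolated "driver" could never perturb downstream expression and would be
biologically inert); a Barabási–Albert option provides heavy-tailed
degrees for shuffle-control studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import PPINetwork

__all__ = ["SyntheticSpec", "SyntheticCohort", "generate_cohort", "write_fixture"]


@dataclass
class SyntheticSpec:
    """Generator settings for one planted-driver cohort."""

    n_genes: int = 200
    n_samples: int = 50
    n_drivers: int = 20
    driver_mut_rate: float = 0.3
    passenger_mut_rate: float = 0.05
    neighbor_shift: float = 3.0
    edge_prob: float = 0.02
    noise_sd: float = 1.0
    network_model: str = "erdos_renyi"
    ba_m: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("driver_mut_rate", "passenger_mut_rate", "edge_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_drivers >= self.n_genes:
            raise ValueError("n_drivers must be smaller than n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.network_model not in ("erdos_renyi", "barabasi_albert"):
            raise ValueError(f"unknown network_model {self.network_model!r}")


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame  # genes x samples
    mutation: pd.DataFrame  # genes x samples, {0,1}
    ppi: PPINetwork
    drivers: set[str]


def _gene_symbols(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"S{j:0{width}d}" for j in range(1, n + 1)]


def _random_network(spec: SyntheticSpec, rng: np.random.Generator) -> nx.Graph:
    graph_seed = int(rng.integers(0, 2**31 - 1))
    if spec.network_model == "erdos_renyi":
        g = nx.gnp_random_graph(spec.n_genes, spec.edge_prob, seed=graph_seed)
    else:
        g = nx.barabasi_albert_graph(spec.n_genes, spec.ba_m, seed=graph_seed)
    # min-degree-1 repair: attach isolated genes to a random partner
    for node in sorted(n for n in g.nodes if g.degree(n) == 0):
        partner = int(rng.integers(0, spec.n_genes - 1))
        if partner >= node:
            partner += 1
        g.add_edge(node, partner)
    return g


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw one cohort; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_symbols(spec.n_genes)
    samples = _sample_ids(spec.n_samples)
    drivers = set(genes[: spec.n_drivers])

    graph = _random_network(spec, rng)
    edges = [
        (genes[u], genes[v], float(rng.uniform(0.5, 1.0)))
        for u, v in sorted(graph.edges())
    ]
    ppi = PPINetwork.from_edges(edges)

    rates = np.full(spec.n_genes, spec.passenger_mut_rate)
    rates[: spec.n_drivers] = spec.driver_mut_rate
    mut = (rng.random((spec.n_genes, spec.n_samples)) < rates[:, None]).astype(np.int8)

    expr = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_samples))
    if spec.neighbor_shift != 0:
        neighbor_idx = {
            i: [genes.index(h) for h in ppi.neighbors(genes[i])]
            for i in range(spec.n_drivers)
        }
        for i in range(spec.n_drivers):
            cols = np.flatnonzero(mut[i])
            for h in neighbor_idx[i]:
                expr[h, cols] += spec.neighbor_shift * spec.noise_sd

    return SyntheticCohort(
        expression=pd.DataFrame(expr, index=genes, columns=samples),
        mutation=pd.DataFrame(mut, index=genes, columns=samples),
        ppi=ppi,
        drivers=drivers,
    )


def write_fixture(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort in the exact dialects the loaders read.

    Returns a name -> path map for expression, mutation, ppi and drivers.
    Floats are written with Python's shortest round-trip repr, so a
    write/load cycle reproduces the matrices bit for bit.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "mutation": directory / "mutation.tsv",
        "ppi": directory / "ppi.tsv",
        "drivers": directory / "drivers.txt",
    }
    cohort.expression.to_csv(paths["expression"], sep="\t")
    cohort.mutation.to_csv(paths["mutation"], sep="\t")
    cohort.ppi.write_tsv(paths["ppi"])
    with open(paths["drivers"], "w") as fh:
        for gene in sorted(cohort.drivers):
            fh.write(gene + "\n")
    return paths
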