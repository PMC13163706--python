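"""Input loading and cohort construction.

Builds the three matrices the model consumes from a gene expression matrix,
a binary somatic mutation matrix, a confidence-weighted protein-protein
interaction (PPI) network, and a list of known driver genes:

* ``Xg`` — gene feature matrix (genes x samples): the mutation matrix
  restricted to retained genes;
* ``Xs`` — sample feature matrix (samples x genes): the expression matrix
  transposed;
* ``A``  — driver gene-sample association matrix: ``A[i, j] = 1`` iff gene
  *i* is mutated in sample *j* and *i* is a known driver gene.

Gene retention follows the DriverNet-style rationale that mutations worth
ranking are those with downstream transcriptional impact: a mutated gene is
kept only if, in some sample where it is mutated, at least one of its PPI
neighbors is aberrantly expressed (|z| outlier) in that same sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "CohortDataset",
    "load_expression",
    "load_mutation",
    "load_driver_genes",
    "load_ppi_edges",
    "harmonize",
    "compute_zscores",
    "flag_aberrant",
    "filter_mutated_genes",
    "build_dataset",
    "preprocess_cohort",
]


@dataclass
class PPINetwork:
    """Undirected, confidence-weighted gene-gene interaction network.

    Invariants: no self-loops, no duplicate unordered pairs; every retained
    edge passed the confidence threshold applied at load time.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "PPINetwork":
        g = nx.Graph()
        for u, v, c in edges:
            if u == v:
                continue
            if g.has_edge(u, v):
                g[u][v]["confidence"] = max(g[u][v]["confidence"], float(c))
            else:
                g.add_edge(u, v, confidence=float(c))
        return cls(g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene))

    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["confidence"]) for u, v, d in self.graph.edges(data=True)]

    def degree_sequence(self) -> list[int]:
        return sorted(d for _, d in self.graph.degree())

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for u, v, c in sorted(self.edges()):
                fh.write(f"{u}\t{v}\t{c}\n")


@dataclass
class CohortDataset:
    """The model-ready cohort: shared gene/sample index maps plus Xg, Xs, A.

    ``Xg`` and ``A`` are genes x samples; ``Xs`` is samples x genes.
    ``A <= Xg`` entrywise and ``A[i, j] = 1`` implies gene i is a known
    driver.
    """

    genes: list[str]
    samples: list[str]
    Xg: np.ndarray
    Xs: np.ndarray
    A: np.ndarray
    known_drivers: frozenset[str]

    def __post_init__(self) -> None:
        G, N = len(self.genes), len(self.samples)
        if self.Xg.shape != (G, N):
            raise ValueError(f"Xg shape {self.Xg.shape} != ({G}, {N})")
        if self.Xs.shape != (N, G):
            raise ValueError(f"Xs shape {self.Xs.shape} != ({N}, {G})")
        if self.A.shape != (G, N):
            raise ValueError(f"A shape {self.A.shape} != ({G}, {N})")
        if np.any(self.A > self.Xg):
            raise ValueError("association matrix A must satisfy A <= Xg entrywise")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def sample_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.samples)}


def _read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene symbols in first column")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def load_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (header = sample IDs)."""
    df = _read_matrix(path).astype(float)
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError(f"{path}: non-finite expression values")
    return df


def load_mutation(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples binary mutation TSV."""
    df = _read_matrix(path)
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{path}: mutation matrix must be binary")
    return df.astype(np.int8)


def load_driver_genes(path: str | Path) -> set[str]:
    """Read a known-driver list: one symbol per line, '#' comments allowed."""
    drivers: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if sym:
                drivers.add(sym)
    return drivers


def load_ppi_edges(
    path: str | Path,
    min_confidence: float = 0.5,
    strict_greater: bool = False,
) -> PPINetwork:
    """Load a 2- or 3-column PPI edge list, applying a confidence threshold.

    Rows with a missing confidence column are treated as confidence 1.0
    (e.g. PCNET-style unweighted exports). Self-loops are dropped and
    duplicate unordered pairs are collapsed keeping the maximum confidence.
    The threshold keeps edges with confidence ``>= min_confidence``, or
    strictly ``>`` when ``strict_greater`` is set (the STRING convention).
    """
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least two fields")
            u, v = fields[0].strip(), fields[1].strip()
            if len(fields) >= 3 and fields[2].strip() != "":
                try:
                    conf = float(fields[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric confidence {fields[2]!r}"
                    ) from exc
            else:
                conf = 1.0
            keep = conf > min_confidence if strict_greater else conf >= min_confidence
            if keep:
                edges.append((u, v, conf))
    return PPINetwork.from_edges(edges)


def harmonize(
    expr: pd.DataFrame, mut: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align expression and mutation matrices on shared genes and samples.

    Genes are intersected and sorted lexicographically; samples are
    intersected keeping the expression matrix's column order. Dropped
    symbols are logged.
    """
    genes = sorted(set(expr.index) & set(mut.index))
    samples = [s for s in expr.columns if s in set(mut.columns)]
    if not genes:
        raise ValueError("no genes shared between expression and mutation matrices")
    if not samples:
        raise ValueError("no samples shared between expression and mutation matrices")
    dropped = (set(expr.index) | set(mut.index)) - set(genes)
    if dropped:
        logger.info("harmonize: dropped %d unshared gene symbols", len(dropped))
    return expr.loc[genes, samples], mut.loc[genes, samples]


def compute_zscores(expr: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Per-gene z-scores of expression across samples: z = (x - mu) / sigma.

    ``ddof=0`` uses the population standard deviation (default); rows with
    zero standard deviation get z = 0 everywhere (a constant gene is never
    an expression outlier).
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scores require at least 2 samples per gene")
    vals = expr.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("expression matrix contains non-finite values")
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (vals - mu) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def flag_aberrant(
    z: pd.DataFrame, threshold: float = 2.0, two_sided: bool = False
) -> pd.DataFrame:
    """Flag aberrantly expressed gene-sample entries (z >= threshold).

    With ``two_sided`` set, |z| >= threshold is used instead, flagging
    strong down-regulation as well.
    """
    vals = z.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("z-score matrix contains non-finite values")
    flags = np.abs(vals) >= threshold if two_sided else vals >= threshold
    return pd.DataFrame(flags.astype(np.int8), index=z.index, columns=z.columns)


def filter_mutated_genes(
    mut: pd.DataFrame,
    aberrant: pd.DataFrame,
    ppi: PPINetwork,
    same_sample: bool = True,
) -> list[str]:
    """Retain mutated genes whose mutations plausibly perturb expression.

    A gene g is retained iff it is mutated in at least one sample j in which
    some PPI neighbor of g is aberrantly expressed. With
    ``same_sample=False`` the coupling is cohort-level: g only needs a
    neighbor aberrant in *some* sample. Returns the retained genes sorted.
    """
    if ppi.n_edges == 0:
        raise ValueError("empty PPI network")
    if mut.to_numpy().sum() == 0:
        raise ValueError("mutation matrix has no mutations")
    if list(mut.index) != list(aberrant.index) or list(mut.columns) != list(
        aberrant.columns
    ):
        raise ValueError("mutation and aberrance matrices must share index maps")

    gene_pos = {g: i for i, g in enumerate(mut.index)}
    mut_vals = mut.to_numpy() != 0
    ab_vals = aberrant.to_numpy() != 0
    retained: list[str] = []
    for g, i in gene_pos.items():
        if not mut_vals[i].any():
            continue  # never mutated: out of the prediction universe
        nb_idx = [gene_pos[h] for h in ppi.neighbors(g) if h in gene_pos]
        if not nb_idx:
            continue
        nb_aberrant = ab_vals[nb_idx].any(axis=0)
        if same_sample:
            keep = bool((mut_vals[i] & nb_aberrant).any())
        else:
            keep = bool(nb_aberrant.any())
        if keep:
            retained.append(g)
    logger.info(
        "filter_mutated_genes: retained %d of %d genes", len(retained), len(gene_pos)
    )
    return sorted(retained)


def build_dataset(
    expr: pd.DataFrame,
    mut: pd.DataFrame,
    retained: Iterable[str],
    known_drivers: Iterable[str],
) -> CohortDataset:
    """Assemble the model-ready cohort over the retained genes.

    Index order is deterministic: lexicographic gene symbols, samples in
    input (expression column) order.
    """
    genes = sorted(set(retained))
    if not genes:
        raise ValueError("retained gene set is empty")
    missing = set(genes) - set(mut.index)
    if missing:
        raise ValueError(f"retained genes absent from mutation matrix: {sorted(missing)[:5]}")
    samples = list(expr.columns)
    drivers = frozenset(known_drivers)
    if not (drivers & set(genes)):
        logger.warning("no known driver gene overlaps the retained gene universe")

    Xg = mut.loc[genes, samples].to_numpy(dtype=float)
    Xs = expr.loc[genes, samples].to_numpy(dtype=float).T
    is_driver = np.array([g in drivers for g in genes], dtype=float)[:, None]
    A = Xg * is_driver
    return CohortDataset(
        genes=genes, samples=samples, Xg=Xg, Xs=Xs, A=A, known_drivers=drivers
    )


def preprocess_cohort(
    expr: pd.DataFrame,
    mut: pd.DataFrame,
    ppi: PPINetwork,
    known_drivers: Iterable[str],
    zscore_threshold: float = 2.0,
    two_sided: bool = False,
    same_sample: bool = True,
    ddof: int = 0,
) -> CohortDataset:
    """Full preprocessing chain: harmonize -> z-score -> flag -> filter -> build."""
    expr_h, mut_h = harmonize(expr, mut)
    z = compute_zscores(expr_h, ddof=ddof)
    aberrant = flag_aberrant(z, threshold=zscore_threshold, two_sided=two_sided)
    retained = filter_mutated_genes(mut_h, aberrant, ppi, same_sample=same_sample)
    return build_dataset(expr_h, mut_h, retained, known_drivers)
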