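"""Co-expression network: soft-threshold adjacency, topological overlap, and
neighbour selection around a seed gene set.

Adjacency is unsigned, ``a_ij = |cor(x_i, x_j)|**beta`` on log2(FPKM + 1)
profiles. The topological overlap for i != j is

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity ``k_i = sum_{j != i} a_ij`` and ``TOM_ii = 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class CoexpressionNetwork:
    genes: list[str]
    adjacency: np.ndarray
    tom: np.ndarray
    beta: float

    def tom_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tom, index=self.genes, columns=self.genes)


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1]."""
    a = np.asarray(adjacency, dtype=float).copy()
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    np.fill_diagonal(a, 0.0)
    shared = a @ a  # sum_u a_iu * a_uj ; diagonal of a is zero so u != i, j
    k = a.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def build_network(fpkm: pd.DataFrame, beta: float = 6.0) -> CoexpressionNetwork:
    """Unsigned adjacency + TOM from expression profiles.

    Genes with a constant profile have undefined correlation and are dropped
    with a warning.
    """
    if fpkm.shape[1] < 3:
        raise ValidationError("need at least three samples to correlate")
    if beta <= 0:
        raise ValidationError("beta must be positive")
    log = np.log2(fpkm + 1.0)
    sd = log.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant-profile genes "
            f"(undefined correlation)"
        )
        log = log[~constant]
    genes = list(log.index)
    corr = np.corrcoef(log.to_numpy())
    corr = np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)
    adjacency = np.abs(corr) ** beta
    np.fill_diagonal(adjacency, 1.0)
    tom = tom_from_adjacency(adjacency)
    return CoexpressionNetwork(genes=genes, adjacency=adjacency, tom=tom, beta=beta)


@dataclass
class CoexpressionSelection:
    seed_genes: list[str]
    threshold: float
    selected: list[str]
    edges: pd.DataFrame        # columns: seed, gene, tom
    seed_degree: pd.Series     # interaction counts per seed, descending


def select_coexpressed(
    network: CoexpressionNetwork,
    seed_genes: Sequence[str],
    threshold: float = 0.2,
    similarity: str = "tom",
) -> CoexpressionSelection:
    """Genes whose similarity to at least one seed reaches ``threshold``.

    ``similarity`` is ``"tom"`` (default) or ``"adjacency"``. Self-pairs are
    ignored. Seed degree (number of partners at or above the threshold) is
    reported for ranking.
    """
    seeds = list(dict.fromkeys(seed_genes))
    index = {g: i for i, g in enumerate(network.genes)}
    unknown = [s for s in seeds if s not in index]
    if unknown:
        raise ValidationError(f"seed genes absent from network: {unknown}")
    matrix = network.tom if similarity == "tom" else network.adjacency
    if similarity not in ("tom", "adjacency"):
        raise ValidationError(f"unknown similarity {similarity!r}")

    gene_array = np.asarray(network.genes, dtype=object)
    rows = []
    for seed in seeds:
        i = index[seed]
        sims = matrix[i]
        hits = np.nonzero(sims >= threshold)[0]
        hits = hits[hits != i]
        rows.append(
            pd.DataFrame({"seed": seed, "gene": gene_array[hits], "tom": sims[hits]})
        )
    edges = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["seed", "gene", "tom"])
    )
    selected = sorted(set(edges["gene"])) if len(edges) else []
    degree = (
        edges.groupby("seed").size().reindex(seeds, fill_value=0)
        if len(edges)
        else pd.Series(0, index=pd.Index(seeds, name="seed"), dtype=int)
    )
    degree = degree.sort_values(ascending=False, kind="stable").rename("degree")
    return CoexpressionSelection(
        seed_genes=seeds,
        threshold=threshold,
        selected=selected,
        edges=edges,
        seed_degree=degree,
    )
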