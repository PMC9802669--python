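"""FPKM normalisation, differential expression, and expression clustering."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


@dataclass
class ExpressionSet:
    """Counts, gene lengths, and sample metadata, with derived FPKM.

    ``counts`` is genes x samples (non-negative integers); ``gene_lengths``
    is bp per gene aligned to the counts index; ``sample_sheet`` has columns
    sample_id / genotype / stage / replicate.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = self.counts.index[self.gene_lengths.isna()][:5].tolist()
            raise ValidationError(f"genes without a length, e.g. {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        unknown = set(self.counts.columns) - set(self.sample_sheet["sample_id"])
        if unknown:
            raise ValidationError(f"samples missing from sheet: {sorted(unknown)}")
        self._fpkm: pd.DataFrame | None = None

    @property
    def fpkm(self) -> pd.DataFrame:
        if self._fpkm is None:
            self._fpkm = compute_fpkm(self.counts, self.gene_lengths)
        return self._fpkm

    def samples_for(self, genotype: str, stage: str) -> list[str]:
        sheet = self.sample_sheet
        mask = (sheet["genotype"] == genotype) & (sheet["stage"] == stage)
        return sheet.loc[mask, "sample_id"].tolist()


def compute_fpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """FPKM[g, s] = 1e9 * C[g, s] / (N_s * L_g).

    N_s is the per-sample total of counted fragments (column sum); L_g the
    gene length in bp.
    """
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        bad = counts.index[(lengths <= 0) | lengths.isna()][:5].tolist()
        raise ValidationError(f"non-positive or missing gene length, e.g. {bad}")
    totals = counts.sum(axis=0).astype(float)
    totals[totals == 0] = np.nan  # empty library: FPKM undefined -> 0 below
    fpkm = 1e9 * counts.div(totals, axis=1).div(lengths.astype(float), axis=0)
    return fpkm.fillna(0.0)


def call_degs(
    expr: ExpressionSet,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_cutoff: float = 2.0,
    adj_p_cutoff: float = 0.001,
    fpkm_filter: float = 1.0,
    fc_floor: float = 0.01,
) -> pd.DataFrame:
    """Differential expression between two sample groups.

    Genes must be expressed (FPKM >= ``fpkm_filter`` in at least one sample
    of the two groups) to be tested. Counts are pooled within group and each
    gene's share of the pooled libraries is compared by an exact binomial
    two-proportion test (conditional on the gene's total count, the group-A
    count is Binomial with success probability N_a / (N_a + N_b) under the
    null); P-values are Benjamini-Hochberg adjusted over tested genes. Fold
    change is computed on mean FPKM with floor ``fc_floor``.

    Returns a per-gene table with DEG fields; unexpressed genes carry NaN
    statistics and ``is_deg = False``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValidationError("both groups need at least one sample")
    for s in group_a + group_b:
        if s not in expr.counts.columns:
            raise ValidationError(f"unknown sample {s!r}")
    if set(group_a) & set(group_b):
        raise ValidationError("groups overlap")

    fpkm = expr.fpkm
    expressed = fpkm[group_a + group_b].max(axis=1) >= fpkm_filter

    pooled_a = expr.counts[group_a].sum(axis=1)
    pooled_b = expr.counts[group_b].sum(axis=1)
    lib_a = float(pooled_a.sum())
    lib_b = float(pooled_b.sum())
    null_share = lib_a / (lib_a + lib_b)

    mean_a = fpkm[group_a].mean(axis=1)
    mean_b = fpkm[group_b].mean(axis=1)
    l2fc = np.log2(np.maximum(mean_a, fc_floor) / np.maximum(mean_b, fc_floor))

    p_values = pd.Series(np.nan, index=expr.counts.index)
    tested = expressed[expressed].index
    for gene in tested:
        total = int(pooled_a[gene] + pooled_b[gene])
        if total == 0:
            p_values[gene] = 1.0
        else:
            p_values[gene] = stats.binomtest(
                int(pooled_a[gene]), total, null_share, alternative="two-sided"
            ).pvalue

    adjusted = pd.Series(np.nan, index=expr.counts.index)
    if len(tested):
        adjusted[tested] = multipletests(
            p_values[tested].to_numpy(), method="fdr_bh"
        )[1]

    is_deg = (
        expressed
        & (np.abs(l2fc) >= np.log2(fc_cutoff))
        & (adjusted <= adj_p_cutoff)
    ).fillna(False)

    return pd.DataFrame(
        {
            "group_a_mean": mean_a,
            "group_b_mean": mean_b,
            "log2_fold_change": l2fc,
            "p_value": p_values,
            "adjusted_p": adjusted,
            "direction": np.where(l2fc >= 0, "up_in_a", "down_in_a"),
            "expressed": expressed,
            "is_deg": is_deg.astype(bool),
        }
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def normalized_profiles(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score of log2(FPKM + 1); constant genes map to zero."""
    log = np.log2(fpkm + 1.0)
    centered = log.sub(log.mean(axis=1), axis=0)
    sd = log.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    return centered.div(sd, axis=0)


@dataclass
class ClusterAssignment:
    labels: pd.Series          # gene -> cluster id in 1..k
    centroids: pd.DataFrame    # cluster id x samples
    inertia: float


def kmeans_cluster(
    fpkm: pd.DataFrame,
    k: int = 9,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> ClusterAssignment:
    """K-means (Lloyd, Euclidean, k-means++ seeding) on normalised profiles."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(fpkm):
        raise ValidationError(f"k={k} exceeds number of genes ({len(fpkm)})")
    profiles = normalized_profiles(fpkm)
    model = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        algorithm="lloyd",
        random_state=seed,
    ).fit(profiles.to_numpy())
    labels = pd.Series(model.labels_ + 1, index=fpkm.index, name="cluster")
    centroids = pd.DataFrame(
        model.cluster_centers_, index=range(1, k + 1), columns=fpkm.columns
    )
    return ClusterAssignment(labels=labels, centroids=centroids, inertia=float(model.inertia_))


@dataclass
class ProfileOverview:
    linkage_matrix: np.ndarray      # scipy hierarchical linkage of samples
    sample_order: list[str]
    distances: pd.DataFrame         # 1 - Pearson sample-sample distances
    pca_coordinates: pd.DataFrame   # samples x components
    variance_explained: np.ndarray  # fraction per component


def profile_overview(fpkm: pd.DataFrame) -> ProfileOverview:
    """Sample-level hierarchical clustering (1 - Pearson, average linkage)
    and PCA of log2(FPKM + 1) profiles."""
    if fpkm.shape[1] < 2:
        raise ValidationError("need at least two samples")
    log = np.log2(fpkm + 1.0)
    corr = np.corrcoef(log.to_numpy().T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    link = linkage(squareform(dist, checks=False), method="average")

    n_comp = min(fpkm.shape[1], max(fpkm.shape[0], 1))
    pca = PCA(n_components=min(n_comp, fpkm.shape[1]))
    coords = pca.fit_transform(log.to_numpy().T)
    coords_df = pd.DataFrame(
        coords,
        index=fpkm.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return ProfileOverview(
        linkage_matrix=link,
        sample_order=list(fpkm.columns),
        distances=pd.DataFrame(dist, index=fpkm.columns, columns=fpkm.columns),
        pca_coordinates=coords_df,
        variance_explained=pca.explained_variance_ratio_,
    )
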