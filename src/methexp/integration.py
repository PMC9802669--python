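"""Joining DMRs, DEGs, gene models, and annotations.

Covers DMR-gene association over "body + 2 kb upstream", DEG enrichment among
DMR-associated genes (fold + hypergeometric tail), hyper/hypo x up/down
cross-tabs, genome-wide window-level methylation-expression correlation, and
flat term enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .methylome import iter_windows


# ---------------------------------------------------------------------------
# Gene geometry
# ---------------------------------------------------------------------------

def upstream_interval(
    start: int,
    end: int,
    strand: str,
    upstream: int = 2000,
    chrom_length: int | None = None,
) -> tuple[int, int] | None:
    """Strand-aware promoter interval (1-based inclusive), clipped.

    ``[start - upstream, start - 1]`` on ``+``; ``[end + 1, end + upstream]``
    on ``-``. Returns None when clipping empties the interval.
    """
    if strand == "+":
        lo, hi = max(1, start - upstream), start - 1
    elif strand == "-":
        lo, hi = end + 1, end + upstream
        if chrom_length is not None:
            hi = min(hi, chrom_length)
    else:
        raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
    if lo > hi:
        return None
    return lo, hi


def genic_intervals(
    genes: pd.DataFrame,
    upstream: int = 2000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Body and promoter intervals per gene (1-based inclusive).

    Columns: gene_id, chrom, start, end, part ('body' | 'upstream').
    """
    rows = []
    for row in genes.itertuples(index=False):
        rows.append((row.gene_id, row.chrom, row.start, row.end, "body"))
        clen = chrom_lengths.get(row.chrom) if chrom_lengths else None
        prom = upstream_interval(row.start, row.end, row.strand, upstream, clen)
        if prom is not None:
            rows.append((row.gene_id, row.chrom, prom[0], prom[1], "upstream"))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "part"])


def associate_dmrs(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    upstream: int = 2000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Associate DMRs with genes by >= 1 bp overlap with body or promoter.

    ``dmrs`` uses 0-based half-open rows (as exported) and must carry a
    ``dmr_id`` column (one is synthesised from the row order if absent).
    Returns one row per (gene, DMR) pair with ``where`` in
    {'body', 'upstream', 'both'}.
    """
    dmrs = dmrs.copy()
    if "dmr_id" not in dmrs.columns:
        dmrs["dmr_id"] = [f"DMR{i:06d}" for i in range(len(dmrs))]
    regions = genic_intervals(genes, upstream=upstream, chrom_lengths=chrom_lengths)

    gene_chroms = set(genes["chrom"])
    dmr_chroms = set(dmrs["chrom"])
    mismatch = dmr_chroms - gene_chroms
    if mismatch and gene_chroms:
        warnings.warn(
            f"{len(mismatch)} DMR chromosome(s) absent from gene models: "
            f"{sorted(mismatch)[:5]}"
        )

    pairs: dict[tuple[str, str], set[str]] = {}
    by_chrom = {chrom: grp for chrom, grp in regions.groupby("chrom")}
    for row in dmrs.itertuples(index=False):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            continue
        # DMR 0-based half-open [start, end); region 1-based inclusive.
        hit = (grp["start"] <= row.end) & (grp["end"] >= row.start + 1)
        for region in grp[hit].itertuples(index=False):
            pairs.setdefault((region.gene_id, row.dmr_id), set()).add(region.part)

    rows = [
        (gene, dmr, "both" if len(parts) > 1 else next(iter(parts)))
        for (gene, dmr), parts in sorted(pairs.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "dmr_id", "where"])


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    fold_enrichment: float
    p_value: float


def hypergeom_upper_tail(k: int, n_total: int, n_marked: int, n_drawn: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N=n_total, K=n_marked, n=n_drawn)."""
    return float(stats.hypergeom.sf(k - 1, n_total, n_marked, n_drawn))


def deg_dmr_enrichment(
    n_total_genes: int,
    n_dmr_assoc_genes: int,
    n_total_degs: int,
    n_dmr_assoc_degs: int,
) -> EnrichmentResult:
    """Fold enrichment of DEGs among DMR-associated genes with a
    hypergeometric upper-tail P.

    fold = (k / n) / (K / N) with N total genes, K DMR-associated genes,
    n total DEGs, k DMR-associated DEGs.
    """
    N, K, n, k = n_total_genes, n_dmr_assoc_genes, n_total_degs, n_dmr_assoc_degs
    if K > N or n > N or k > min(K, n) or min(N, K, n, k) < 0:
        raise ValidationError(
            f"inconsistent enrichment inputs N={N} K={K} n={n} k={k}"
        )
    if K == 0 or n == 0:
        raise ValidationError("fold enrichment undefined: K or n is zero")
    fold = (k / n) / (K / N)
    return EnrichmentResult(fold_enrichment=fold, p_value=hypergeom_upper_tail(k, N, K, n))


def term_enrichment(
    gene_set: Iterable[str],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Flat over-representation test of ``gene_set`` against a gene -> term
    background annotation (columns gene_id, term_id).

    Per term: N = annotated background genes, K = the term's genes, n = set
    genes within the background, k = the term's genes in the set. Upper-tail
    hypergeometric P plus a BH q-value column; sorted by P.
    """
    background = set(annotation["gene_id"])
    if not background:
        raise ValidationError("empty background annotation")
    genes = set(gene_set) & background
    N, n = len(background), len(genes)

    rows = []
    for term, grp in annotation.groupby("term_id"):
        members = set(grp["gene_id"])
        K = len(members)
        k = len(members & genes)
        p = hypergeom_upper_tail(k, N, K, n)
        expected = n * K / N
        fold = (k / expected) if expected > 0 else float("nan")
        rows.append((term, K, k, fold, p))
    table = pd.DataFrame(
        rows, columns=["term_id", "term_size", "overlap", "fold_enrichment", "p_value"]
    )
    table["q_value"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    table.sort_values(["p_value", "term_id"], inplace=True, kind="stable")
    table.reset_index(drop=True, inplace=True)
    return table


# ---------------------------------------------------------------------------
# Hyper/hypo x up/down cross-tab
# ---------------------------------------------------------------------------

def hyper_hypo_crosstab(
    dmrs: pd.DataFrame,
    degs: pd.DataFrame,
    association: pd.DataFrame,
) -> pd.DataFrame:
    """Direction cross-tab of DEG-overlapping DMRs.

    ``dmrs`` needs dmr_id / context / direction; ``degs`` is the per-gene DEG
    table (index gene_id, columns direction / is_deg); ``association`` maps
    gene_id <-> dmr_id. Each (DMR, DEG) pair counts once. Hyper fraction is
    hyper / (hyper + hypo) per (context, DEG direction); empty classes yield
    NaN, not zero.
    """
    deg_dirs = degs.loc[degs["is_deg"], "direction"]
    pairs = association.merge(
        deg_dirs.rename("deg_direction"), left_on="gene_id", right_index=True
    )
    pairs = pairs.merge(
        dmrs[["dmr_id", "context", "direction"]].rename(
            columns={"direction": "dmr_direction"}
        ),
        on="dmr_id",
    )
    rows = []
    contexts = sorted(dmrs["context"].unique())
    for context in contexts:
        for deg_direction in ("up_in_a", "down_in_a"):
            cell = pairs[
                (pairs["context"] == context)
                & (pairs["deg_direction"] == deg_direction)
            ]
            n_hyper = int((cell["dmr_direction"] == "hyper").sum())
            n_hypo = int((cell["dmr_direction"] == "hypo").sum())
            total = n_hyper + n_hypo
            frac = n_hyper / total if total else float("nan")
            rows.append((context, deg_direction, n_hyper, n_hypo, frac))
    return pd.DataFrame(
        rows,
        columns=["context", "deg_direction", "n_hyper", "n_hypo", "hyper_fraction"],
    )


# ---------------------------------------------------------------------------
# Window-level methylation vs expression
# ---------------------------------------------------------------------------

def window_expression_track(
    fpkm: pd.DataFrame | pd.Series,
    genes: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window_size: int = 1_000_000,
    window_step: int = 200_000,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Per-window mean log10(FPKM + eps) of genes anchored by body midpoint.

    ``fpkm`` may be a per-gene Series (e.g. a group mean) or a matrix whose
    row means are used. Windows without genes carry NaN.
    """
    values = fpkm.mean(axis=1) if isinstance(fpkm, pd.DataFrame) else fpkm
    values = np.log10(values.reindex(genes["gene_id"]).to_numpy(dtype=float) + eps)
    mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
    chroms = genes["chrom"].to_numpy()

    rows = []
    for chrom, length in chrom_lengths.items():
        mask = chroms == chrom
        mids = mid[mask] - 1  # 0-based for window arithmetic
        vals = values[mask]
        order = np.argsort(mids, kind="stable")
        mids, vals = mids[order], vals[order]
        cum = np.concatenate([[0.0], np.cumsum(vals)])
        for start, end in iter_windows(length, window_size, window_step):
            lo = np.searchsorted(mids, start, side="left")
            hi = np.searchsorted(mids, end, side="left")
            n_genes = int(hi - lo)
            mean_expr = (cum[hi] - cum[lo]) / n_genes if n_genes else float("nan")
            rows.append((chrom, start, end, n_genes, mean_expr))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_genes", "mean_log_fpkm"]
    )


def methylation_expression_correlation(
    window_methylation: Sequence[float] | pd.Series,
    window_expression: Sequence[float] | pd.Series,
) -> tuple[float, float]:
    """Pearson r (+ two-sided t-transform P) over aligned window tracks.

    Windows where either track is undefined (NaN) are dropped; fewer than
    three joint windows is an error.
    """
    x = np.asarray(window_methylation, dtype=float)
    y = np.asarray(window_expression, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("window tracks are not aligned")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValidationError(f"only {len(x)} joint windows (< 3)")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
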