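"""Differentially methylated region (DMR) detection between two samples.

The scan slides a window of ``window_sites`` consecutive shared same-context
cytosines (step one site). A window is differentially methylated when the
pooled-read level difference exceeds ``diff_cutoff`` in absolute value
(strict) and the two-sided Fisher exact P on the pooled 2x2 count table is at
most ``p_cutoff``. Overlapping passing windows are collapsed into candidates;
nearby candidates whose joint spanning region still passes both criteria are
merged into one continuous DMR, iterated to a fixed point.

Read counts are pooled across biological replicates per group before testing;
coordinates are 1-based inclusive internally, converted to 0-based half-open
in the exported table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .methylome import CONTEXTS


@dataclass
class DMRCandidate:
    chrom: str
    start: int  # 1-based inclusive, position of the first member site
    end: int    # 1-based inclusive, position of the last member site
    context: str
    n_sites: int
    m_a: int
    n_a: int
    m_b: int
    n_b: int
    p_value: float
    merged_from: int = 1

    @property
    def level_a(self) -> float:
        return self.m_a / self.n_a if self.n_a else float("nan")

    @property
    def level_b(self) -> float:
        return self.m_b / self.n_b if self.n_b else float("nan")

    @property
    def diff(self) -> float:
        return self.level_a - self.level_b

    @property
    def direction(self) -> str:
        return "hyper" if self.diff > 0 else "hypo"


def fisher_two_sided(m_a: int, u_a: int, m_b: int, u_b: int) -> float:
    """Two-sided Fisher exact P for the 2x2 table [[m_a, u_a], [m_b, u_b]]."""
    return float(stats.fisher_exact([[m_a, u_a], [m_b, u_b]])[1])


def shared_sites(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    context: str,
    min_coverage: int = 4,
) -> pd.DataFrame:
    """Same-context sites covered >= min_coverage in both groups.

    Returns columns chrom, pos, strand, m_a, n_a, m_b, n_b sorted by
    (chrom, pos, strand).
    """
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    keys = ["chrom", "pos", "strand"]

    def _prep(sites: pd.DataFrame, tag: str) -> pd.DataFrame:
        sub = sites[sites["context"] == context]
        out = sub[keys].copy()
        out[f"m_{tag}"] = sub["m"].to_numpy()
        out[f"n_{tag}"] = (sub["m"] + sub["u"]).to_numpy()
        return out[out[f"n_{tag}"] >= min_coverage]

    merged = _prep(sites_a, "a").merge(_prep(sites_b, "b"), on=keys, how="inner")
    merged.sort_values(keys, inplace=True, kind="stable")
    merged.reset_index(drop=True, inplace=True)
    return merged


def _window_pools(values: np.ndarray, w: int) -> np.ndarray:
    """Sliding-window sums of length w (step 1)."""
    cum = np.concatenate([[0], np.cumsum(values)])
    return cum[w:] - cum[:-w]


def _span_candidate(
    chrom: str,
    context: str,
    pos: np.ndarray,
    m_a: np.ndarray,
    n_a: np.ndarray,
    m_b: np.ndarray,
    n_b: np.ndarray,
    s: int,
    e: int,
) -> DMRCandidate:
    """Pooled statistics of the site span [s, e] (inclusive site indices)."""
    sm_a = int(m_a[s : e + 1].sum())
    sn_a = int(n_a[s : e + 1].sum())
    sm_b = int(m_b[s : e + 1].sum())
    sn_b = int(n_b[s : e + 1].sum())
    p = fisher_two_sided(sm_a, sn_a - sm_a, sm_b, sn_b - sm_b)
    return DMRCandidate(
        chrom=chrom,
        start=int(pos[s]),
        end=int(pos[e]),
        context=context,
        n_sites=e - s + 1,
        m_a=sm_a,
        n_a=sn_a,
        m_b=sm_b,
        n_b=sn_b,
        p_value=p,
    )


def _passes(cand: DMRCandidate, diff_cutoff: float, p_cutoff: float) -> bool:
    return abs(cand.diff) > diff_cutoff and cand.p_value <= p_cutoff


def scan_candidates(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    context: str,
    min_coverage: int = 4,
    min_sites: int = 5,
    diff_cutoff: float = 0.1,
    p_cutoff: float = 0.05,
    window_sites: int = 5,
) -> tuple[list[DMRCandidate], pd.DataFrame]:
    """Window scan for DMR candidates in one context.

    Returns the candidate list and the shared-site table (the latter is
    needed again when merging nearby candidates over their spanning region).
    Overlapping passing windows are collapsed greedily: a window extends the
    open candidate only if the extended span itself still passes both
    criteria, so every emitted candidate satisfies the thresholds.
    """
    if window_sites < min_sites:
        window_sites = min_sites
    shared = shared_sites(sites_a, sites_b, context, min_coverage=min_coverage)
    if len(shared) < min_sites:
        warnings.warn(
            f"context {context}: only {len(shared)} shared covered sites "
            f"genome-wide (< {min_sites}); no candidates"
        )
        return [], shared

    candidates: list[DMRCandidate] = []
    w = window_sites
    for chrom, grp in shared.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        m_a = grp["m_a"].to_numpy()
        n_a = grp["n_a"].to_numpy()
        m_b = grp["m_b"].to_numpy()
        n_b = grp["n_b"].to_numpy()
        if len(pos) < w:
            continue
        wm_a = _window_pools(m_a, w)
        wn_a = _window_pools(n_a, w)
        wm_b = _window_pools(m_b, w)
        wn_b = _window_pools(n_b, w)
        with np.errstate(invalid="ignore", divide="ignore"):
            diff = wm_a / wn_a - wm_b / wn_b
        # Cheap vectorised prefilter; Fisher only on windows past the level
        # cutoff (the expensive part of the scan).
        maybe = np.nonzero(np.abs(diff) > diff_cutoff)[0]
        passing = [
            int(i)
            for i in maybe
            if fisher_two_sided(
                int(wm_a[i]), int(wn_a[i] - wm_a[i]), int(wm_b[i]), int(wn_b[i] - wm_b[i])
            )
            <= p_cutoff
        ]
        if not passing:
            continue

        cur_s = passing[0]
        cur_e = cur_s + w - 1
        cur = _span_candidate(chrom, context, pos, m_a, n_a, m_b, n_b, cur_s, cur_e)
        for i in passing[1:]:
            if i <= cur_e:  # shares at least one site with the open span
                trial = _span_candidate(
                    chrom, context, pos, m_a, n_a, m_b, n_b, cur_s, i + w - 1
                )
                if _passes(trial, diff_cutoff, p_cutoff):
                    cur, cur_e = trial, i + w - 1
                    continue
            candidates.append(cur)
            cur_s, cur_e = i, i + w - 1
            cur = _span_candidate(chrom, context, pos, m_a, n_a, m_b, n_b, cur_s, cur_e)
        candidates.append(cur)
    return candidates, shared


def merge_interdependent(
    candidates: Sequence[DMRCandidate],
    shared: pd.DataFrame,
    diff_cutoff: float = 0.1,
    p_cutoff: float = 0.05,
    max_gap: int = 100,
) -> list[DMRCandidate]:
    """Join nearby interdependent candidates into continuous DMRs.

    Two adjacent candidates (gap <= ``max_gap`` bp) are joined when the
    genomic region from the upstream start to the downstream end — pooled
    over *all* shared covered context sites inside it — still has a level
    difference > ``diff_cutoff`` and Fisher P <= ``p_cutoff``. The pass is
    repeated until a fixed point.
    """
    by_chrom: dict[str, list[DMRCandidate]] = {}
    for cand in candidates:
        by_chrom.setdefault(cand.chrom, []).append(cand)

    result: list[DMRCandidate] = []
    for chrom in sorted(by_chrom):
        grp = shared[shared["chrom"] == chrom]
        pos = grp["pos"].to_numpy()
        m_a = grp["m_a"].to_numpy()
        n_a = grp["n_a"].to_numpy()
        m_b = grp["m_b"].to_numpy()
        n_b = grp["n_b"].to_numpy()
        chain = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        changed = True
        while changed:
            changed = False
            merged: list[DMRCandidate] = []
            i = 0
            while i < len(chain):
                cur = chain[i]
                while i + 1 < len(chain):
                    nxt = chain[i + 1]
                    gap = nxt.start - cur.end - 1
                    if gap > max_gap:
                        break
                    s = int(np.searchsorted(pos, cur.start, side="left"))
                    e = int(np.searchsorted(pos, nxt.end, side="right")) - 1
                    joined = _span_candidate(
                        cur.chrom, cur.context, pos, m_a, n_a, m_b, n_b, s, e
                    )
                    if not _passes(joined, diff_cutoff, p_cutoff):
                        break
                    joined = replace(
                        joined, merged_from=cur.merged_from + nxt.merged_from
                    )
                    cur = joined
                    i += 1
                    changed = True
                merged.append(cur)
                i += 1
            chain = merged
        result.extend(chain)
    return result


def call_dmrs(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    context: str,
    min_coverage: int = 4,
    min_sites: int = 5,
    diff_cutoff: float = 0.1,
    p_cutoff: float = 0.05,
    window_sites: int = 5,
    max_gap: int = 100,
) -> list[DMRCandidate]:
    """Full per-context DMR calling: scan, collapse, merge."""
    candidates, shared = scan_candidates(
        sites_a,
        sites_b,
        context,
        min_coverage=min_coverage,
        min_sites=min_sites,
        diff_cutoff=diff_cutoff,
        p_cutoff=p_cutoff,
        window_sites=window_sites,
    )
    return merge_interdependent(
        candidates, shared, diff_cutoff=diff_cutoff, p_cutoff=p_cutoff, max_gap=max_gap
    )


def dmrs_to_frame(dmrs: Sequence[DMRCandidate]) -> pd.DataFrame:
    """Export DMRs as a BED-like table (0-based half-open coordinates)."""
    rows = [
        (
            d.chrom,
            d.start - 1,
            d.end,
            d.context,
            d.n_sites,
            d.level_a,
            d.level_b,
            d.diff,
            d.p_value,
            d.direction,
            d.merged_from,
        )
        for d in dmrs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "context",
            "n_sites",
            "level_a",
            "level_b",
            "diff",
            "p_value",
            "direction",
            "merged_from",
        ],
    )


def classify_dmr_location(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    upstream: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each DMR genic/intergenic and report per-context genic fractions.

    A DMR (0-based half-open rows, as produced by :func:`dmrs_to_frame`) is
    genic when it overlaps >= 1 bp of any gene body or its strand-aware
    ``upstream`` promoter region.
    """
    from .integration import genic_intervals  # shared strand-aware geometry

    labelled = dmrs.copy()
    regions = genic_intervals(genes, upstream=upstream)
    location = []
    by_chrom = {
        chrom: grp[["start", "end"]].to_numpy()
        for chrom, grp in regions.groupby("chrom")
    }
    for row in labelled.itertuples(index=False):
        ivs = by_chrom.get(row.chrom)
        genic = False
        if ivs is not None:
            # DMR in 0-based half-open; regions in 1-based inclusive.
            genic = bool(
                np.any((ivs[:, 0] <= row.end) & (ivs[:, 1] >= row.start + 1))
            )
        location.append("genic" if genic else "intergenic")
    labelled["location"] = location
    fractions = (
        labelled.groupby("context")["location"]
        .apply(lambda s: float((s == "genic").mean()))
        .rename("genic_fraction")
        .reset_index()
    )
    return labelled, fractions
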