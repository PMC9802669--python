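"""Cytosine context assignment, methylcytosine calling, and methylome summaries.

A cytosine site is a row of a 6-column report (``chrom pos strand m u
context``); ``pos`` is the 1-based reference coordinate of the cytosine on
its strand (on ``-`` the reference base is G). Contexts follow the plant
convention CG / CHG / CHH with H in {A, T, C}, read 5'->3' on the site's own
strand. A site whose context window runs off the chromosome end is labelled
``NA`` and excluded from context-stratified statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

CONTEXTS = ("CG", "CHG", "CHH")

_A, _C, _G, _T = 65, 67, 71, 84
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
_COMPLEMENT[_A], _COMPLEMENT[_T] = _T, _A
_COMPLEMENT[_C], _COMPLEMENT[_G] = _G, _C


def _classify(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """Context code from the two downstream bases (0 = off-chromosome pad)."""
    is_h1 = (d1 == _A) | (d1 == _T) | (d1 == _C)
    is_h2 = (d2 == _A) | (d2 == _T) | (d2 == _C)
    out = np.full(d1.shape, "NA", dtype="<U3")
    out[d1 == _G] = "CG"
    out[is_h1 & (d2 == _G)] = "CHG"
    out[is_h1 & is_h2] = "CHH"
    return out


def chrom_cytosines(seq: str, chrom: str) -> pd.DataFrame:
    """Enumerate every cytosine on both strands of one chromosome.

    Returns a frame with columns ``chrom, pos, strand, context`` sorted by
    position (``+`` before ``-`` at equal positions).
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    pad = np.concatenate([np.zeros(2, dtype=np.uint8), arr, np.zeros(2, dtype=np.uint8)])

    plus_idx = np.nonzero(arr == _C)[0]
    plus_ctx = _classify(pad[plus_idx + 3], pad[plus_idx + 4])

    minus_idx = np.nonzero(arr == _G)[0]
    minus_ctx = _classify(
        _COMPLEMENT[pad[minus_idx + 1]], _COMPLEMENT[pad[minus_idx]]
    )

    frame = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.concatenate([plus_idx, minus_idx]) + 1,
            "strand": np.repeat(["+", "-"], [len(plus_idx), len(minus_idx)]),
            "context": np.concatenate([plus_ctx, minus_ctx]),
        }
    )
    frame.sort_values(["pos", "strand"], inplace=True, kind="stable")
    frame.reset_index(drop=True, inplace=True)
    return frame


def assign_context(genome: Mapping[str, str], chrom: str, pos: int, strand: str) -> str:
    """Context of the cytosine at ``(chrom, pos, strand)`` (1-based).

    Raises :class:`ValidationError` when the reference base at the position is
    not a cytosine on the requested strand.
    """
    seq = genome[chrom]
    if not 1 <= pos <= len(seq):
        raise ValidationError(f"position {chrom}:{pos} outside chromosome")
    base = seq[pos - 1].upper()
    if strand == "+":
        if base != "C":
            raise ValidationError(
                f"no cytosine at {chrom}:{pos}:+ (reference base {base})"
            )
        down = seq[pos : pos + 2].upper()
    elif strand == "-":
        if base != "G":
            raise ValidationError(
                f"no cytosine at {chrom}:{pos}:- (reference base {base})"
            )
        down = seq[max(pos - 3, 0) : pos - 1].upper()[::-1]
        down = down.translate(str.maketrans("ACGT", "TGCA"))
    else:
        raise ValidationError(f"strand must be '+' or '-', got {strand!r}")

    if len(down) >= 1 and down[0] == "G":
        return "CG"
    if len(down) < 2:
        return "NA"
    if down[0] in "ATC" and down[1] == "G":
        return "CHG"
    if down[0] in "ATC" and down[1] in "ATC":
        return "CHH"
    return "NA"


# ---------------------------------------------------------------------------
# Binomial methylcytosine calling
# ---------------------------------------------------------------------------

def binomial_upper_tail(m: np.ndarray, n: np.ndarray, error_rate: float) -> np.ndarray:
    """P(X >= m) for X ~ Binomial(n, error_rate); vectorised."""
    return stats.binom.sf(np.asarray(m) - 1, np.asarray(n), error_rate)


@dataclass
class CallResult:
    """Per-sample methylation calls plus shared-site bookkeeping."""

    calls: dict[str, pd.DataFrame]
    n_excluded: int


def call_methylcytosines(
    sites_per_sample: Mapping[str, pd.DataFrame],
    error_rate: float,
    min_coverage: int = 4,
    p_threshold: float = 1e-4,
) -> CallResult:
    """Binomial-test methylcytosine calls over sites shared across samples.

    A site (keyed by chrom, pos, strand) enters testing only when its total
    coverage ``n = m + u`` is at least ``min_coverage`` in *every* supplied
    sample; all other sites are excluded from every sample's calls. Per
    sample, ``p = P(X >= m | n, error_rate)`` under the binomial null, and a
    site is methylated iff ``p < p_threshold``.
    """
    if not 0 <= error_rate < 1:
        raise ValidationError(f"error_rate must be in [0, 1), got {error_rate}")
    if not sites_per_sample:
        raise ValidationError("no samples supplied")

    keys = ["chrom", "pos", "strand"]
    coverage = None
    for name, sites in sites_per_sample.items():
        if (sites[["m", "u"]] < 0).to_numpy().any():
            raise ValidationError(f"negative counts in sample {name}")
        n = (sites["m"] + sites["u"]).rename(name)
        frame = sites[keys].copy()
        frame[name] = n.to_numpy()
        frame = frame.set_index(keys)
        coverage = frame if coverage is None else coverage.join(frame, how="outer")
    # Missing site in a sample counts as zero coverage there.
    covered = (coverage.fillna(0) >= min_coverage).all(axis=1)
    shared_index = coverage.index[covered.to_numpy()]
    n_excluded = int(len(coverage) - len(shared_index))

    calls: dict[str, pd.DataFrame] = {}
    for name, sites in sites_per_sample.items():
        out = sites.set_index(keys)
        out = out.loc[out.index.isin(shared_index)].reset_index()
        n = (out["m"] + out["u"]).to_numpy()
        out["n"] = n
        out["level"] = np.where(n > 0, out["m"] / np.maximum(n, 1), np.nan)
        out["p_value"] = binomial_upper_tail(out["m"].to_numpy(), n, error_rate)
        out["is_methylated"] = out["p_value"] < p_threshold
        calls[name] = out
    return CallResult(calls=calls, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def iter_windows(chrom_length: int, size: int, step: int) -> Iterator[tuple[int, int]]:
    """0-based half-open sliding windows; every start < chrom_length."""
    start = 0
    while start < chrom_length:
        yield start, min(start + size, chrom_length)
        start += step


@dataclass
class MethylomeSummary:
    context_level: dict[str, float]
    mc_fraction: dict[str, float]
    overall_level: float
    windows: pd.DataFrame
    n_na_context: int = 0
    n_sites: int = 0

    def as_dict(self) -> dict:
        return {
            "context_level": self.context_level,
            "mc_fraction": self.mc_fraction,
            "overall_level": self.overall_level,
            "n_na_context": self.n_na_context,
            "n_sites": self.n_sites,
        }


def summarize_methylome(
    calls: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window_size: int = 1_000_000,
    window_step: int = 200_000,
) -> MethylomeSummary:
    """Per-context levels, mC fractions, and sliding-window mean levels.

    ``calls`` is one sample's call table (needs columns chrom, pos, context,
    level, is_methylated). Context averages are means of per-site levels over
    covered sites; the mC fraction is the share of all methylated cytosines
    falling in each context. Windows with zero covered sites carry NaN (they
    are missing, not zero).
    """
    usable = calls[calls["context"].isin(CONTEXTS)]
    n_na = int(len(calls) - len(usable))

    context_level = {
        ctx: float(grp["level"].mean()) if len(grp) else float("nan")
        for ctx, grp in ((c, usable[usable["context"] == c]) for c in CONTEXTS)
    }
    mc = usable[usable["is_methylated"]]
    total_mc = len(mc)
    mc_fraction = {
        ctx: (float((mc["context"] == ctx).sum()) / total_mc) if total_mc else float("nan")
        for ctx in CONTEXTS
    }
    overall = float(usable["level"].mean()) if len(usable) else float("nan")

    rows = []
    for chrom, length in chrom_lengths.items():
        sub = usable[usable["chrom"] == chrom]
        pos0 = sub["pos"].to_numpy() - 1
        order = np.argsort(pos0, kind="stable")
        pos0 = pos0[order]
        levels = sub["level"].to_numpy()[order]
        cum = np.concatenate([[0.0], np.cumsum(levels)])
        for start, end in iter_windows(length, window_size, window_step):
            lo = np.searchsorted(pos0, start, side="left")
            hi = np.searchsorted(pos0, end, side="left")
            n_sites = int(hi - lo)
            mean_level = (cum[hi] - cum[lo]) / n_sites if n_sites else float("nan")
            rows.append((chrom, start, end, n_sites, mean_level))
    windows = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "mean_level"]
    )
    return MethylomeSummary(
        context_level=context_level,
        mc_fraction=mc_fraction,
        overall_level=overall,
        windows=windows,
        n_na_context=n_na,
        n_sites=int(len(usable)),
    )


def pool_replicates(site_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sum methylated/unmethylated counts across replicate site tables."""
    if not site_tables:
        raise ValidationError("no replicate tables to pool")
    merged = pd.concat(site_tables, ignore_index=True)
    pooled = (
        merged.groupby(["chrom", "pos", "strand", "context"], sort=True, as_index=False)[
            ["m", "u"]
        ].sum()
    )
    pooled.sort_values(["chrom", "pos", "strand"], inplace=True, kind="stable")
    pooled.reset_index(drop=True, inplace=True)
    return pooled
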