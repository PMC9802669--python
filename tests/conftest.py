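import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from methexp.synthetic import SimulationConfig, SyntheticDataset


# ---------------------------------------------------------------------------
# Independent statistical oracles (pure enumeration; no scipy)
# ---------------------------------------------------------------------------

def binom_tail_oracle(m: int, n: int, p: float) -> float:
    """P(X >= m) by direct term-wise summation."""
    frac = Fraction(p).limit_denominator(10**12)
    total = sum(
        Fraction(math.comb(n, k)) * frac**k * (1 - frac) ** (n - k)
        for k in range(m, n + 1)
    )
    return float(total)


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by full enumeration."""
    denom = math.comb(N, n)
    total = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    )
    return total / denom


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P: sum of probabilities of all tables with the
    observed margins whose probability does not exceed the observed one."""
    row1, col1, total = a + b, a + c, a + b + c + d

    def table_prob(x: int) -> Fraction:
        return Fraction(
            math.comb(col1, x) * math.comb(total - col1, row1 - x),
            math.comb(total, row1),
        )

    lo = max(0, row1 - (total - col1))
    hi = min(row1, col1)
    observed = table_prob(a)
    cutoff = observed * (1 + Fraction(1, 10**9))  # tolerate fp ties
    return float(sum(table_prob(x) for x in range(lo, hi + 1) if table_prob(x) <= cutoff))


# ---------------------------------------------------------------------------
# Shared synthetic fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_chromosomes=2,
        chrom_length=120_000,
        n_genes=24,
        n_replicates=2,
        stages=("R5",),
        n_planted_dmrs=3,
        n_null_regions=3,
        n_planted_degs=6,
        anticorrelation_fraction=0.25,
        n_modules=1,
        module_size=4,
        coverage_mean=25.0,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config) -> SyntheticDataset:
    return SyntheticDataset(tiny_config)


def make_sites(rows) -> pd.DataFrame:
    """Site table from (chrom, pos, strand, m, u, context) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "m", "u", "context"]
    )


def interval_hit(table: pd.DataFrame, chrom: str, start0: int, end: int) -> bool:
    """Does any 0-based half-open row of ``table`` overlap [start0, end)?"""
    sub = table[table["chrom"] == chrom]
    return bool(((sub["start"] < end) & (sub["end"] > start0)).any())


@pytest.fixture(scope="session")
def global_rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
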