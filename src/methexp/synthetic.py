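"""Synthetic genomes, methylomes, and expression matrices with planted truth.

The generator mirrors the two-genotype x two-stage x replicated study design:
uniform-random chromosomes, non-overlapping strand-assigned genes, per-context
baseline methylation with genotype-specific planted DMRs, negative-binomial
counts with planted DEGs, planted promoter-methylation <-> expression
anti-correlation, and planted co-expression modules. Every planted effect is
recorded in :class:`TruthTables` so each downstream stage can be scored
against ground truth.

Randomness is funnelled through one seed: every output stream draws from a
``numpy`` ``SeedSequence`` keyed by a fixed stream id (per-sample streams are
keyed by sample index), so individual outputs are reproducible in isolation
and the whole dataset is byte-identical across runs.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as mio
from .errors import ConfigError, ValidationError
from .expression import ExpressionSet
from .integration import upstream_interval
from .methylome import CONTEXTS, chrom_cytosines

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed stream ids (never reorder: they define the byte-level output)
_S_GENOME, _S_GENES, _S_REGIONAL, _S_PLACEMENT, _S_ROLES = 0, 1, 2, 3, 4
_S_BASELINE, _S_MODULES, _S_ANNOTATION = 5, 6, 7
_S_METHYLOME, _S_EXPRESSION = 10, 20


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults give a small but detectable
    dataset (all planted effects pass the default pipeline thresholds)."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (1000, 5000)
    n_replicates: int = 3
    genotypes: tuple[str, str] = ("245", "Z16")
    stages: tuple[str, ...] = ("R5", "R8")
    coverage_mean: float = 30.0
    bisulfite_error: float = 0.01
    context_base_levels: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.8, "CHG": 0.7, "CHH": 0.1}
    )
    n_planted_dmrs: int = 10          # per context
    dmr_effect: float = 0.4
    dmr_n_sites: int = 8
    n_null_regions: int = 10          # matched no-effect regions per context
    n_planted_degs: int = 20
    deg_fold_change: float = 4.0
    nb_dispersion: float = 0.05
    anticorrelation_fraction: float = 0.0
    n_modules: int = 0
    module_size: int = 20
    module_strength: float = 0.6
    expr_log_mean: float = 5.0
    expr_log_sd: float = 1.0
    regional_amplitude: float = 0.0   # smooth per-chromosome methylation wave
    regional_coupling: float = 2.0    # expression response to the wave
    n_terms: int = 20
    on_undetectable_dmr: str = "error"  # or "regenerate"

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 10:
            raise ConfigError("need >= 1 chromosome of length >= 10")
        if self.n_genes < 0 or self.n_replicates < 1:
            raise ConfigError("n_genes must be >= 0 and n_replicates >= 1")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ConfigError(f"invalid gene_length_range {self.gene_length_range}")
        if not 0 <= self.bisulfite_error < 1:
            raise ConfigError("bisulfite_error must be in [0, 1)")
        if self.coverage_mean < 0:
            raise ConfigError("coverage_mean must be >= 0")
        for ctx in CONTEXTS:
            level = self.context_base_levels.get(ctx)
            if level is None or not 0 <= level <= 1:
                raise ConfigError(f"context_base_levels[{ctx}] must be in [0, 1]")
        if not 0.1 < self.dmr_effect <= 1:
            raise ConfigError(
                "dmr_effect must exceed the 0.1 DMR difference cutoff (and be <= 1)"
            )
        if self.dmr_n_sites < 5:
            raise ConfigError("dmr_n_sites must be >= 5 (the minimum DMR site count)")
        if self.deg_fold_change < 1:
            raise ConfigError("deg_fold_change must be >= 1")
        if 1 < self.deg_fold_change < 2:
            warnings.warn(
                "deg_fold_change < 2: planted DEGs will not pass the default "
                "fold-change threshold"
            )
        if not 0 <= self.anticorrelation_fraction <= 1:
            raise ConfigError("anticorrelation_fraction must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if not 0 <= self.regional_amplitude < 1:
            raise ConfigError("regional_amplitude must be in [0, 1)")
        if self.on_undetectable_dmr not in ("error", "regenerate"):
            raise ConfigError("on_undetectable_dmr must be 'error' or 'regenerate'")
        if len(self.genotypes) != 2:
            raise ConfigError("exactly two genotypes")

    def sample_ids(self) -> list[str]:
        return [
            f"{g}_{s}_r{r}"
            for g in self.genotypes
            for s in self.stages
            for r in range(1, self.n_replicates + 1)
        ]


@dataclass
class TruthTables:
    """Planted structure: the acceptance oracle for every pipeline stage."""

    planted_dmrs: pd.DataFrame        # chrom start end context direction n_sites
    null_regions: pd.DataFrame        # chrom start end context
    planted_degs: pd.DataFrame        # gene_id stage direction fold
    anticorrelated: pd.DataFrame      # gene_id promoter_direction expression_direction
    modules: pd.DataFrame             # gene_id module_id


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


class SyntheticDataset:
    """Deterministic builder for one simulated study."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.genome = self._make_genome()
        self.chrom_lengths = {c: len(s) for c, s in self.genome.items()}
        self.genes = self._make_genes()
        self._sites = {
            chrom: chrom_cytosines(seq, chrom) for chrom, seq in self.genome.items()
        }
        self._regional = self._make_regional()
        self.truth = self._plant_truth()
        self._levels: dict[str, dict[str, np.ndarray]] | None = None

    # -- genome and genes ---------------------------------------------------

    def _chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.config.n_chromosomes)]

    def _make_genome(self) -> dict[str, str]:
        genome = {}
        for i, chrom in enumerate(self._chrom_names()):
            rng = _rng(self.config.seed, _S_GENOME, i)
            codes = rng.integers(0, 4, size=self.config.chrom_length)
            genome[chrom] = _BASES[codes].tobytes().decode("ascii")
        return genome

    def _make_genes(self) -> pd.DataFrame:
        cfg = self.config
        chroms = self._chrom_names()
        per_chrom = [cfg.n_genes // len(chroms)] * len(chroms)
        for i in range(cfg.n_genes % len(chroms)):
            per_chrom[i] += 1
        rng = _rng(cfg.seed, _S_GENES)
        lo, hi = cfg.gene_length_range
        rows = []
        for chrom, k in zip(chroms, per_chrom):
            if k == 0:
                continue
            lengths = rng.integers(lo, hi + 1, size=k)
            free = cfg.chrom_length - int(lengths.sum())
            if free < 0:
                raise ValidationError(
                    f"cannot place {k} non-overlapping genes of total length "
                    f"{int(lengths.sum())} bp on {chrom} ({cfg.chrom_length} bp)"
                )
            gaps = np.floor(rng.dirichlet(np.ones(k + 1)) * free).astype(int)
            start = 1
            for length, gap in zip(lengths, gaps):
                start += int(gap)
                end = start + int(length) - 1
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((chrom, start, end, strand))
                start = end + 1
        genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
        genes.sort_values(["chrom", "start"], inplace=True, kind="stable")
        genes.insert(0, "gene_id", [f"G{i:05d}" for i in range(len(genes))])
        genes.reset_index(drop=True, inplace=True)
        return genes

    # -- regional methylation/expression wave -------------------------------

    def _make_regional(self) -> dict[str, tuple[float, float]]:
        """(n_periods, phase) of a sinusoidal modifier per chromosome."""
        rng = _rng(self.config.seed, _S_REGIONAL)
        out = {}
        for chrom in self._chrom_names():
            out[chrom] = (float(rng.integers(2, 6)), float(rng.uniform(0, 2 * np.pi)))
        return out

    def regional_wave(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Smooth modifier in [-amplitude, +amplitude] at 1-based positions."""
        amp = self.config.regional_amplitude
        if amp == 0:
            return np.zeros(len(pos))
        periods, phase = self._regional[chrom]
        length = self.chrom_lengths[chrom]
        return amp * np.sin(2 * np.pi * periods * (np.asarray(pos) / length) + phase)

    # -- truth planting -----------------------------------------------------

    def _genic_exclusion(self) -> dict[str, np.ndarray]:
        """Per-chrom (start, end) 1-based intervals covering body + 2 kb
        promoter; planted DMR/null regions avoid these so the interval truth
        stays independent of the gene-level anti-correlation truth."""
        rows = []
        for g in self.genes.itertuples(index=False):
            rows.append((g.chrom, max(1, g.start - 2000), min(self.chrom_lengths[g.chrom], g.end + 2000)))
        out: dict[str, list] = {}
        for chrom, s, e in rows:
            out.setdefault(chrom, []).append((s, e))
        return {c: np.array(v) for c, v in out.items()}

    def _plant_truth(self) -> TruthTables:
        cfg = self.config
        attempts = 10 if cfg.on_undetectable_dmr == "regenerate" else 1
        last_err: Exception | None = None
        for attempt in range(attempts):
            try:
                dmrs, nulls = self._place_regions(attempt)
                break
            except ValidationError as err:  # not enough eligible site runs
                last_err = err
        else:
            raise ValidationError(
                f"could not place planted DMRs after {attempts} attempt(s): {last_err}"
            )
        degs, anti, modules = self._assign_gene_roles()
        return TruthTables(
            planted_dmrs=dmrs,
            null_regions=nulls,
            planted_degs=degs,
            anticorrelated=anti,
            modules=modules,
        )

    def _place_regions(self, attempt: int) -> tuple[pd.DataFrame, pd.DataFrame]:
        cfg = self.config
        rng = _rng(cfg.seed, _S_PLACEMENT, attempt)
        k = cfg.dmr_n_sites
        buffer = 500
        excl = self._genic_exclusion()
        taken: dict[str, list[tuple[int, int]]] = {c: [] for c in self._chrom_names()}

        def free(chrom: str, s: int, e: int) -> bool:
            g = excl.get(chrom)
            if g is not None and len(g) and bool(
                np.any((g[:, 0] <= e) & (g[:, 1] >= s))
            ):
                return False
            return all(not (ts <= e + buffer and te >= s - buffer) for ts, te in taken[chrom])

        dmr_rows, null_rows = [], []
        for context in CONTEXTS:
            candidates = []
            for chrom, sites in self._sites.items():
                pos = sites.loc[sites["context"] == context, "pos"].to_numpy()
                for i in range(0, len(pos) - k + 1):
                    if pos[i + k - 1] - pos[i] <= 5000:
                        candidates.append((chrom, int(pos[i]), int(pos[i + k - 1])))
            order = rng.permutation(len(candidates))
            needed = cfg.n_planted_dmrs + cfg.n_null_regions
            placed = 0
            direction_cycle = ["hyper", "hypo"]
            for idx in order:
                chrom, s, e = candidates[idx]
                if not free(chrom, s, e):
                    continue
                taken[chrom].append((s, e))
                if placed < cfg.n_planted_dmrs:
                    direction = direction_cycle[placed % 2]
                    dmr_rows.append((chrom, s, e, context, direction, k))
                else:
                    null_rows.append((chrom, s, e, context))
                placed += 1
                if placed == needed:
                    break
            if placed < needed:
                raise ValidationError(
                    f"only {placed}/{needed} non-overlapping {context} runs of "
                    f"{k} sites available outside genic regions"
                )
        dmrs = pd.DataFrame(
            dmr_rows, columns=["chrom", "start", "end", "context", "direction", "n_sites"]
        ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        nulls = pd.DataFrame(
            null_rows, columns=["chrom", "start", "end", "context"]
        ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        return dmrs, nulls

    def _assign_gene_roles(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        cfg = self.config
        rng = _rng(cfg.seed, _S_ROLES)
        gene_ids = self.genes["gene_id"].tolist()
        n_anti = int(round(cfg.anticorrelation_fraction * len(gene_ids)))
        n_module = cfg.n_modules * cfg.module_size
        if n_anti + cfg.n_planted_degs + n_module > len(gene_ids):
            raise ConfigError(
                "planted gene roles exceed gene count: "
                f"{n_anti} anticorrelated + {cfg.n_planted_degs} DEGs + "
                f"{n_module} module genes > {len(gene_ids)} genes"
            )
        shuffled = list(rng.permutation(gene_ids))
        anti_ids = shuffled[:n_anti]
        deg_ids = shuffled[n_anti : n_anti + cfg.n_planted_degs]
        module_ids = shuffled[
            n_anti + cfg.n_planted_degs : n_anti + cfg.n_planted_degs + n_module
        ]

        anti = pd.DataFrame(
            {
                "gene_id": anti_ids,
                "promoter_direction": ["hyper" if i % 2 == 0 else "hypo" for i in range(n_anti)],
            }
        )
        anti["expression_direction"] = np.where(
            anti["promoter_direction"] == "hyper", "down", "up"
        )

        degs = pd.DataFrame(
            {
                "gene_id": deg_ids,
                "stage": [cfg.stages[i % len(cfg.stages)] for i in range(len(deg_ids))],
                "direction": ["up" if i % 2 == 0 else "down" for i in range(len(deg_ids))],
                "fold": cfg.deg_fold_change,
            }
        )

        modules = pd.DataFrame(
            {
                "gene_id": module_ids,
                "module_id": [
                    i // cfg.module_size + 1 for i in range(len(module_ids))
                ],
            }
        )
        return degs, anti, modules

    # -- methylomes ---------------------------------------------------------

    def _true_levels(self) -> dict[str, dict[str, np.ndarray]]:
        """Per chromosome, per genotype true methylation level per site."""
        if self._levels is not None:
            return self._levels
        cfg = self.config
        focal, other = cfg.genotypes
        levels: dict[str, dict[str, np.ndarray]] = {}
        for chrom, sites in self._sites.items():
            pos = sites["pos"].to_numpy()
            ctx = sites["context"].to_numpy()
            base = np.zeros(len(sites))
            for context in CONTEXTS:
                base[ctx == context] = cfg.context_base_levels[context]
            base = np.clip(base * (1.0 + self.regional_wave(chrom, pos)), 0.0, 1.0)

            shift = np.zeros(len(sites))  # focal-genotype shift
            planted = self.truth.planted_dmrs
            for row in planted[planted["chrom"] == chrom].itertuples(index=False):
                mask = (pos >= row.start) & (pos <= row.end) & (ctx == row.context)
                shift[mask] += cfg.dmr_effect if row.direction == "hyper" else -cfg.dmr_effect
            anti = self.truth.anticorrelated
            if len(anti):
                gene_rows = self.genes.set_index("gene_id")
                for row in anti.itertuples(index=False):
                    g = gene_rows.loc[row.gene_id]
                    if g["chrom"] != chrom:
                        continue
                    prom = upstream_interval(
                        int(g["start"]), int(g["end"]), g["strand"],
                        2000, self.chrom_lengths[chrom],
                    )
                    if prom is None:
                        continue
                    mask = (pos >= prom[0]) & (pos <= prom[1])
                    shift[mask] += (
                        cfg.dmr_effect if row.promoter_direction == "hyper" else -cfg.dmr_effect
                    )
            levels[chrom] = {
                focal: np.clip(base + shift, 0.0, 1.0),
                other: base,
            }
        self._levels = levels
        return levels

    def methylome(self, sample_id: str) -> pd.DataFrame:
        """Observed per-cytosine report for one sample."""
        cfg = self.config
        ids = cfg.sample_ids()
        if sample_id not in ids:
            raise ValidationError(f"unknown sample {sample_id!r}")
        k = ids.index(sample_id)
        genotype = sample_id.split("_")[0]
        rng = _rng(cfg.seed, _S_METHYLOME, k)
        levels = self._true_levels()
        frames = []
        for chrom in self._chrom_names():
            sites = self._sites[chrom]
            true = levels[chrom][genotype]
            p_obs = np.clip(true + cfg.bisulfite_error * (1.0 - true), 0.0, 1.0)
            n = rng.poisson(cfg.coverage_mean, size=len(sites))
            m = rng.binomial(n, p_obs)
            frame = sites.copy()
            frame["m"] = m
            frame["u"] = n - m
            frames.append(frame[["chrom", "pos", "strand", "m", "u", "context"]])
        return pd.concat(frames, ignore_index=True)

    def methylomes(self) -> dict[str, pd.DataFrame]:
        return {s: self.methylome(s) for s in self.config.sample_ids()}

    # -- expression ---------------------------------------------------------

    def _mean_matrix(self) -> pd.DataFrame:
        cfg = self.config
        genes = self.genes
        rng = _rng(cfg.seed, _S_BASELINE)
        baseline = rng.lognormal(cfg.expr_log_mean, cfg.expr_log_sd, size=len(genes))
        if cfg.regional_amplitude > 0:
            mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
            chrom_col = genes["chrom"].to_numpy()
            wave = np.zeros(len(genes))
            for chrom in self._chrom_names():
                mask = chrom_col == chrom
                wave[mask] = self.regional_wave(chrom, mid[mask])
            baseline = baseline * np.exp(-cfg.regional_coupling * wave)

        samples = cfg.sample_ids()
        gene_row = {g: i for i, g in enumerate(genes["gene_id"])}
        values = np.tile(baseline[:, None], (1, len(samples)))
        focal = cfg.genotypes[0]
        sample_genotype = np.array([s.split("_")[0] for s in samples])
        sample_stage = np.array([s.split("_")[1] for s in samples])

        for row in self.truth.planted_degs.itertuples(index=False):
            factor = row.fold if row.direction == "up" else 1.0 / row.fold
            cols = (sample_genotype == focal) & (sample_stage == row.stage)
            values[gene_row[row.gene_id], cols] *= factor
        for row in self.truth.anticorrelated.itertuples(index=False):
            factor = (
                cfg.deg_fold_change
                if row.expression_direction == "up"
                else 1.0 / cfg.deg_fold_change
            )
            values[gene_row[row.gene_id], sample_genotype == focal] *= factor

        if len(self.truth.modules):
            zrng = _rng(cfg.seed, _S_MODULES)
            factors = zrng.normal(
                0.0, 1.0, size=(int(self.truth.modules["module_id"].max()), len(samples))
            )
            w = cfg.module_strength
            for row in self.truth.modules.itertuples(index=False):
                z = factors[row.module_id - 1]
                values[gene_row[row.gene_id]] *= np.exp(w * z - w * w / 2.0)
        return pd.DataFrame(values, index=genes["gene_id"], columns=samples)

    def expression(self) -> ExpressionSet:
        cfg = self.config
        mu = self._mean_matrix()
        samples = cfg.sample_ids()
        counts = np.empty(mu.shape, dtype=np.int64)
        for j, sample in enumerate(samples):
            rng = _rng(cfg.seed, _S_EXPRESSION, j)
            means = mu[sample].to_numpy()
            if cfg.nb_dispersion > 0:
                lam = rng.gamma(
                    shape=1.0 / cfg.nb_dispersion, scale=means * cfg.nb_dispersion
                )
            else:
                lam = means
            counts[:, j] = rng.poisson(lam)
        counts_df = pd.DataFrame(counts, index=mu.index, columns=samples)
        lengths = pd.Series(
            (self.genes["end"] - self.genes["start"] + 1).to_numpy(),
            index=self.genes["gene_id"],
            name="length",
        )
        sheet = pd.DataFrame(
            [
                (s, *s.split("_")[:2], int(s.split("_r")[1]))
                for s in samples
            ],
            columns=["sample_id", "genotype", "stage", "replicate"],
        )
        return ExpressionSet(counts=counts_df, gene_lengths=lengths, sample_sheet=sheet)

    # -- annotation and output ---------------------------------------------

    def annotation(self) -> pd.DataFrame:
        cfg = self.config
        rng = _rng(cfg.seed, _S_ANNOTATION)
        terms = [f"T{i:03d}" for i in range(cfg.n_terms)]
        rows = []
        for gene_id in self.genes["gene_id"]:
            for term in rng.choice(terms, size=rng.integers(1, 4), replace=False):
                rows.append((gene_id, term))
        for row in self.truth.modules.itertuples(index=False):
            rows.append((row.gene_id, f"MOD{row.module_id:02d}"))
        return pd.DataFrame(rows, columns=["gene_id", "term_id"])

    def seed_genes(self) -> list[str]:
        if len(self.truth.modules):
            first = self.truth.modules[self.truth.modules["module_id"] == 1]
            return first["gene_id"].tolist()[:5]
        if len(self.truth.anticorrelated):
            return self.truth.anticorrelated["gene_id"].tolist()[:5]
        return self.genes["gene_id"].tolist()[:5]

    def write(self, outdir: str) -> dict[str, str]:
        """Write the full dataset as plain-text files; returns name -> path."""
        os.makedirs(outdir, exist_ok=True)
        meth_dir = os.path.join(outdir, "methylomes")
        os.makedirs(meth_dir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fa"),
            "genes_gff3": os.path.join(outdir, "genes.gff3"),
            "genes_bed": os.path.join(outdir, "genes.bed"),
            "counts": os.path.join(outdir, "counts.tsv"),
            "gene_lengths": os.path.join(outdir, "gene_lengths.tsv"),
            "sample_sheet": os.path.join(outdir, "samples.tsv"),
            "annotation": os.path.join(outdir, "annotation.tsv"),
            "seed_genes": os.path.join(outdir, "seed_genes.tsv"),
            "truth_dmrs": os.path.join(outdir, "truth_dmrs.tsv"),
            "truth_null_regions": os.path.join(outdir, "truth_null_regions.tsv"),
            "truth_degs": os.path.join(outdir, "truth_degs.tsv"),
            "truth_anticorrelated": os.path.join(outdir, "truth_anticorrelated.tsv"),
            "truth_modules": os.path.join(outdir, "truth_modules.tsv"),
        }
        mio.write_fasta(self.genome, paths["genome"])
        mio.write_gff3(self.genes, paths["genes_gff3"])
        mio.write_bed6(self.genes, paths["genes_bed"])
        expr = self.expression()
        mio.write_matrix(expr.counts, paths["counts"])
        mio.write_gene_lengths(expr.gene_lengths, paths["gene_lengths"])
        mio.write_sample_sheet(expr.sample_sheet, paths["sample_sheet"])
        mio.write_annotation(self.annotation(), paths["annotation"])
        with open(paths["seed_genes"], "w") as fh:
            fh.write("\n".join(self.seed_genes()) + "\n")
        self.truth.planted_dmrs.to_csv(paths["truth_dmrs"], sep="\t", index=False)
        self.truth.null_regions.to_csv(paths["truth_null_regions"], sep="\t", index=False)
        self.truth.planted_degs.to_csv(paths["truth_degs"], sep="\t", index=False)
        self.truth.anticorrelated.to_csv(paths["truth_anticorrelated"], sep="\t", index=False)
        self.truth.modules.to_csv(paths["truth_modules"], sep="\t", index=False)
        for sample in self.config.sample_ids():
            path = os.path.join(meth_dir, f"{sample}.tsv")
            mio.write_cytosine_report(self.methylome(sample), path)
            paths[f"methylome:{sample}"] = path
        return paths


# ---------------------------------------------------------------------------
# Functional wrappers matching the stage-wise API
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Genome (chrom -> sequence) and non-overlapping gene models."""
    ds = SyntheticDataset(config)
    return ds.genome, ds.genes


def simulate_methylomes(
    config: SimulationConfig, dataset: SyntheticDataset | None = None
) -> dict[str, pd.DataFrame]:
    """Per-sample cytosine report frames."""
    ds = dataset or SyntheticDataset(config)
    return ds.methylomes()


def simulate_expression(
    config: SimulationConfig, dataset: SyntheticDataset | None = None
) -> ExpressionSet:
    """Counts, gene lengths, and sample sheet with planted effects."""
    ds = dataset or SyntheticDataset(config)
    return ds.expression()
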