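import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methexp.errors import ConfigError, ValidationError
from methexp.methylome import assign_context
from methexp.synthetic import (
    SimulationConfig,
    SyntheticDataset,
    simulate_expression,
    simulate_genome,
)


class TestConfigValidation:
    def test_dmr_effect_must_exceed_cutoff(self):
        with pytest.raises(ConfigError, match="dmr_effect"):
            SimulationConfig(dmr_effect=0.05)

    def test_bad_probability_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(bisulfite_error=1.0)
        with pytest.raises(ConfigError):
            SimulationConfig(context_base_levels={"CG": 1.2, "CHG": 0.5, "CHH": 0.1})

    def test_small_fold_change_warns(self):
        with pytest.warns(UserWarning, match="fold-change"):
            SimulationConfig(deg_fold_change=1.5)

    def test_min_site_count_enforced(self):
        with pytest.raises(ConfigError, match="dmr_n_sites"):
            SimulationConfig(dmr_n_sites=4)


class TestSimulateGenome:
    def test_determinism_byte_identical(self, tmp_path, tiny_config):
        d1 = SyntheticDataset(tiny_config)
        d2 = SyntheticDataset(tiny_config)
        assert d1.genome == d2.genome
        pd.testing.assert_frame_equal(d1.genes, d2.genes)
        p1, p2 = tmp_path / "a", tmp_path / "b"
        d1.write(str(p1))
        d2.write(str(p2))
        for name in ("genome.fa", "genes.gff3", "counts.tsv", "truth_dmrs.tsv"):
            assert (p1 / name).read_bytes() == (p2 / name).read_bytes()

    def test_no_genes_empty_table_valid_fasta(self):
        cfg = SimulationConfig(
            seed=3, n_genes=0, n_planted_degs=0, chrom_length=20_000,
            n_planted_dmrs=0, n_null_regions=0,
        )
        genome, genes = simulate_genome(cfg)
        assert len(genes) == 0
        assert all(set(seq) <= set("ACGT") for seq in genome.values())
        assert all(len(seq) == 20_000 for seq in genome.values())

    def test_genes_fit_and_are_pairwise_disjoint(self):
        cfg = SimulationConfig(
            seed=5, n_chromosomes=1, chrom_length=1_000_000, n_genes=200,
            gene_length_range=(1000, 5000), n_planted_dmrs=0, n_null_regions=0,
            n_planted_degs=0,
        )
        _, genes = simulate_genome(cfg)
        assert len(genes) == 200
        assert (genes["end"] <= 1_000_000).all() and (genes["start"] >= 1).all()
        # interval sweep: sorted by start, each gene must start after the
        # previous one ends
        for chrom, grp in genes.groupby("chrom"):
            grp = grp.sort_values("start")
            assert (grp["start"].to_numpy()[1:] > grp["end"].to_numpy()[:-1]).all()

    def test_impossible_placement_errors(self):
        with pytest.raises(ValidationError, match="non-overlapping genes"):
            SyntheticDataset(
                SimulationConfig(
                    seed=1, n_chromosomes=1, chrom_length=10_000, n_genes=20,
                    gene_length_range=(1000, 1000), n_planted_dmrs=0,
                    n_null_regions=0, n_planted_degs=0,
                )
            )


class TestSimulateMethylomes:
    def test_context_column_matches_assign_context(self, tiny_dataset):
        report = tiny_dataset.methylome("245_R5_r1")
        sample = report.sample(n=300, random_state=0)
        for row in sample.itertuples(index=False):
            assert (
                assign_context(tiny_dataset.genome, row.chrom, row.pos, row.strand)
                == row.context
            )

    def test_mean_cg_level_near_baseline(self):
        cfg = SimulationConfig(
            seed=7, n_chromosomes=1, chrom_length=400_000, n_genes=0,
            n_planted_degs=0, n_planted_dmrs=0, n_null_regions=0,
            coverage_mean=30.0, stages=("R5",), n_replicates=1,
            context_base_levels={"CG": 0.8, "CHG": 0.7, "CHH": 0.1},
        )
        ds = SyntheticDataset(cfg)
        report = ds.methylome("245_R5_r1")
        cg = report[report["context"] == "CG"]
        n = cg["m"] + cg["u"]
        level = (cg["m"] / n.where(n > 0)).dropna()
        # observed mean includes the +error*(1-level) floor: 0.8 + 0.01*0.2
        assert level.mean() == pytest.approx(0.8 + 0.01 * 0.2, abs=0.01)

    def test_zero_coverage_degenerate(self):
        cfg = SimulationConfig(
            seed=7, n_chromosomes=1, chrom_length=20_000, n_genes=0,
            n_planted_degs=0, n_planted_dmrs=0, n_null_regions=0,
            coverage_mean=0.0, stages=("R5",), n_replicates=1,
        )
        ds = SyntheticDataset(cfg)
        report = ds.methylome("245_R5_r1")
        assert (report["m"] == 0).all() and (report["u"] == 0).all()

    def test_planted_dmr_levels_shifted(self, tiny_dataset, tiny_config):
        report_a = tiny_dataset.methylome("245_R5_r1")
        report_b = tiny_dataset.methylome("Z16_R5_r1")
        effects = []
        for row in tiny_dataset.truth.planted_dmrs.itertuples(index=False):
            def pooled(report):
                sub = report[
                    (report["chrom"] == row.chrom)
                    & (report["pos"] >= row.start)
                    & (report["pos"] <= row.end)
                    & (report["context"] == row.context)
                ]
                return sub["m"].sum() / max((sub["m"] + sub["u"]).sum(), 1)

            diff = pooled(report_a) - pooled(report_b)
            signed = diff if row.direction == "hyper" else -diff
            effects.append(signed)
        # every planted region realises a difference beyond the DMR cutoff
        assert np.mean(effects) > 0.1
        assert min(effects) > 0.05

    def test_unknown_sample_rejected(self, tiny_dataset):
        with pytest.raises(ValidationError):
            tiny_dataset.methylome("nope")

    def test_undetectable_placement_errors(self):
        # CHH sites are scarce enough on a tiny chromosome that demanding
        # hundreds of runs fails loudly
        with pytest.raises(ValidationError, match="could not place|runs"):
            SyntheticDataset(
                SimulationConfig(
                    seed=1, n_chromosomes=1, chrom_length=5_000, n_genes=0,
                    n_planted_degs=0, n_planted_dmrs=500, n_null_regions=0,
                )
            )


class TestSimulateExpression:
    def test_determinism(self, tiny_config):
        e1 = simulate_expression(tiny_config)
        e2 = simulate_expression(tiny_config)
        pd.testing.assert_frame_equal(e1.counts, e2.counts)

    def test_null_gene_group_means_equal(self):
        cfg = SimulationConfig(
            seed=13, n_chromosomes=1, chrom_length=300_000, n_genes=40,
            n_planted_degs=0, n_planted_dmrs=0, n_null_regions=0,
            n_replicates=50, stages=("R5",), nb_dispersion=0.05,
        )
        expr = simulate_expression(cfg)
        sheet = expr.sample_sheet
        a = sheet.loc[sheet["genotype"] == "245", "sample_id"]
        b = sheet.loc[sheet["genotype"] == "Z16", "sample_id"]
        log_a = np.log1p(expr.counts[a])
        log_b = np.log1p(expr.counts[b])
        _, p = stats.ttest_ind(log_a, log_b, axis=1)
        # no gene should differ wildly; most p-values comfortably non-extreme
        assert (p > 1e-4).mean() > 0.95

    def test_planted_deg_fold_realised(self):
        cfg = SimulationConfig(
            seed=17, n_chromosomes=1, chrom_length=400_000, n_genes=60,
            n_planted_degs=20, deg_fold_change=4.0, n_planted_dmrs=0,
            n_null_regions=0, n_replicates=6, stages=("R5",), nb_dispersion=0.05,
        )
        expr = simulate_expression(cfg)
        ds = SyntheticDataset(cfg)
        sheet = expr.sample_sheet
        a = sheet.loc[sheet["genotype"] == "245", "sample_id"]
        b = sheet.loc[sheet["genotype"] == "Z16", "sample_id"]
        folds = []
        for row in ds.truth.planted_degs.itertuples(index=False):
            ratio = (
                expr.counts.loc[row.gene_id, a].mean()
                / max(expr.counts.loc[row.gene_id, b].mean(), 1e-9)
            )
            folds.append(ratio if row.direction == "up" else 1.0 / ratio)
        # realised fold within 25% of the planted multiplicative effect
        assert np.median(folds) == pytest.approx(4.0, rel=0.25)

    def test_module_genes_more_correlated(self):
        cfg = SimulationConfig(
            seed=19, n_chromosomes=1, chrom_length=600_000, n_genes=80,
            n_planted_degs=0, n_planted_dmrs=0, n_null_regions=0,
            n_modules=1, module_size=20, module_strength=0.6,
            n_replicates=4, stages=("R5", "R8"), nb_dispersion=0.05,
        )
        ds = SyntheticDataset(cfg)
        expr = ds.expression()
        log = np.log1p(expr.counts)
        members = ds.truth.modules["gene_id"].tolist()
        others = [g for g in log.index if g not in members][:20]
        corr = np.corrcoef(log.to_numpy())
        idx = {g: i for i, g in enumerate(log.index)}
        mi = [idx[g] for g in members]
        oi = [idx[g] for g in others]
        within = np.mean([corr[i, j] for i in mi for j in mi if i < j])
        between = np.mean([corr[i, j] for i in mi for j in oi])
        assert within > between + 0.2

    def test_sample_sheet_consistent(self, tiny_dataset, tiny_config):
        expr = tiny_dataset.expression()
        assert list(expr.counts.columns) == tiny_config.sample_ids()
        assert set(expr.sample_sheet["genotype"]) == set(tiny_config.genotypes)
        assert (expr.counts.to_numpy() >= 0).all()


class TestTruthTables:
    def test_planted_intervals_within_bounds(self, tiny_dataset):
        for table in (tiny_dataset.truth.planted_dmrs, tiny_dataset.truth.null_regions):
            for row in table.itertuples(index=False):
                assert 1 <= row.start <= row.end <= tiny_dataset.chrom_lengths[row.chrom]

    def test_roles_are_disjoint(self, tiny_dataset):
        truth = tiny_dataset.truth
        anti = set(truth.anticorrelated["gene_id"])
        degs = set(truth.planted_degs["gene_id"])
        mods = set(truth.modules["gene_id"])
        assert not (anti & degs) and not (anti & mods) and not (degs & mods)

    def test_roles_exceeding_gene_count_rejected(self):
        with pytest.raises(ConfigError, match="roles"):
            SyntheticDataset(
                SimulationConfig(
                    seed=1, n_chromosomes=1, chrom_length=200_000, n_genes=10,
                    n_planted_degs=20, n_planted_dmrs=0, n_null_regions=0,
                )
            )
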