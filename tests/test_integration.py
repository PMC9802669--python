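import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methexp.errors import ValidationError
from methexp.integration import (
    associate_dmrs,
    deg_dmr_enrichment,
    genic_intervals,
    hyper_hypo_crosstab,
    hypergeom_upper_tail,
    methylation_expression_correlation,
    term_enrichment,
    upstream_interval,
    window_expression_track,
)

from .conftest import hypergeom_tail_oracle


def dmr_frame(rows):
    """rows: (dmr_id, chrom, start0, end, context, direction)"""
    return pd.DataFrame(
        rows, columns=["dmr_id", "chrom", "start", "end", "context", "direction"]
    )


GENES = pd.DataFrame(
    {
        "gene_id": ["g1", "g2", "g3"],
        "chrom": ["c", "c", "c"],
        "start": [1000, 5000, 30],
        "end": [2000, 6000, 400],
        "strand": ["+", "-", "+"],
    }
)


class TestGeneGeometry:
    def test_plus_upstream(self):
        assert upstream_interval(5000, 6000, "+") == (3000, 4999)

    def test_minus_upstream_clipped(self):
        assert upstream_interval(5000, 6000, "-", chrom_length=7000) == (6001, 7000)

    def test_clip_to_chromosome_start(self):
        assert upstream_interval(30, 400, "+") == (1, 29)

    def test_empty_after_clipping(self):
        assert upstream_interval(1, 100, "+") is None

    def test_upstream_never_overlaps_body(self):
        regions = genic_intervals(GENES)
        for gene_id, grp in regions.groupby("gene_id"):
            body = grp[grp["part"] == "body"].iloc[0]
            for prom in grp[grp["part"] == "upstream"].itertuples(index=False):
                assert prom.end < body["start"] or prom.start > body["end"]


class TestAssociateDMRs:
    def test_body_overlap(self):
        dmrs = dmr_frame([("d1", "c", 899, 1100, "CG", "hyper")])
        assoc = associate_dmrs(dmrs, GENES)
        hit = assoc[(assoc["gene_id"] == "g1") & (assoc["dmr_id"] == "d1")]
        assert len(hit) == 1
        # [900, 1100] 1-based overlaps both g1's promoter tail and its body
        assert hit["where"].iloc[0] == "both"

    def test_clipped_upstream_and_body(self):
        dmrs = dmr_frame([("d1", "c", 0, 50, "CG", "hyper")])
        assoc = associate_dmrs(dmrs, GENES)
        hit = assoc[assoc["gene_id"] == "g3"]
        assert hit["where"].iloc[0] == "both"

    def test_distant_dmr_unassociated(self):
        dmrs = dmr_frame([("d1", "c", 20_000, 20_050, "CG", "hyper")])
        assoc = associate_dmrs(dmrs, GENES)
        assert len(assoc) == 0

    def test_chrom_mismatch_warns(self):
        dmrs = dmr_frame([("d1", "chrX", 10, 20, "CG", "hyper")])
        with pytest.warns(UserWarning, match="absent"):
            assoc = associate_dmrs(dmrs, GENES)
        assert len(assoc) == 0

    def test_one_dmr_many_genes(self):
        dmrs = dmr_frame([("d1", "c", 0, 7000, "CG", "hyper")])
        assoc = associate_dmrs(dmrs, GENES)
        assert set(assoc["gene_id"]) == {"g1", "g2", "g3"}


class TestEnrichment:
    def test_fold_closed_form(self):
        res = deg_dmr_enrichment(1000, 200, 100, 50)
        assert res.fold_enrichment == pytest.approx((50 / 100) / (200 / 1000))
        assert res.fold_enrichment == pytest.approx(2.5)

    def test_no_enrichment_fold_one(self):
        res = deg_dmr_enrichment(1000, 200, 100, 20)  # k = n*K/N exactly
        assert res.fold_enrichment == pytest.approx(1.0)

    def test_hypergeom_oracle_small(self):
        res = deg_dmr_enrichment(20, 5, 5, 4)
        assert res.p_value == pytest.approx(hypergeom_tail_oracle(4, 20, 5, 5), abs=1e-12)

    def test_oracle_agreement_random(self, global_rng):
        for _ in range(200):
            N = int(global_rng.integers(5, 61))
            K = int(global_rng.integers(1, N + 1))
            n = int(global_rng.integers(1, N + 1))
            k = int(global_rng.integers(0, min(K, n) + 1))
            assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(
                hypergeom_tail_oracle(k, N, K, n), abs=1e-12
            )

    def test_zero_margins_error(self):
        with pytest.raises(ValidationError):
            deg_dmr_enrichment(1000, 0, 100, 0)
        with pytest.raises(ValidationError):
            deg_dmr_enrichment(1000, 200, 0, 0)


class TestTermEnrichment:
    def _annotation(self, global_rng, n_genes=2000, n_terms=100, term_size=20):
        genes = [f"g{i}" for i in range(n_genes)]
        rows = []
        for t in range(n_terms):
            for g in global_rng.choice(genes, size=term_size, replace=False):
                rows.append((g, f"T{t:03d}"))
        # make sure every gene is annotated (background = all genes)
        for g in genes:
            rows.append((g, "ROOT"))
        return pd.DataFrame(rows, columns=["gene_id", "term_id"])

    def test_exact_term_ranks_first(self):
        annotation = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d", "e", "f"],
                "term_id": ["T1", "T1", "T2", "T2", "T2", "T2"],
            }
        )
        table = term_enrichment({"a", "b"}, annotation)
        assert table.iloc[0]["term_id"] == "T1"
        assert table.iloc[0]["overlap"] == 2

    def test_zero_overlap_p_one(self):
        annotation = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "term_id": ["T1", "T2", "T2"]}
        )
        table = term_enrichment({"b"}, annotation).set_index("term_id")
        assert table.loc["T1", "p_value"] == pytest.approx(1.0)

    def test_null_calibration(self, global_rng):
        annotation = self._annotation(global_rng)
        genes = sorted(set(annotation["gene_id"]) - {"ROOT"})
        fractions = []
        for _ in range(30):
            gene_set = set(global_rng.choice(genes, size=200, replace=False))
            table = term_enrichment(gene_set, annotation)
            sub = table[table["term_id"] != "ROOT"]
            fractions.append((sub["p_value"] < 0.05).mean())
        assert 0.005 <= np.mean(fractions) <= 0.08

    def test_empty_background_errors(self):
        with pytest.raises(ValidationError):
            term_enrichment({"a"}, pd.DataFrame(columns=["gene_id", "term_id"]))


class TestCrosstab:
    DEGS = pd.DataFrame(
        {
            "direction": ["up_in_a", "down_in_a", "up_in_a"],
            "is_deg": [True, True, False],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )

    def test_all_hyper_degenerate(self):
        dmrs = dmr_frame(
            [("d1", "c", 0, 10, "CG", "hyper"), ("d2", "c", 20, 30, "CG", "hyper")]
        )
        assoc = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "dmr_id": ["d1", "d2"], "where": ["body", "body"]}
        )
        tab = hyper_hypo_crosstab(dmrs, self.DEGS, assoc).set_index("deg_direction")
        assert tab.loc["up_in_a", "hyper_fraction"] == 1.0
        assert tab.loc["down_in_a", "hyper_fraction"] == 1.0

    def test_empty_class_missing_not_zero(self):
        dmrs = dmr_frame([("d1", "c", 0, 10, "CG", "hyper")])
        assoc = pd.DataFrame(
            {"gene_id": ["g1"], "dmr_id": ["d1"], "where": ["body"]}
        )
        tab = hyper_hypo_crosstab(dmrs, self.DEGS, assoc).set_index("deg_direction")
        assert np.isnan(tab.loc["down_in_a", "hyper_fraction"])

    def test_focal_swap_flips_fractions(self):
        dmrs = dmr_frame(
            [
                ("d1", "c", 0, 10, "CG", "hyper"),
                ("d2", "c", 20, 30, "CG", "hypo"),
                ("d3", "c", 40, 50, "CG", "hyper"),
            ]
        )
        assoc = pd.DataFrame(
            {
                "gene_id": ["g1", "g1", "g2"],
                "dmr_id": ["d1", "d2", "d3"],
                "where": ["body"] * 3,
            }
        )
        tab = hyper_hypo_crosstab(dmrs, self.DEGS, assoc).set_index("deg_direction")
        # swap focal sample: directions of both DMRs and DEGs flip
        swapped_dmrs = dmrs.assign(
            direction=dmrs["direction"].map({"hyper": "hypo", "hypo": "hyper"})
        )
        swapped_degs = self.DEGS.assign(
            direction=self.DEGS["direction"].map(
                {"up_in_a": "down_in_a", "down_in_a": "up_in_a"}
            )
        )
        swapped = hyper_hypo_crosstab(swapped_dmrs, swapped_degs, assoc).set_index(
            "deg_direction"
        )
        for direction, flipped in (("up_in_a", "down_in_a"), ("down_in_a", "up_in_a")):
            f = tab.loc[direction, "hyper_fraction"]
            g = swapped.loc[flipped, "hyper_fraction"]
            assert f == pytest.approx(1.0 - g)


class TestWindowCorrelation:
    def test_perfect_anticorrelation(self):
        meth = np.linspace(0.1, 0.9, 50)
        expr = -meth + 1.0
        r, p = methylation_expression_correlation(meth, expr)
        assert r == pytest.approx(-1.0)
        assert p < 1e-20

    def test_nan_windows_dropped(self):
        meth = np.array([0.1, np.nan, 0.5, 0.9, 0.3])
        expr = np.array([1.0, 2.0, np.nan, 3.0, 4.0])
        r, _ = methylation_expression_correlation(meth, expr)
        expected, _ = stats.pearsonr([0.1, 0.9, 0.3], [1.0, 3.0, 4.0])
        assert r == pytest.approx(expected)

    def test_too_few_windows_errors(self):
        with pytest.raises(ValidationError, match="joint windows"):
            methylation_expression_correlation([0.1, 0.2], [1.0, 2.0])

    def test_null_tracks_small_r(self, global_rng):
        hits = 0
        for _ in range(20):
            x = global_rng.normal(size=2000)
            y = global_rng.normal(size=2000)
            r, _ = methylation_expression_correlation(x, y)
            hits += abs(r) < 0.08
        assert hits >= 19

    def test_window_expression_track_midpoint_anchoring(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "chrom": ["c", "c"],
                "start": [100, 900],
                "end": [300, 1100],  # midpoints 200 and 1000
                "strand": ["+", "+"],
            }
        )
        fpkm = pd.Series([10.0, 100.0], index=["g1", "g2"])
        track = window_expression_track(
            fpkm, genes, {"c": 1200}, window_size=500, window_step=500
        )
        assert track.loc[0, "n_genes"] == 1
        assert track.loc[0, "mean_log_fpkm"] == pytest.approx(np.log10(10.01))
        assert track.loc[1, "n_genes"] == 1
        assert np.isnan(track.loc[2, "mean_log_fpkm"]) if len(track) > 2 else True
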