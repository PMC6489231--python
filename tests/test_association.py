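import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metdep.association import (
    AssociationError,
    bh_fdr,
    compare_pvalue_distributions,
    lineage_robustness,
    lineage_robustness_table,
    media_association,
    media_partial_association,
    partial_spearman,
    rank_sum_test,
    related_expression_correlations,
    shuffled_set_null,
    sign_fraction_test,
    spearman,
)
from metdep.neighbors import RelatednessMap

from helpers import make_dataset


class TestBhFdr:
    def test_stepup_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.42]), [0.42])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0] * 3)

    def test_rejects_out_of_range(self):
        with pytest.raises(AssociationError):
            bh_fdr([0.5, 1.5])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(200)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_order_invariance_and_dominates_raw(self, rng):
        p = rng.random(50)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-15).all()
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_fdr(p[perm]), adj[perm], atol=1e-15)

    def test_nan_passthrough(self):
        adj = bh_fdr([0.01, np.nan, 0.02])
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], bh_fdr([0.01, 0.02]))


class TestRankSum:
    def test_exact_extreme_arrangement(self):
        # all C(6,3)=20 arrangements equally likely; the observed split is one
        # of the two most extreme -> two-sided p = 2/20
        stat, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_too_small_group_flagged(self):
        stat, p = rank_sum_test([1, 2], [3, 4, 5])
        assert np.isnan(p)

    def test_null_uniformity(self, rng):
        pvals = []
        for _ in range(500):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            pvals.append(rank_sum_test(a, b)[1])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_compare_pvalue_distributions_delegates(self, rng):
        a, b = rng.random(30), rng.random(40)
        assert compare_pvalue_distributions(a, b) == rank_sum_test(a, b)


class TestSpearman:
    def test_monotone_is_one(self):
        r, p = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r == pytest.approx(1.0)

    def test_hand_rank_example(self):
        # ranks of y = (1,3,2,5,4): sum of squared rank differences = 4,
        # r = 1 - 6*4 / (5*(25-1)) = 0.8
        r, _ = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert r == pytest.approx(0.8)

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=100), rng.normal(size=100)
        r, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_independent_small_r(self, rng):
        hits = 0
        for _ in range(100):
            x, y = rng.normal(size=1000), rng.normal(size=1000)
            r, _ = spearman(x, y)
            hits += abs(r) < 0.1
        assert hits >= 99

    def test_min_pairs_flagged(self):
        r, p = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert np.isnan(r) and np.isnan(p)


def residual_rank_oracle(x, y, z):
    """Partial Spearman via OLS residuals of ranks (independent route)."""
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
    design = np.column_stack([np.ones(len(rz)), rz])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    return float(np.corrcoef(res_x, res_y)[0, 1])


class TestPartialSpearman:
    def test_residual_oracle_fixture(self, rng):
        for _ in range(10):
            x = rng.normal(size=20)
            y = rng.normal(size=20) + 0.5 * x
            z = rng.normal(size=20) + 0.3 * x
            r, _ = partial_spearman(x, y, z)
            assert r == pytest.approx(residual_rank_oracle(x, y, z), abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pingouin as pg
        x, y, z = rng.normal(size=40), rng.normal(size=40), rng.normal(size=40)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pg.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        r, p = partial_spearman(x, y, z)
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_degenerate_covariate_flagged(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r, p = partial_spearman(x, y, x)  # z identical to x
        assert np.isnan(r) and np.isnan(p)

    def test_reduces_to_spearman_with_independent_covariate(self, rng):
        x = rng.normal(size=500)
        y = 0.5 * x + rng.normal(size=500)
        z = rng.normal(size=500)
        r_partial, _ = partial_spearman(x, y, z)
        r_plain, _ = spearman(x, y)
        assert abs(r_partial - r_plain) < 0.05

    def test_binary_covariate_supported(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        z = (rng.random(60) < 0.5).astype(float)
        r, p = partial_spearman(x, y, z)
        assert np.isfinite(r) and 0 <= p <= 1


class TestSignFractionTest:
    @staticmethod
    def results(directions, fdr=0.01):
        return pd.DataFrame({
            "gene": [f"g{i}" for i in range(len(directions))],
            "test": "expr_self", "partner": "",
            "statistic": directions, "direction": directions,
            "p": 0.001, "fdr_p": fdr,
        })

    def test_zero_of_ten(self):
        frac, p = sign_fraction_test(self.results([1] * 10))
        assert frac == 0.0
        assert p == pytest.approx(2 / 1024)

    def test_five_of_ten(self):
        frac, p = sign_fraction_test(self.results([-1] * 5 + [1] * 5))
        assert frac == 0.5 and p == pytest.approx(1.0)

    def test_two_of_ten(self):
        frac, p = sign_fraction_test(self.results([-1] * 2 + [1] * 8))
        assert p == pytest.approx(0.109375)

    def test_no_significant_flagged(self):
        frac, p = sign_fraction_test(self.results([1] * 10, fdr=0.9))
        assert np.isnan(frac) and np.isnan(p)


def plant_media_shift(ds, gene, shift_sd=2.0, medium="DMEM"):
    mask = (ds.annotations["medium"] == medium).to_numpy()
    row = ds.dependency.loc[gene].to_numpy().copy()
    row[mask] -= shift_sd * row.std()
    ds.dependency.loc[gene] = row
    return ds


class TestMediaAssociation:
    def test_planted_shift_detected_with_direction(self):
        ds = make_dataset(n_lines=100, seed=5)
        plant_media_shift(ds, "G0003", shift_sd=2.0, medium="DMEM")
        res = media_association(ds, sorted(ds.metabolic_genes), "DMEM", "RPMI")
        row = res[res["gene"] == "G0003"].iloc[0]
        assert row["fdr_p"] < 0.05
        assert row["direction"] == 1  # more essential (lower median) in DMEM

    def test_null_gene_large_fdr(self):
        ds = make_dataset(n_lines=100, seed=6)
        res = media_association(ds, sorted(ds.metabolic_genes), "DMEM", "RPMI")
        assert res["fdr_p"].min() > 0.05  # no planted effect

    def test_unknown_medium_raises(self):
        ds = make_dataset()
        with pytest.raises(AssociationError, match="unknown medium"):
            media_association(ds, ["G0000"], "DMEM", "EMEM")

    def test_permuted_labels_control_type_one_error(self, rng):
        fractions = []
        for seed in range(15):
            ds = make_dataset(n_lines=80, n_genes=40, seed=100 + seed)
            perm = rng.permutation(len(ds.annotations))
            ds.annotations["medium"] = ds.annotations["medium"].to_numpy()[perm]
            res = media_association(ds, sorted(ds.metabolic_genes), "DMEM", "RPMI")
            fractions.append((res["fdr_p"] < 0.05).mean())
        assert np.mean(fractions) <= 0.05

    def test_fdr_families_split(self):
        ds = make_dataset(n_lines=60, n_genes=10, n_other=10, seed=3)
        res = media_association(ds, list(ds.dependency.index), "DMEM", "RPMI")
        met = res["gene"].isin(ds.metabolic_genes)
        np.testing.assert_allclose(
            res.loc[met, "fdr_p"], bh_fdr(res.loc[met, "p"]), atol=1e-12
        )
        np.testing.assert_allclose(
            res.loc[~met, "fdr_p"], bh_fdr(res.loc[~met, "p"]), atol=1e-12
        )


class TestMediaPartialAndLineage:
    def test_partial_culture_keeps_true_media_effect(self):
        ds = make_dataset(n_lines=120, seed=7)
        plant_media_shift(ds, "G0001", shift_sd=2.5)
        res = media_partial_association(ds, sorted(ds.metabolic_genes), "DMEM", "RPMI")
        assert res[res["gene"] == "G0001"]["fdr_p"].iloc[0] < 0.05

    def test_lineage_robust_when_orthogonal(self):
        ds = make_dataset(n_lines=120, seed=8)
        plant_media_shift(ds, "G0002", shift_sd=2.5)
        assert lineage_robustness(ds, "G0002", "DMEM", "RPMI")

    def test_confounded_gene_not_robust(self, rng):
        # lineage0 drives both the medium assignment and the score shift
        ds = make_dataset(n_lines=120, n_lineages=2, seed=9)
        lin0 = (ds.annotations["lineage"] == "lineage0").to_numpy()
        medium = np.where(lin0 ^ (rng.random(120) < 0.08), "DMEM", "RPMI")
        ds.annotations["medium"] = medium
        row = ds.dependency.loc["G0004"].to_numpy().copy()
        row[lin0] -= 2.5
        ds.dependency.loc["G0004"] = row
        assert not lineage_robustness(ds, "G0004", "DMEM", "RPMI")

    def test_single_lineage_vacuous_fallback(self):
        ds = make_dataset(n_lines=60, n_lineages=1, seed=10)
        plant_media_shift(ds, "G0005", shift_sd=2.5)
        # constant indicator -> fallback to unadjusted correlation (still significant)
        table, verdict = lineage_robustness_table(
            ds, sorted(ds.metabolic_genes), "DMEM", "RPMI", min_lineage=10
        )
        assert verdict.loc["G0005"]


def single_partner_map(gene, partner, mode="neighbor"):
    relmap = RelatednessMap()
    if mode == "neighbor":
        relmap.neighbors[gene] = [partner]
    else:
        relmap.isozymes[gene] = {partner}
    return relmap


class TestRelatedExpressionCorrelations:
    def test_planted_neighbor_coupling_explained_negative(self):
        ds = make_dataset(n_lines=80, seed=11)
        expr = ds.expression.loc["G0009"].to_numpy()
        z = (expr - expr.mean()) / expr.std()
        ds.dependency.loc["G0001"] = -2.0 * z + 0.5 * np.random.default_rng(0).normal(size=80)
        relmap = single_partner_map("G0001", "G0009")
        table, explained = related_expression_correlations(
            ds, relmap, "neighbor", genes=sorted(ds.metabolic_genes)
        )
        row = table[(table["gene"] == "G0001") & (table["partner"] == "G0009")].iloc[0]
        assert row["fdr_p"] < 0.05 and row["direction"] == -1
        assert explained.loc["G0001"]

    def test_empty_relatedness_map(self):
        ds = make_dataset(seed=12)
        table, explained = related_expression_correlations(
            ds, RelatednessMap(), "neighbor", genes=sorted(ds.metabolic_genes)
        )
        assert len(table) == 0
        assert not explained.any()

    def test_constant_partner_expression_skipped(self):
        ds = make_dataset(n_lines=40, seed=13)
        ds.expression.loc["G0009"] = 3.14
        relmap = single_partner_map("G0001", "G0009")
        table, _ = related_expression_correlations(ds, relmap, "neighbor", genes=["G0001"])
        assert np.isnan(table.iloc[0]["p"])  # degenerate pair flagged, not significant

    def test_missing_partner_skipped(self):
        ds = make_dataset(seed=14)
        relmap = single_partner_map("G0001", "NOT_MEASURED")
        table, _ = related_expression_correlations(ds, relmap, "neighbor", genes=["G0001"])
        assert len(table) == 0

    def test_self_mode_one_row_per_gene(self):
        ds = make_dataset(n_genes=8, seed=15)
        table, _ = related_expression_correlations(
            ds, RelatednessMap(), "self", genes=sorted(ds.metabolic_genes)
        )
        assert list(table["gene"]) == sorted(ds.metabolic_genes)
        assert (table["partner"] == table["gene"]).all()

    def test_fast_engine_matches_generic(self, rng):
        from metdep.association import _PairCorrEngine
        ds = make_dataset(n_lines=50, seed=16)
        engine = _PairCorrEngine(ds.dependency, ds.expression)
        assert engine.fast
        for gene, partner in [("G0000", "G0001"), ("G0002", "NG0000")]:
            r_fast, p_fast = engine.corr(gene, partner)
            r_ref, p_ref = spearman(ds.dependency.loc[gene], ds.expression.loc[partner])
            assert r_fast == pytest.approx(r_ref, abs=1e-12)
            assert p_fast == pytest.approx(p_ref, rel=1e-9)


class TestShuffledSetNull:
    def test_formula_boundary_cases(self):
        ds = make_dataset(n_lines=60, seed=17)
        relmap = single_partner_map("G0001", "G0002")
        out = shuffled_set_null(ds, relmap, "neighbor", repetitions=1, seed=0,
                                genes=sorted(ds.metabolic_genes))
        assert out.empirical_p in (0.5, 1.0)  # 1 rep: (1+hits)/2
        assert len(out.null_fractions) == 1

    def test_reproducible_given_seed(self):
        ds = make_dataset(n_lines=60, seed=18)
        relmap = single_partner_map("G0003", "G0004")
        a = shuffled_set_null(ds, relmap, "neighbor", repetitions=20, seed=42,
                              genes=sorted(ds.metabolic_genes))
        b = shuffled_set_null(ds, relmap, "neighbor", repetitions=20, seed=42,
                              genes=sorted(ds.metabolic_genes))
        assert a.null_fractions == b.null_fractions
        assert a.empirical_p == b.empirical_p

    def test_null_data_not_significant_in_most_seeds(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            ds = make_dataset(n_lines=50, n_genes=15, seed=200 + seed)
            relmap = RelatednessMap(
                neighbors={g: [f"G{(int(g[1:]) + 1) % 15:04d}"] for g in ds.metabolic_genes}
            )
            out = shuffled_set_null(ds, relmap, "neighbor", repetitions=99, seed=seed,
                                    genes=sorted(ds.metabolic_genes))
            hits += out.empirical_p < 0.05
        assert hits <= 1  # >= 90% of seeds non-significant


class TestTypeOneError:
    def test_null_fdr_discovery_rate(self):
        discoveries, total = 0, 0
        for seed in range(25):
            ds = make_dataset(n_lines=60, n_genes=30, n_other=5, seed=300 + seed)
            res = media_association(ds, sorted(ds.metabolic_genes), "DMEM", "RPMI")
            discoveries += int((res["fdr_p"] < 0.05).sum())
            total += len(res)
        rate = discoveries / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 2 * se

    def test_power_planted_two_sd_shift(self):
        detected = 0
        for seed in range(20):
            ds = make_dataset(n_lines=100, n_genes=25, seed=400 + seed)
            plant_media_shift(ds, "G0000", shift_sd=2.0)
            res = media_association(ds, sorted(ds.metabolic_genes), "DMEM", "RPMI")
            detected += res[res["gene"] == "G0000"]["fdr_p"].iloc[0] < 0.05
        assert detected >= 19  # >= 95%
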