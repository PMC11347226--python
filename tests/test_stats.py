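"""Size factors, dispersion, Wald tests, NTC binning and gene calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from screentriage.quant import LibraryDesign
from screentriage.stats import aggregate_genes, bin_ntcs, estimate_dispersion, estimate_size_factors
from screentriage.stats import test_constructs as wald_constructs

from conftest import nb_counts


def brute_force_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Independent median-of-ratios evaluation, row by row."""
    rows = [r for _, r in counts.iterrows() if (r > 0).all()]
    ratios = {s: [] for s in counts.columns}
    for r in rows:
        gm = float(np.prod(r.to_numpy(dtype=float))) ** (1 / len(r))
        for s in counts.columns:
            ratios[s].append(r[s] / gm)
    sf = pd.Series({s: float(np.median(v)) for s, v in ratios.items()})
    return sf / float(np.prod(sf)) ** (1 / len(sf))


class TestSizeFactors:
    def test_identical_samples_give_unity(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf = estimate_size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 1000, 50)
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        sf = estimate_size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            nb_counts(rng, 500.0, 0.1, (100, 4)), columns=list("abcd")
        )
        sf = estimate_size_factors(counts)
        expected = brute_force_size_factors(counts)
        assert np.allclose(sf.to_numpy(), expected.to_numpy(), rtol=1e-8)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(nb_counts(rng, 800.0, 0.05, (60, 5)))
        sf = estimate_size_factors(counts)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)

    def test_no_all_positive_row_falls_back_with_warning(self):
        counts = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
        with pytest.warns(RuntimeWarning, match="fall back"):
            sf = estimate_size_factors(counts)
        assert np.isfinite(sf).all() and (sf > 0).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            estimate_size_factors(pd.DataFrame({"a": [1, 2]}))


class TestDispersion:
    def test_constant_counts_hit_floor(self):
        counts = pd.DataFrame(np.full((10, 6), 100))
        groups = pd.Series(["t"] * 3 + ["v"] * 3, index=counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersion(counts, sf, groups)
        assert np.allclose(disp, 1e-8)

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.poisson(2000.0, (500, 40)))
        groups = pd.Series(["t"] * 20 + ["v"] * 20, index=counts.columns)
        sf = estimate_size_factors(counts)
        disp = estimate_dispersion(counts, sf, groups)
        assert disp.mean() < 5e-4  # true alpha = 0

    def test_recovers_planted_alpha_at_high_replication(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(nb_counts(rng, 1000.0, 0.1, (300, 100)))
        groups = pd.Series(["t"] * 50 + ["v"] * 50, index=counts.columns)
        sf = estimate_size_factors(counts)
        disp = estimate_dispersion(counts, sf, groups)
        inside = ((disp >= 0.05) & (disp <= 0.2)).mean()
        assert inside >= 0.9

    def test_single_replicate_group_uses_trend(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(nb_counts(rng, 1000.0, 0.05, (50, 4)))
        groups = pd.Series(["t", "v", "v", "v"], index=counts.columns)
        sf = estimate_size_factors(counts)
        disp = estimate_dispersion(counts, sf, groups)
        assert np.isfinite(disp).all() and (disp > 0).all()


class TestWaldTest:
    def test_equal_means_give_null_result(self):
        counts = pd.DataFrame(np.tile([[1000]], (5, 6)), columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(["treated"] * 3 + ["vehicle"] * 3, index=counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.05, index=counts.index)
        res = wald_constructs(counts, sf, disp, groups)
        assert np.allclose(res["log2FC"], 0.0)
        assert (res["p"] > 0.99).all()

    def test_zero_in_both_groups_flagged_untestable(self):
        counts = pd.DataFrame(np.zeros((3, 6), dtype=int), columns=[f"s{i}" for i in range(6)])
        counts.iloc[0] = 500
        groups = pd.Series(["treated"] * 3 + ["vehicle"] * 3, index=counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.05, index=counts.index)
        res = wald_constructs(counts, sf, disp, groups)
        assert not res["untestable"].iloc[0]
        assert res["untestable"].iloc[1:].all()
        assert (res.loc[res["untestable"], "p"] == 1.0).all()
        assert (res.loc[res["untestable"], "log2FC"] == 0.0).all()

    def test_planted_depletion_coverage(self):
        # 4-fold depletion: estimate within +/-2 SE of -2 in >=95% of constructs
        rng = np.random.default_rng(8)
        n = 400
        mu = np.tile([2500.0] * 3 + [10000.0] * 3, (n, 1))
        counts = pd.DataFrame(nb_counts(rng, mu, 0.05, (n, 6)), columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(["treated"] * 3 + ["vehicle"] * 3, index=counts.columns)
        # a uniform 4-fold shift is indistinguishable from a depth change,
        # so unit size factors are the correct normalization here
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersion(counts, sf, groups)
        res = wald_constructs(counts, sf, disp, groups)
        covered = np.abs(res["log2FC"] + 2.0) <= 2 * res["SE"]
        assert covered.mean() >= 0.95

    def test_type_one_error_calibrated(self, null_count_matrix):
        counts, groups = null_count_matrix
        sf = estimate_size_factors(counts)
        disp = estimate_dispersion(counts, sf, groups)
        res = wald_constructs(counts, sf, disp, groups)
        rate = (res["p"] < 0.05).mean()
        mc_se = np.sqrt(0.05 * 0.95 / len(res))
        assert abs(rate - 0.05) <= 3 * mc_se + 0.02  # single small screen; tight check in acceptance

    def test_bh_adjustment_is_monotone(self, null_count_matrix):
        counts, groups = null_count_matrix
        sf = estimate_size_factors(counts)
        disp = estimate_dispersion(counts, sf, groups)
        res = wald_constructs(counts, sf, disp, groups).sort_values("p")
        assert (res["padj"].to_numpy()[1:] >= res["padj"].to_numpy()[:-1] - 1e-12).all()
        assert (res["padj"] >= res["p"] - 1e-12).all()

    def test_wald_tracks_exact_permutation(self):
        """Exact 6v6 permutation p and Wald p agree in calibration and
        ordering (pointwise they differ by the permutation's conditioning
        on each construct's empirical spread)."""
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(
            nb_counts(rng, 1000.0, 0.05, (150, 12)), columns=[f"s{i}" for i in range(12)]
        )
        groups = pd.Series(["treated"] * 6 + ["vehicle"] * 6, index=counts.columns)
        sf = estimate_size_factors(counts)
        disp = estimate_dispersion(counts, sf, groups)
        res = wald_constructs(counts, sf, disp, groups)
        norm = (counts / sf).to_numpy()
        alpha = disp.to_numpy()
        idx = np.arange(12)

        def zstat(cols):
            cols = np.asarray(cols)
            rest = np.setdiff1d(idx, cols)
            mt, mc = norm[:, cols].mean(1), norm[:, rest].mean(1)
            lfc = np.log2((mt + 0.5) / (mc + 0.5))
            se = np.sqrt(
                (1 / 6) * (1 / np.maximum(mt, 0.5) + alpha)
                + (1 / 6) * (1 / np.maximum(mc, 0.5) + alpha)
            ) / np.log(2)
            return np.abs(lfc / se)

        obs = zstat(np.arange(6))
        hits = np.zeros(len(counts))
        n_splits = 0
        for cols in itertools.combinations(range(12), 6):
            hits += zstat(cols) >= obs - 1e-12
            n_splits += 1
        p_perm = hits / n_splits
        p_wald = res["p"].to_numpy()
        assert ((p_perm < 0.05) == (p_wald < 0.05)).mean() >= 0.9
        assert pd.Series(p_perm).corr(pd.Series(p_wald), method="spearman") > 0.9
        assert abs((p_perm - p_wald).mean()) < 0.02


class TestNtcBinning:
    def test_sizes_5544(self):
        ids = [f"NTC_sh{i}" for i in range(1, 19)]
        binning = bin_ntcs(ids, seed=0)
        assert sorted(binning.group_sizes.values()) == [4, 4, 5, 5]
        assert set(binning.group_sizes) == {"NTC1", "NTC2", "NTC3", "NTC4"}

    def test_deterministic_and_partition(self):
        ids = [f"NTC_sh{i}" for i in range(1, 19)]
        a = bin_ntcs(ids, seed=7)
        b = bin_ntcs(ids, seed=7)
        pd.testing.assert_series_equal(a.assignment, b.assignment)
        assert set(a.assignment.index) == set(ids)

    def test_wrong_count_without_sizes_rejected(self):
        with pytest.raises(ValueError):
            bin_ntcs([f"n{i}" for i in range(10)], seed=0)

    def test_explicit_sizes(self):
        binning = bin_ntcs([f"n{i}" for i in range(10)], seed=0, sizes=(5, 5))
        assert sorted(binning.group_sizes.values()) == [5, 5]


def _design_for(stats_index, gene_map):
    rng = np.random.default_rng(0)
    table = pd.DataFrame(
        {
            "construct_id": stats_index,
            "gene": [gene_map[c] for c in stats_index],
            "guide_seq": ["".join(rng.choice(list("ACGT"), 22)) for _ in stats_index],
        }
    )
    return LibraryDesign(table)


class TestAggregateGenes:
    def make_stats(self, lfcs, ps=None):
        ids = [f"g_sh{i}" for i in range(len(lfcs))]
        return pd.DataFrame(
            {
                "log2FC": lfcs,
                "SE": 0.1,
                "p": ps if ps is not None else [1.0] * len(lfcs),
                "untestable": False,
            },
            index=ids,
        )

    def test_identical_constructs(self):
        stats = self.make_stats([-1.5] * 5)
        design = _design_for(stats.index, dict.fromkeys(stats.index, "g"))
        out = aggregate_genes(stats, design)
        assert out.loc["g", "median_log2FC"] == pytest.approx(-1.5)
        assert out.loc["g", "sem"] == pytest.approx(0.0)

    def test_symmetric_lfcs_not_essential(self):
        stats = self.make_stats([-2, -1, 0, 1, 2])
        design = _design_for(stats.index, dict.fromkeys(stats.index, "g"))
        out = aggregate_genes(stats, design)
        assert out.loc["g", "median_log2FC"] == pytest.approx(0.0)
        assert not out.loc["g", "essential"]

    def test_even_group_uses_mean_of_central_pair(self):
        stats = self.make_stats([-2.0, -1.0, 0.0, 3.0])
        design = _design_for(stats.index, dict.fromkeys(stats.index, "g"))
        out = aggregate_genes(stats, design)
        assert out.loc["g", "median_log2FC"] == pytest.approx(-0.5)

    def test_essential_requires_median_and_corroboration(self):
        stats = self.make_stats([-1.3, -1.4, -1.2, 0.1, 0.2], ps=[0.01, 0.02, 0.03, 0.5, 0.5])
        design = _design_for(stats.index, dict.fromkeys(stats.index, "g"))
        out = aggregate_genes(stats, design)
        assert out.loc["g", "n_sig_constructs"] == 3
        assert out.loc["g", "essential"]
        # same medians but no individually significant constructs: not essential
        stats2 = self.make_stats([-1.3, -1.4, -1.2, 0.1, 0.2], ps=[0.5] * 5)
        out2 = aggregate_genes(stats2, design)
        assert not out2.loc["g", "essential"]

    def test_order_invariance_and_sign_equivariance(self):
        rng = np.random.default_rng(1)
        lfcs = rng.normal(size=10)
        ids = [f"h_sh{i}" for i in range(10)]
        stats = pd.DataFrame({"log2FC": lfcs, "SE": 0.1, "p": 0.5, "untestable": False}, index=ids)
        design = _design_for(ids, dict.fromkeys(ids, "h"))
        out = aggregate_genes(stats, design)
        shuffled = stats.iloc[rng.permutation(10)]
        out_shuffled = aggregate_genes(shuffled, design)
        assert out.loc["h", "median_log2FC"] == pytest.approx(out_shuffled.loc["h", "median_log2FC"])
        flipped = stats.assign(log2FC=-stats["log2FC"])
        out_flipped = aggregate_genes(flipped, design)
        assert out_flipped.loc["h", "median_log2FC"] == pytest.approx(-out.loc["h", "median_log2FC"])

    def test_untestable_gene_excluded_with_warning(self):
        ids = ["a_sh1", "b_sh1"]
        stats = pd.DataFrame(
            {"log2FC": [0.5, 0.0], "SE": 0.1, "p": [0.5, 1.0], "untestable": [False, True]},
            index=ids,
        )
        design = _design_for(ids, {"a_sh1": "a", "b_sh1": "b"})
        with pytest.warns(RuntimeWarning, match="no testable"):
            out = aggregate_genes(stats, design)
        assert "b" not in out.index
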