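import numpy as np
import pandas as pd
import pytest

from refstab import (
    CtTable,
    ValidationError,
    bestkeeper,
    bk_correlation,
    bk_descriptives,
    bk_index,
    bk_rank,
)
from refstab.examples import lentinula_bestkeeper_summary


class TestDescriptives:
    def test_constant_gene(self):
        frame = pd.DataFrame(
            {"s1": [20.0, 19.0], "s2": [20.0, 21.0], "s3": [20.0, 20.0]},
            index=["const", "vary"],
        )
        stats = bk_descriptives(frame)
        row = stats.loc["const"]
        assert row["sd"] == 0.0
        assert row["cv"] == 0.0
        assert row["geo_mean"] == pytest.approx(20.0)
        assert row["ar_mean"] == pytest.approx(20.0)
        assert not row["sd_flag"]

    def test_hand_computed_two_samples(self):
        frame = pd.DataFrame({"s1": [19.0, 20.0], "s2": [21.0, 20.0]},
                             index=["g", "h"])
        stats = bk_descriptives(frame)
        row = stats.loc["g"]
        assert row["ar_mean"] == pytest.approx(20.0)
        assert row["geo_mean"] == pytest.approx(np.sqrt(399.0))
        assert row["sd"] == pytest.approx(np.sqrt(2.0))  # sample SD of (19, 21)
        assert row["sd_flag"]  # SD 1.414 > 1 cycle

    def test_sd_just_above_one_cycle_is_flagged(self):
        # a gene whose Ct SD is 1.27 must carry the instability flag
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, size=30)
        values = 24.0 + base / base.std(ddof=1) * 1.27
        frame = pd.DataFrame(
            {f"s{i}": [values[i], 20.0 + 0.01 * i] for i in range(30)},
            index=["wobbly", "steady"],
        )
        stats = bk_descriptives(frame)
        assert stats.at["wobbly", "sd"] == pytest.approx(1.27)
        assert bool(stats.at["wobbly", "sd_flag"])
        assert not stats.at["steady", "sd_flag"]

    def test_mad_geomean_convention(self):
        frame = pd.DataFrame({"s1": [19.0, 20.0], "s2": [21.0, 20.0]},
                             index=["g", "h"])
        stats = bk_descriptives(frame, sd_convention="mad_geomean")
        geo = np.sqrt(399.0)
        expected = (abs(19 - geo) + abs(21 - geo)) / 2
        assert stats.at["g", "sd"] == pytest.approx(expected)

    def test_ordering_invariant(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame(rng.uniform(15, 30, (3, 10)), index=list("abc"),
                             columns=[f"s{i}" for i in range(10)])
        stats = bk_descriptives(frame)
        assert (stats["min"] <= stats["geo_mean"]).all()
        assert (stats["geo_mean"] <= stats["ar_mean"]).all()
        assert (stats["ar_mean"] <= stats["max"]).all()


class TestIndex:
    def test_identical_genes_reproduce_vector(self):
        row = [20.0, 22.0, 24.0]
        frame = pd.DataFrame([row, row, row], index=list("abc"),
                             columns=["s1", "s2", "s3"])
        assert np.allclose(bk_index(frame).to_numpy(), row)

    def test_geometric_mean_of_two(self):
        frame = pd.DataFrame({"s1": [20.0, 5.0], "s2": [20.0, 20.0]},
                             index=["a", "b"])
        assert bk_index(frame)["s1"] == pytest.approx(10.0)

    def test_gene_permutation_invariant(self):
        rng = np.random.default_rng(8)
        frame = pd.DataFrame(rng.uniform(15, 30, (4, 6)), index=list("abcd"),
                             columns=[f"s{i}" for i in range(6)])
        assert np.allclose(
            bk_index(frame).to_numpy(),
            bk_index(frame.loc[list("dcba")]).to_numpy(),
        )


class TestCorrelation:
    def test_gene_equal_to_index(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(18, 28, size=10)
        frame = pd.DataFrame([values, values], index=["a", "b"],
                             columns=[f"s{i}" for i in range(10)])
        corr = bk_correlation(frame)
        assert corr.at["a", "r"] == pytest.approx(1.0)
        assert corr.at["a", "p_value"] < 1e-12

    def test_anticorrelated_gene(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(18, 22, size=8)
        frame = pd.DataFrame([values, 44.0 - values], index=["a", "b"],
                             columns=[f"s{i}" for i in range(8)])
        idx = pd.Series(values, index=frame.columns)
        corr = bk_correlation(frame, idx)
        assert corr.at["b", "r"] == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        frame = pd.DataFrame(
            {"s1": [20.0, 25.0], "s2": [21.5, 24.0], "s3": [19.0, 26.5],
             "s4": [22.0, 23.5], "s5": [20.5, 25.5]},
            index=["a", "b"],
        )
        idx = bk_index(frame)
        corr = bk_correlation(frame, idx)
        for g in frame.index:
            y = frame.loc[g].to_numpy()
            x = idx.to_numpy()
            r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            assert corr.at[g, "r"] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_gene_reported_missing_and_demoted(self):
        frame = pd.DataFrame(
            {"s1": [20.0, 21.0, 25.0], "s2": [20.0, 23.0, 24.0],
             "s3": [20.0, 22.0, 26.0]},
            index=["flat", "a", "b"],
        )
        result = bestkeeper(frame)
        assert np.isnan(result.correlations.at["flat", "r"])
        assert result.ranking["flat"] == 3  # bottom of tier 2


class TestRanking:
    @pytest.mark.parametrize("block", ["substrates", "development", "stresses", "total"])
    def test_reproduces_published_rankings(self, block):
        frame = lentinula_bestkeeper_summary(block)[block]
        ranks = bk_rank(frame["sd"], frame["r"], r_threshold=0.9)
        for gene in frame.index:
            assert ranks[gene] == frame.at[gene, "published_rank"], gene

    def test_all_above_threshold_is_sd_order(self):
        sd = {"a": 0.3, "b": 0.1, "c": 0.2}
        r = {"a": 0.95, "b": 0.99, "c": 0.91}
        assert bk_rank(sd, r) == {"b": 1, "c": 2, "a": 3}

    def test_low_r_demoted_despite_small_sd(self):
        sd = {"a": 0.05, "b": 0.5, "c": 0.6}
        r = {"a": 0.2, "b": 0.95, "c": 0.93}
        ranks = bk_rank(sd, r)
        assert ranks == {"b": 1, "c": 2, "a": 3}

    def test_shifting_one_gene_keeps_rank_with_fixed_index(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame(rng.uniform(18, 26, (4, 8)), index=list("abcd"),
                             columns=[f"s{i}" for i in range(8)])
        idx = bk_index(frame)
        shifted = frame.copy()
        shifted.loc["b"] += 3.0
        s1 = bk_descriptives(frame)["sd"]
        s2 = bk_descriptives(shifted)["sd"]
        r1 = bk_correlation(frame, idx)["r"]
        r2 = bk_correlation(shifted, idx)["r"]
        assert s1["b"] == pytest.approx(s2["b"], abs=1e-12)
        assert r1["b"] == pytest.approx(r2["b"], abs=1e-12)
        assert bk_rank(s1, r1) == bk_rank(s2, r2)

    def test_mismatched_gene_sets_rejected(self):
        with pytest.raises(ValidationError):
            bk_rank({"a": 0.1}, {"b": 0.9})
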