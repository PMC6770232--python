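import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab import (
    QuantityTable,
    ValidationError,
    genorm,
    genorm_m,
    genorm_rank,
    pairwise_v_series,
    pairwise_variation,
)


def brute_force_m(frame: pd.DataFrame) -> pd.Series:
    """Direct evaluation of the definition: mean over partners of the
    SD across samples of the pairwise log2 ratio."""
    out = {}
    for j in frame.index:
        vs = []
        for k in frame.index:
            if k == j:
                continue
            ratios = [
                np.log2(frame.at[j, s] / frame.at[k, s]) for s in frame.columns
            ]
            vs.append(np.std(ratios, ddof=1))
        out[j] = np.mean(vs)
    return pd.Series(out)


class TestPairwiseVariation:
    def test_constant_ratio_is_zero(self):
        assert pairwise_variation([1, 2, 4, 8], [2, 4, 8, 16]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # log2 ratios (0, -1): sample SD = 1/sqrt(2)
        assert pairwise_variation([1, 2], [1, 4]) == pytest.approx(0.70710678, abs=1e-8)

    def test_symmetry(self, random_quantities):
        a = random_quantities.q.iloc[0].to_numpy()
        b = random_quantities.q.iloc[1].to_numpy()
        assert pairwise_variation(a, b) == pairwise_variation(b, a)

    def test_rejects_short_or_nonpositive(self):
        with pytest.raises(ValidationError):
            pairwise_variation([1.0], [2.0])
        with pytest.raises(ValidationError):
            pairwise_variation([1.0, -1.0], [2.0, 2.0])


class TestGenormM:
    def test_matches_brute_force(self, random_quantities):
        m = genorm_m(random_quantities)
        expected = brute_force_m(random_quantities.q)
        assert np.allclose(m.to_numpy(), expected[m.index].to_numpy(), atol=1e-12)

    def test_proportional_genes_have_zero_m(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        frame = pd.DataFrame(
            {"s%d" % i: base[i] * np.array([1.0, 2.0, 0.5]) for i in range(4)},
            index=["a", "b", "c"],
        )
        m = genorm_m(QuantityTable(frame))
        assert np.allclose(m.to_numpy(), 0.0, atol=1e-12)

    def test_two_genes_rejected(self):
        frame = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 3.0]}, index=["a", "b"])
        with pytest.raises(ValidationError):
            genorm_m(frame)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_gene_scaling_leaves_m_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        frame = pd.DataFrame(
            rng.lognormal(0, 0.4, size=(4, 6)),
            index=list("abcd"),
            columns=[f"s{i}" for i in range(6)],
        )
        scaled = frame.copy()
        scaled.loc["b"] *= 7.3
        assert np.allclose(
            genorm_m(frame).to_numpy(), genorm_m(scaled).to_numpy(), atol=1e-12
        )

    def test_sample_permutation_invariance(self, random_quantities):
        frame = random_quantities.q
        permuted = frame[list(frame.columns[::-1])]
        assert np.allclose(
            genorm_m(frame).to_numpy(), genorm_m(permuted).to_numpy(), atol=1e-12
        )


class TestGenormRank:
    @pytest.fixture
    def proportional_pair_dataset(self):
        """A and B exactly proportional; C, D, E with independent noise."""
        rng = np.random.default_rng(21)
        base = rng.lognormal(0.0, 0.4, size=12)
        frame = pd.DataFrame(
            {
                "A": base,
                "B": 2.5 * base,
                "C": base * rng.lognormal(0, 0.3, size=12),
                "D": base * rng.lognormal(0, 0.3, size=12),
                "E": base * rng.lognormal(0, 0.3, size=12),
            }
        ).T
        frame.columns = [f"s{i}" for i in range(12)]
        return QuantityTable(frame)

    def test_proportional_pair_survives(self, proportional_pair_dataset):
        result = genorm_rank(proportional_pair_dataset)
        assert set(result.gene_order[:2]) == {"A", "B"}
        assert result.ranking["A"] == result.ranking["B"] == 1
        assert len(result.exclusion_order) == 3

    def test_input_order_does_not_matter(self, proportional_pair_dataset):
        frame = proportional_pair_dataset.q
        shuffled = QuantityTable(frame.loc[["D", "A", "E", "B", "C"]])
        r1 = genorm_rank(proportional_pair_dataset)
        r2 = genorm_rank(shuffled)
        assert r1.ranking == r2.ranking
        assert r1.exclusion_order == r2.exclusion_order

    def test_tie_removes_reverse_lexicographic_larger(self):
        # all genes proportional: every M equal at every step
        base = np.array([1.0, 2.0, 4.0, 8.0])
        frame = pd.DataFrame(
            {f"s{i}": base[i] * np.array([1, 2, 3, 4.0]) for i in range(4)},
            index=["a", "b", "c", "d"],
        )
        result = genorm_rank(QuantityTable(frame))
        assert result.exclusion_order == ["d", "c"]
        assert set(result.gene_order[:2]) == {"a", "b"}

    def test_noise_order_recovery(self):
        """Genes with smaller injected noise rank better, on average."""
        from scipy.stats import spearmanr

        sds = np.linspace(0.05, 0.9, 8)
        rhos = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            loading = rng.normal(0, 0.5, size=20)
            ct = np.array(
                [22.0 + loading + rng.normal(0, sd, size=20) for sd in sds]
            )
            frame = pd.DataFrame(
                2.0**-ct, index=[f"g{i}" for i in range(8)],
                columns=[f"s{j}" for j in range(20)],
            )
            ranking = genorm_rank(QuantityTable(frame * 1e8)).ranking
            rhos.append(spearmanr(sds, [ranking[f"g{i}"] for i in range(8)]).statistic)
        assert np.mean(rhos) >= 0.8


class TestVSeries:
    def test_gene_proportional_to_nf_gives_zero_v(self):
        rng = np.random.default_rng(3)
        a = rng.lognormal(0, 0.3, size=10)
        b = a * rng.lognormal(0, 0.05, size=10)
        nf2 = np.sqrt(a * b)
        frame = pd.DataFrame(
            {"s%d" % i: [a[i], b[i], 3.0 * nf2[i]] for i in range(10)},
            index=["a", "b", "c"],
        )
        result = genorm(QuantityTable(frame))
        order = result.gene_order
        if order[:3] == ["a", "b", "c"] or order[:3] == ["b", "a", "c"]:
            assert result.v_series[0] == pytest.approx(0.0, abs=1e-12)

    def test_v_matches_brute_force(self, random_quantities):
        result = genorm(random_quantities)
        frame = random_quantities.q
        order = result.gene_order
        for i, n in enumerate(range(2, len(order))):
            nf_n = [
                np.exp(np.mean([np.log(frame.at[g, s]) for g in order[:n]]))
                for s in frame.columns
            ]
            nf_n1 = [
                np.exp(np.mean([np.log(frame.at[g, s]) for g in order[: n + 1]]))
                for s in frame.columns
            ]
            v = np.std(np.log2(np.array(nf_n) / np.array(nf_n1)), ddof=1)
            assert result.v_series[i] == pytest.approx(v, abs=1e-12)

    def test_low_noise_needs_only_two_genes(self):
        rng = np.random.default_rng(17)
        loading = rng.normal(0, 0.4, size=12)
        ct = np.array(
            [20.0 + i + loading + rng.normal(0, 0.05, size=12) for i in range(6)]
        )
        frame = pd.DataFrame(
            2.0**-ct * 1e8, index=[f"g{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(12)],
        )
        result = genorm(QuantityTable(frame))
        assert result.v_series[0] < 0.15
        assert result.recommended_n == 2
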