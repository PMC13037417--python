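"""GeNorm M/V statistics against brute-force oracles and invariances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirvalid.core import ValidationError
from mirvalid.genorm import (
    evaluate,
    m_values,
    pairwise_variation,
    quantities_from_ct,
    rank_by_stability,
)


def m_oracle(expr: pd.DataFrame) -> pd.Series:
    """Independent loop-based M: mean over partners of sd of log2 ratios."""
    log = np.log2(expr.to_numpy(float))
    out = {}
    for j, gj in enumerate(expr.index):
        sds = []
        for k in range(len(expr.index)):
            if k == j:
                continue
            sds.append(np.std(log[j] - log[k], ddof=1))
        out[gj] = np.mean(sds)
    return pd.Series(out)


def v_oracle(expr: pd.DataFrame, ranking) -> dict[int, float]:
    """Independent V(n, n+1) via explicit geometric means."""
    out = {}
    for n in range(2, len(ranking)):
        top_n = expr.loc[ranking[:n]].to_numpy(float)
        top_n1 = expr.loc[ranking[: n + 1]].to_numpy(float)
        nf_n = np.exp(np.mean(np.log(top_n), axis=0))
        nf_n1 = np.exp(np.mean(np.log(top_n1), axis=0))
        out[n] = np.std(np.log2(nf_n / nf_n1), ddof=1)
    return out


def random_expr(rng, g, s):
    return pd.DataFrame(
        rng.lognormal(mean=2.0, sigma=1.0, size=(g, s)),
        index=[f"g{i}" for i in range(g)],
        columns=[f"s{j}" for j in range(s)],
    )


class TestMValues:
    def test_proportional_genes_have_zero_m(self, rng):
        base = rng.lognormal(size=6)
        expr = pd.DataFrame(
            {"g1": base, "g2": 3.0 * base, "g3": 0.25 * base}
        ).T
        assert np.allclose(m_values(expr), 0.0)

    def test_matches_oracle_on_toy(self, rng):
        expr = random_expr(rng, 3, 4)
        pd.testing.assert_series_equal(
            m_values(expr), m_oracle(expr), check_names=False
        )

    def test_noise_increases_m(self, rng):
        base = rng.lognormal(size=8)
        clean = pd.DataFrame({f"g{i}": base * (i + 1) for i in range(4)}).T
        worse = 0
        for trial in range(50):
            noisy = clean.copy()
            noisy.iloc[0] = noisy.iloc[0] * np.exp(
                rng.normal(0, 0.5, size=clean.shape[1])
            )
            m = m_values(noisy)
            worse += m.iloc[0] > m.iloc[1:].max()
        assert worse >= 45

    def test_rejects_nonpositive(self):
        expr = pd.DataFrame({"g1": [1.0, 0.0], "g2": [1.0, 2.0]}).T
        with pytest.raises(ValidationError, match="pseudocount"):
            m_values(expr)

    def test_sample_scaling_invariance(self, rng):
        expr = random_expr(rng, 4, 5)
        scaled = expr * rng.lognormal(size=5)[None, :]
        assert np.allclose(m_values(expr), m_values(scaled))

    def test_gene_relabeling_symmetry(self, rng):
        expr = random_expr(rng, 4, 5)
        perm = ["g2", "g0", "g3", "g1"]
        m1 = m_values(expr)
        m2 = m_values(expr.loc[perm])
        assert np.allclose(m1[perm].to_numpy(), m2.to_numpy())


class TestRanking:
    def test_noisy_gene_removed_first(self, rng):
        base = rng.lognormal(size=10)
        expr = pd.DataFrame(
            {
                "stable1": base,
                "stable2": 2 * base,
                "noisy": base * np.exp(rng.normal(0, 1.0, size=10)),
            }
        ).T
        ranking = rank_by_stability(expr)
        assert ranking[-1] == "noisy"
        assert set(ranking[:2]) == {"stable1", "stable2"}

    def test_all_proportional_ties_lexicographic(self, rng):
        base = rng.lognormal(size=5)
        expr = pd.DataFrame({f"g{i}": base * (i + 1) for i in range(4)}).T
        assert rank_by_stability(expr) == ["g0", "g1", "g2", "g3"]

    def test_matches_exhaustive_recomputation(self, rng):
        expr = random_expr(rng, 4, 6)
        # oracle: recompute M from scratch at each exclusion step
        remaining = list(expr.index)
        excluded = []
        while len(remaining) > 2:
            m = m_oracle(expr.loc[remaining])
            worst = m.sort_values(ascending=False).index
            worst = sorted(m.index[m == m.max()])[-1]
            excluded.append(worst)
            remaining.remove(worst)
        expected = sorted(remaining) + excluded[::-1]
        assert rank_by_stability(expr) == expected


class TestPairwiseVariation:
    def test_proportional_extra_gene_gives_zero_v(self, rng):
        base = rng.lognormal(size=6)
        expr = pd.DataFrame(
            {"g1": base, "g2": 2 * base, "g3": 0.5 * base}
        ).T
        ranking = ["g1", "g2", "g3"]
        v, n = pairwise_variation(expr, ranking)
        assert v[2] == pytest.approx(0.0, abs=1e-12)
        assert n == 2

    def test_threshold_strictly_less(self, rng):
        # construct V(2,3) exactly at the cutoff: must NOT recommend 2
        base = np.ones(4)
        delta = np.array([-1.5, -0.5, 0.5, 1.5])
        sd = np.std(delta, ddof=1)
        third = np.exp2(3 * 0.15 * delta / sd)  # V = sd(log2 NF2/NF3) = 0.15
        expr = pd.DataFrame({"g1": base, "g2": base, "g3": third}).T
        v, n = pairwise_variation(expr, ["g1", "g2", "g3"], v_threshold=0.15)
        assert v[2] == pytest.approx(0.15)
        with pytest.warns(UserWarning):
            _, n = pairwise_variation(expr, ["g1", "g2", "g3"], 0.15)
        assert n == 3

    def test_matches_oracle_on_toy(self, rng):
        expr = random_expr(rng, 4, 5)
        ranking = rank_by_stability(expr)
        v, _ = pairwise_variation(expr, ranking)
        oracle = v_oracle(expr, ranking)
        for n, val in oracle.items():
            assert v[n] == pytest.approx(val)

    def test_two_genes_empty_curve(self, rng):
        expr = random_expr(rng, 2, 4)
        with pytest.warns(UserWarning, match="fewer than 3"):
            v, n = pairwise_variation(expr, list(expr.index))
        assert v.empty and n == 2


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    g=st.integers(3, 5),
    s=st.integers(3, 6),
    seed=st.integers(0, 10_000),
)
def test_brute_force_equivalence_property(g, s, seed):
    """M and V match independent loop-based recomputation on random matrices."""
    rng = np.random.default_rng(seed)
    expr = random_expr(rng, g, s)
    pd.testing.assert_series_equal(
        m_values(expr), m_oracle(expr), check_names=False
    )
    ranking = rank_by_stability(expr)
    v, _ = pairwise_variation(expr, ranking)
    for n, val in v_oracle(expr, ranking).items():
        assert v[n] == pytest.approx(val)


def test_quantities_from_ct_roundtrip():
    ct = pd.DataFrame({"s1": [20.0, 25.0], "s2": [21.0, 24.0]},
                      index=["a1", "a2"])
    q = quantities_from_ct(ct)
    assert q.loc["a1", "s1"] == pytest.approx(2.0 ** -20.0)
    # one cycle difference = factor 2 at 100% efficiency
    assert q.loc["a1", "s1"] / q.loc["a1", "s2"] == pytest.approx(2.0)


def test_evaluate_bundles_consistent_result(rng):
    expr = random_expr(rng, 5, 6)
    res = evaluate(expr)
    assert sorted(res.ranking) == sorted(expr.index)
    assert set(res.v_curve.index) == {2, 3, 4}
    assert (res.m_values >= 0).all()
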