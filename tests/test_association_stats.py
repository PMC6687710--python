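"""Tests for association_stats: closed forms and enumeration oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sccproteo.association_stats import (
    bh_adjust,
    cmh_ordinal_test,
    fisher_exact,
    hypergeom_ora,
    storey_qvalue,
    wilcoxon_de,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------------------
# rank-sum test


def _ranksum_enumeration(a, b) -> float:
    """Exact two-sided p by full enumeration of group assignments.

    Under H0 every split of the combined sample into groups of sizes
    (n1, n2) is equally likely; p is the fraction of splits whose
    Mann-Whitney U is at least as far from its null mean as observed.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    combined = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = stats.rankdata(combined)
    mu = n1 * n2 / 2.0

    def u_stat(idx) -> float:
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_stat(range(n1))
    hits = 0
    total = 0
    for idx in combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_stat(idx) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def test_ranksum_fully_separated_small_groups():
    # {1,2,3} vs {4,5,6}: 2 of the 20 splits are as extreme -> p = 0.1
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


@pytest.mark.parametrize("n1,n2", [(3, 3), (4, 4), (3, 5), (5, 5), (4, 6)])
def test_ranksum_matches_enumeration_oracle(n1, n2, rng):
    for _ in range(5):
        a = rng.normal(size=n1)
        b = rng.normal(loc=rng.uniform(-1, 1), size=n2)
        p = wilcoxon_rank_sum(a, b)
        assert p == pytest.approx(_ranksum_enumeration(a, b), abs=1e-12)


def test_ranksum_all_values_tied_gives_p_one():
    assert wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0]) == 1.0


def test_ranksum_ties_fall_back_to_corrected_asymptotic():
    a = [1.0, 2.0, 2.0, 3.0]
    b = [2.0, 4.0, 5.0, 6.0]
    expected = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert wilcoxon_rank_sum(a, b) == pytest.approx(float(expected.pvalue))


def test_ranksum_symmetric_in_group_order(rng):
    a, b = rng.normal(size=8), rng.normal(size=12)
    assert wilcoxon_rank_sum(a, b) == pytest.approx(wilcoxon_rank_sum(b, a))


# ---------------------------------------------------------------------------
# differential expression


def test_wilcoxon_de_flags_only_shifted_features(rng):
    n_a, n_b = 20, 30
    data = rng.normal(0.0, 0.3, size=(40, n_a + n_b))
    shifted = [0, 7, 13]
    for i in shifted:
        data[i, :n_a] += 2.0
    matrix = pd.DataFrame(
        data,
        index=[f"F{i:03d}" for i in range(40)],
        columns=[f"S{j}" for j in range(n_a + n_b)],
    )
    mask = np.arange(n_a + n_b) < n_a
    res = wilcoxon_de(matrix, mask, fc_threshold=1.5, alpha=0.05)
    assert sorted(res.index[res["significant"]]) == [f"F{i:03d}" for i in shifted]
    assert res.loc["F000", "log2_fc"] == pytest.approx(2.0, abs=0.4)


def test_wilcoxon_de_skips_underpowered_features():
    matrix = pd.DataFrame(
        [[1.0, np.nan, np.nan, 2.0, 3.0, 4.0]],
        index=["F0"],
        columns=list("abcdef"),
    )
    mask = np.array([True, True, True, False, False, False])
    res = wilcoxon_de(matrix, mask, min_group_n=3)
    assert np.isnan(res.loc["F0", "p"])
    assert not res.loc["F0", "significant"]


def test_wilcoxon_de_rejects_mismatched_mask(small_cohort):
    matrix = pd.DataFrame(np.zeros((3, 4)), columns=list("abcd"))
    with pytest.raises(ValueError):
        wilcoxon_de(matrix, [True, False])


# ---------------------------------------------------------------------------
# Fisher exact


def _fisher_enumeration(table) -> float:
    """Two-sided p by summing margin-fixed hypergeometric probabilities of
    every table at most as probable as the observed one."""
    t = np.asarray(table, dtype=int)
    r1, r2 = t.sum(axis=1)
    c1 = t[:, 0].sum()
    n = t.sum()
    dist = stats.hypergeom(n, r1, c1)
    p_obs = dist.pmf(t[0, 0])
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = 0.0
    for a in range(lo, hi + 1):
        pk = dist.pmf(a)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def test_fisher_p_matches_enumeration_for_all_small_tables():
    # every 2x2 table with grand total <= 12 and positive margins
    for n in range(2, 13):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    t = [[a, b], [c, d]]
                    if min(a + b, c + d, a + c, b + d) == 0:
                        continue
                    assert fisher_exact(t).p == pytest.approx(
                        _fisher_enumeration(t), abs=1e-12
                    ), f"table {t}"


def test_fisher_transpose_invariance(rng):
    for _ in range(20):
        t = rng.integers(0, 15, size=(2, 2))
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            continue
        assert fisher_exact(t).p == pytest.approx(fisher_exact(t.T).p)


def test_fisher_conditional_mle_differs_from_cross_product():
    res = fisher_exact([[7, 2], [3, 8]])
    sample_or = (7 * 8) / (2 * 3)
    assert res.odds_ratio != pytest.approx(sample_or)
    assert 1.0 < res.odds_ratio < sample_or


def test_fisher_zero_margin_returns_p_one():
    res = fisher_exact([[0, 0], [3, 5]])
    assert res.p == 1.0
    assert np.isnan(res.odds_ratio)


def test_fisher_rejects_bad_input():
    with pytest.raises(ValueError):
        fisher_exact([[1, 2, 3], [4, 5, 6]])
    with pytest.raises(ValueError):
        fisher_exact([[1, -2], [3, 4]])


# ---------------------------------------------------------------------------
# CMH ordinal test


def test_cmh_on_2x2_equals_continuity_free_chi2():
    # For a 2x2 table, (N-1) r^2 equals (N-1)/N times the Pearson chi2.
    t = np.array([[10, 5], [3, 12]], dtype=float)
    n = t.sum()
    chi2 = stats.chi2_contingency(t, correction=False)[0]
    m2, p = cmh_ordinal_test(t)
    assert m2 == pytest.approx((n - 1) / n * chi2)
    assert p == pytest.approx(stats.chi2.sf(m2, 1))


def test_cmh_invariant_under_affine_score_transform():
    t = [[5, 8, 2, 1], [1, 4, 6, 9]]
    m2_a, p_a = cmh_ordinal_test(t, scores=[0, 1, 2, 3])
    m2_b, p_b = cmh_ordinal_test(t, scores=[10, 13, 16, 19])
    assert m2_a == pytest.approx(m2_b)
    assert p_a == pytest.approx(p_b)


def test_cmh_nonlinear_scores_change_the_statistic():
    t = [[5, 8, 2, 1], [1, 4, 6, 9]]
    m2_lin, _ = cmh_ordinal_test(t, scores=[0, 1, 2, 3])
    m2_sq, _ = cmh_ordinal_test(t, scores=[0, 1, 4, 9])
    assert m2_lin != pytest.approx(m2_sq)


def test_cmh_zero_variance_margin_gives_p_one():
    assert cmh_ordinal_test([[0, 0, 0], [4, 5, 6]]) == (0.0, 1.0)


def test_cmh_general_variant_uses_k_minus_1_df():
    t = np.array([[5, 8, 2], [1, 4, 6]], dtype=float)
    n = t.sum()
    chi2 = stats.chi2_contingency(t, correction=False)[0]
    m2, p = cmh_ordinal_test(t, variant="general")
    assert m2 == pytest.approx((n - 1) / n * chi2)
    assert p == pytest.approx(stats.chi2.sf(m2, 2))


# ---------------------------------------------------------------------------
# multiple testing


def test_bh_adjust_worked_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_adjust_preserves_nan_positions():
    out = bh_adjust([0.04, np.nan, 0.01])
    assert np.isnan(out[1])
    np.testing.assert_allclose(out[[0, 2]], [0.04, 0.02])


def test_bh_adjust_monotone_and_capped(rng):
    p = rng.uniform(size=200)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    assert (q <= 1.0).all()


def test_storey_q_never_exceeds_bh(rng):
    p = np.concatenate([rng.uniform(size=150), rng.uniform(0, 1e-4, size=20)])
    q, pi0 = storey_qvalue(p)
    assert 0 < pi0 <= 1.0
    assert (q <= bh_adjust(p) + 1e-12).all()


def test_storey_small_input_falls_back_to_pi0_one():
    p = [0.01, 0.2, 0.5]
    with pytest.warns(UserWarning, match="pi0"):
        q, pi0 = storey_qvalue(p)
    assert pi0 == 1.0
    np.testing.assert_allclose(q, bh_adjust(p))


def test_storey_respects_explicit_pi0():
    p = np.linspace(0.001, 0.999, 50)
    q, pi0 = storey_qvalue(p, pi0=0.5)
    assert pi0 == 0.5
    np.testing.assert_allclose(q, np.minimum(bh_adjust(p) * 0.5, 1.0))


# ---------------------------------------------------------------------------
# over-representation


def test_ora_closed_form():
    universe = [f"g{i}" for i in range(10)]
    collection = {"setA": ["g0", "g1", "g2", "g3"]}
    query = ["g0", "g1", "g5"]
    res = hypergeom_ora(query, collection, universe)
    # P(overlap >= 2) drawing 3 from 10 with 4 marked
    expected = float(stats.hypergeom.sf(1, 10, 4, 3))
    assert res.loc["setA", "overlap"] == 2
    assert res.loc["setA", "p"] == pytest.approx(expected)


def test_ora_rejects_query_outside_universe():
    with pytest.raises(ValueError, match="outside the universe"):
        hypergeom_ora(["gX"], {"s": ["g0"]}, ["g0", "g1"])
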