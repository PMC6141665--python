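"""Rank statistics: Kruskal-Wallis, Dunn's post hoc, Spearman."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from glycopap import dunn_posthoc, kruskal_wallis, spearman
from glycopap.errors import ValidationError


def test_hand_computed_h():
    """Groups {1,2,3},{4,5,6},{7,8,9}: H = 12/90 * 279 - 30 = 7.2."""
    res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert res.statistic == pytest.approx(7.2, rel=1e-12)
    assert res.df == 2


def test_all_identical_observations():
    res = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_empty_group_rejected():
    with pytest.raises(ValidationError):
        kruskal_wallis([[1, 2], []])


def test_matches_scipy_with_and_without_ties():
    rng = np.random.default_rng(0)
    for _ in range(20):
        groups = [rng.integers(0, 8, size=rng.integers(3, 12)).astype(float)
                  for _ in range(int(rng.integers(2, 5)))]
        ours = kruskal_wallis(groups)
        ref_h, ref_p = sps.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref_h, rel=1e-10)
        assert ours.p_value == pytest.approx(ref_p, rel=1e-10)


def test_no_ties_correction_is_identity():
    """Without ties the tie-corrected H equals the raw rank-sum H exactly."""
    rng = np.random.default_rng(1)
    groups = [rng.permutation(30)[:10].astype(float) + i * 100 for i in range(3)]
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    splits = np.split(ranks, np.cumsum([len(g) for g in groups])[:-1])
    N = len(pooled)
    raw_h = 12.0 / (N * (N + 1)) * sum(r.sum() ** 2 / len(r) for r in splits) - 3 * (N + 1)
    assert kruskal_wallis(groups).statistic == pytest.approx(raw_h, rel=1e-12)


def test_permutation_null_oracle():
    """The chi-square p tracks a sampled permutation null.

    At 3 x 5 the chi-square approximation carries a small documented bias,
    so the tolerance combines Monte-Carlo error with that approximation
    error; at 3 x 30 the agreement is tight.
    """
    rng = np.random.default_rng(2)
    for n_per, tol in ((5, 0.03), (30, 0.012)):
        groups = [rng.normal(size=n_per) for _ in range(3)]
        p_chi2 = kruskal_wallis(groups).p_value
        pooled = np.concatenate(groups)
        h_obs = kruskal_wallis(groups).statistic
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            h = kruskal_wallis(np.split(perm, 3)).statistic
            count += h >= h_obs - 1e-12
        p_perm = count / n_perm
        assert abs(p_chi2 - p_perm) <= tol + 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm)


@given(st.integers(0, 2 ** 31 - 1))
@settings(derandomize=True, max_examples=25)
def test_kw_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    groups = [rng.normal(size=8), rng.normal(size=6), rng.normal(size=7)]
    h0 = kruskal_wallis(groups).statistic
    h1 = kruskal_wallis([np.exp(g) for g in groups]).statistic
    assert h1 == pytest.approx(h0, rel=1e-12)


def test_dunn_identical_two_groups():
    res = dunn_posthoc([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    assert res[0].z == 0.0
    assert res[0].p_raw == 1.0


def test_dunn_pair_count_and_adjustment_ordering():
    rng = np.random.default_rng(3)
    groups = [rng.normal(i, 1, 12) for i in range(4)]
    for adj in ("none", "bonferroni", "sidak"):
        res = dunn_posthoc(groups, adjustment=adj)
        assert len(res) == 6
        for r in res:
            assert r.p_adjusted >= r.p_raw - 1e-15
            assert 0.0 <= r.p_adjusted <= 1.0
    pairs = {r.pair for r in dunn_posthoc(groups, labels=list("ABCD"))}
    assert pairs == set(itertools.combinations("ABCD", 2))


def test_dunn_two_group_z_squared_equals_h():
    """In the 2-group case Dunn's z^2 reproduces the tie-corrected H."""
    rng = np.random.default_rng(4)
    for _ in range(20):
        g1 = rng.integers(0, 6, 15).astype(float)
        g2 = rng.integers(0, 6, 11).astype(float) + rng.integers(0, 2)
        h = kruskal_wallis([g1, g2]).statistic
        z = dunn_posthoc([g1, g2], adjustment="none")[0].z
        assert z * z == pytest.approx(h, rel=1e-9, abs=1e-12)


def test_spearman_examples():
    x = np.arange(10.0)
    assert spearman(x, 2 * x + 1).statistic == pytest.approx(1.0)
    assert spearman(x, -x).statistic == pytest.approx(-1.0)


def test_spearman_tied_fixture_rank_oracle():
    x, y = [1.0, 2.0, 2.0, 3.0], [10.0, 20.0, 20.0, 40.0]
    ours = spearman(x, y)
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert ours.statistic == pytest.approx(oracle, rel=1e-12)
    ref_rho, ref_p = sps.spearmanr(x, y)
    assert ours.statistic == pytest.approx(ref_rho, rel=1e-12)
    assert ours.p_value == pytest.approx(ref_p, rel=1e-9)


def test_spearman_constant_input_rejected():
    with pytest.raises(ValidationError):
        spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@given(st.integers(0, 2 ** 31 - 1))
@settings(derandomize=True, max_examples=25)
def test_spearman_symmetries(seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=15), rng.normal(size=15)
    rho = spearman(x, y).statistic
    assert spearman(x, -y).statistic == pytest.approx(-rho, rel=1e-9, abs=1e-12)
    assert spearman(np.exp(x), y).statistic == pytest.approx(rho, rel=1e-9, abs=1e-12)
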