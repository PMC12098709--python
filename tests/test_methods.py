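"""Scorer-level checks: frozen hand-derived values, algebraic invariances
and brute-force oracles for the enrichment running sum."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinactbench import methods as M

# ---------------------------------------------------------------------------
# hand-derived expected values
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "values,stat,expected",
    [
        ([1, 2, 3], "mean", 2.0),
        ([1, 2, 4], "median", 2.0),
        ([1, 2], "sum", 3.0),
        # type-7 quantile: h = (n-1)*0.75 + 1 = 3.25 -> 3 + 0.25*(4-3)
        ([1, 2, 3, 4], "uq", 3.25),
        ([7, 7], "mean", 7.0),
        ([7, 7], "median", 7.0),
        ([7, 7], "uq", 7.0),
    ],
)
def test_location_statistics(values, stat, expected):
    assert M.score_location(values, stat) == pytest.approx(expected, abs=1e-12)


def test_ksea_hand_value():
    # (2 - 1) * sqrt(2) / sqrt(4/3)
    assert M.score_ksea([2, 2], [2, 2, 0, 0]) == pytest.approx(1.224745, abs=1e-6)


def test_ksea_targets_equal_background_is_zero():
    assert M.score_ksea([2, 2, 0, 0], [2, 2, 0, 0]) == pytest.approx(0.0)


def test_zscore_rokai_hand_value():
    # 2 * sqrt(2) / sqrt(4/3)
    assert M.score_zscore_rokai([2, 2], [2, 2, 0, 0]) == pytest.approx(
        2.449490, abs=1e-6
    )


def test_zscore_rokai_zero_mean_targets():
    assert M.score_zscore_rokai([-1, 1], [-1, 1, 5, -5]) == pytest.approx(0.0)


@pytest.mark.parametrize("t_known,expected", [(2, 1.0), (8, 0.5)])
def test_karp_hand_values(t_known, expected):
    assert M.score_karp([2, 2], [2, 2, 0, 0], t_known) == pytest.approx(
        expected, abs=1e-12
    )


def test_karp_all_targets_full_coverage_is_one():
    assert M.score_karp([1, 2, 3], [1, 2, 3], 3) == pytest.approx(1.0)


def test_mwu_exact_enumeration_value():
    # targets [3,4] vs nontargets [1,2]: two-sided exact p = 2/6 = 1/3
    assert M.score_rank_test([3, 4], [1, 2], "mwu") == pytest.approx(
        np.log(3.0), abs=1e-6
    )


def test_rank_test_identical_groups_score_zero():
    v = [1.0, 2.0, 3.0]
    assert M.score_rank_test(v, v, "mwu") == pytest.approx(0.0, abs=1e-12)
    assert M.score_rank_test(v, v, "ks") == pytest.approx(0.0, abs=1e-12)


def test_rank_test_sign_convention():
    up = M.score_rank_test([10, 11, 12], [1, 2, 3], "mwu")
    down = M.score_rank_test([1, 2, 3], [10, 11, 12], "mwu")
    assert up > 0 and down < 0 and up == pytest.approx(-down)


def test_fisher_hypergeometric_hand_value():
    # 5 targets (4 deregulated), 5 non-targets (1 deregulated):
    # one-sided P(X>=4) = 26/252; score = -log10(26/252)
    targets = [2.0, 2.0, 2.0, 2.0, 0.5]
    nontargets = [0.5, 0.5, 0.5, 0.5, 2.0]
    expected = -np.log10(26 / 252)
    assert M.score_overrep(targets, nontargets, "fisher") == pytest.approx(
        expected, abs=1e-6
    )


def test_overrep_no_deregulated_sites_scores_zero():
    assert M.score_overrep([0.1, 0.2], [0.3, 0.1], "fisher") == 0.0


def test_fisher_monotone_in_sample_size():
    scores = []
    for n in (5, 10, 20):
        t = [2.0] * n
        nt = [0.1] * n
        scores.append(M.score_overrep(t, nt, "fisher"))
    assert scores[0] < scores[1] < scores[2] and scores[0] > 0


def test_chisq_small_expected_cells_is_nan():
    with pytest.warns(UserWarning):
        out = M.score_overrep([2.0], [0.1, 0.1], "chisq")
    assert np.isnan(out)


def test_ulm_closed_form_t():
    # y=[2,1,0,1], x=[1,1,0,0]: beta=1, SE=sqrt(0.5), t=sqrt(2)
    assert M.score_ulm([2, 1, 0, 1], [1, 1, 0, 0]) == pytest.approx(
        1.414214, abs=1e-6
    )


def test_ulm_constant_response_is_nan():
    assert np.isnan(M.score_ulm([3, 3, 3, 3], [1, 1, 0, 0]))


def test_ulm_matches_normal_equations_oracle():
    rng = np.random.default_rng(5)
    y = rng.normal(size=30)
    x = (rng.random(30) < 0.3).astype(float)
    X = np.column_stack([np.ones(30), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (30 - 2)
    se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
    assert M.score_ulm(y, x) == pytest.approx(beta[1] / se, abs=1e-10)


def test_mlm_duplicate_columns_dropped_and_match_ulm():
    rng = np.random.default_rng(7)
    y = rng.normal(size=40)
    member = (rng.random(40) < 0.25).astype(float)
    design = np.column_stack([member, member])  # two kinases, identical targets
    with pytest.warns(UserWarning):
        t_vals, kept = M.score_mlm(y, design, ["K1", "K2"])
    assert kept == ["K1"] and np.isnan(t_vals[1])
    assert t_vals[0] == pytest.approx(M.score_ulm(y, member), abs=1e-10)


class TestRidgeLinearModel:
    def test_single_kinase_ols_is_mean(self):
        A = np.ones((2, 1))
        out = M.score_lm_rokai([1, 3], A, lam=0)
        assert out[0] == pytest.approx(2.0)

    def test_block_diagonal_equals_independent_fits(self):
        A = np.zeros((6, 2))
        A[:3, 0] = 1
        A[3:, 1] = 1
        y = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        out = M.score_lm_rokai(y, A, lam=0)
        assert out == pytest.approx([2.0, 11.0])

    def test_ridge_monotone_shrinkage_to_zero(self):
        rng = np.random.default_rng(1)
        A = (rng.random((40, 4)) < 0.3).astype(float)
        y = rng.normal(size=40)
        norms = [
            np.linalg.norm(M.score_lm_rokai(y, A, lam=lam))
            for lam in (0.1, 1.0, 10.0, 1e6)
        ]
        assert norms == sorted(norms, reverse=True)
        assert norms[-1] < 1e-4

    def test_singular_at_zero_lambda_raises(self):
        A = np.ones((3, 2))  # collinear columns
        with pytest.raises(np.linalg.LinAlgError):
            M.score_lm_rokai([1, 2, 3], A, lam=0)


# ---------------------------------------------------------------------------
# running-sum enrichment: brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_es(values, in_set):
    """O(N) reference running sum, written independently of the implementation."""
    values = np.asarray(values, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    order = np.argsort(-values, kind="stable")
    m = in_set.sum()
    N = values.size
    wsum = np.abs(values[in_set]).sum()
    running, best = 0.0, 0.0
    for idx in order:
        if in_set[idx]:
            running += np.abs(values[idx]) / wsum if wsum > 0 else 1.0 / m
        else:
            running -= 1.0 / (N - m)
        if abs(running) > abs(best):
            best = running
    return best


@pytest.mark.parametrize("seed", range(10))
def test_fgsea_es_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 51))
    values = rng.normal(size=n)
    in_set = np.zeros(n, dtype=bool)
    m = int(rng.integers(1, n))
    in_set[rng.choice(n, size=m, replace=False)] = True
    assert M.score_fgsea_es(values, in_set) == pytest.approx(
        brute_force_es(values, in_set), abs=1e-12
    )


def test_fgsea_top_block_reaches_full_deviation():
    # targets hold the top m ranks: running sum peaks at 1 - 0 after the block
    values = np.array([5.0, 4.0, 3.0, 1.0, 0.5, 0.2])
    in_set = np.array([True, True, True, False, False, False])
    assert M.score_fgsea_es(values, in_set) == pytest.approx(1.0)


def test_fgsea_es_ignores_out_of_set_permutation():
    rng = np.random.default_rng(3)
    values = rng.normal(size=30)
    in_set = np.zeros(30, dtype=bool)
    in_set[:6] = True
    base = M.score_fgsea_es(values, in_set)
    out_idx = np.where(~in_set)[0]
    permuted = values.copy()
    permuted[out_idx] = values[out_idx][rng.permutation(out_idx.size)]
    assert M.score_fgsea_es(permuted, in_set) == pytest.approx(base, abs=1e-12)


def test_fgsea_full_set_is_nan():
    assert np.isnan(M.score_fgsea_es([1.0, 2.0], [True, True]))


# ---------------------------------------------------------------------------
# permutation-normalized scores
# ---------------------------------------------------------------------------


def test_norm_mean_zero_for_constant_values():
    out = M.score_norm_mean([1.0, 1.0], [1.0] * 10, n_perm=200, rng=0)
    assert np.isnan(out)  # sd of null is zero -> guarded


def test_norm_mean_detects_shift():
    rng = np.random.default_rng(0)
    background = rng.normal(size=200)
    targets = background[:10] + 3.0
    values_all = np.concatenate([targets, background[10:]])
    z = M.score_norm_mean(targets, values_all, n_perm=500, rng=1)
    assert z > 3


@pytest.mark.parametrize("fn", [M.score_ptmsea, M.score_viper])
def test_permutation_scores_seeded_reproducible(fn):
    rng = np.random.default_rng(8)
    values = rng.normal(size=60)
    in_set = np.zeros(60, dtype=bool)
    in_set[:8] = True
    a = fn(values, in_set, n_perm=200, rng=123)
    b = fn(values, in_set, n_perm=200, rng=123)
    assert a == b and np.isfinite(a)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_pca_rank_one_block():
    block = np.outer([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
    scores, var = M.score_pca(block)
    assert var == pytest.approx(1.0)
    # scores proportional to (centered) column effects
    assert abs(np.corrcoef(scores, [1.0, 2.0, 4.0])[0, 1]) == pytest.approx(1.0)


def test_pca_orientation_follows_column_means():
    rng = np.random.default_rng(2)
    block = rng.normal(size=(8, 6)) + np.linspace(-2, 2, 6)
    scores, _ = M.score_pca(block)
    assert np.corrcoef(scores, block.mean(axis=0))[0, 1] > 0


def test_pca_two_by_two_against_eigen_oracle():
    block = np.array([[1.0, 3.0], [2.0, 5.0]])
    scores, var = M.score_pca(block)
    Xc = block.T - block.T.mean(axis=0)
    cov = Xc.T @ Xc
    evals, evecs = np.linalg.eigh(cov)
    proj = Xc @ evecs[:, -1]
    assert var == pytest.approx(evals[-1] / evals.sum())
    assert np.abs(scores) == pytest.approx(np.abs(proj), abs=1e-10)


def test_pca_zero_variance_block_is_nan():
    scores, var = M.score_pca(np.ones((4, 3)))
    assert np.isnan(var) and np.all(np.isnan(scores))


# ---------------------------------------------------------------------------
# algebraic invariances (seeded property tests)
# ---------------------------------------------------------------------------


@settings(max_examples=40, derandomize=True)
@given(
    shift=st.floats(-50, 50, allow_nan=False),
    scale=st.floats(0.01, 50, allow_nan=False),
    seed=st.integers(0, 10_000),
)
def test_ksea_affine_invariance(shift, scale, seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=25)
    idx = rng.choice(25, size=6, replace=False)
    base = M.score_ksea(values[idx], values)
    transformed = M.score_ksea(scale * values[idx] + shift, scale * values + shift)
    assert transformed == pytest.approx(base, rel=1e-9, abs=1e-9)


@settings(max_examples=40, derandomize=True)
@given(
    scale=st.floats(0.01, 50, allow_nan=False),
    seed=st.integers(0, 10_000),
)
def test_zscore_rokai_scale_invariant_but_shift_sensitive(scale, seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=25)
    idx = rng.choice(25, size=6, replace=False)
    base = M.score_zscore_rokai(values[idx], values)
    scaled = M.score_zscore_rokai(scale * values[idx], scale * values)
    assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)
    if abs(base) > 1e-6:
        shifted = M.score_zscore_rokai(values[idx] + 5.0, values + 5.0)
        assert shifted != pytest.approx(base, rel=1e-3)
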