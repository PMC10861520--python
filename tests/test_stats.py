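"""Tests of rank tests, variance test, FDR control, correlation and ICC."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from wearra import stats as st


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def test_mwut_exact_extreme_case():
    res = st.mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)


def test_mwut_identical_samples():
    res = st.mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert res.p_value == pytest.approx(1.0, abs=0.05)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(hst.integers(min_value=0, max_value=10_000))
def test_mwut_u_identity(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=rng.integers(2, 10))
    y = rng.normal(size=rng.integers(2, 10))
    ux = st.mann_whitney_u(x, y).statistic
    uy = st.mann_whitney_u(y, x).statistic
    assert ux + uy == pytest.approx(x.size * y.size)


def _exact_mwut_p(x, y):
    """Exhaustive-permutation two-sided p for the MWU test (no ties)."""
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, len(x)

    def u_stat(ix):
        xs = pooled[list(ix)]
        ranks = np.searchsorted(np.sort(pooled), xs) + 1
        return ranks.sum() - nx * (nx + 1) / 2

    u_obs = u_stat(range(nx))
    mean = nx * (n - nx) / 2
    count = sum(abs(u_stat(ix) - mean) >= abs(u_obs - mean) - 1e-12
                for ix in itertools.combinations(range(n), nx))
    total = sum(1 for _ in itertools.combinations(range(n), nx))
    return count / total


@pytest.mark.parametrize("seed", range(6))
def test_mwut_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    nx, ny = int(rng.integers(2, 5)), int(rng.integers(2, 5))
    pooled = rng.permutation(np.arange(1.0, nx + ny + 1))  # distinct values
    x, y = pooled[:nx], pooled[nx:]
    res = st.mann_whitney_u(x, y)
    assert res.p_value == pytest.approx(_exact_mwut_p(x, y), abs=1e-12)


def test_mwut_empty_sample_rejected():
    with pytest.raises(ValueError):
        st.mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_kw_hand_computed_h():
    res = st.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    assert res.statistic == pytest.approx(32 / 7, abs=1e-3)


def test_kw_total_ties_defined_zero():
    res = st.kruskal_wallis([[5, 5], [5, 5], [5, 5]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_kw_exact_p_matches_enumeration():
    """Exact permutation p at combined n <= 8 agrees with brute force."""
    rng = np.random.default_rng(3)
    for _ in range(4):
        sizes = [2, 3, 2]
        pooled = rng.permutation(np.arange(1.0, sum(sizes) + 1))
        groups = [pooled[:2], pooled[2:5], pooled[5:]]
        res = st.kruskal_wallis(groups)
        h_obs = res.statistic
        # brute force over all distinct assignments via permutations
        count = total = 0
        for perm in itertools.permutations(range(pooled.size)):
            gs = [pooled[list(perm[:2])], pooled[list(perm[2:5])],
                  pooled[list(perm[5:])]]
            count += st._kw_h([np.asarray(g) for g in gs]) >= h_obs - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)


def test_kw_two_groups_matches_squared_mwut_z():
    """For two groups, H equals the squared standardised U asymptotically."""
    rng = np.random.default_rng(11)
    x = rng.normal(0, 1, 50)
    y = rng.normal(0.3, 1, 50)
    h = st.kruskal_wallis([x, y]).statistic
    u = st.mann_whitney_u(x, y).statistic
    n1, n2 = 50, 50
    z = (u - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
    assert h == pytest.approx(z ** 2, abs=0.05)


def test_kw_needs_two_groups():
    with pytest.raises(ValueError):
        st.kruskal_wallis([[1, 2, 3]])


# ---------------------------------------------------------------------------
# Brown-Forsythe
# ---------------------------------------------------------------------------

def test_bf_equal_spread_null():
    res = st.brown_forsythe([[1, 2, 3, 4], [11, 12, 13, 14]])
    assert res.statistic == pytest.approx(0.0, abs=1e-9)
    assert res.p_value == pytest.approx(1.0, abs=1e-9)


def test_bf_detects_unequal_variance():
    res = st.brown_forsythe([[0, 0, 0, 0.1, -0.1, 0], [-5, 5, -5, 5, -4, 4]])
    assert res.p_value < 0.05


def test_bf_location_invariance(rng):
    a = rng.normal(0, 1, 20)
    b = rng.normal(0, 3, 20)
    s1 = st.brown_forsythe([a, b]).statistic
    s2 = st.brown_forsythe([a + 100.0, b]).statistic
    assert s1 == pytest.approx(s2, rel=1e-9)


def test_bf_small_group_rejected():
    with pytest.raises(ValueError):
        st.brown_forsythe([[1.0], [2.0, 3.0]])


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_bh_linear_stepup_example():
    reject, p_adj = st.benjamini_hochberg([0.01, 0.02, 0.03, 0.04], alpha=0.05)
    assert reject.all()
    assert p_adj[-1] == pytest.approx(0.04)


def test_bh_null_and_single_test():
    reject, _ = st.benjamini_hochberg([1.0, 1.0, 1.0], alpha=0.05)
    assert not reject.any()
    reject, p_adj = st.benjamini_hochberg([0.04], alpha=0.05)
    assert reject[0] and p_adj[0] == pytest.approx(0.04)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        st.benjamini_hochberg([0.5, 1.2])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(hst.lists(hst.floats(min_value=0, max_value=1), min_size=1, max_size=30),
       hst.floats(min_value=0.01, max_value=0.2))
def test_bh_monotonicity_properties(p_values, alpha):
    """Adjusted p is monotone in raw p; rejections nest across alpha levels."""
    reject, p_adj = st.benjamini_hochberg(p_values, alpha)
    order = np.argsort(p_values)
    assert (np.diff(np.asarray(p_adj)[order]) >= -1e-12).all()
    reject_hi, _ = st.benjamini_hochberg(p_values, min(1.0, alpha * 2))
    assert (reject <= reject_hi).all()


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def test_correlation_perfect_linear():
    x = np.arange(10.0)
    res = st.correlation(x, 2 * x + 1, "pearson")
    assert res.r == pytest.approx(1.0)
    assert res.category == "good_excellent"


def test_correlation_monotone_transform():
    x = np.arange(1.0, 11.0)
    y = np.exp(x)
    assert st.correlation(x, y, "spearman").r == pytest.approx(1.0)
    assert st.correlation(x, y, "pearson").r < 1.0


@pytest.mark.parametrize("r, category", [
    (0.6, "moderate_good"), (-0.6, "moderate_good"), (0.8, "good_excellent"),
    (0.3, "fair"), (0.1, "none"), (0.75, "moderate_good"),
])
def test_correlation_strength_categories(r, category):
    assert st.correlation_category(r) == category


def test_correlation_zero_variance_rejected():
    with pytest.raises(ValueError):
        st.correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# ICC(3,k)
# ---------------------------------------------------------------------------

def test_icc_identical_columns_is_one(rng):
    col = rng.normal(0, 1, 20)
    m = np.tile(col[:, None], (1, 5))
    res = st.icc_3k(m)
    assert res.icc == pytest.approx(1.0)
    assert res.category == "excellent"


def test_icc_two_way_model_expectation(rng):
    """Subject:error variance 9:1 with k=14 days gives ICC near
    9 / (9 + 1/14) (average-measures consistency)."""
    n, k = 50, 14
    expected = 9 / (9 + 1 / k)
    vals = []
    for _ in range(200):
        subj = rng.normal(0, 3, (n, 1))
        m = subj + rng.normal(0, 1, (n, k))
        vals.append(st.icc_3k(m).icc)
    assert np.mean(vals) == pytest.approx(expected, abs=0.05)


def test_icc_pure_noise_near_zero(rng):
    vals = [st.icc_3k(rng.normal(0, 1, (30, 10))).icc for _ in range(200)]
    assert abs(np.mean(vals)) < 0.1


def test_icc_spearman_brown_identity(rng):
    """ICC(3,k) equals the Spearman-Brown-stepped ICC(3,1) algebraically."""
    m = rng.normal(0, 1, (12, 6)) + rng.normal(0, 2, (12, 1))
    n, k = m.shape
    grand = m.mean()
    ss_rows = k * ((m.mean(1) - grand) ** 2).sum()
    ss_cols = n * ((m.mean(0) - grand) ** 2).sum()
    ms_rows = ss_rows / (n - 1)
    ms_err = (((m - grand) ** 2).sum() - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    icc1 = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    stepped = k * icc1 / (1 + (k - 1) * icc1)
    assert st.icc_3k(m).icc == pytest.approx(stepped, abs=1e-10)


def test_icc_matches_pingouin(rng):
    import pandas as pd
    import pingouin as pg

    m = rng.normal(0, 1, (15, 5)) + rng.normal(0, 1.5, (15, 1))
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(15), 5),
        "rater": np.tile(np.arange(5), 15),
        "score": m.ravel(),
    })
    ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                             ratings="score")
    # consistency, average of k raters — ICC(3,k); labelled ICC(C,k) or ICC3k
    mask = ref["Type"].isin(["ICC3k", "ICC(C,k)"])
    icc3k_ref = float(ref.loc[mask, "ICC"].iloc[0])
    assert st.icc_3k(m).icc == pytest.approx(icc3k_ref, abs=1e-10)


def test_icc_rejects_missing_cells(rng):
    m = rng.normal(0, 1, (5, 4))
    m[2, 1] = np.nan
    with pytest.raises(ValueError):
        st.icc_3k(m)


@pytest.mark.parametrize("icc, category", [
    (0.3, "poor"), (-0.2, "poor"), (0.6, "moderate"), (0.8, "good"),
    (0.95, "excellent"),
])
def test_icc_categories(icc, category):
    assert st.icc_category(icc) == category


# ---------------------------------------------------------------------------
# ICC vs days
# ---------------------------------------------------------------------------

def test_icc_vs_days_noise_free_feature(rng):
    import pandas as pd

    subj_vals = rng.normal(0, 1, 10)
    rows = [{"participant_id": f"p{i}", "day_index": d, "f": subj_vals[i]}
            for i in range(10) for d in range(14)]
    out = st.icc_vs_days(pd.DataFrame(rows), ["f"], d_grid=[2, 7, 14])
    assert np.allclose(out["icc"], 1.0)


def test_icc_vs_days_increases_with_days(study_features):
    """Median ICC across the active+passive feature set grows with the
    number of contiguous days (Spearman-Brown behaviour under the
    generative model)."""
    from scipy import stats as sps

    daily = study_features.daily["active"].merge(
        study_features.daily["passive"], on=["participant_id", "day_index"])
    feat_cols = [c for c in daily.columns
                 if c not in ("participant_id", "day_index")]
    out = st.icc_vs_days(daily, feat_cols, d_grid=range(2, 15))
    med = out.groupby("d")["icc"].median()
    rho, _ = sps.spearmanr(med.index, med.values)
    assert rho > 0.8
    assert med.loc[2] < med.loc[14]
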