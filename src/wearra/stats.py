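"""Univariate statistics, FDR control, correlation and test-retest reliability.

Group comparisons use the Mann-Whitney U test (two groups), the Kruskal-Wallis
H test (several groups) and the Brown-Forsythe test (equality of variances,
ANOVA on absolute deviations from group medians).  All tests are two-sided.
Small untied samples get exact permutation p-values; otherwise the usual
tie-corrected large-sample approximations apply.  Multiplicity is controlled
with the Benjamini-Hochberg linear step-up procedure.  Test-retest reliability
over study days uses the two-way random average-measures intraclass
correlation ICC(3,k), with the conventional category bands.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

EXACT_MAX_N = 12  # MWUT switches to normal approximation above this combined n
KW_EXACT_MAX_N = 8


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # MWUT | KW | BF
    n_per_group: tuple[int, ...]


@dataclass
class IccResult:
    icc: float
    n_subjects: int
    k_raters: int

    @property
    def category(self) -> str:
        return icc_category(self.icc)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    method: str  # pearson | spearman

    @property
    def category(self) -> str:
        return correlation_category(self.r)


def icc_category(icc: float) -> str:
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def correlation_category(r: float) -> str:
    a = abs(r)
    if a > 0.75:
        return "good_excellent"
    if a >= 0.50:
        return "moderate_good"
    if a >= 0.25:
        return "fair"
    return "none"


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _has_ties(*samples: np.ndarray) -> bool:
    pooled = np.concatenate(samples)
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact p for combined n <= 12 without ties, otherwise the tie-corrected
    normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    exact = (x.size + y.size) <= EXACT_MAX_N and not _has_ties(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), "MWUT",
                      (x.size, y.size))


def _kw_h(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with midrank tie correction (0 under total ties)."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return 0.0 if tie == 0 else h / tie


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H by ranks.

    p from an exact permutation distribution for small untied samples
    (combined n <= 8), chi-squared with g-1 degrees of freedom otherwise.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size == 0 for g in gs):
        raise ValueError("need >= 2 non-empty groups")
    h = _kw_h(gs)
    n = sum(g.size for g in gs)
    if n <= KW_EXACT_MAX_N and not _has_ties(*gs):
        p = _kw_exact_p(gs, h)
    else:
        p = float(sps.chi2.sf(h, df=len(gs) - 1)) if h > 0 else 1.0
    return TestResult(float(h), float(p), "KW", tuple(g.size for g in gs))


def _kw_exact_p(gs: list[np.ndarray], h_obs: float) -> float:
    """P(H >= h_obs) over all distinct assignments of ranks to groups."""
    sizes = [g.size for g in gs]
    pooled = np.concatenate(gs)
    count = 0
    total = 0
    for perm in _group_assignments(pooled.size, sizes):
        groups = [pooled[list(idx)] for idx in perm]
        if _kw_h(groups) >= h_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def _group_assignments(n: int, sizes: list[int]):
    """All distinct ways to split indices 0..n-1 into groups of given sizes."""
    idx = frozenset(range(n))

    def rec(remaining: frozenset, k: int):
        if k == len(sizes) - 1:
            yield (tuple(sorted(remaining)),)
            return
        for comb in itertools.combinations(sorted(remaining), sizes[k]):
            for rest in rec(remaining - set(comb), k + 1):
                yield (comb,) + rest

    yield from rec(idx, 0)


def brown_forsythe(groups) -> TestResult:
    """One-way ANOVA F on absolute deviations from group medians."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    stat, p = sps.levene(*gs, center="median")
    return TestResult(float(stat), float(p), "BF", tuple(g.size for g in gs))


# ---------------------------------------------------------------------------
# multiplicity
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """BH linear step-up: (reject flags, adjusted p), in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def correlation(x, y, method: str = "pearson") -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(float(r), float(p), method)


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def icc_3k(data: np.ndarray) -> IccResult:
    """ICC(3,k): two-way average-measures consistency over a subjects x days
    matrix.

    From the two-way ANOVA decomposition (subjects as rows, days as raters):
    ICC(3,k) = (MS_subjects - MS_error) / MS_subjects.  Negative estimates are
    reported as computed (they categorise as poor).  The matrix must be
    complete; reduce to complete cases first.
    """
    m = np.asarray(data, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 2 subjects, k >= 2 days")
    if not np.isfinite(m).all():
        raise ValueError("matrix has missing cells; reduce to complete cases "
                         "before computing the ICC")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows == 0:
        icc = 0.0
    else:
        icc = (ms_rows - ms_err) / ms_rows
    return IccResult(float(icc), n, k)


def icc_vs_days(daily: pd.DataFrame, feature_cols: list[str],
                d_grid=range(2, 15), group_col: str | None = None) -> pd.DataFrame:
    """ICC(3,d) per feature on the first d contiguous study days.

    ``daily`` is a tidy table with participant_id, day_index and feature
    columns.  Per feature and d, subjects with any missing value on days
    0..d-1 are dropped (complete-case on the day grid); points with fewer than
    2 complete subjects or d exceeding the available days are omitted.
    Returns rows (feature, group, d, n_subjects, icc, category).
    """
    frames = []
    if group_col is None:
        daily = daily.assign(_group="all")
        group_col = "_group"
    max_day = int(daily["day_index"].max())
    for group, sub in daily.groupby(group_col):
        for feat in feature_cols:
            wide = sub.pivot_table(index="participant_id", columns="day_index",
                                   values=feat, aggfunc="mean")
            for d in d_grid:
                if d - 1 > max_day:
                    log.debug("d=%d exceeds available days; omitted", d)
                    continue
                cols = [c for c in range(d) if c in wide.columns]
                if len(cols) < d:
                    continue
                block = wide[cols].dropna()
                n_dropped = wide.shape[0] - block.shape[0]
                if n_dropped:
                    log.debug("%s/%s d=%d: dropped %d incomplete subjects",
                              group, feat, d, n_dropped)
                if block.shape[0] < 2:
                    continue
                res = icc_3k(block.to_numpy())
                frames.append({"feature": feat, "group": group, "d": d,
                               "n_subjects": res.n_subjects, "icc": res.icc,
                               "category": res.category})
    return pd.DataFrame(frames)


# ---------------------------------------------------------------------------
# feature-table report
# ---------------------------------------------------------------------------

def univariate_feature_report(subject_features: pd.DataFrame, groups: pd.Series,
                              domain_map: dict[str, str] | None = None,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature group comparisons with BH correction.

    For each feature column: MWUT of HC vs all-RA and Kruskal-Wallis across
    the three groups; BH is applied per test family.  Zero-variance or
    all-missing features are skipped.
    """
    rows = []
    is_ra = groups != "HC"
    levels = [lv for lv in ("HC", "RA_mod", "RA_sev") if (groups == lv).any()]
    for feat in subject_features.columns:
        vals = subject_features[feat]
        ok = vals.notna()
        if ok.sum() < 6 or vals[ok].nunique() < 2:
            continue
        x = vals[ok & ~is_ra].to_numpy()
        y = vals[ok & is_ra].to_numpy()
        row = {"feature": feat,
               "domain": (domain_map or {}).get(feat, "")}
        if x.size and y.size:
            mw = mann_whitney_u(x, y)
            row["mwut_stat"] = mw.statistic
            row["mwut_p"] = mw.p_value
        gs = [vals[ok & (groups == lv)].to_numpy() for lv in levels]
        gs = [g for g in gs if g.size]
        if len(gs) >= 2:
            kw = kruskal_wallis(gs)
            row["kw_stat"] = kw.statistic
            row["kw_p"] = kw.p_value
            if all(g.size >= 2 for g in gs):
                bf = brown_forsythe(gs)
                row["bf_stat"] = bf.statistic
                row["bf_p"] = bf.p_value
        rows.append(row)
    report = pd.DataFrame(rows)
    for col in ("mwut_p", "kw_p"):
        if col in report and report[col].notna().any():
            mask = report[col].notna()
            rej, adj = benjamini_hochberg(report.loc[mask, col].to_numpy(), alpha)
            report.loc[mask, col + "_adj"] = adj
            sig_col = col.replace("_p", "_significant")
            report[sig_col] = False
            report.loc[mask, sig_col] = rej
            report[sig_col] = report[sig_col].astype(bool)
    return report
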