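"""Two-level group statistics for U-fibre tractometry.

Density level: per-tract streamline counts are residualized on age and
sex, group variances are compared with Bartlett's test, group means with
Welch's two-sided t-test (always Welch — no data-dependent test
switching), and per-tract p-values are corrected with Benjamini-Hochberg
FDR.  Total frontal density gets its own Welch test.

Along-tract level: each (tract, node) value is residualized on age and
sex across the pooled sample, compared node-wise with Welch's t, and the
family-wise error over all (tract, node) tests of one metric is
controlled by a permutation min-p procedure: group labels are permuted on
the residuals, the minimum p over the family is recorded per permutation,
and the significance threshold is the alpha-quantile of that null
minimum-p distribution.  Contiguous significant nodes merge into
segments, whose means feed Pearson correlations with clinical and
cognitive scores (BH-corrected across the whole correlation family).

Welch, Bartlett, BH and Pearson delegate to scipy/statsmodels; the
permutation machinery is vectorised here (all permutations at once via
matrix products, NaN-aware for subjects missing a tract).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import stdtr
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "PermutationResult",
    "AlongTractResult",
    "load_cohort_table",
    "design_matrix",
    "residualize",
    "bartlett_test",
    "welch_t",
    "bh_fdr",
    "pearson_r",
    "permutation_alpha",
    "compare_along_tract",
    "compare_densities",
    "clinical_correlation_table",
]

GROUP_CONTROL = "control"
GROUP_PATIENT = "patient"

#: Clinical and cognitive variables examined in the patient cohort.
CLINICAL_VARIABLES = (
    "panss8_total",
    "panss8_positive",
    "panss8_negative",
    "cgi_s",
    "sofas",
    "dup_months",
    "age_of_onset",
    "tmtb_time",
    "tmtb_errors",
    "category_fluency",
)


@dataclass(frozen=True)
class TestResult:
    """A single test: statistic (t, chi2 or r), p, df, optional adjusted p."""

    statistic: float
    p: float
    df: float
    p_adjusted: float | None = None


@dataclass
class PermutationResult:
    """Permutation min-p null distribution and the adjusted alpha threshold."""

    alpha_adjusted: float
    null_min_p: np.ndarray
    n_perm: int
    seed: int | None
    alpha: float = 0.05
    exhaustive: bool = False


# ---------------------------------------------------------------------------
# cohort table


def load_cohort_table(path) -> pd.DataFrame:
    """Read a cohort TSV (subject_id, group, age, sex, scores...), validated."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "group", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    bad = set(df["group"].unique()) - {GROUP_CONTROL, GROUP_PATIENT}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if df["group"].isna().any():
        raise ValueError("group must be non-missing")
    return df


def design_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Intercept + age + sex (M=0, F=1) design for covariate residualization."""
    sex01 = cohort["sex"].map({"M": 0.0, "F": 1.0, 0: 0.0, 1: 1.0})
    if sex01.isna().any():
        raise ValueError("sex must be coded M/F")
    return pd.DataFrame(
        {
            "intercept": np.ones(len(cohort)),
            "age": cohort["age"].astype(float).to_numpy(),
            "sex": sex01.to_numpy(),
        },
        index=cohort.index,
    )


def residualize(y: np.ndarray, design: pd.DataFrame | np.ndarray) -> np.ndarray:
    """OLS residuals of ``y`` on the pooled design (both groups, one fit).

    Rows where ``y`` is NaN are excluded from the fit and stay NaN in the
    output.  A rank-deficient design raises an error naming a collinear
    column.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(design, dtype=np.float64)
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=np.float64)
    if len(y) != len(X):
        raise ValueError("y and design have different lengths")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the first column whose removal restores full column rank
        for j in range(X.shape[1]):
            rest = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(X):
                raise ValueError(f"design is rank-deficient: column {names[j]!r} is collinear")
        raise ValueError("design is rank-deficient")
    ok = ~np.isnan(y)
    if ok.sum() < X.shape[1] + 2:
        raise ValueError("too few complete observations for residualization")
    beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    out = np.full_like(y, np.nan)
    out[ok] = y[ok] - X[ok] @ beta
    return out


def _residualize_matrix(Y: np.ndarray, design: pd.DataFrame) -> np.ndarray:
    """Column-wise residualization of a (subjects x tests) matrix."""
    out = np.full_like(Y, np.nan, dtype=np.float64)
    for j in range(Y.shape[1]):
        col = Y[:, j]
        if np.isnan(col).all():
            continue
        out[:, j] = residualize(col, design)
    return out


# ---------------------------------------------------------------------------
# elementary two-sample tests (scipy/statsmodels behind the module surface)


def bartlett_test(a, b) -> TestResult:
    """Two-group Bartlett test of equal variances, chi2(1) p-value."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0 or np.var(b, ddof=1) == 0:
        raise ValueError("zero variance sample: Bartlett test degenerate")
    stat, p = scipy.stats.bartlett(a, b)
    return TestResult(statistic=float(stat), p=float(p), df=1.0)


def _welch_df(va, na, vb, nb) -> float:
    num = (va / na + vb / nb) ** 2
    den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    return num / den


def welch_t(a, b) -> TestResult:
    """Welch's two-sided t-test (unequal variances); statistic is mean(a)-mean(b) scaled."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    df = getattr(res, "df", None)
    if df is None:
        df = _welch_df(np.var(a, ddof=1), len(a), np.var(b, ddof=1), len(b))
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue), df=float(df))


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with two-sided p via the t transform (n-2 df).

    Pairs with a missing value in either variable are dropped
    (pairwise-complete).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 pairwise-complete pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance input")
    res = scipy.stats.pearsonr(x, y)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue), df=float(len(x) - 2))


# ---------------------------------------------------------------------------
# vectorised Welch over a permutation stack


def _welch_p_stack(X: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch t, df, p for every (permutation, test) pair at once.

    X : (n_subjects, m_tests), NaN marks a subject missing that test.
    A : (K, n_subjects) boolean; True = group A (control) under that
        labelling.  Group B is the complement.

    Returns (t, df, p), each (K, m).  Tests with fewer than two valid
    subjects in either group get NaN p.  Sign convention: t > 0 when
    group A (control) exceeds group B (patient).
    """
    valid = ~np.isnan(X)
    Xz = np.nan_to_num(X)
    X2 = Xz * Xz
    Af = A.astype(np.float64)
    Bf = (~A).astype(np.float64)
    Vf = valid.astype(np.float64)

    na = Af @ Vf  # (K, m) valid counts per group
    nb = Bf @ Vf
    sa = Af @ Xz
    sb = Bf @ Xz
    qa = Af @ X2
    qb = Bf @ X2

    with np.errstate(invalid="ignore", divide="ignore"):
        ma = sa / na
        mb = sb / nb
        va = (qa - na * ma * ma) / (na - 1)
        vb = (qb - nb * mb * mb) / (nb - 1)
        va = np.clip(va, 0.0, None)  # guard tiny negatives from cancellation
        vb = np.clip(vb, 0.0, None)
        se2 = va / na + vb / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stdtr(df, -np.abs(t))
    bad = (na < 2) | (nb < 2) | ~np.isfinite(t)
    p = np.where(bad, np.nan, p)
    return t, df, p


def _permutation_masks(
    group_a: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Stack of permuted group-A membership masks.

    When the number of distinct label assignments C(n, n_a) is at most
    ``n_perm`` the permutation group is enumerated exactly; otherwise
    ``n_perm`` relabellings are sampled with replacement.
    """
    n = len(group_a)
    n_a = int(group_a.sum())
    total = comb(n, n_a)
    if total <= n_perm:
        log.info("enumerating all %d label assignments exactly", total)
        A = np.zeros((total, n), dtype=bool)
        for k, idx in enumerate(combinations(range(n), n_a)):
            A[k, list(idx)] = True
        return A, True
    A = np.zeros((n_perm, n), dtype=bool)
    for k in range(n_perm):
        idx = rng.permutation(n)[:n_a]
        A[k, idx] = True
    return A, False


def permutation_alpha(
    values: np.ndarray,
    groups,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PermutationResult:
    """Family-wise adjusted significance threshold by permutation min-p.

    ``values`` is a (subjects x tests) matrix of residualized node values
    covering the whole test family (all analyzed tracts' nodes for one
    metric); ``groups`` the per-subject group labels.  For every
    relabelling, Welch p-values are computed at each test and the family
    minimum recorded; the adjusted threshold is the alpha-quantile of
    that null minimum-p distribution.  Observed tests with
    p < alpha_adjusted are then significant.

    The result is between Bonferroni (alpha/m) and the uncorrected alpha,
    adapting to dependence between tests.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("values must be (subjects, tests)")
    group_a = _as_control_mask(groups)
    if group_a.sum() < 2 or (~group_a).sum() < 2:
        raise ValueError("need >= 2 subjects per group")
    if n_perm < 100:
        log.warning("n_perm=%d gives an unstable alpha quantile", n_perm)
    rng = np.random.default_rng(seed)
    A, exhaustive = _permutation_masks(group_a, n_perm, rng)
    _, _, p = _welch_p_stack(values, A)
    with np.errstate(all="ignore"):
        null_min_p = np.nanmin(np.where(np.isnan(p), 1.0, p), axis=1)
    alpha_adjusted = float(np.quantile(null_min_p, alpha))
    return PermutationResult(
        alpha_adjusted=alpha_adjusted,
        null_min_p=null_min_p,
        n_perm=len(A),
        seed=seed,
        alpha=alpha,
        exhaustive=exhaustive,
    )


def _as_control_mask(groups) -> np.ndarray:
    groups = np.asarray(groups)
    if groups.dtype == bool:
        return groups
    mask = groups == GROUP_CONTROL
    if not mask.any() or mask.all():
        raise ValueError("groups must contain both 'control' and 'patient'")
    return mask


# ---------------------------------------------------------------------------
# pipeline-level comparisons


@dataclass
class AlongTractResult:
    """Node-wise Welch tests for one metric with permutation FWER control.

    ``segments`` maps tract id to maximal runs of contiguous significant
    nodes as (start, stop) 0-based inclusive index pairs.
    """

    metric: str
    tract_ids: list[int]
    t: np.ndarray  # (n_tracts, n_nodes), control - patient sign
    p: np.ndarray
    df: np.ndarray
    permutation: PermutationResult
    segments: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def significant(self) -> np.ndarray:
        return self.p < self.permutation.alpha_adjusted

    def to_frame(self) -> pd.DataFrame:
        recs = []
        sig = self.significant
        for ti, tid in enumerate(self.tract_ids):
            for node in range(self.p.shape[1]):
                recs.append(
                    (
                        self.metric,
                        tid,
                        node + 1,
                        self.t[ti, node],
                        self.df[ti, node],
                        self.p[ti, node],
                        bool(sig[ti, node]),
                    )
                )
        return pd.DataFrame(
            recs, columns=["metric", "tract_id", "node", "t", "df", "p", "significant"]
        )


def _runs(flags: np.ndarray, min_run: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) inclusive, runs < min_run dropped."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return [(a, b) for a, b in runs if b - a + 1 >= min_run]


def compare_along_tract(
    matrix,
    cohort: pd.DataFrame,
    metric: str,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    min_run: int = 1,
) -> AlongTractResult:
    """Along-tract group comparison for one metric with FWER correction.

    Every (tract, node) value is residualized on age and sex across the
    pooled cohort, compared with Welch's t (control minus patient), and
    thresholded at the permutation-adjusted alpha computed over the whole
    (tract x node) family of this metric.  Subjects missing a tract are
    excluded pairwise for that tract's tests.
    """
    slab = matrix.metric_slab(metric)  # (n_subj, T, nodes)
    n_subj, n_tracts, n_nodes = slab.shape
    if list(cohort["subject_id"]) != list(matrix.subject_ids):
        cohort = cohort.set_index("subject_id").loc[matrix.subject_ids].reset_index()
    design = design_matrix(cohort)
    groups = cohort["group"].to_numpy()

    Y = slab.reshape(n_subj, n_tracts * n_nodes)
    R = _residualize_matrix(Y, design)
    perm = permutation_alpha(R, groups, n_perm=n_perm, alpha=alpha, seed=seed)

    obs_mask = _as_control_mask(groups)[None, :]
    t, df, p = _welch_p_stack(R, obs_mask)
    t = t.reshape(n_tracts, n_nodes)
    df = df.reshape(n_tracts, n_nodes)
    p = np.where(np.isnan(p), 1.0, p).reshape(n_tracts, n_nodes)

    sig = p < perm.alpha_adjusted
    segments = {}
    for ti, tid in enumerate(matrix.tract_ids):
        runs = _runs(sig[ti], min_run=min_run)
        if runs:
            segments[tid] = runs
    return AlongTractResult(
        metric=metric,
        tract_ids=list(matrix.tract_ids),
        t=t,
        p=p,
        df=df,
        permutation=perm,
        segments=segments,
    )


def compare_densities(
    densities: pd.DataFrame, cohort: pd.DataFrame, q: float = 0.05
) -> tuple[pd.DataFrame, TestResult]:
    """Group comparison of per-tract and total streamline densities.

    ``densities`` is subjects x tracts (index = subject_id, columns =
    tract ids).  Each tract's density is residualized on age and sex;
    Bartlett's variance test is reported alongside Welch's t (always
    used), and BH-FDR corrects across tracts.  The per-subject total
    density over all tracts gets a separate Welch test (no correction).
    """
    cohort = cohort.set_index("subject_id").loc[densities.index].reset_index()
    design = design_matrix(cohort)
    ctrl = _as_control_mask(cohort["group"].to_numpy())

    rows = []
    for tract in densities.columns:
        y = densities[tract].to_numpy(dtype=np.float64)
        r = residualize(y, design)
        a, b = r[ctrl], r[~ctrl]
        try:
            bart = bartlett_test(a[~np.isnan(a)], b[~np.isnan(b)])
            bart_stat, bart_p = bart.statistic, bart.p
        except ValueError:
            bart_stat, bart_p = np.nan, np.nan
        w = welch_t(a, b)
        rows.append((tract, bart_stat, bart_p, w.statistic, w.df, w.p))
    table = pd.DataFrame(
        rows, columns=["tract_id", "bartlett_stat", "bartlett_p", "t", "df", "p"]
    )
    p_adj, reject = bh_fdr(table["p"].to_numpy(), q=q)
    table["p_adjusted"] = p_adj
    table["reject"] = reject

    total = densities.sum(axis=1).to_numpy(dtype=np.float64)
    r_tot = residualize(total, design)
    total_res = welch_t(r_tot[ctrl], r_tot[~ctrl])
    return table, total_res


def clinical_correlation_table(
    segment_means: pd.DataFrame,
    cohort: pd.DataFrame,
    variables=CLINICAL_VARIABLES,
    q: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations of segment means with clinical/cognitive scores.

    ``segment_means`` is long format with columns (subject, tract_id,
    metric, value), one row per patient per (tract, metric) cell that had
    a significant segment — cells without segments are simply absent,
    mirroring how metrics with no detected segment are not correlated.
    Patients only; pairwise-complete; BH across the full table family.
    """
    patients = cohort[cohort["group"] == GROUP_PATIENT].set_index("subject_id")
    rows = []
    for (tract_id, metric), cell in segment_means.groupby(["tract_id", "metric"], sort=True):
        cell = cell.set_index("subject")
        for var in variables:
            if var not in patients.columns:
                continue
            joined = cell.join(patients[[var]], how="inner")
            x = joined["value"].to_numpy(dtype=np.float64)
            y = joined[var].to_numpy(dtype=np.float64)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or np.var(x[ok]) == 0 or np.var(y[ok]) == 0:
                log.warning("correlation cell (%s, %s, %s) has insufficient pairs",
                            tract_id, metric, var)
                rows.append((tract_id, metric, var, int(ok.sum()), np.nan, np.nan))
                continue
            res = pearson_r(x, y)
            rows.append((tract_id, metric, var, int(ok.sum()), res.statistic, res.p))
    table = pd.DataFrame(rows, columns=["tract_id", "metric", "variable", "n", "r", "p"])
    table["p_adjusted"] = np.nan
    ok = table["p"].notna()
    if ok.any():
        p_adj, _ = bh_fdr(table.loc[ok, "p"].to_numpy(), q=q)
        table.loc[ok, "p_adjusted"] = p_adj
    return table
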