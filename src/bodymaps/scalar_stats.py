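"""Scalar and repeated-measures statistics.

Covers the group-comparison toolbox used around the pixel maps:
percentile-based group assignment, two-sample tests (from raw data or from
printed summary statistics) with Cohen's d, chi-square and Spearman
helpers, and a split-plot (between x within) mixed ANOVA with Mauchly's
sphericity test and the Greenhouse–Geisser degrees-of-freedom correction.

The mixed ANOVA is implemented directly from the classical sums-of-squares
decomposition: the between-groups effect is tested against the
subjects-within-groups mean square, the within effect and the interaction
against the subject-by-level residual. When Mauchly's test rejects
sphericity (p < 0.05) both degrees of freedom of the within-level effects
are multiplied by the Greenhouse–Geisser epsilon estimated from the
eigenvalues of the contrast-transformed pooled covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SummaryTestResult:
    """A two-sample (or contingency) test result.

    ``t`` holds the test statistic: the t value for t-tests, U for
    Mann-Whitney, chi-square for contingency tests.
    """

    t: float
    df: float
    p: float
    cohens_d: float
    method: str  # pooled | welch | mann_whitney | chi_square
    degenerate: bool = False


@dataclass
class AnovaEffect:
    """One effect line of a mixed ANOVA.

    ``df_num``/``df_den`` are the degrees of freedom actually used for the
    p-value (Greenhouse-Geisser corrected when the correction fired);
    ``gg_epsilon`` is 1 for between-subject effects.
    """

    name: str
    df_num: float
    df_den: float
    F: float
    p: float
    eta_sq: float
    gg_epsilon: float
    sphericity_p: float  # NaN when not applicable
    ss: float = float("nan")


def percentile_group_assign(
    scores,
    low_pct: float = 33.0,
    high_pct: float = 66.0,
    method: str = "nearest_rank",
) -> np.ndarray:
    """Split scores into ``low`` / ``middle`` / ``high`` by percentiles.

    The low group is the bottom ``low_pct`` percentile block (scores at or
    below the nearest-rank ``low_pct`` quantile); the high group is the
    complement of the bottom ``high_pct`` block (scores at or above the
    next order statistic past the nearest-rank ``high_pct`` quantile).
    Ties at either cutoff value are included in the extreme groups, so the
    extreme groups can exceed a third of the sample — the behaviour that
    makes an integer score distribution with 33rd percentile 4 and 66th
    percentile 7 reproduce a "<= 4 vs >= 7" grouping.

    ``method="linear"`` instead takes both cutoffs from the linearly
    interpolated empirical quantile.

    Scores for which the low and high conditions both hold (possible only
    when the two cutoffs collapse, e.g. all scores equal) are assigned to
    ``middle`` with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 3:
        raise ValueError("need at least 3 scores")
    if low_pct >= high_pct:
        raise ValueError("low_pct must be < high_pct")
    s = np.sort(scores)
    if method == "nearest_rank":
        k_low = max(int(np.ceil(low_pct / 100.0 * n)), 1)
        cutoff_low = s[k_low - 1]
        k_high = int(np.ceil(high_pct / 100.0 * n))  # 0-based index of next rank
        cutoff_high = s[k_high] if k_high < n else np.inf
    elif method == "linear":
        cutoff_low = float(np.percentile(scores, low_pct))
        cutoff_high = float(np.percentile(scores, high_pct))
    else:
        raise ValueError(f"unknown quantile method '{method}'")
    is_low = scores <= cutoff_low
    is_high = scores >= cutoff_high
    ambiguous = is_low & is_high
    if ambiguous.any():
        warnings.warn(
            "low and high cutoffs overlap; ambiguous scores assigned to 'middle'",
            stacklevel=2,
        )
    labels = np.full(n, "middle", dtype=object)
    labels[is_low & ~ambiguous] = "low"
    labels[is_high & ~ambiguous] = "high"
    return labels


def two_sample_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> SummaryTestResult:
    """Pooled-variance t-test and Cohen's d from printed summary statistics.

    ``s = sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2))``;
    ``t = (m1-m2) / (s sqrt(1/n1 + 1/n2))``; ``d = (m1-m2)/s``; two-sided
    p with ``n1+n2-2`` degrees of freedom.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    s = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    if s == 0:
        degenerate = m1 != m2
        t = np.inf * np.sign(m1 - m2) if degenerate else 0.0
        d = np.inf * np.sign(m1 - m2) if degenerate else 0.0
        p = 0.0 if degenerate else 1.0
        return SummaryTestResult(t=t, df=df, p=p, cohens_d=d, method="pooled",
                                 degenerate=degenerate)
    t = (m1 - m2) / (s * np.sqrt(1.0 / n1 + 1.0 / n2))
    d = (m1 - m2) / s
    p = 2.0 * stats.t.sf(abs(t), df)
    return SummaryTestResult(t=float(t), df=float(df), p=float(p), cohens_d=float(d),
                             method="pooled")


def two_sample_from_raw(x, y, method: str = "pooled") -> SummaryTestResult:
    """Two-sample test on raw samples.

    ``pooled`` and ``welch`` run Student/Welch t-tests; ``mann_whitney``
    runs the Mann-Whitney U test with the normal approximation (the U
    statistic is returned in the ``t`` field and ``df`` is NaN). Cohen's d
    is always the pooled-SD standardized mean difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    n1, n2 = x.size, y.size
    df_pooled = n1 + n2 - 2
    sp = np.sqrt(
        ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df_pooled
    )
    d = float((x.mean() - y.mean()) / sp) if sp > 0 else 0.0
    if method == "pooled":
        res = stats.ttest_ind(x, y, equal_var=True)
        return SummaryTestResult(t=float(res.statistic), df=float(df_pooled),
                                 p=float(res.pvalue), cohens_d=d, method="pooled")
    if method == "welch":
        res = stats.ttest_ind(x, y, equal_var=False)
        return SummaryTestResult(t=float(res.statistic), df=float(res.df),
                                 p=float(res.pvalue), cohens_d=d, method="welch")
    if method == "mann_whitney":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return SummaryTestResult(t=float(res.statistic), df=float("nan"),
                                 p=float(res.pvalue), cohens_d=d, method="mann_whitney")
    raise ValueError(f"unknown method '{method}'")


def chi_square_contingency(table) -> SummaryTestResult:
    """Pearson chi-square on a contingency table, no continuity correction.

    The chi-square statistic is returned in the ``t`` field with
    ``df = (r-1)(c-1)``.
    """
    table = np.asarray(table)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)) or (table < 0).any():
            raise ValueError("table must hold nonnegative integer counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return SummaryTestResult(t=float(chi2), df=float(df), p=float(p),
                             cohens_d=float("nan"), method="chi_square")


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties, t-approximation p).

    A constant input vector leaves the correlation undefined: returns
    ``(nan, nan)`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """A (k-1) x k orthonormal basis orthogonal to the unit vector."""
    center = np.eye(k) - np.full((k, k), 1.0 / k)
    _u, s, vt = np.linalg.svd(center)
    return vt[: k - 1]


@dataclass
class MixedAnovaResult:
    """Effects plus the sphericity diagnostics of one mixed ANOVA."""

    effects: list[AnovaEffect]
    n_subjects: int
    n_dropped_incomplete: int
    mauchly_w: float
    sphericity_p: float
    gg_epsilon: float
    gg_applied: bool

    def __iter__(self):
        return iter(self.effects)

    def __getitem__(self, name: str) -> AnovaEffect:
        for eff in self.effects:
            if eff.name == name:
                return eff
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": e.name,
                    "df_num": e.df_num,
                    "df_den": e.df_den,
                    "F": e.F,
                    "p": e.p,
                    "eta_sq": e.eta_sq,
                    "epsilon": e.gg_epsilon,
                    "sphericity_p": e.sphericity_p,
                    "ss": e.ss,
                }
                for e in self.effects
            ]
        )


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str,
    sphericity_alpha: float = 0.05,
    eta: str = "classical",
) -> MixedAnovaResult:
    """Split-plot mixed ANOVA: one between-subject and one within factor.

    Parameters
    ----------
    data
        Long-format table; one row per subject x within-level.
    dv, within, subject, between
        Column names. Subjects missing any within level are dropped
        listwise (counted in the result).
    sphericity_alpha
        Mauchly gate: the Greenhouse-Geisser correction is applied to the
        within and interaction effects when Mauchly's p falls below this.
    eta
        ``classical`` (SS_effect / SS_total) or ``partial``.

    Returns
    -------
    MixedAnovaResult
        Effects named after the factors: between, within, and
        ``"{between} * {within}"``.
    """
    if eta not in ("classical", "partial"):
        raise ValueError("eta must be 'classical' or 'partial'")
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    complete = wide.dropna(axis=0)
    n_dropped = len(wide) - len(complete)
    groups = (
        data.drop_duplicates(subject).set_index(subject)[between].reindex(complete.index)
    )
    levels = list(complete.columns)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 within levels")
    glabels = sorted(groups.unique())
    g = len(glabels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError("each group needs at least 2 complete subjects")
    Y = complete.to_numpy(dtype=float)
    N = Y.shape[0]
    gm = Y.mean()
    ss_total = float(((Y - gm) ** 2).sum())
    subj_means = Y.mean(axis=1)
    ss_between_subj = k * float(((subj_means - gm) ** 2).sum())
    group_idx = {lab: np.flatnonzero(groups.to_numpy() == lab) for lab in glabels}
    ss_group = k * sum(
        len(idx) * (subj_means[idx].mean() - gm) ** 2 for lab, idx in group_idx.items()
    )
    ss_subj_within = ss_between_subj - ss_group
    level_means = Y.mean(axis=0)
    ss_level = N * float(((level_means - gm) ** 2).sum())
    ss_cells = sum(
        len(idx) * float(((Y[idx].mean(axis=0) - gm) ** 2).sum())
        for lab, idx in group_idx.items()
    )
    ss_inter = ss_cells - ss_group - ss_level
    ss_err_within = ss_total - ss_between_subj - ss_level - ss_inter

    df_group = g - 1
    df_subj = N - g
    df_level = k - 1
    df_inter = (g - 1) * (k - 1)
    df_err = (N - g) * (k - 1)

    # pooled within-group covariance of the level vectors
    S = np.zeros((k, k))
    for lab, idx in group_idx.items():
        resid = Y[idx] - Y[idx].mean(axis=0)
        S += resid.T @ resid
    S /= max(N - g, 1)
    C = _orthonormal_contrasts(k)
    T = C @ S @ C.T
    lam = np.clip(np.linalg.eigvalsh(T), 0.0, None)
    tr = lam.sum()
    if tr <= 0:
        eps = 1.0
        mauchly_w = float("nan")
        sphericity_p = float("nan")
    else:
        eps = float(tr**2 / ((k - 1) * (lam**2).sum()))
        eps = min(max(eps, 1.0 / (k - 1)), 1.0)
        if k == 2:
            mauchly_w = 1.0
            sphericity_p = float("nan")
        else:
            with np.errstate(divide="ignore"):
                logw = float(np.sum(np.log(np.clip(lam, 1e-300, None))) - (k - 1) * np.log(tr / (k - 1)))
            mauchly_w = float(np.exp(logw))
            dcorr = 1.0 - (2.0 * (k - 1) ** 2 + (k - 1) + 2.0) / (6.0 * (k - 1) * (N - g))
            chi2 = -(N - g) * dcorr * logw
            df_m = k * (k - 1) // 2 - 1
            sphericity_p = float(stats.chi2.sf(max(chi2, 0.0), df_m))
    if k == 2:
        eps = 1.0  # epsilon is exactly 1 with two within levels

    gg_applied = k >= 3 and np.isfinite(sphericity_p) and sphericity_p < sphericity_alpha

    ms_group = ss_group / df_group
    ms_subj = ss_subj_within / df_subj
    ms_level = ss_level / df_level
    ms_inter = ss_inter / df_inter
    ms_err = ss_err_within / df_err

    def _eta(ss_eff: float, ss_err: float) -> float:
        if eta == "classical":
            return ss_eff / ss_total if ss_total > 0 else float("nan")
        return ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else float("nan")

    def _f_p(ms_eff, ms_error, d1, d2, corr):
        F = ms_eff / ms_error if ms_error > 0 else (0.0 if ms_eff == 0 else float("inf"))
        d1c, d2c = d1 * corr, d2 * corr
        p = float(stats.f.sf(F, d1c, d2c)) if np.isfinite(F) else 0.0
        return float(F), d1c, d2c, p

    corr_w = eps if gg_applied else 1.0
    F_g, d1_g, d2_g, p_g = _f_p(ms_group, ms_subj, df_group, df_subj, 1.0)
    F_l, d1_l, d2_l, p_l = _f_p(ms_level, ms_err, df_level, df_err, corr_w)
    F_i, d1_i, d2_i, p_i = _f_p(ms_inter, ms_err, df_inter, df_err, corr_w)

    effects = [
        AnovaEffect(name=between, df_num=d1_g, df_den=d2_g, F=F_g, p=p_g,
                    eta_sq=_eta(ss_group, ss_subj_within), gg_epsilon=1.0,
                    sphericity_p=float("nan"), ss=ss_group),
        AnovaEffect(name=within, df_num=d1_l, df_den=d2_l, F=F_l, p=p_l,
                    eta_sq=_eta(ss_level, ss_err_within), gg_epsilon=eps,
                    sphericity_p=sphericity_p, ss=ss_level),
        AnovaEffect(name=f"{between} * {within}", df_num=d1_i, df_den=d2_i, F=F_i,
                    p=p_i, eta_sq=_eta(ss_inter, ss_err_within), gg_epsilon=eps,
                    sphericity_p=sphericity_p, ss=ss_inter),
    ]
    return MixedAnovaResult(
        effects=effects,
        n_subjects=N,
        n_dropped_incomplete=n_dropped,
        mauchly_w=mauchly_w,
        sphericity_p=sphericity_p,
        gg_epsilon=eps,
        gg_applied=bool(gg_applied),
    )
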