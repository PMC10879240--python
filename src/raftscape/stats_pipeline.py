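"""Group statistics for lipid cohorts.

The battery mirrors what small-n lipid raft studies report: per-variable
Mann-Whitney U tests with Cohen's d effect sizes and confidence
intervals (the forest plot), varimax-rotated PCA lipid signatures with a
one-way ANOVA on factor scores, group-wise Pearson correlation / R^2
heatmaps with a between-group correlation-difference effect size, and
homogeneity-of-slopes regression (ANCOVA interaction F) for bivariate
lipid relationships.

Sign conventions
----------------
Cohen's d is computed as reference-group mean minus contrast-group mean
(NSL minus ALS by default), so a variable that *decreases* with disease
plots a *positive* d.  Percent change is reported the other way round,
100*(contrast/reference - 1).  All p-values are two-sided, and no
multiple-testing correction is applied by default (a Benjamini-Hochberg
option exists on the forest table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.multivariate.factor_rotation import rotate_factors
from statsmodels.stats.multitest import multipletests

from .lipid_core import SubjectRecord, index_frame

__all__ = [
    "EffectSizeResult",
    "PCAResult",
    "CorrelationHeatmap",
    "RegressionResult",
    "SlopeComparison",
    "mann_whitney",
    "cohens_d",
    "cohens_f2",
    "pca_signature",
    "correlation_heatmap",
    "simple_regression",
    "compare_slopes",
    "forest_table",
    "LARGE_EFFECT_THRESHOLD",
]

#: conventional |d| threshold for a large effect (forest-plot dashed lines)
LARGE_EFFECT_THRESHOLD = 0.8

#: largest n1+n2 for which the exact Mann-Whitney null is used (no ties)
_EXACT_MAX_N = 12


@dataclass
class EffectSizeResult:
    token: str
    d: float
    ci_low: float
    ci_high: float
    u_stat: float
    p_value: float
    pct_change: float = float("nan")
    large_effect: bool = False
    method: str = ""
    undefined: bool = False


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables x components, rotated
    variance_fraction: np.ndarray  # per retained component, pre-rotation order
    scores: pd.DataFrame  # subjects x components
    anova_f: np.ndarray
    anova_p: np.ndarray
    eigenvalues: np.ndarray  # all eigenvalues of the correlation matrix
    dropped: tuple[str, ...] = ()


@dataclass
class CorrelationHeatmap:
    r: dict[str, pd.DataFrame]  # per-group Pearson r, rows x cols
    r_squared: dict[str, pd.DataFrame]
    difference_q: pd.DataFrame  # Cohen's q = |z(r1) - z(r2)|
    groups: tuple[str, str]


@dataclass
class RegressionResult:
    beta: float
    intercept: float
    r_squared: float
    f_squared: float
    p_value: float


@dataclass
class SlopeComparison:
    beta_by_group: dict[str, float]
    intercept_by_group: dict[str, float]
    f_stat: float
    p_value: float
    df: tuple[int, int]


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test; returns (U_x, p, method).

    Uses the exact permutation null when the pooled sample is small
    (n1+n2 <= 12) and tie-free, otherwise the normal approximation with
    tie and continuity corrections.  Two identical samples are reported
    as p = 1 with a warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both samples; p set to 1", stacklevel=2)
        return len(x) * len(y) / 2.0, 1.0, "degenerate"
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= _EXACT_MAX_N and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "asymptotic"
    return float(res.statistic), float(min(res.pvalue, 1.0)), method


def cohens_d(x: Sequence[float], y: Sequence[float], token: str = "") -> EffectSizeResult:
    """Cohen's d = (mean_x - mean_y)/s_pooled with a normal-approximation CI.

    The pooled standard deviation uses the Bessel-corrected pooled
    variance.  SE(d) = sqrt((n1+n2)/(n1 n2) + d^2/(2(n1+n2))), the common
    large-sample approximation; the 95% CI is d +- 1.96 SE.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        return EffectSizeResult(
            token=token, d=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            u_stat=float("nan"), p_value=float("nan"), undefined=True,
            method="zero pooled sd",
        )
    d = float((x.mean() - y.mean()) / np.sqrt(sp2))
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    return EffectSizeResult(
        token=token, d=d, ci_low=d - 1.959963984540054 * se,
        ci_high=d + 1.959963984540054 * se, u_stat=float("nan"), p_value=float("nan"),
        large_effect=abs(d) > LARGE_EFFECT_THRESHOLD, method="pooled-sd",
    )


def cohens_f2(r_squared: float) -> float:
    """Cohen's f^2 = R^2 / (1 - R^2); infinite at R^2 = 1."""
    if not (0.0 <= r_squared <= 1.0):
        raise ValueError(f"R^2 must lie in [0, 1], got {r_squared}")
    if r_squared == 1.0:
        return float("inf")
    return r_squared / (1.0 - r_squared)


def _varimax_sorted(loadings: np.ndarray) -> np.ndarray:
    """Varimax-rotate retained loadings; orient columns to positive net sign."""
    if loadings.shape[1] < 2:
        rotated = loadings.copy()
    else:
        rotated, _ = rotate_factors(loadings, "varimax")
    # sign convention: each component's largest-|loading| variable positive
    for j in range(rotated.shape[1]):
        i = np.argmax(np.abs(rotated[:, j]))
        if rotated[i, j] < 0:
            rotated[:, j] = -rotated[:, j]
    return rotated


def pca_signature(
    matrix: pd.DataFrame,
    groups: Sequence[str],
    n_components: int = 2,
) -> PCAResult:
    """Rotated-PCA lipid signature with per-component group ANOVA.

    Columns are z-scored and the correlation matrix eigendecomposed, so
    variables on very different percentage scales contribute equally.
    The retained loadings (eigenvector x sqrt(eigenvalue)) are varimax
    rotated; subject scores use the regression method (Z R^-1 Lambda);
    each score column is tested for group differences by one-way ANOVA.
    Constant columns are dropped with a warning.
    """
    if len(matrix) < 3:
        raise ValueError("PCA needs at least 3 subjects")
    X = matrix.astype(float)
    sd = X.std(ddof=1)
    dropped = tuple(sd.index[sd == 0])
    if dropped:
        warnings.warn(f"dropping constant variables: {list(dropped)}", stacklevel=2)
        X = X.drop(columns=list(dropped))
    Z = (X - X.mean()) / X.std(ddof=1)
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = np.clip(w[order], 0.0, None), V[:, order]
    k = min(n_components, Z.shape[1])
    load_unrot = V[:, :k] * np.sqrt(w[:k])
    loadings = _varimax_sorted(load_unrot)
    # regression-method factor scores on the rotated structure
    R_inv = np.linalg.pinv(R)
    scores = Z.to_numpy() @ R_inv @ loadings
    scores -= scores.mean(axis=0, keepdims=True)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    groups = np.asarray(groups)
    fs, ps = [], []
    for j in range(k):
        samples = [scores[groups == g, j] for g in np.unique(groups)]
        f, p = sps.f_oneway(*samples)
        fs.append(float(f))
        ps.append(float(p))
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=X.columns, columns=comp_names),
        variance_fraction=w[:k] / w.sum(),
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        anova_f=np.array(fs),
        anova_p=np.array(ps),
        eigenvalues=w,
        dropped=dropped,
    )


def _fisher_z(r: float) -> float:
    r = np.clip(r, -0.999999, 0.999999)
    return float(np.arctanh(r))


def correlation_heatmap(
    records: Sequence[SubjectRecord],
    row_vars: Sequence[str],
    col_vars: Sequence[str],
    value_frame: pd.DataFrame | None = None,
) -> CorrelationHeatmap:
    """Per-group Pearson r / R^2 for each (row, col) pair, plus Cohen's q.

    Variables are resolved against the flat per-subject table (raw tokens
    and derived indexes).  The between-group difference effect size is
    Cohen's q = |arctanh(r1) - arctanh(r2)| per cell.  Zero-variance
    variables yield NaN cells rather than an error.
    """
    df = value_frame if value_frame is not None else subject_table(records)
    labels = sorted(df["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    for g in labels:
        if (df["group"] == g).sum() < 3:
            raise ValueError(f"group {g}: need at least 3 subjects")
    r_by_group: dict[str, pd.DataFrame] = {}
    for g in labels:
        sub = df[df["group"] == g]
        mat = np.full((len(row_vars), len(col_vars)), np.nan)
        for i, rv in enumerate(row_vars):
            for j, cv in enumerate(col_vars):
                a = sub[rv].to_numpy(dtype=float)
                b = sub[cv].to_numpy(dtype=float)
                if a.std() == 0 or b.std() == 0:
                    continue
                mat[i, j] = sps.pearsonr(a, b).statistic
        r_by_group[g] = pd.DataFrame(mat, index=row_vars, columns=col_vars)
    q = np.abs(
        np.vectorize(_fisher_z)(r_by_group[labels[0]].to_numpy())
        - np.vectorize(_fisher_z)(r_by_group[labels[1]].to_numpy())
    )
    return CorrelationHeatmap(
        r=r_by_group,
        r_squared={g: m**2 for g, m in r_by_group.items()},
        difference_q=pd.DataFrame(q, index=row_vars, columns=col_vars),
        groups=(labels[0], labels[1]),
    )


def simple_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of y on x with R^2 and Cohen's f^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = float(fit.rsquared)
    return RegressionResult(
        beta=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=r2,
        f_squared=cohens_f2(min(r2, 1.0)),
        p_value=float(fit.pvalues[1]),
    )


def compare_slopes(
    x: Sequence[float], y: Sequence[float], groups: Sequence[str]
) -> SlopeComparison:
    """Homogeneity-of-slopes test (ANCOVA interaction).

    Fits the pooled two-slope model y ~ x * group and tests the
    group-by-x interaction with an F test on 1 and n-4 degrees of
    freedom; per-group OLS slopes and intercepts are reported alongside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(np.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    betas, intercepts = {}, {}
    for g in labels:
        xs, ys = x[groups == g], y[groups == g]
        if len(xs) < 3:
            raise ValueError(f"group {g}: need at least 3 subjects")
        if xs.std() == 0:
            raise ValueError(f"group {g}: x has no variance (singular design)")
        fit_g = sm.OLS(ys, sm.add_constant(xs)).fit()
        intercepts[g], betas[g] = float(fit_g.params[0]), float(fit_g.params[1])
    ind = (groups == labels[1]).astype(float)
    X = np.column_stack([np.ones_like(x), x, ind, x * ind])
    fit = sm.OLS(y, X).fit()
    # F for the interaction column: square of its t statistic, df (1, n-4)
    f_stat = float(fit.tvalues[3] ** 2)
    p = float(fit.pvalues[3])
    return SlopeComparison(
        beta_by_group=betas,
        intercept_by_group=intercepts,
        f_stat=f_stat,
        p_value=p,
        df=(1, len(x) - 4),
    )


def subject_table(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flat per-subject table: group, raw tokens and derived indexes."""
    records = list(records)
    rows = []
    for r in records:
        row: dict[str, float | str] = {"group": r.group}
        row.update(r.fatty_acids.values)
        row.update(r.lipid_classes.values)
        row.update(r.indexes().as_dict())
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index([r.subject_id for r in records], name="subject_id"))


def forest_table(
    records: Sequence[SubjectRecord],
    tokens: Sequence[str] | None = None,
    reference: str = "NSL",
    contrast: str = "ALS",
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-variable effect-size table (the forest plot's data).

    For every token: Cohen's d (reference minus contrast) with its 95%
    CI, Mann-Whitney U and two-sided p, percent change of the contrast
    group relative to the reference, and a large-effect flag at |d| > 0.8.
    ``fdr=True`` appends Benjamini-Hochberg adjusted p-values (off by
    default; the raw per-variable p-values are the primary output).
    """
    df = subject_table(records)
    present = set(df["group"])
    if not {reference, contrast} <= present:
        raise ValueError(f"need groups {reference!r} and {contrast!r}, found {sorted(present)}")
    if tokens is None:
        tokens = [c for c in df.columns if c != "group"]
    ref_df = df[df["group"] == reference]
    con_df = df[df["group"] == contrast]
    rows = []
    for tok in tokens:
        xr = ref_df[tok].to_numpy(dtype=float)
        xc = con_df[tok].to_numpy(dtype=float)
        es = cohens_d(xr, xc, token=tok)
        if not es.undefined:
            u, p, method = mann_whitney(xr, xc)
            es.u_stat, es.p_value, es.method = u, p, f"{es.method}+{method}"
        mr = xr.mean()
        es.pct_change = 100.0 * (xc.mean() / mr - 1.0) if mr != 0 else float("nan")
        rows.append(
            {
                "token": tok, "d": es.d, "ci_low": es.ci_low, "ci_high": es.ci_high,
                "u_stat": es.u_stat, "p_value": es.p_value, "pct_change": es.pct_change,
                "large_effect": es.large_effect, "method": es.method,
            }
        )
    out = pd.DataFrame(rows).set_index("token")
    if fdr:
        mask = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(out.loc[mask, "p_value"], method="fdr_bh")[1]
        out["p_adjusted"] = adj
    return out
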