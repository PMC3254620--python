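"""Statistical primitives shared by the phalanx and foot analyses.

The centrepiece is the single-specimen t-test (Sokal & Rohlf's special case
of the two-sample t-test in which one individual is compared with a sample):

    t = (x - xbar) / ( s * sqrt((n + 1) / n) ),    df = n - 1

which lets a fossil be placed against a published group mean/variance/n
without access to the raw comparative data.  Around it sit the supporting
battery: Welch's unequal-variance t, a Tamhane-T2-style pairwise comparison
(pairwise Welch t with Satterthwaite df and Sidak multiplicity), one-way
ANOVA, Hotelling's pairwise T-squared, an overall MANOVA, and the Bonferroni
alpha adjustment.
"""

from __future__ import annotations

import itertools
import warnings
import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateBaselineError,
    InsufficientDataError,
    SingularCovarianceError,
)
from .records import GroupSummary

__all__ = [
    "single_specimen_t",
    "bonferroni",
    "welch_t",
    "anova_oneway",
    "tamhane_t2",
    "hotelling_t2",
    "manova_pairwise",
]


def single_specimen_t(
    x: float, baseline: GroupSummary | tuple[float, float, int]
) -> tuple[float, int, float]:
    """Compare one observation ``x`` with a sample summarised by ``baseline``.

    Parameters
    ----------
    x : float
        The single specimen's value.
    baseline : GroupSummary or (mean, variance, n)
        Reference-sample summary.  ``n >= 2`` and ``variance > 0`` required.

    Returns
    -------
    (t, df, p) : the t statistic, ``n - 1`` degrees of freedom, and the
    two-tailed p-value.

    Notes
    -----
    As ``n`` grows the statistic converges to the z-score ``(x - mean)/sd``.
    """
    if isinstance(baseline, GroupSummary):
        mean, variance, n = baseline.mean, baseline.variance, baseline.n
    else:
        mean, variance, n = baseline
    if n < 2:
        raise DegenerateBaselineError(f"baseline n must be >= 2, got {n}")
    if variance <= 0:
        raise DegenerateBaselineError(f"baseline variance must be > 0, got {variance}")
    df = int(n) - 1
    t = (x - mean) / (np.sqrt(variance) * np.sqrt((n + 1.0) / n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-comparison alpha for ``m`` comparisons."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t-test (unequal variances, Satterthwaite df).

    Returns ``(t, df, p)`` with a two-tailed p-value.  Reduces to the pooled
    t when variances and sample sizes are equal.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs >= 2 observations")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def anova_oneway(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA across named groups; returns ``(F, p)``."""
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 groups")
    arrays = []
    for name, g in groups.items():
        g = np.asarray(g, dtype=float)
        if g.size < 2:
            raise InsufficientDataError(f"group {name!r} has fewer than 2 observations")
        arrays.append(g)
    F, p = sps.f_oneway(*arrays)
    return float(F), float(p)


def tamhane_t2(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tamhane-T2-style post hoc battery over all group pairs.

    Realised as pairwise Welch t-tests with Satterthwaite degrees of freedom
    and a Sidak multiplicity adjustment over the ``k(k-1)/2`` pairs
    (``p_adj = 1 - (1 - p)**m``).  Software implementations of Tamhane's T2
    differ in the exact multiplicity multiplier; the Sidak form is used here
    because it is the standard conservative choice for unequal variances.

    Returns a DataFrame with one row per pair: ``group1, group2, t, df,
    p_raw, p_adj``.  ``p_adj >= p_raw`` always.
    """
    names = list(groups)
    if len(names) < 2:
        raise InsufficientDataError("post hoc tests need >= 2 groups")
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    rows = []
    for g1, g2 in pairs:
        t, df, p = welch_t(groups[g1], groups[g2])
        p_adj = min(1.0, 1.0 - (1.0 - p) ** m)
        rows.append({"group1": g1, "group2": g2, "t": t, "df": df,
                     "p_raw": p, "p_adj": p_adj})
    return pd.DataFrame(rows)


def _pooled_cov(X: np.ndarray, Y: np.ndarray, ridge: bool) -> np.ndarray:
    n1, n2, p = X.shape[0], Y.shape[0], X.shape[1]
    S = ((n1 - 1) * np.cov(X, rowvar=False, ddof=1)
         + (n2 - 1) * np.cov(Y, rowvar=False, ddof=1)) / (n1 + n2 - 2)
    S = np.atleast_2d(S)
    if np.linalg.matrix_rank(S) < p:
        if not ridge:
            raise SingularCovarianceError(
                "pooled covariance is singular; enable the ridge policy"
            )
        warnings.warn("singular pooled covariance: shrinking toward the diagonal",
                      stacklevel=3)
        S = S + np.eye(p) * (1e-8 * np.trace(S) / p)
    return S


def hotelling_t2(X, Y, ridge: bool = True) -> dict[str, float]:
    """Hotelling's two-sample T-squared with F conversion.

    Uses the pooled two-group covariance; if it is singular (p >= n) a fixed
    ridge of ``1e-8 * trace/p`` is added to the diagonal (with a warning)
    when ``ridge`` is enabled, otherwise a singularity error is raised.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n1, p = X.shape
    n2 = Y.shape[0]
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("each group needs >= 2 observations")
    S = _pooled_cov(X, Y, ridge)
    d = X.mean(axis=0) - Y.mean(axis=0)
    T2 = (n1 * n2) / (n1 + n2) * float(d @ np.linalg.solve(S, d))
    df2 = n1 + n2 - p - 1
    if df2 <= 0:
        # T2 is still reported; the F conversion is undefined.
        return {"T2": T2, "F": np.nan, "df1": p, "df2": df2, "p": np.nan}
    F = T2 * df2 / ((n1 + n2 - 2) * p)
    pval = float(sps.f.sf(F, p, df2))
    return {"T2": T2, "F": float(F), "df1": p, "df2": df2, "p": pval}


def manova_pairwise(groups: dict[str, np.ndarray], ridge: bool = True) -> dict:
    """Overall MANOVA across groups plus pairwise Hotelling T-squared tests.

    The omnibus test is Wilks' lambda (via statsmodels); each pair of groups
    is then compared with :func:`hotelling_t2`.  Returns a dict with keys
    ``wilks_lambda``, ``F``, ``p`` and ``pairwise`` (a DataFrame).
    """
    from statsmodels.multivariate.manova import MANOVA

    names = list(groups)
    if len(names) < 2:
        raise InsufficientDataError("MANOVA needs >= 2 groups")
    X = np.vstack([np.atleast_2d(np.asarray(groups[g], dtype=float)) for g in names])
    labels = np.concatenate(
        [np.repeat(g, np.atleast_2d(groups[g]).shape[0]) for g in names]
    )
    df = pd.DataFrame(X, columns=[f"v{i}" for i in range(X.shape[1])])
    df["group"] = labels
    formula = " + ".join(df.columns[:-1]) + " ~ group"
    mv = MANOVA.from_formula(formula, data=df)
    wilks = mv.mv_test().results["group"]["stat"].loc["Wilks' lambda"]
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        ht = hotelling_t2(groups[g1], groups[g2], ridge=ridge)
        rows.append({"group1": g1, "group2": g2, **ht})
    return {
        "wilks_lambda": float(wilks["Value"]),
        "F": float(wilks["F Value"]),
        "p": float(wilks["Pr > F"]),
        "pairwise": pd.DataFrame(rows),
    }
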