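"""Pedal-proportion analysis: inter-element ratios and discriminant models.

Prosimian primates differ from anthropoids in foot architecture (long
fourth proximal phalanx relative to its metatarsal, hypertrophied hallucal
metatarsal, lateral foot axis), and clades with a grooming claw reduce the
second digit relative to the fifth.  This module computes the six indices
that capture those contrasts, standardizes element lengths to a geometric
mean for multivariate work, fits linear discriminant models over nine
extant family-level groups with leave-one-out (jackknife) validation, and
places single fossils against extant group distributions with the shared
single-specimen t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InsufficientDataError, InvalidMeasurementError
from .records import FOOT_ELEMENTS, FootRecord, GroupSummary
from .stats import anova_oneway, bonferroni, single_specimen_t, welch_t

#: The six pedal indices: (name, numerator element, denominator element).
RATIO_DEFS = (
    ("pp4_mt4", "pp4", "mt4"),
    ("mt1_mt2", "mt1", "mt2"),
    ("mt3_mt4", "mt3", "mt4"),
    ("mt4_mt5", "mt4", "mt5"),
    ("pp2_pp5", "pp2", "pp5"),
    ("pp3_pp4", "pp3", "pp4"),
)

#: Variable sets for the two discriminant analyses: all thirteen elements,
#: or the phalangeal elements only.  The phalanx-only analysis uses seven
#: variables; eight phalangeal lengths exist, so the hallucal proximal
#: phalanx (pp1, dominated by hallux size rather than digit formula) is
#: dropped — a documented choice, logged on every standardization call.
VARIABLE_SETS = {
    "all13": FOOT_ELEMENTS,
    "phalanges7": ("pp2", "pp3", "pp4", "pp5", "ip2", "ip3", "ip5"),
}

_warned_pp1: list[bool] = []


@dataclass(frozen=True)
class RatioSet:
    individual_id: str
    pp4_mt4: float | None = None
    mt1_mt2: float | None = None
    mt3_mt4: float | None = None
    mt4_mt5: float | None = None
    pp2_pp5: float | None = None
    pp3_pp4: float | None = None


def compute_ratios(record: FootRecord) -> RatioSet:
    """The six pedal indices; any ratio with a missing element is None."""
    values: dict[str, float | None] = {}
    for name, num, den in RATIO_DEFS:
        a, b = getattr(record, num), getattr(record, den)
        if a is None or b is None:
            values[name] = None
        elif b <= 0:
            raise InvalidMeasurementError(den, f"zero/negative denominator {b}")
        else:
            values[name] = a / b
    return RatioSet(individual_id=record.individual_id, **values)


def gm_standardize_foot(record: FootRecord, variable_set: str = "all13") -> pd.Series:
    """Element lengths divided by the geometric mean of the chosen set.

    ``all13`` uses every element; ``phalanges7`` recomputes the geometric
    mean over the seven phalangeal lengths only (see VARIABLE_SETS).
    Scale-invariant: doubling a skeleton leaves the vector unchanged.
    """
    try:
        elements = VARIABLE_SETS[variable_set]
    except KeyError:
        raise ConfigurationError(f"unknown variable set {variable_set!r}") from None
    if variable_set == "phalanges7" and not _warned_pp1:
        import warnings

        warnings.warn(
            "phalanges7 drops pp1: eight phalangeal lengths exist but the "
            "phalanx-only analysis uses seven variables; the hallucal "
            "proximal phalanx is excluded", stacklevel=2,
        )
        _warned_pp1.append(True)
    vals = []
    for name in elements:
        v = getattr(record, name)
        if v is None:
            raise InsufficientDataError(
                f"record {record.individual_id!r} is missing element {name!r}"
            )
        vals.append(v)
    logs = np.log(vals)
    gm = np.exp(logs.mean())
    return pd.Series(np.asarray(vals) / gm, index=list(elements),
                     name=record.individual_id)


@dataclass
class LDAModel:
    """Linear discriminant model over GM-standardized element lengths."""

    groups: list[str]
    variable_set: str
    centroids: pd.DataFrame            # groups x variables (standardized space)
    pooled_covariance: pd.DataFrame
    coefficients: pd.DataFrame         # standardized canonical coefficients
    _sk: object = None                 # fitted sklearn estimator
    priors: str = "equal"

    @property
    def n_functions(self) -> int:
        return self.coefficients.shape[1]


def _design(records: list[FootRecord], variable_set: str) -> tuple[pd.DataFrame, pd.Series]:
    rows, labels = [], []
    for r in records:
        if r.dfa_group is None:
            continue
        try:
            rows.append(gm_standardize_foot(r, variable_set))
        except InsufficientDataError:
            continue  # complete-case analysis
        labels.append(r.dfa_group)
    if not rows:
        raise InsufficientDataError("no complete-case records with a dfa_group")
    X = pd.DataFrame(rows)
    return X, pd.Series(labels, index=X.index, name="group")


def lda_fit(
    records: list[FootRecord], variable_set: str = "all13", ridge: float | None = None
) -> LDAModel:
    """Fit a linear discriminant model with equal priors.

    Equal (not proportional) priors are used because extant group sizes are
    collection artifacts.  ``ridge`` (0..1) enables covariance shrinkage
    when the pooled within-group covariance is singular.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    X, y = _design(records, variable_set)
    groups = sorted(y.unique())
    if len(groups) < 2:
        raise InsufficientDataError("LDA needs >= 2 groups")
    priors = np.full(len(groups), 1.0 / len(groups))
    if ridge is None:
        # enforce the invertibility precondition explicitly: the SVD
        # solver would silently work in a subspace otherwise
        centred = X.to_numpy().astype(float).copy()
        for g in groups:
            sel = (y == g).to_numpy()
            centred[sel] -= centred[sel].mean(axis=0)
        Sw = np.cov(centred, rowvar=False, ddof=len(groups))
        if np.linalg.matrix_rank(Sw) < X.shape[1]:
            from .errors import SingularCovarianceError

            raise SingularCovarianceError(
                "pooled within-group covariance is singular; pass a ridge value"
            )
        est = LinearDiscriminantAnalysis(
            solver="svd", priors=priors, store_covariance=True
        )
    else:
        est = LinearDiscriminantAnalysis(
            solver="eigen", priors=priors, shrinkage=float(ridge),
            store_covariance=True,
        )
    est.fit(X.to_numpy(), y.to_numpy())
    n_funcs = min(len(groups) - 1, X.shape[1])
    scalings = est.scalings_[:, :n_funcs]
    within_sd = np.sqrt(np.diag(est.covariance_))
    coefs = pd.DataFrame(
        scalings * within_sd[:, None],
        index=X.columns,
        columns=[f"DF{i + 1}" for i in range(n_funcs)],
    )
    centroids = pd.DataFrame(
        [X[y == g].mean() for g in groups], index=groups, columns=X.columns
    )
    return LDAModel(
        groups=groups, variable_set=variable_set, centroids=centroids,
        pooled_covariance=pd.DataFrame(est.covariance_, index=X.columns,
                                       columns=X.columns),
        coefficients=coefs, _sk=est,
    )


def lda_classify(model: LDAModel, record: FootRecord) -> tuple[str, pd.Series]:
    """Classify one individual; returns (group, posterior per group).

    Posteriors sum to 1 and use the model's equal priors.
    """
    x = gm_standardize_foot(record, model.variable_set).to_numpy()[None, :]
    post = model._sk.predict_proba(x)[0]
    posteriors = pd.Series(post, index=list(model._sk.classes_))
    return str(posteriors.idxmax()), posteriors


@dataclass
class CrossValidationResult:
    success_rate: float
    per_group: pd.Series
    assignments: pd.DataFrame  # individual_id, true, predicted, correct
    n_refits: int


def loo_cv(
    records: list[FootRecord], variable_set: str = "all13", ridge: float | None = None
) -> CrossValidationResult:
    """Leave-one-out (jackknife) classification success.

    Each complete-case record is classified by a model refit without it;
    exactly one refit per record.
    """
    usable = []
    for r in records:
        if r.dfa_group is None:
            continue
        try:
            gm_standardize_foot(r, variable_set)
        except InsufficientDataError:
            continue
        usable.append(r)
    counts = pd.Series([r.dfa_group for r in usable]).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise InsufficientDataError(
            f"groups with a single record cannot be jackknifed: {list(small.index)}"
        )
    rows = []
    n_refits = 0
    for i, rec in enumerate(usable):
        rest = usable[:i] + usable[i + 1:]
        model = lda_fit(rest, variable_set, ridge)
        n_refits += 1
        pred, _ = lda_classify(model, rec)
        rows.append({"individual_id": rec.individual_id, "true": rec.dfa_group,
                     "predicted": pred, "correct": pred == rec.dfa_group})
    df = pd.DataFrame(rows)
    per_group = df.groupby("true")["correct"].mean()
    return CrossValidationResult(
        success_rate=float(df["correct"].mean()), per_group=per_group,
        assignments=df, n_refits=n_refits,
    )


def estimate_mt4(
    mt3: float, mt5: float, extant: list[FootRecord], policy: str = "conservative-min"
) -> dict:
    """Estimate a fossil's fourth-metatarsal length from mt3 and mt5.

    The extant sample supplies the distributions of mt4/mt3 and mt4/mt5;
    under the default policy the point estimate is the smaller of
    ``mt3 * min(mt4/mt3)`` and ``mt5 * min(mt4/mt5)`` — the shortest mt4 any
    sampled extant proportion would imply, i.e. the estimate least
    favourable to an anomalously short mt4 being real.  The full predictive
    intervals from both ratio distributions are returned alongside.
    """
    r43, r45 = [], []
    for r in extant:
        if r.mt3 and r.mt4 and r.mt5:
            r43.append(r.mt4 / r.mt3)
            r45.append(r.mt4 / r.mt5)
    if not r43:
        raise InsufficientDataError("no extant records with mt3, mt4 and mt5")
    r43, r45 = np.array(r43), np.array(r45)
    pred3 = mt3 * r43
    pred5 = mt5 * r45
    if policy == "conservative-min":
        estimate = min(pred3.min(), pred5.min())
    elif policy == "mean":
        estimate = float(np.mean(np.concatenate([pred3, pred5])))
    else:
        raise ConfigurationError(f"unknown estimator policy {policy!r}")
    return {
        "estimate": float(estimate),
        "interval_mt3": (float(pred3.min()), float(pred3.max())),
        "interval_mt5": (float(pred5.min()), float(pred5.max())),
        "n_extant": len(r43),
        "policy": policy,
    }


def group_tests(
    ratios_by_group: dict[str, np.ndarray],
    design: str,
    alpha: float = 0.05,
    m: int | None = None,
) -> dict:
    """The published test battery for one pedal index.

    ``two_group``: Welch t (unequal variances) plus Mann-Whitney U across
    the two gradistic groups.  ``five_group``: one-way ANOVA F and
    Kruskal-Wallis H across the five clades, with post hoc Tukey HSD and
    pairwise Mann-Whitney at the Bonferroni-adjusted alpha.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in ratios_by_group.items()}
    for k, v in groups.items():
        if v.size < 2:
            raise InsufficientDataError(f"group {k!r} has fewer than 2 values")
    if design == "two_group":
        if len(groups) != 2:
            raise ConfigurationError("two_group design needs exactly 2 groups")
        (ga, a), (gb, b) = groups.items()
        t, df, p = welch_t(a, b)
        u = sps.mannwhitneyu(a, b, alternative="two-sided")
        return {"design": design, "welch_t": t, "welch_df": df, "welch_p": p,
                "mannwhitney_U": float(u.statistic), "mannwhitney_p": float(u.pvalue)}
    if design != "five_group":
        raise ConfigurationError(f"unknown design {design!r}")
    F, p_f = anova_oneway(groups)
    names = list(groups)
    H, p_h = sps.kruskal(*groups.values())
    adj_alpha = bonferroni(alpha, m if m is not None else len(names) * (len(names) - 1) // 2)
    tukey = sps.tukey_hsd(*groups.values())
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            mw = sps.mannwhitneyu(groups[names[i]], groups[names[j]],
                                  alternative="two-sided")
            rows.append({
                "group1": names[i], "group2": names[j],
                "tukey_p": float(tukey.pvalue[i, j]),
                "mannwhitney_p": float(mw.pvalue),
                "significant": mw.pvalue < adj_alpha and tukey.pvalue[i, j] < adj_alpha,
            })
    return {"design": design, "anova_F": F, "anova_p": p_f,
            "kruskal_H": float(H), "kruskal_p": float(p_h),
            "adjusted_alpha": adj_alpha, "pairwise": pd.DataFrame(rows)}


def fossil_vs_groups(
    value: float,
    summaries: list[GroupSummary],
    alpha: float = 0.05,
    m: int = 4,
) -> dict:
    """Single-specimen t of one fossil ratio against each extant group.

    The nearest group minimises |t|; exact ties resolve to the first group
    in input order and are flagged.  Significance uses ``alpha / m``.
    """
    if not summaries:
        raise InsufficientDataError("no group summaries supplied")
    adj_alpha = bonferroni(alpha, m)
    rows = []
    for s in summaries:
        t, df, p = single_specimen_t(value, s)
        rows.append({"group": s.group, "t": t, "df": df, "p": p,
                     "significant": p < adj_alpha})
    df_out = pd.DataFrame(rows)
    abs_t = df_out["t"].abs()
    best = int(abs_t.idxmin())  # idxmin takes the first minimum -> input order
    tie = bool((abs_t == abs_t.iloc[best]).sum() > 1)
    return {"table": df_out, "nearest": df_out.loc[best, "group"],
            "tie": tie, "adjusted_alpha": adj_alpha}
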