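"""Distal-phalanx shape analysis: the grooming-claw diagnosis pipeline.

Grooming claws (the modified unguis of the second pedal digit of prosimian
primates) differ from nails in having a dorsally canted shaft (low
facet-shaft angle, FSA), a proximally restricted volar process (low VFL
relative to phalanx length) and a strongly tapering shaft (high
SH-1/4 / SH-3/4).  The pipeline removes size by dividing each linear
measurement by the specimen's geometric mean, summarises shape with a
correlation-matrix PCA, and places fossils against extant group baselines
with single-specimen t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import (
    ConfigurationError,
    DegenerateHullError,
    DegenerateVariableError,
    InsufficientDataError,
    InvalidMeasurementError,
)
from .records import PHALANX_LINEAR_FIELDS, GroupSummary, PhalanxRecord
from .stats import bonferroni, single_specimen_t

#: Column order of the nine shape variables entering the PCA.
SHAPE_VARIABLES = tuple(f"{v}_GM" for v in PHALANX_LINEAR_FIELDS) + ("FSA",)

#: Ratio variables (dimensionless indices built from raw measurements).
RATIO_VARIABLES = ("VFL_TPL", "SH14_SH34", "SW34_TPL")

#: Variables entering the combined grooming-vs-ungular verdict.  The
#: tuft-width index SW34_TPL is reported but excluded: it does not separate
#: the fossils from nails (every fossil is nail-like in tuft width).
VERDICT_VARIABLES = ("FSA", "VFL_TPL", "SH14_SH34")


@dataclass(frozen=True)
class ShapeVector:
    """Size-free shape of one phalanx: eight linears / GM, plus FSA and GM."""

    specimen_id: str
    values: dict[str, float]  # keys: SHAPE_VARIABLES
    GM: float


@dataclass(frozen=True)
class RatioVector:
    specimen_id: str
    VFL_TPL: float
    SH14_SH34: float
    SW34_TPL: float


def geometric_mean(record: PhalanxRecord) -> float:
    """Geometric mean of the eight linear measurements (the size proxy).

    Computed in the log domain for numerical stability.
    """
    logs = []
    for name in PHALANX_LINEAR_FIELDS:
        v = getattr(record, name)
        if v is None or v <= 0:
            raise InvalidMeasurementError(name, f"positive value required, got {v}")
        logs.append(np.log(v))
    return float(np.exp(np.mean(logs)))


def standardize(record: PhalanxRecord) -> ShapeVector:
    """Divide each linear measurement by the geometric mean; FSA untouched.

    The eight standardized values multiply to 1 by construction, so the
    result is invariant to uniform scaling of the specimen.
    """
    gm = geometric_mean(record)
    values = {f"{name}_GM": getattr(record, name) / gm for name in PHALANX_LINEAR_FIELDS}
    values["FSA"] = record.FSA
    return ShapeVector(specimen_id=record.specimen_id, values=values, GM=gm)


def ratios(record: PhalanxRecord) -> RatioVector:
    """The three simple shape indices: VFL/TPL, SH14/SH34, SW34/TPL."""
    for den in ("TPL", "SH34"):
        v = getattr(record, den)
        if v is None or v <= 0:
            raise InvalidMeasurementError(den, f"positive denominator required, got {v}")
    for num in ("VFL", "SH14", "SW34"):
        v = getattr(record, num)
        if v is None or v <= 0:
            raise InvalidMeasurementError(num, f"positive value required, got {v}")
    return RatioVector(
        specimen_id=record.specimen_id,
        VFL_TPL=record.VFL / record.TPL,
        SH14_SH34=record.SH14 / record.SH34,
        SW34_TPL=record.SW34 / record.TPL,
    )


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # non-increasing, sums to n_variables
    proportion_variance: np.ndarray
    loadings: pd.DataFrame           # Pearson r of each variable with each PC
    scores: pd.DataFrame             # specimens x components
    variables: tuple[str, ...]
    center: pd.Series = None         # training means (for projection)
    scale: pd.Series = None          # training sds
    components: np.ndarray = None    # eigenvectors, columns = components

    def project(self, vectors: "list[ShapeVector] | pd.DataFrame") -> pd.DataFrame:
        """Project new specimens into this fit's component space.

        Supports the fit-on-extant, project-fossils-afterwards workflow:
        new rows are standardized with the training means/sds and rotated
        by the training eigenvectors.
        """
        if isinstance(vectors, pd.DataFrame):
            df = vectors.loc[:, list(self.variables)].astype(float)
        else:
            df = pd.DataFrame(
                [v.values for v in vectors],
                index=[v.specimen_id for v in vectors],
            ).loc[:, list(self.variables)]
        Z = (df - self.center) / self.scale
        return pd.DataFrame(Z.to_numpy() @ self.components, index=df.index,
                            columns=self.scores.columns)


def pca_shape(vectors: list[ShapeVector] | pd.DataFrame) -> PCAResult:
    """Correlation-matrix PCA of the nine shape variables.

    Components are eigenvectors of the 9x9 Pearson correlation matrix, so
    the eigenvalues sum to 9 and the loadings (correlation of each variable
    with each component score) lie in [-1, 1].  Component signs are fixed so
    that the loading of BH/GM on component 1 is positive.
    """
    if isinstance(vectors, pd.DataFrame):
        df = vectors.loc[:, list(SHAPE_VARIABLES)].astype(float)
    else:
        if len(vectors) < 3:
            raise InsufficientDataError("PCA needs >= 3 specimens")
        df = pd.DataFrame(
            [v.values for v in vectors], index=[v.specimen_id for v in vectors]
        ).loc[:, list(SHAPE_VARIABLES)]
    if len(df) < 3:
        raise InsufficientDataError("PCA needs >= 3 specimens")
    sd = df.std(ddof=1)
    constant = sd.index[sd.values == 0].tolist()
    if constant:
        raise DegenerateVariableError(f"constant variable(s): {', '.join(constant)}")
    Z = (df - df.mean()) / sd
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: BH/GM loads positively on PC1; for the other
    # components, fix the sign by the largest-magnitude loading.
    i_bh = list(SHAPE_VARIABLES).index("BH_GM")
    if evecs[i_bh, 0] < 0:
        evecs[:, 0] = -evecs[:, 0]
    for k in range(1, evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    loadings = evecs * np.sqrt(evals)  # == corr(variable, component score)
    comp_names = [f"PC{i + 1}" for i in range(len(evals))]
    scores = Z.to_numpy() @ evecs
    return PCAResult(
        eigenvalues=evals,
        proportion_variance=evals / evals.sum(),
        loadings=pd.DataFrame(loadings, index=list(SHAPE_VARIABLES), columns=comp_names),
        scores=pd.DataFrame(scores, index=df.index, columns=comp_names),
        variables=SHAPE_VARIABLES,
        center=df.mean(),
        scale=sd,
        components=evecs,
    )


def _point_in_hull(point: np.ndarray, hull: ConvexHull, tol: float) -> tuple[bool, bool]:
    """(inside-or-on, near-boundary) for one 2-D point against a hull."""
    # hull.equations rows are (a, b, c) with a*x + b*y + c <= 0 inside.
    margins = hull.equations[:, :-1] @ point + hull.equations[:, -1]
    inside = bool(np.all(margins <= tol))
    on_edge = bool(inside and np.any(np.abs(margins) <= tol))
    return inside, on_edge


def convex_hull_assign(
    fossil_scores: pd.DataFrame,
    extant_scores: pd.DataFrame,
    groups: pd.Series,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Membership of each fossil point in each extant group's 2-D convex hull.

    ``fossil_scores`` and ``extant_scores`` hold the first two component
    scores (columns are taken in order); ``groups`` labels the extant rows.
    Returns a boolean DataFrame (fossils x groups); cells within ``tol`` of a
    hull boundary are reported as the string ``"edge"``.
    """
    fx = np.asarray(fossil_scores.iloc[:, :2], dtype=float)
    hulls = {}
    for g in pd.unique(groups):
        pts = np.asarray(extant_scores.loc[groups == g].iloc[:, :2], dtype=float)
        if len(pts) < 3:
            raise DegenerateHullError(f"group {g!r} has fewer than 3 points")
        try:
            hulls[g] = ConvexHull(pts)
        except QhullError as exc:
            raise DegenerateHullError(f"group {g!r} points are collinear") from exc
    out = pd.DataFrame(index=fossil_scores.index, columns=list(hulls), dtype=object)
    for i, point in enumerate(fx):
        for g, hull in hulls.items():
            inside, on_edge = _point_in_hull(point, hull, tol)
            out.iloc[i, out.columns.get_loc(g)] = "edge" if on_edge else inside
    return out


@dataclass
class ClassificationReport:
    """Per-variable single-specimen t-tests of one fossil vs group baselines."""

    specimen_id: str
    table: pd.DataFrame       # rows: variable x group; cols: t, df, p, significant
    nearest: dict[str, str]   # variable -> group with min |t|
    verdict: str              # grooming-like | ungular-like | mixed
    alpha: float
    m: int


def classify_fossil(
    fossil: PhalanxRecord | dict[str, float],
    baselines: list[GroupSummary],
    variables: tuple[str, ...] = VERDICT_VARIABLES + ("SW34_TPL",),
    alpha: float = 0.05,
    m: int = 12,
) -> ClassificationReport:
    """Place a fossil against extant unguis-group baselines, variable by variable.

    For every requested variable the fossil value is tested against each
    group's (mean, variance, n) with the single-specimen t-test; the nearest
    group is the one with the smallest |t|.  The combined verdict is
    "grooming-like" only when the fossil is nearer the grooming baseline for
    all of FSA, VFL/TPL and SH14/SH34 (the three traits that jointly
    diagnose a grooming claw), "ungular-like" when nearer the nail group for
    all three, and "mixed" otherwise.  SW34/TPL (tuft width) is reported but
    never enters the verdict.  Significance flags use the Bonferroni-adjusted
    alpha ``alpha / m``.
    """
    if isinstance(fossil, PhalanxRecord):
        values = dict(standardize(fossil).values)
        r = ratios(fossil)
        values.update(VFL_TPL=r.VFL_TPL, SH14_SH34=r.SH14_SH34, SW34_TPL=r.SW34_TPL)
        specimen_id = fossil.specimen_id
    else:
        values = dict(fossil)
        specimen_id = str(values.pop("specimen_id", "fossil"))

    by_var: dict[str, dict[str, GroupSummary]] = {}
    for b in baselines:
        by_var.setdefault(b.variable, {})[b.group] = b
    adj_alpha = bonferroni(alpha, m)
    rows = []
    nearest: dict[str, str] = {}
    for var in variables:
        if var not in values:
            raise ConfigurationError(f"fossil has no value for variable {var!r}")
        groups = by_var.get(var, {})
        for need in ("ungular", "grooming"):
            if need not in groups:
                raise ConfigurationError(f"baseline set lacks {need!r} for {var!r}")
        best, best_t = None, np.inf
        for gname, summ in groups.items():
            t, df, p = single_specimen_t(values[var], summ)
            rows.append({"variable": var, "group": gname, "t": t, "df": df,
                         "p": p, "significant": p < adj_alpha})
            if abs(t) < best_t:
                best, best_t = gname, abs(t)
        nearest[var] = best
    verdict = "mixed"
    if all(nearest.get(v) == "grooming" for v in VERDICT_VARIABLES):
        verdict = "grooming-like"
    elif all(nearest.get(v) == "ungular" for v in VERDICT_VARIABLES):
        verdict = "ungular-like"
    table = pd.DataFrame(rows).set_index(["variable", "group"])
    return ClassificationReport(
        specimen_id=specimen_id, table=table, nearest=nearest,
        verdict=verdict, alpha=alpha, m=m,
    )
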