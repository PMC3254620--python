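"""Synthetic datasets with the statistical structure the analyses assume.

Three generators: (1) distal-phalanx specimens drawn from group-wise
normal distributions of the GM-standardized shape variables and FSA, with
raw millimetre measurements back-synthesised through a log-normal size
factor; (2) foot skeletons whose six pedal indices follow specified group
distributions; (3) discrete character matrices evolved on a known random
tree, with ordered characters taking +-1 random-walk steps and unordered
characters uniform jumps, plus injected missing cells and polymorphism.

All generators are deterministic under a seed.  Defaults reproduce the
published study conditions: unguis-group means/variances of the extant
nail and grooming-claw samples with n = 21/10/4/7, and the published
prosimian/anthropoid and five-clade ratio summaries.  Group variables are
drawn independently by default (published tables report only marginal
moments); an exchangeable-correlation mode supports robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InsufficientDataError
from .parsimony.matrix import Character, CharacterMatrix
from .parsimony.trees import Topology
from .records import FootRecord, PhalanxRecord
from . import tables

_MAX_REJECT = 10_000

#: Falcular and tegular shape summaries are not published; these synthetic
#: specs (used only when a four-group dataset is requested) put claws at
#: the strongly curved, narrow-tufted end of the morphospace and tegulae
#: between claws and nails.
SYNTHETIC_FALCULAR_MEANS = {
    "BH_GM": 1.40, "TPL_GM": 3.10, "SH14_GM": 1.00, "SH34_GM": 0.55,
    "BW_GM": 0.95, "SW14_GM": 0.55, "SW34_GM": 0.35, "FSA": 95.0, "VFL_GM": 1.50,
}
SYNTHETIC_TEGULAR_MEANS = {
    "BH_GM": 1.10, "TPL_GM": 2.90, "SH14_GM": 0.85, "SH34_GM": 0.50,
    "BW_GM": 1.05, "SW14_GM": 0.62, "SW34_GM": 0.50, "FSA": 85.0, "VFL_GM": 1.80,
}


@dataclass
class PhalanxGroupSpec:
    """Sampling spec for one unguis group: marginal moments + size."""

    group: str
    means: dict[str, float]       # 8 *_GM variables and FSA
    variances: dict[str, float]
    n: int
    correlation: str = "independent"   # or "exchangeable"
    rho: float = 0.0
    gm_log_mean: float = np.log(2.5)   # size factor: log-normal GM in mm
    gm_log_sd: float = 0.25

    def __post_init__(self):
        if self.n < 0:
            raise ConfigurationError("n must be >= 0")
        if any(v < 0 for v in self.variances.values()):
            raise ConfigurationError("variances must be >= 0")
        if not -1 < self.rho < 1:
            raise ConfigurationError("|rho| must be < 1")


def default_phalanx_specs(
    n_ungular: int = 21, n_grooming: int = 10, n_tegular: int = 4, n_falcular: int = 7
) -> list[PhalanxGroupSpec]:
    """Published nail/grooming specs plus the synthetic claw/tegula specs."""
    df = tables.unguis_group_summaries()
    shape_vars = [v for v in df["variable"].unique() if "_" not in v or v.endswith("_GM")]
    specs = []
    for group, n in (("ungular", n_ungular), ("grooming", n_grooming)):
        sub = df[(df["group"] == group) & df["variable"].isin(shape_vars)]
        means = dict(zip(sub["variable"], sub["mean"]))
        variances = dict(zip(sub["variable"], sub["variance"]))
        specs.append(PhalanxGroupSpec(group=group, means=means,
                                      variances=variances, n=n))
    for group, n, means in (
        ("falcular", n_falcular, SYNTHETIC_FALCULAR_MEANS),
        ("tegular", n_tegular, SYNTHETIC_TEGULAR_MEANS),
    ):
        variances = {k: (20.0 if k == "FSA" else 0.02) for k in means}
        specs.append(PhalanxGroupSpec(group=group, means=dict(means),
                                      variances=variances, n=n))
    return specs


_SHAPE_ORDER = ("BH_GM", "BW_GM", "TPL_GM", "SH14_GM", "SW14_GM",
                "SH34_GM", "SW34_GM", "VFL_GM", "FSA")


def _draw_group(spec: PhalanxGroupSpec, rng: np.random.Generator) -> np.ndarray:
    mu = np.array([spec.means[v] for v in _SHAPE_ORDER])
    var = np.array([spec.variances[v] for v in _SHAPE_ORDER])
    sd = np.sqrt(var)
    if spec.correlation == "independent":
        return mu + sd * rng.standard_normal(len(mu))
    if spec.correlation == "exchangeable":
        k = len(mu)
        R = np.full((k, k), spec.rho)
        np.fill_diagonal(R, 1.0)
        L = np.linalg.cholesky(R)
        return mu + sd * (L @ rng.standard_normal(k))
    raise ConfigurationError(f"unknown correlation policy {spec.correlation!r}")


def gen_phalanx_dataset(
    specs: list[PhalanxGroupSpec] | None = None, seed: int = 0
) -> list[PhalanxRecord]:
    """Draw phalanx specimens; raw measurements = draw x log-normal GM.

    Draws violating the record invariants (non-positive lengths, VFL > TPL,
    shaft heights >= TPL, FSA outside (0, 180)) are rejected and resampled;
    a spec that keeps forcing rejections raises after 10,000 attempts.
    """
    if specs is None:
        specs = default_phalanx_specs()
    rng = np.random.default_rng(seed)
    records: list[PhalanxRecord] = []
    for spec in specs:
        for i in range(spec.n):
            for attempt in range(_MAX_REJECT):
                draw = _draw_group(spec, rng)
                vals = dict(zip(_SHAPE_ORDER, draw))
                fsa = vals.pop("FSA")
                if any(v <= 0 for v in vals.values()) or not 0 < fsa < 180:
                    continue
                if vals["VFL_GM"] > vals["TPL_GM"]:
                    continue
                if vals["SH14_GM"] >= vals["TPL_GM"] or vals["SH34_GM"] >= vals["TPL_GM"]:
                    continue
                gm = float(np.exp(rng.normal(spec.gm_log_mean, spec.gm_log_sd)))
                records.append(PhalanxRecord(
                    specimen_id=f"{spec.group}-{i:04d}",
                    taxon=f"synthetic {spec.group}",
                    unguis_group=spec.group,
                    BH=vals["BH_GM"] * gm, BW=vals["BW_GM"] * gm,
                    TPL=vals["TPL_GM"] * gm, SH14=vals["SH14_GM"] * gm,
                    SW14=vals["SW14_GM"] * gm, SH34=vals["SH34_GM"] * gm,
                    SW34=vals["SW34_GM"] * gm, VFL=vals["VFL_GM"] * gm,
                    FSA=float(fsa),
                ))
                break
            else:
                raise InsufficientDataError(
                    f"spec {spec.group!r} rejected {_MAX_REJECT} consecutive draws"
                )
    return records


@dataclass
class FootGroupSpec:
    """Sampling spec for one foot-proportion group.

    ``ratio_means``/``ratio_variances`` cover any subset of the six pedal
    indices; unspecified ratios fall back to neutral defaults.  ``scale``
    is the mean mt4 length in mm (log-normal).
    """

    group: str
    ratio_means: dict[str, float]
    ratio_variances: dict[str, float]
    n: int
    scale: float = 25.0
    scale_log_sd: float = 0.15
    accessory_log_sd: float = 0.04  # independent jitter on accessory proportions
    dfa_group: str | None = None
    ratio_group: str | None = None
    gradistic_group: str | None = None


_NEUTRAL_RATIOS = {"pp4_mt4": 0.75, "mt1_mt2": 0.8, "mt3_mt4": 1.0,
                   "mt4_mt5": 1.06, "pp2_pp5": 0.95, "pp3_pp4": 0.95}
#: Ratios a spec leaves unspecified still vary a little between
#: individuals; zero variance would make element columns exactly
#: proportional and degenerate for multivariate work.
_NEUTRAL_RATIO_VAR = 0.002

#: Fixed accessory proportions (relative to mt4 / pp4 / each pp) used to
#: fill in elements the six target ratios do not constrain; loosely shaped
#: on the packaged AMNH 143612/143640 foot.
_ACCESSORY = {"mt2_mt4": 0.93, "pp5_pp4": 0.86, "pp1_mt4": 0.62,
              "ip2_pp2": 0.67, "ip3_pp3": 0.65, "ip5_pp5": 0.68}


def default_foot_specs(n_prosimian: int = 100, n_anthropoid: int = 100) -> list[FootGroupSpec]:
    """Prosimian/anthropoid specs at the published metatarsal-ratio moments."""
    mts = tables.metatarsal_ratio_summaries()
    pps = tables.phalanx_ratio_summaries()
    out = []
    for grad, n, pp_group in (("prosimian", n_prosimian, "lemuroids"),
                              ("anthropoid", n_anthropoid, "anthropoids")):
        means = {r: mts.loc[r, f"{grad}_mean"] for r in mts.index}
        variances = {r: mts.loc[r, f"{grad}_var"] for r in mts.index}
        sub = pps[pps["group"] == pp_group]
        for row in sub.itertuples():
            means[row.ratio] = row.mean
            variances[row.ratio] = row.variance
        out.append(FootGroupSpec(
            group=grad, ratio_means=means, ratio_variances=variances, n=n,
            gradistic_group=grad, ratio_group=pp_group,
        ))
    return out


def gen_foot_dataset(
    specs: list[FootGroupSpec], seed: int = 0
) -> list[FootRecord]:
    """Build foot skeletons whose pedal indices follow the group specs.

    mt4 sets the size; the six target ratios are drawn from (truncated
    positive) normals and the remaining elements are filled through fixed
    accessory proportions, so recomputing any target ratio from the
    generated lengths recovers the drawn value exactly.
    """
    rng = np.random.default_rng(seed)
    records: list[FootRecord] = []
    for spec in specs:
        means = {**_NEUTRAL_RATIOS, **spec.ratio_means}
        var = {**{k: _NEUTRAL_RATIO_VAR for k in _NEUTRAL_RATIOS},
               **spec.ratio_variances}
        for i in range(spec.n):
            for attempt in range(_MAX_REJECT):
                r = {k: rng.normal(means[k], np.sqrt(var[k])) for k in means}
                if any(v <= 0 for v in r.values()):
                    continue
                mt4 = spec.scale * float(np.exp(rng.normal(0.0, spec.scale_log_sd)))
                # accessory proportions get independent log-normal jitter so
                # the generated columns are not exactly collinear (the six
                # target ratios are still recovered exactly by construction)
                acc = {k: v * float(np.exp(rng.normal(0.0, spec.accessory_log_sd)))
                       for k, v in _ACCESSORY.items()}
                mt3 = mt4 * r["mt3_mt4"]
                mt5 = mt4 / r["mt4_mt5"]
                mt2 = mt4 * acc["mt2_mt4"]
                mt1 = mt2 * r["mt1_mt2"]
                pp4 = mt4 * r["pp4_mt4"]
                pp3 = pp4 * r["pp3_pp4"]
                pp5 = pp4 * acc["pp5_pp4"]
                pp2 = pp5 * r["pp2_pp5"]
                pp1 = mt4 * acc["pp1_mt4"]
                records.append(FootRecord(
                    individual_id=f"{spec.group}-{i:04d}",
                    taxon=f"synthetic {spec.group}",
                    dfa_group=spec.dfa_group, ratio_group=spec.ratio_group,
                    gradistic_group=spec.gradistic_group,
                    mt1=mt1, mt2=mt2, mt3=mt3, mt4=mt4, mt5=mt5,
                    pp1=pp1, pp2=pp2, pp3=pp3, pp4=pp4, pp5=pp5,
                    ip2=pp2 * acc["ip2_pp2"],
                    ip3=pp3 * acc["ip3_pp3"],
                    ip5=pp5 * acc["ip5_pp5"],
                ))
                break
            else:
                raise InsufficientDataError(
                    f"spec {spec.group!r} rejected {_MAX_REJECT} consecutive draws"
                )
    return records


@dataclass
class EvolSpec:
    """Spec for evolving a character matrix on a random tree."""

    n_taxa: int = 8
    n_characters: int = 25
    n_states: int = 3
    ordered: bool = True
    change_prob: float = 0.05   # per character per edge
    missing_rate: float = 0.0
    polymorphism_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ConfigurationError("need >= 3 taxa")
        if self.n_states < 2:
            raise ConfigurationError("need >= 2 states")
        for p in (self.change_prob, self.missing_rate, self.polymorphism_rate):
            if not 0 <= p <= 1:
                raise ConfigurationError("probabilities must lie in [0, 1]")


def _random_topology(n: int, rng: np.random.Generator) -> Topology:
    """Uniform random unrooted binary tree by random stepwise insertion."""
    edges = [(0, n), (1, n), (2, n)]
    next_internal = n + 1
    for k in range(3, n):
        idx = int(rng.integers(len(edges)))
        u, v = edges[idx]
        w = next_internal
        next_internal += 1
        edges[idx] = (u, w)
        edges.append((w, v))
        edges.append((w, k))
    taxa = tuple(f"T{i + 1}" for i in range(n))
    return Topology.from_edges(taxa, edges)


def gen_character_matrix(spec: EvolSpec) -> tuple[CharacterMatrix, Topology]:
    """Evolve characters on a random tree; returns (matrix, generating tree).

    Ordered characters start at the middle state and take +-1 steps
    (reflecting at the ends) whenever an edge changes; unordered characters
    jump uniformly to a different state.  Missing cells and two-state
    polymorphism (the true state plus a neighbour) are injected at the
    given rates.  The first taxon is the designated outgroup.
    """
    rng = np.random.default_rng(spec.seed)
    tree = _random_topology(spec.n_taxa, rng)
    n = spec.n_taxa
    n_nodes = len(tree.adj)
    states = np.zeros((n_nodes, spec.n_characters), dtype=int)
    root = tree.adj[0][0]
    root_state = (spec.n_states - 1) // 2 if spec.ordered else 0
    states[root] = root_state
    # preorder from the root internal node (leaf 0 hangs off it directly)
    stack = [(kid, root) for kid in tree.adj[root] if kid != 0]
    visited = {root, 0}
    order: list[tuple[int, int]] = [(0, root)]
    while stack:
        node, parent = stack.pop()
        if node in visited:
            continue
        visited.add(node)
        order.append((node, parent))
        for kid in tree.adj[node]:
            if kid != parent:
                stack.append((kid, node))
    for node, parent in order:
        change = rng.random(spec.n_characters) < spec.change_prob
        s = states[parent].copy()
        if spec.ordered:
            step = np.where(rng.random(spec.n_characters) < 0.5, -1, 1)
            moved = s + step
            # reflect at the alphabet ends
            moved = np.where(moved < 0, 1, moved)
            moved = np.where(moved >= spec.n_states, spec.n_states - 2, moved)
            s = np.where(change, moved, s)
        else:
            jump = (s + rng.integers(1, spec.n_states, spec.n_characters)) % spec.n_states
            s = np.where(change, jump, s)
        states[node] = s
    characters = [
        Character(id=j + 1, label=f"char{j + 1}",
                  states=tuple(range(spec.n_states)), ordered=spec.ordered)
        for j in range(spec.n_characters)
    ]
    cells = []
    for i in range(n):
        row = []
        for j in range(spec.n_characters):
            u = rng.random()
            s = int(states[i, j])
            if u < spec.missing_rate:
                row.append(None)
            elif u < spec.missing_rate + spec.polymorphism_rate:
                other = s + 1 if s + 1 < spec.n_states else s - 1
                row.append(frozenset([s, other]))
            else:
                row.append(frozenset([s]))
        cells.append(row)
    matrix = CharacterMatrix(
        taxa=tree.taxa, characters=characters, cells=cells, outgroup=tree.taxa[0]
    )
    return matrix, tree
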