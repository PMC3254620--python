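"""Parsimony length of a tree: Fitch and Farris dynamic programming.

Unordered characters use Fitch set intersection/union (cost 1 per required
union).  Ordered characters use the Farris interval method — each node
carries the interval of optimal ancestral states; non-overlapping child
intervals cost their gap — which equals Sankoff dynamic programming with
linear costs ``|i - j|``.  Both are evaluated vectorised across characters,
so one pass over the tree scores every column at once.

Polymorphic/ambiguous cells enter as leaf state sets (unordered) or as the
interval spanning the set (ordered); this is the minimum-cost "uncertainty"
reading.  The alternative "polymorphism-as-both" costing, in which a
polymorphic terminal is charged the steps needed to realise every recorded
state, adds a tree-independent surcharge per polymorphic cell (state range
for ordered characters, set size minus one for unordered ones); it is
offered as a sensitivity flag because historic parsimony software treats
the two readings differently.

Missing cells are unconstrained (full state set / full interval) and never
force steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .matrix import Cell, CharacterMatrix
from .trees import Topology

POLYMORPHISM_MODES = ("uncertainty", "as-both")


@dataclass
class EncodedMatrix:
    """Leaf-state arrays for fast repeated length evaluation.

    ``ord_lo``/``ord_hi``: (ntax, n_ordered) int arrays of leaf intervals.
    ``mask``: (ntax, n_unordered) int arrays of Fitch bitmasks.
    ``surcharge``: tree-independent extra steps per character (nchar,) —
    zero in "uncertainty" mode.
    """

    matrix: CharacterMatrix
    ord_cols: list[int]
    unord_cols: list[int]
    ord_lo: np.ndarray
    ord_hi: np.ndarray
    mask: np.ndarray
    surcharge: np.ndarray
    polymorphism: str


def encode_matrix(
    matrix: CharacterMatrix, polymorphism: str = "uncertainty"
) -> EncodedMatrix:
    if polymorphism not in POLYMORPHISM_MODES:
        raise ValueError(f"polymorphism must be one of {POLYMORPHISM_MODES}")
    ord_cols = [j for j, c in enumerate(matrix.characters) if c.ordered]
    unord_cols = [j for j, c in enumerate(matrix.characters) if not c.ordered]
    ntax = matrix.ntax
    lo = np.zeros((ntax, len(ord_cols)), dtype=np.int64)
    hi = np.zeros((ntax, len(ord_cols)), dtype=np.int64)
    mask = np.zeros((ntax, len(unord_cols)), dtype=np.int64)
    surcharge = np.zeros(matrix.nchar, dtype=np.int64)
    for k, j in enumerate(ord_cols):
        states = matrix.characters[j].states
        for i in range(ntax):
            c = matrix.cells[i][j]
            if c is None:
                lo[i, k], hi[i, k] = min(states), max(states)
            else:
                lo[i, k], hi[i, k] = min(c), max(c)
                if polymorphism == "as-both" and len(c) > 1:
                    surcharge[j] += max(c) - min(c)
    for k, j in enumerate(unord_cols):
        states = matrix.characters[j].states
        full = 0
        for s in states:
            full |= 1 << s
        for i in range(ntax):
            c = matrix.cells[i][j]
            if c is None:
                mask[i, k] = full
            else:
                m = 0
                for s in c:
                    m |= 1 << s
                mask[i, k] = m
                if polymorphism == "as-both" and len(c) > 1:
                    surcharge[j] += len(c) - 1
    return EncodedMatrix(
        matrix=matrix, ord_cols=ord_cols, unord_cols=unord_cols,
        ord_lo=lo, ord_hi=hi, mask=mask, surcharge=surcharge,
        polymorphism=polymorphism,
    )


def _lengths_from_plan(
    enc: EncodedMatrix,
    plan: list[tuple[int, int, int]],
    root_leaf: int,
    n_nodes: int,
    leaf_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Per-character steps for a merge plan (see Topology.postorder)."""
    n_ord = enc.ord_lo.shape[1]
    n_unord = enc.mask.shape[1]
    lo = np.zeros((n_nodes, n_ord), dtype=np.int64)
    hi = np.zeros((n_nodes, n_ord), dtype=np.int64)
    mk = np.zeros((n_nodes, n_unord), dtype=np.int64)
    ntax = enc.matrix.ntax
    lo[:ntax] = enc.ord_lo
    hi[:ntax] = enc.ord_hi
    mk[:ntax] = enc.mask
    cost_ord = np.zeros(n_ord, dtype=np.int64)
    cost_unord = np.zeros(n_unord, dtype=np.int64)

    def merge(a, b, out):
        if n_ord:
            ga = np.maximum(lo[a], lo[b])
            gb = np.minimum(hi[a], hi[b])
            gap = ga - gb
            np.maximum(gap, 0, out=gap)
            nonlocal cost_ord
            cost_ord = cost_ord + gap
            disjoint = gap > 0
            lo[out] = np.where(disjoint, gb, ga)
            hi[out] = np.where(disjoint, ga, gb)
        if n_unord:
            inter = mk[a] & mk[b]
            empty = inter == 0
            nonlocal cost_unord
            cost_unord = cost_unord + empty
            mk[out] = np.where(empty, mk[a] | mk[b], inter)

    for parent, left, right in plan:
        merge(left, right, parent)
    # final combine with the root leaf (scratch slot reuses the root's row)
    root_internal = plan[-1][0] if plan else None
    if root_internal is not None:
        merge(root_internal, root_leaf, root_internal)
    steps = np.zeros(enc.matrix.nchar, dtype=np.int64)
    for k, j in enumerate(enc.ord_cols):
        steps[j] = cost_ord[k]
    for k, j in enumerate(enc.unord_cols):
        steps[j] = cost_unord[k]
    return steps + enc.surcharge


def tree_length(
    tree: Topology,
    matrix: CharacterMatrix | EncodedMatrix,
    polymorphism: str = "uncertainty",
) -> tuple[int, np.ndarray]:
    """Total parsimony length of ``tree`` and per-character steps.

    The length is invariant to root placement and character order.
    """
    enc = (
        matrix
        if isinstance(matrix, EncodedMatrix)
        else encode_matrix(matrix, polymorphism)
    )
    if tree.taxa != enc.matrix.taxa:
        raise ValueError("tree taxa do not match matrix taxa")
    if tree.n_leaves == 2:
        steps = _two_leaf_steps(enc)
        return int(steps.sum()), steps
    n_nodes = len(tree.adj)
    plan = tree.postorder(0)
    steps = _lengths_from_plan(enc, plan, 0, n_nodes)
    return int(steps.sum()), steps


def _two_leaf_steps(enc: EncodedMatrix) -> np.ndarray:
    steps = np.zeros(enc.matrix.nchar, dtype=np.int64)
    for k, j in enumerate(enc.ord_cols):
        gap = max(enc.ord_lo[:, k].max() - enc.ord_hi[:, k].min(), 0)
        steps[j] = gap
    for k, j in enumerate(enc.unord_cols):
        steps[j] = int(enc.mask[0, k] & enc.mask[1, k] == 0)
    return steps + enc.surcharge


def char_bounds(
    matrix: CharacterMatrix,
    char_id: int,
    polymorphism: str = "uncertainty",
) -> tuple[int, int]:
    """(m, g): minimum steps on any tree; steps on the star tree.

    ``m`` resolves ambiguity to minimise the required state span (ordered:
    smallest achievable range; unordered: smallest hitting set of the cell
    sets, minus one).  ``g`` is the best star-tree score over all central
    state assignments, again resolving ambiguity favourably.  An all-missing
    character is flagged uninformative with ``m = g = 0``.
    """
    j = matrix.char_index(char_id)
    char = matrix.characters[j]
    cells: list[Cell] = [row[j] for row in matrix.cells if row[j] is not None]
    if not cells:
        return 0, 0
    extra = 0
    if polymorphism == "as-both":
        for c in cells:
            if len(c) > 1:
                extra += (max(c) - min(c)) if char.ordered else (len(c) - 1)
    if char.ordered:
        m = max(0, max(min(c) for c in cells) - min(max(c) for c in cells))
        g = min(
            sum(max(0, min(c) - s, s - max(c)) for c in cells)
            for s in char.states
        )
        return m + extra, g + extra
    # unordered: m = smallest hitting set minus one (exact, tiny alphabets)
    alphabet = sorted(char.states)
    m = None
    for size in range(1, len(alphabet) + 1):
        for sub in combinations(alphabet, size):
            if all(c & set(sub) for c in cells):
                m = size - 1
                break
        if m is not None:
            break
    g = len(cells) - max(sum(1 for c in cells if s in c) for s in alphabet)
    return m + extra, g + extra
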