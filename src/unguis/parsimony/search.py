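"""Exhaustive and branch-and-bound search for most parsimonious trees.

Both searches enumerate unrooted binary topologies by stepwise leaf
insertion (taxon ``k`` is attached to each of the ``2k - 3`` branches of
every tree over the first ``k`` taxa), which generates each of the
``(2n - 5)!!`` topologies exactly once.  Branch-and-bound additionally
scores every partial tree: parsimony length can only grow as leaves are
added, so a partial tree already longer than the best complete tree found
so far is pruned together with its entire subtree of completions.  The two
searches return identical most-parsimonious (MP) sets; branch-and-bound is
simply faster.

Ensemble statistics over the MP set follow the standard definitions:
``TL = sum(s_i)``; ``CI = sum(m_i)/sum(s_i)``; ``HI = 1 - CI``;
``RI = (sum(g_i) - sum(s_i)) / (sum(g_i) - sum(m_i))`` (1 when the
denominator vanishes); ``RC = CI * RI`` — where ``s_i`` are observed steps,
``m_i`` the per-character minimum over all trees and ``g_i`` the star-tree
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .length import char_bounds, encode_matrix, tree_length
from .matrix import CharacterMatrix
from .trees import Topology

#: Exhaustive enumeration refuses above this taxon count (34,459,425 trees
#: at 12 taxa); branch_and_bound has no ceiling.
EXHAUSTIVE_CEILING = 11


@dataclass
class ParsimonyResult:
    """MP tree set with tree length and ensemble fit statistics."""

    mp_trees: list[Topology]
    TL: int
    per_char_steps: np.ndarray   # s_i on the first MP tree
    min_steps: np.ndarray        # m_i
    max_steps: np.ndarray        # g_i (star tree)
    CI: float
    HI: float
    RI: float
    RC: float
    n_trees_examined: int
    polymorphism: str = "uncertainty"

    def statistics(self, exclude_uninformative: bool = False) -> dict[str, float]:
        """TL/CI/HI/RI/RC, optionally over informative characters only.

        A character whose minimum and star-tree step counts coincide
        contributes the same steps to every topology and is treated as
        parsimony-uninformative.
        """
        s, m, g = self.per_char_steps, self.min_steps, self.max_steps
        if exclude_uninformative:
            keep = m != g
            s, m, g = s[keep], m[keep], g[keep]
        return _ensemble_stats(s, m, g)


def _ensemble_stats(s: np.ndarray, m: np.ndarray, g: np.ndarray) -> dict[str, float]:
    S, M, G = int(s.sum()), int(m.sum()), int(g.sum())
    CI = 1.0 if S == 0 else M / S
    RI = 1.0 if G == M else (G - S) / (G - M)
    return {"TL": S, "CI": CI, "HI": 1.0 - CI, "RI": RI, "RC": CI * RI}


class _Search:
    """Shared stepwise-insertion enumerator with optional pruning."""

    def __init__(self, matrix: CharacterMatrix, polymorphism: str, prune: bool):
        if matrix.ntax < 3:
            raise ValueError("searches need at least 3 taxa")
        self.matrix = matrix
        self.enc = encode_matrix(matrix, polymorphism)
        self.prune = prune
        n = matrix.ntax
        self.n = n
        max_nodes = 2 * n - 2
        self.n_ord = self.enc.ord_lo.shape[1]
        self.n_unord = self.enc.mask.shape[1]
        # plain-int state rows: tie-heavy searches evaluate every topology,
        # so the inner loop avoids per-merge array overhead entirely
        self.lo: list[list[int]] = [[0] * self.n_ord for _ in range(max_nodes)]
        self.hi: list[list[int]] = [[0] * self.n_ord for _ in range(max_nodes)]
        self.mk: list[list[int]] = [[0] * self.n_unord for _ in range(max_nodes)]
        for i in range(n):
            self.lo[i] = [int(x) for x in self.enc.ord_lo[i]]
            self.hi[i] = [int(x) for x in self.enc.ord_hi[i]]
            self.mk[i] = [int(x) for x in self.enc.mask[i]]
        self.adj: list[list[int]] = [[] for _ in range(max_nodes)]
        self.surcharge = int(self.enc.surcharge.sum())
        self.best: int | None = None
        self.mp_edges: list[list[tuple[int, int]]] = []
        self.examined = 0

    # -- scoring -----------------------------------------------------------
    def _partial_length(self) -> int:
        """Wagner/Fitch length of the current (possibly partial) tree."""
        adj = self.adj
        lo, hi, mk = self.lo, self.hi, self.mk
        n = self.n
        n_ord, n_unord = self.n_ord, self.n_unord
        total = 0
        # iterative postorder rooted at leaf 0
        start = adj[0][0]
        stack = [(start, 0, False)]
        order: list[tuple[int, int, int]] = []
        while stack:
            node, parent, processed = stack.pop()
            if node < n:
                continue
            kids = [x for x in adj[node] if x != parent]
            if processed:
                order.append((node, kids[0], kids[1]))
            else:
                stack.append((node, parent, True))
                stack.extend((k, node, False) for k in kids)
        order.append((start, start, 0))  # final merge with the root leaf
        for out, a, b in order:
            if n_ord:
                la, ha, lb, hb = lo[a], hi[a], lo[b], hi[b]
                lo_o, hi_o = lo[out], hi[out]
                for j in range(n_ord):
                    a1, a2 = la[j], lb[j]
                    ga = a1 if a1 > a2 else a2
                    b1, b2 = ha[j], hb[j]
                    gb = b1 if b1 < b2 else b2
                    if ga > gb:
                        total += ga - gb
                        lo_o[j] = gb
                        hi_o[j] = ga
                    else:
                        lo_o[j] = ga
                        hi_o[j] = gb
            if n_unord:
                ma, mb, mo = mk[a], mk[b], mk[out]
                for j in range(n_unord):
                    t = ma[j] & mb[j]
                    if t:
                        mo[j] = t
                    else:
                        total += 1
                        mo[j] = ma[j] | mb[j]
        # the root-leaf merge overwrote the scratch row for ``start``;
        # harmless, every evaluation recomputes all internal rows.
        return total + self.surcharge

    # -- enumeration -------------------------------------------------------
    def run(self) -> None:
        n, adj = self.n, self.adj
        first_internal = n
        adj[first_internal] = [0, 1, 2]
        for leaf in (0, 1, 2):
            adj[leaf] = [first_internal]
        edges = [(0, first_internal), (1, first_internal), (2, first_internal)]
        self._recurse(edges, next_taxon=3, next_internal=n + 1)

    def _record(self, edges: list[tuple[int, int]], length: int) -> None:
        if self.best is None or length < self.best:
            self.best = length
            self.mp_edges = [list(edges)]
        elif length == self.best:
            self.mp_edges.append(list(edges))

    def _recurse(self, edges, next_taxon: int, next_internal: int) -> None:
        if next_taxon == self.n:
            self.examined += 1
            self._record(edges, self._partial_length())
            return
        adj = self.adj
        k = next_taxon
        w = next_internal
        for idx in range(len(edges)):
            u, v = edges[idx]
            # insert leaf k on edge (u, v) via new internal node w
            adj[u][adj[u].index(v)] = w
            adj[v][adj[v].index(u)] = w
            adj[w] = [u, v, k]
            adj[k] = [w]
            edges[idx] = (u, w)
            edges.append((w, v))
            edges.append((w, k))
            if self.prune and self.best is not None:
                if self._partial_length() > self.best:
                    self._undo(edges, idx, u, v, w, k)
                    continue
            self._recurse(edges, k + 1, w + 1)
            self._undo(edges, idx, u, v, w, k)

    def _undo(self, edges, idx, u, v, w, k) -> None:
        adj = self.adj
        edges.pop()
        edges.pop()
        edges[idx] = (u, v)
        adj[u][adj[u].index(w)] = v
        adj[v][adj[v].index(w)] = u
        adj[w] = []
        adj[k] = []

    # -- results -----------------------------------------------------------
    def result(self) -> ParsimonyResult:
        mat = self.matrix
        trees = [Topology.from_edges(mat.taxa, e) for e in self.mp_edges]
        trees.sort(key=lambda t: t.newick(mat.outgroup or mat.taxa[0]))
        enc = self.enc
        TL, steps = tree_length(trees[0], enc)
        for t in trees[1:]:
            tl_other, _ = tree_length(t, enc)
            if tl_other != TL:  # pragma: no cover - defensive
                raise AssertionError("MP trees disagree in total length")
        bounds = [
            char_bounds(mat, c.id, enc.polymorphism) for c in mat.characters
        ]
        m = np.array([b[0] for b in bounds], dtype=np.int64)
        g = np.array([b[1] for b in bounds], dtype=np.int64)
        stats = _ensemble_stats(steps, m, g)
        return ParsimonyResult(
            mp_trees=trees, TL=stats["TL"], per_char_steps=steps,
            min_steps=m, max_steps=g, CI=stats["CI"], HI=stats["HI"],
            RI=stats["RI"], RC=stats["RC"], n_trees_examined=self.examined,
            polymorphism=enc.polymorphism,
        )


def exhaustive_search(
    matrix: CharacterMatrix,
    polymorphism: str = "uncertainty",
    ceiling: int = EXHAUSTIVE_CEILING,
) -> ParsimonyResult:
    """Score every unrooted binary topology; guaranteed MP set.

    Refuses above ``ceiling`` taxa (the tree count grows as ``(2n - 5)!!``);
    use :func:`branch_and_bound` beyond that — it returns the same MP set.
    """
    if matrix.ntax > ceiling:
        raise ValueError(
            f"{matrix.ntax} taxa exceed the exhaustive ceiling of {ceiling}; "
            "use branch_and_bound, which returns an identical MP set"
        )
    s = _Search(matrix, polymorphism, prune=False)
    s.run()
    return s.result()


def branch_and_bound(
    matrix: CharacterMatrix, polymorphism: str = "uncertainty"
) -> ParsimonyResult:
    """Exact MP search with monotone-length pruning of partial trees."""
    s = _Search(matrix, polymorphism, prune=True)
    s.run()
    return s.result()
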