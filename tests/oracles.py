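"""Independent brute-force oracles used to validate the parsimony engine.

These deliberately avoid the package's dynamic programming: tree length is
found by enumerating every assignment of single states to internal nodes
and summing explicit edge costs, and the star-tree score by scanning all
central states.  Exponential, so only usable at tiny sizes — which is the
point.
"""

from __future__ import annotations

import itertools

from unguis.parsimony.matrix import CharacterMatrix
from unguis.parsimony.trees import Topology


def _dist(a: int, b: int, ordered: bool) -> int:
    if ordered:
        return abs(a - b)
    return 0 if a == b else 1


def brute_force_tree_length(tree: Topology, matrix: CharacterMatrix) -> int:
    """Minimum total cost over all internal-node state assignments."""
    n = tree.n_leaves
    internals = [i for i in range(len(tree.adj)) if i >= n]
    edges = tree.edges
    total = 0
    for j, char in enumerate(matrix.characters):
        ordered = char.ordered
        states = char.states
        leaf_sets = []
        for i in range(n):
            c = matrix.cells[i][j]
            leaf_sets.append(tuple(states) if c is None else tuple(sorted(c)))
        best = None
        for assign in itertools.product(states, repeat=len(internals)):
            amap = dict(zip(internals, assign))
            cost = 0
            for u, v in edges:
                if u < n and v < n:  # only in 2-taxon trees
                    cost += min(
                        _dist(a, b, ordered)
                        for a in leaf_sets[u] for b in leaf_sets[v]
                    )
                elif u < n:
                    cost += min(_dist(a, amap[v], ordered) for a in leaf_sets[u])
                elif v < n:
                    cost += min(_dist(amap[u], b, ordered) for b in leaf_sets[v])
                else:
                    cost += _dist(amap[u], amap[v], ordered)
            if best is None or cost < best:
                best = cost
        total += best
    return total


def brute_force_star_score(matrix: CharacterMatrix, char_id: int) -> int:
    """Best star-tree score: scan every central state assignment."""
    j = matrix.char_index(char_id)
    char = matrix.characters[j]
    cells = [row[j] for row in matrix.cells if row[j] is not None]
    if not cells:
        return 0
    best = None
    for c in char.states:
        cost = 0
        for cell in cells:
            cost += min(_dist(s, c, char.ordered) for s in cell)
        if best is None or cost < best:
            best = cost
    return best
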