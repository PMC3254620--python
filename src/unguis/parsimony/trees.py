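"""Unrooted binary tree topologies over a fixed taxon set.

Leaves are numbered ``0 .. n-1`` in the order of ``taxa``; internal nodes
take larger ids.  An unrooted binary tree over ``n`` taxa has ``2n - 3``
edges and ``n - 2`` internal nodes.  For display the tree is rooted on the
outgroup: the outgroup leaf becomes the first child of the root.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Topology:
    """Immutable unrooted binary tree; ``adj`` maps node -> sorted neighbours."""

    taxa: tuple[str, ...]
    adj: tuple[tuple[int, ...], ...]  # index = node id

    @classmethod
    def from_edges(cls, taxa, edges) -> "Topology":
        n_nodes = max(max(e) for e in edges) + 1
        nbr: list[list[int]] = [[] for _ in range(n_nodes)]
        for u, v in edges:
            nbr[u].append(v)
            nbr[v].append(u)
        n = len(taxa)
        for i in range(n):
            if len(nbr[i]) != 1:
                raise ValueError(f"leaf {i} must have degree 1")
        for i in range(n, n_nodes):
            if len(nbr[i]) != 3:
                raise ValueError(f"internal node {i} must have degree 3")
        if len(edges) != 2 * n - 3:
            raise ValueError(f"expected {2 * n - 3} edges, got {len(edges)}")
        return cls(taxa=tuple(taxa), adj=tuple(tuple(sorted(x)) for x in nbr))

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def edges(self) -> list[tuple[int, int]]:
        out = []
        for u, nbrs in enumerate(self.adj):
            for v in nbrs:
                if u < v:
                    out.append((u, v))
        return out

    # -- traversal ---------------------------------------------------------
    def postorder(self, root_leaf: int = 0) -> list[tuple[int, int, int]]:
        """Postorder merge plan rooted at ``root_leaf``.

        Returns triples ``(parent, left, right)``; the last triple's parent
        is the internal node adjacent to ``root_leaf``.
        """
        start = self.adj[root_leaf][0]
        plan: list[tuple[int, int, int]] = []
        stack = [(start, root_leaf, False)]
        while stack:
            node, parent, processed = stack.pop()
            if node < self.n_leaves:
                continue
            kids = [x for x in self.adj[node] if x != parent]
            if processed:
                plan.append((node, kids[0], kids[1]))
            else:
                stack.append((node, parent, True))
                for k in kids:
                    stack.append((k, node, False))
        return plan

    # -- identity & display ------------------------------------------------
    def canonical_key(self) -> tuple:
        """Hashable key identical for topologically equal trees."""
        return tuple(sorted(tuple(sorted(s)) for s in self.splits(nontrivial=True)))

    def splits(self, nontrivial: bool = True) -> set[frozenset[int]]:
        """Bipartitions as the leaf side not containing leaf 0."""
        out: set[frozenset[int]] = set()
        for parent, left, right in self.postorder(0):
            for child in (left, right):
                leaves = self._leafset(child, parent)
                if not nontrivial or 2 <= len(leaves) <= self.n_leaves - 2:
                    out.add(frozenset(leaves))
        return out

    def _leafset(self, node: int, parent: int) -> set[int]:
        if node < self.n_leaves:
            return {node}
        out: set[int] = set()
        for k in self.adj[node]:
            if k != parent:
                out |= self._leafset(k, node)
        return out

    def newick(self, outgroup: str | None = None) -> str:
        """Newick rooted on the outgroup (outgroup = first child of root)."""
        og = self.taxa.index(outgroup) if outgroup else 0

        def sub(node: int, parent: int) -> str:
            if node < self.n_leaves:
                return _quote(self.taxa[node])
            kids = sorted(
                (sub(k, node) for k in self.adj[node] if k != parent)
            )
            return "(" + ",".join(kids) + ")"

        inner = self.adj[og][0]
        return f"({_quote(self.taxa[og])},{sub(inner, og)});"


def _quote(name: str) -> str:
    if any(ch in name for ch in " ()[]{}:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name
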