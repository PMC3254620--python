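"""Strict and majority-rule consensus of tree sets by bipartition counting."""

from __future__ import annotations

from dataclasses import dataclass

from .trees import Topology, _quote


@dataclass
class ConsensusTree:
    """Possibly multifurcating consensus with per-clade support frequencies.

    Clades are taxon-name frozensets measured on trees rooted at the
    reference taxon (the outgroup when given, else the first taxon);
    ``support`` maps each retained clade to its frequency in the input set.
    """

    taxa: tuple[str, ...]
    reference: str
    support: dict[frozenset, float]
    rule: str

    def contains_clade(self, names) -> bool:
        return frozenset(names) in self.support

    def newick(self, decimals: int = 2) -> str:
        """Newick with support frequencies as internal node labels."""
        n = len(self.taxa)
        ref = self.reference
        rest = [t for t in self.taxa if t != ref]

        # nest clades: each clade's parent is its smallest strict superset
        children: dict[frozenset | None, list[frozenset]] = {None: []}
        parent_of: dict[frozenset, frozenset | None] = {}
        bysize = sorted(self.support, key=len, reverse=True)
        for c in bysize:
            children[c] = []
        root = frozenset(rest)
        for c in bysize:
            if c == root:
                parent_of[c] = None
            else:
                sups = [s for s in bysize if len(s) > len(c) and c < s]
                parent_of[c] = min(sups, key=len, default=None)
            children.setdefault(parent_of[c], []).append(c)
        placed: dict[frozenset | None, set[str]] = {}
        for c in list(children):
            kids = children[c]
            covered = set().union(*kids) if kids else set()
            base = set(c) if c is not None else set(rest)
            placed[c] = base - covered

        def render(c: frozenset | None) -> str:
            parts = sorted(_quote(t) for t in placed[c])
            parts += sorted(render(k) for k in children[c])
            label = ""
            if c is not None and c != root:
                label = f"{self.support[c]:.{decimals}f}"
            return "(" + ",".join(parts) + ")" + label

        if root in self.support:
            inner = render(root)
        else:
            # no full ingroup clade recorded: hang everything off the root
            inner = render(None)
        return f"({_quote(ref)},{inner});"


def consensus(
    trees: list[Topology],
    rule: str = "majority",
    threshold: float = 0.5,
    outgroup: str | None = None,
) -> ConsensusTree:
    """Consensus of one or more topologies on an identical taxon set.

    ``strict`` keeps clades present in every tree; ``majority`` keeps those
    with frequency strictly above ``threshold``.  Clades are counted as
    bipartition sides not containing the reference taxon.
    """
    if not trees:
        raise ValueError("consensus needs at least one tree")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise ValueError("trees have mismatched taxon sets")
    if rule not in ("strict", "majority"):
        raise ValueError(f"unknown rule {rule!r}")
    ref = outgroup if outgroup is not None else taxa[0]
    if ref not in taxa:
        raise ValueError(f"outgroup {ref!r} not among the taxa")
    ref_i = taxa.index(ref)
    counts: dict[frozenset, int] = {}
    for t in trees:
        for side in t.splits(nontrivial=True):
            if ref_i in side:
                side = frozenset(range(len(taxa))) - side
            names = frozenset(taxa[i] for i in side)
            counts[names] = counts.get(names, 0) + 1
    ntrees = len(trees)
    ingroup = frozenset(t for t in taxa if t != ref)
    support: dict[frozenset, float] = {ingroup: 1.0}
    for names, c in counts.items():
        freq = c / ntrees
        keep = freq == 1.0 if rule == "strict" else freq > threshold
        if keep:
            support[names] = freq
    return ConsensusTree(taxa=taxa, reference=ref, support=support, rule=rule)
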