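"""Leaf-stability scores from bootstrap tree sets and rogue-taxon pruning.

A rogue taxon is a sequence whose attachment point varies wildly across
bootstrap replicates; it depresses support values without carrying
phylogenetic signal. Leaf stability quantifies this per taxon: every
3-taxon subset (triplet) containing the taxon induces, in each tree, one
of the three rooted topologies ab|c, ac|b, bc|a, or none when the taxa
meet at a polytomy. Let f1 >= f2 >= f3 be the frequencies of the three
topologies over the resolved trees. A stable taxon resolves the same way
almost everywhere (f1 near 1); a rogue spreads its votes (f1 near 1/3).

The per-taxon score is the mean over all triplets containing the taxon of
f1 (the ``max`` variant) or f1 - f2 (the ``difference`` variant);
triplets unresolved in every tree contribute nothing. The difference
variant is the default: under it a taxon wandering uniformly over the
tree scores far below the conventional 0.55 pruning cutoff regardless of
tree size, whereas the max variant of such a taxon levels off near 0.6
on moderate-size trees, above the cutoff. Above a cap the
triplets are subsampled with a seeded generator, keeping large tree sets
tractable (triplet counts grow as O(n^2) per taxon). Taxa scoring below
the chosen threshold (default 0.55) are pruned.

Polytomies contribute no vote rather than fractional votes; trees whose
leaf sets differ are rejected rather than silently intersected.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TreeSet",
    "StabilityTable",
    "read_tree_set",
    "triplet_frequencies",
    "leaf_stability_scores",
    "prune_unstable",
    "DEFAULT_THRESHOLD",
    "DEFAULT_VARIANT",
    "DEFAULT_MAX_TRIPLETS",
]

DEFAULT_THRESHOLD = 0.55
DEFAULT_MAX_TRIPLETS = 20_000
DEFAULT_VARIANT = "difference"


class TreeSetError(ValueError):
    pass


class TreeSet:
    """A set of leaf-labelled trees sharing one leaf set.

    Trees may be multifurcating. Internally each tree is reduced to its
    set of rooted clades as taxon bitmasks, which makes triplet
    resolution a couple of bit operations.
    """

    def __init__(self, trees: Sequence[dendropy.Tree]):
        if not trees:
            raise TreeSetError("empty tree set")
        leaf_sets = [
            frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in trees
        ]
        if len(set(leaf_sets)) != 1:
            raise TreeSetError(
                "trees have mismatched leaf sets; bootstrap replicates must "
                "share all taxa"
            )
        self.taxa: list[str] = sorted(leaf_sets[0])
        self.n_trees = len(trees)
        self._bit = {t: 1 << i for i, t in enumerate(self.taxa)}
        self._clades: list[list[int]] = [self._clade_masks(t) for t in trees]

    def _clade_masks(self, tree: dendropy.Tree) -> list[int]:
        masks = []

        def visit(node) -> int:
            if node.is_leaf():
                return self._bit[node.taxon.label]
            m = 0
            for child in node.child_nodes():
                m |= visit(child)
            masks.append(m)
            return m

        visit(tree.seed_node)
        masks.sort(key=_popcount)
        return masks

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def _mrca_mask(self, tree_idx: int, pair_mask: int) -> int:
        for m in self._clades[tree_idx]:
            if m & pair_mask == pair_mask:
                return m
        return (1 << self.n_taxa) - 1  # whole tree

    def resolve_triplet(self, tree_idx: int, a: int, b: int, c: int) -> Optional[int]:
        """Which leaf is the outlier of triplet (a,b,c) in one tree?

        Returns the bitmask of the leaf split off from the other two
        (e.g. ``c`` for topology ab|c), or None at a polytomy.
        """
        if self._mrca_mask(tree_idx, a | b) & c == 0:
            return c
        if self._mrca_mask(tree_idx, a | c) & b == 0:
            return b
        if self._mrca_mask(tree_idx, b | c) & a == 0:
            return a
        return None


def _popcount(x: int) -> int:
    return x.bit_count()


def read_tree_set(source: str | os.PathLike) -> TreeSet:
    """Read one Newick tree per line (multifurcations allowed)."""
    with open(source) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    namespace = dendropy.TaxonNamespace()
    trees = [
        dendropy.Tree.get(data=ln, schema="newick", taxon_namespace=namespace, preserve_underscores=True)
        for ln in lines
    ]
    return TreeSet(trees)


def tree_set_from_newicks(newicks: Iterable[str]) -> TreeSet:
    namespace = dendropy.TaxonNamespace()
    return TreeSet(
        [
            dendropy.Tree.get(data=nw, schema="newick", taxon_namespace=namespace, preserve_underscores=True)
            for nw in newicks
        ]
    )


def triplet_frequencies(
    ts: TreeSet, triplet: Sequence[str]
) -> tuple[tuple[float, float, float], int]:
    """Frequencies of the three topologies of one triplet, sorted descending.

    Frequencies are over resolved trees only and sum to 1 when at least
    one tree resolves the triplet; otherwise all three are 0. The second
    return value counts unresolved (polytomy) trees.
    """
    missing = [t for t in triplet if t not in ts._bit]
    if missing or len(set(triplet)) != 3:
        raise TreeSetError(f"invalid triplet {tuple(triplet)}: not 3 distinct leaves")
    a, b, c = (ts._bit[t] for t in triplet)
    counts = {a: 0, b: 0, c: 0}
    unresolved = 0
    for i in range(ts.n_trees):
        outlier = ts.resolve_triplet(i, a, b, c)
        if outlier is None:
            unresolved += 1
        else:
            counts[outlier] += 1
    resolved = ts.n_trees - unresolved
    if resolved == 0:
        return (0.0, 0.0, 0.0), unresolved
    freqs = sorted((n / resolved for n in counts.values()), reverse=True)
    return (freqs[0], freqs[1], freqs[2]), unresolved


@dataclass
class StabilityTable:
    scores: dict[str, float]
    n_triplets: dict[str, int]
    variant: str
    n_trees: int
    seed: Optional[int]
    subsampled: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": list(self.scores),
                "score": [self.scores[t] for t in self.scores],
                "n_triplets": [self.n_triplets[t] for t in self.scores],
                "variant": self.variant,
            }
        ).sort_values("score", ignore_index=True)

    def min_taxon(self) -> str:
        return min(self.scores, key=lambda t: (self.scores[t], t))


def leaf_stability_scores(
    ts: TreeSet,
    variant: str = DEFAULT_VARIANT,
    max_triplets_per_taxon: int = DEFAULT_MAX_TRIPLETS,
    seed: int = 0,
) -> StabilityTable:
    """Score every taxon by mean triplet resolution frequency.

    All triplets containing a taxon are enumerated when their number
    (C(n-1, 2)) is at most ``max_triplets_per_taxon``; otherwise that
    many are drawn uniformly without replacement with a generator seeded
    from ``seed``, so results are reproducible. Triplets with zero
    resolved trees are excluded from the mean.
    """
    if variant not in ("max", "difference"):
        raise TreeSetError(f"unknown variant {variant!r}")
    if ts.n_taxa < 4:
        raise TreeSetError("leaf stability needs at least 4 leaves")
    rng = np.random.default_rng(seed)
    scores: dict[str, float] = {}
    n_used: dict[str, int] = {}
    subsampled = False
    others_all = ts.taxa
    for taxon in ts.taxa:
        others = [t for t in others_all if t != taxon]
        n_pairs = len(others) * (len(others) - 1) // 2
        if n_pairs <= max_triplets_per_taxon:
            pairs = itertools.combinations(others, 2)
        else:
            subsampled = True
            chosen = rng.choice(n_pairs, size=max_triplets_per_taxon, replace=False)
            chosen.sort()
            all_pairs = itertools.combinations(others, 2)
            chosen_set = iter(chosen)
            nxt = next(chosen_set)
            picked = []
            for idx, pair in enumerate(all_pairs):
                if idx == nxt:
                    picked.append(pair)
                    nxt = next(chosen_set, None)
                    if nxt is None:
                        break
            pairs = picked
        total = 0.0
        used = 0
        for x, y in pairs:
            (f1, f2, _), _ = triplet_frequencies(ts, (taxon, x, y))
            if f1 == 0.0:
                continue  # never resolved
            total += f1 if variant == "max" else f1 - f2
            used += 1
        scores[taxon] = total / used if used else 0.0
        n_used[taxon] = used
    return StabilityTable(
        scores=scores,
        n_triplets=n_used,
        variant=variant,
        n_trees=ts.n_trees,
        seed=seed if subsampled else None,
        subsampled=subsampled,
    )


def prune_unstable(
    table: StabilityTable, threshold: float = DEFAULT_THRESHOLD
) -> tuple[list[str], list[str]]:
    """Split taxa into (retained, removed): removed iff score < threshold.

    The inequality is strict — a taxon scoring exactly the threshold is
    retained.
    """
    removed = sorted(t for t, s in table.scores.items() if s < threshold)
    retained = sorted(t for t in table.scores if t not in set(removed))
    return retained, removed
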