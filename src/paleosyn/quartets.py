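"""Gene-tree quartet support for a focal three-clade split.

Given gene trees whose leaves are assigned to four groups — G1
(magnoliid-like), G2 (monocot-like), G3 (eudicot-like) and OUT — each tree
votes for one of the three unrooted resolutions of the split:

* T1: G2 + G3 sisters,
* T2: G1 + G3 sisters,
* T3: G1 + G2 sisters,

or "unresolved" when its quartets are star-like or tied. Low-support edges
can first be collapsed into polytomies (bootstrap below a threshold), which
is how weakly resolved gene trees stop voting. The aggregated tally feeds a
chi-square polytomy test: under a hard polytomy (zero-length internal branch
in coalescent units) the three resolutions are equally likely, each with
expected frequency 1/3.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import numpy as np
from scipy import stats

from .model import ValidationError, read_tree

logger = logging.getLogger(__name__)

GROUPS = ("G1", "G2", "G3", "OUT")
TOPOLOGIES = ("T1", "T2", "T3")
UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class QuartetTally:
    """Counts of gene trees supporting each resolution of the focal split."""

    n_t1: int
    n_t2: int
    n_t3: int
    n_unresolved: int
    n_skipped: int = 0

    @property
    def n_resolved(self) -> int:
        return self.n_t1 + self.n_t2 + self.n_t3

    @property
    def total(self) -> int:
        return self.n_resolved + self.n_unresolved

    @property
    def frequencies(self) -> tuple[float, float, float]:
        if self.n_resolved == 0:
            raise ValidationError("no resolved trees; frequencies undefined")
        n = self.n_resolved
        return (self.n_t1 / n, self.n_t2 / n, self.n_t3 / n)


def _as_tree(tree: dendropy.Tree | str) -> dendropy.Tree:
    if isinstance(tree, str):
        return read_tree(tree)
    return tree


def collapse_low_support(tree: dendropy.Tree, threshold: int) -> dendropy.Tree:
    """Contract internal edges with bootstrap support below ``threshold``.

    Missing supports are treated as 100 (fully supported), so collapsing is
    opt-in per edge evidence. The input tree is not modified.
    """
    if not 0 <= threshold <= 100:
        raise ValidationError(f"threshold {threshold} outside [0, 100]")
    tree = tree.clone(depth=1)
    to_collapse = []
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node.is_leaf() or edge.tail_node is None:
            continue
        support = getattr(node, "support", None)
        if support is None:
            support = 100
        if support < threshold:
            to_collapse.append(edge)
    for edge in to_collapse:
        edge.collapse()
    return tree


def _quartet_topology(pdm, taxa: dict[str, dendropy.Taxon]) -> str:
    """Resolve one quartet by the four-point condition on edge-count distances."""
    d = {
        (x, y): pdm.path_edge_count(taxa[x], taxa[y])
        for x, y in itertools.combinations(GROUPS, 2)
    }
    s_t3 = d[("G1", "G2")] + d[("G3", "OUT")]  # G1G2 | G3 OUT
    s_t2 = d[("G1", "G3")] + d[("G2", "OUT")]  # G1G3 | G2 OUT
    s_t1 = d[("G2", "G3")] + d[("G1", "OUT")]  # G2G3 | G1 OUT
    sums = {"T1": s_t1, "T2": s_t2, "T3": s_t3}
    best = min(sums.values())
    winners = [t for t, s in sums.items() if s == best]
    return winners[0] if len(winners) == 1 else UNRESOLVED


def classify_quartet(
    tree: dendropy.Tree | str, groups: Mapping[str, str]
) -> str:
    """Classify one gene tree as T1, T2, T3 or unresolved.

    ``groups`` maps leaf labels to {"G1","G2","G3","OUT"}. Every quartet with
    one representative per group is resolved by the four-point condition on
    unit-length (edge count) distances — a polytomy-induced star quartet
    votes unresolved — and the tree's call is the strict majority over its
    quartets; ties are unresolved. Rooting and leaf order do not matter.
    """
    tree = _as_tree(tree).clone(depth=1)
    # a degree-2 root would perturb edge-count distances across the root
    tree.deroot()
    members: dict[str, list[dendropy.Taxon]] = {g: [] for g in GROUPS}
    for leaf in tree.leaf_node_iter():
        g = groups.get(leaf.taxon.label)
        if g is not None:
            if g not in members:
                raise ValidationError(f"unknown group {g!r} for leaf {leaf.taxon.label!r}")
            members[g].append(leaf.taxon)
    empty = [g for g in GROUPS if not members[g]]
    if empty:
        raise ValidationError(f"tree has no leaf for group(s) {empty}")
    for edge in tree.preorder_edge_iter():
        edge.length = 1.0
    pdm = tree.phylogenetic_distance_matrix()
    votes: Counter[str] = Counter()
    for combo in itertools.product(*(members[g] for g in GROUPS)):
        taxa = dict(zip(GROUPS, combo))
        votes[_quartet_topology(pdm, taxa)] += 1
    resolved = {t: votes.get(t, 0) for t in TOPOLOGIES}
    best = max(resolved.values())
    winners = [t for t, c in resolved.items() if c == best]
    if best == 0 or len(winners) > 1:
        return UNRESOLVED
    return winners[0]


def tally_quartets(
    trees: Iterable[dendropy.Tree | str],
    groups: Mapping[str, str],
    collapse_threshold: int | None = None,
) -> QuartetTally:
    """Aggregate per-tree quartet classifications into a tally.

    Trees missing a group are skipped with a logged reason. Raises when no
    tree is classifiable at all.
    """
    counts: Counter[str] = Counter()
    skipped = 0
    for i, t in enumerate(trees):
        tree = _as_tree(t)
        if collapse_threshold is not None:
            tree = collapse_low_support(tree, collapse_threshold)
        try:
            counts[classify_quartet(tree, groups)] += 1
        except ValidationError as exc:
            skipped += 1
            logger.info("tree %d skipped: %s", i, exc)
    if sum(counts.values()) == 0:
        raise ValidationError("zero classifiable trees")
    return QuartetTally(
        n_t1=counts.get("T1", 0),
        n_t2=counts.get("T2", 0),
        n_t3=counts.get("T3", 0),
        n_unresolved=counts.get(UNRESOLVED, 0),
        n_skipped=skipped,
    )


def polytomy_test(tally: QuartetTally) -> tuple[float, float]:
    """Chi-square goodness-of-fit of the resolved counts against equal
    expectations (2 degrees of freedom). Returns (statistic, p_value)."""
    counts = np.array([tally.n_t1, tally.n_t2, tally.n_t3], dtype=float)
    if counts.sum() == 0:
        raise ValidationError("all resolved counts are zero")
    statistic, p_value = stats.chisquare(counts)
    return float(statistic), float(p_value)
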