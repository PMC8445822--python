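"""Region projection, adjacency patterns, and ancestral-state parsimony.

Labelled chromosomal regions (curated intervals on a reference genome) are
projected into other genomes through synteny blocks, giving for each genome
the ordered, oriented sequence of region occurrences along each chromosome
(:class:`RegionCatalog`). Consecutive occurrences define adjacencies between
facing region ends (head/tail, orientation-aware); the adjacency set of one
genome is its :class:`AdjacencyPattern`. Each adjacency observed in any leaf
becomes a binary presence/absence character and ancestral states on a rooted
species tree are reconstructed by unweighted parsimony. Chromosome fusions
create adjacencies and fissions destroy them, so a fusion on an internal
branch surfaces as a shared derived adjacency (synapomorphy) of the clade
below it.

Parsimony is computed as unit-cost Sankoff with a down pass of outside
costs, so that the reported per-node state is the exact set of states
attained in at least one most-parsimonious reconstruction: nodes where both
states are optimal are reported ambiguous, never silently resolved. The
minimal change count equals the Fitch minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .model import GenomeTable, RegionDefinition, ValidationError
from .synteny import SyntenyBlock

HEAD = "head"
TAIL = "tail"

#: An adjacency is an unordered pair of region ends, e.g.
#: ``frozenset({("A2", "tail"), ("B1", "head")})``.
Adjacency = frozenset


def adjacency(label_a: str, end_a: str, label_b: str, end_b: str) -> Adjacency:
    return frozenset({(label_a, end_a), (label_b, end_b)})


@dataclass(frozen=True)
class RegionOccurrence:
    """One occurrence of a labelled region along a chromosome."""

    label: str
    chromosome: str
    start: int  # rank or bp position used only for ordering
    end: int
    orientation: str  # "+" | "-"


@dataclass
class RegionCatalog:
    """Ordered, oriented region occurrences per chromosome for several species."""

    occurrences: dict[str, dict[str, list[RegionOccurrence]]]  # species -> chrom -> ordered
    missing: dict[str, list[str]] = field(default_factory=dict)  # species -> region labels

    @classmethod
    def from_arrangements(
        cls, arrangements: Mapping[str, Mapping[str, Sequence[tuple[str, str]]]]
    ) -> "RegionCatalog":
        """Build a catalog directly from per-species chromosome arrangements,
        e.g. ``{"magnoliid": {"chr1": [("A1", "+"), ("A2", "+")]}}``."""
        occ: dict[str, dict[str, list[RegionOccurrence]]] = {}
        for species, chroms in arrangements.items():
            occ[species] = {}
            for chrom, labels in chroms.items():
                occ[species][chrom] = [
                    RegionOccurrence(label, chrom, i, i + 1, orient)
                    for i, (label, orient) in enumerate(labels)
                ]
        return cls(occurrences=occ)

    def species(self) -> list[str]:
        return sorted(self.occurrences)


@dataclass
class AdjacencyPattern:
    """The set of region-end adjacencies of one genome or ancestor."""

    name: str
    adjacencies: frozenset[Adjacency]

    def linear_groups(self, all_labels: Iterable[str] | None = None) -> list[list[str]]:
        """Maximal paths of regions implied by the adjacencies.

        ``all_labels`` optionally names the full region universe so that
        regions without adjacencies appear as singletons. Each path is
        reported starting from a free (unconnected) end.
        """
        neighbour: dict[tuple[str, str], tuple[str, str]] = {}
        labels: set[str] = set(all_labels or ())
        for adj in self.adjacencies:
            (la, ea), (lb, eb) = sorted(adj)
            neighbour[(la, ea)] = (lb, eb)
            neighbour[(lb, eb)] = (la, ea)
            labels.update((la, lb))

        def other_end(end: tuple[str, str]) -> tuple[str, str]:
            return (end[0], HEAD if end[1] == TAIL else TAIL)

        groups: list[list[str]] = []
        seen: set[str] = set()
        starts = sorted(
            lab for lab in labels
            if (lab, HEAD) not in neighbour or (lab, TAIL) not in neighbour
        )
        for start in starts:
            if start in seen:
                continue
            free = (start, HEAD) if (start, HEAD) not in neighbour else (start, TAIL)
            path = [start]
            seen.add(start)
            cursor = other_end(free)  # walk away from the free end
            while cursor in neighbour:
                nxt = neighbour[cursor]
                if nxt[0] in seen:
                    break
                path.append(nxt[0])
                seen.add(nxt[0])
                cursor = other_end(nxt)
            groups.append(path)
        return sorted(groups)


def _validate_linear(adjacencies: Iterable[Adjacency], name: str) -> list[tuple[str, str]]:
    """Return region ends used by more than one adjacency (linearity violations)."""
    counts: dict[tuple[str, str], int] = {}
    for adj in adjacencies:
        for end in adj:
            counts[end] = counts.get(end, 0) + 1
    return sorted(end for end, c in counts.items() if c > 1)


# ---------------------------------------------------------------------------
# region projection
# ---------------------------------------------------------------------------

def _region_rank_span(region: RegionDefinition, genome: GenomeTable) -> tuple[int, int] | None:
    genes = [
        g
        for g in genome.chromosomes.get(region.chromosome, [])
        if g.start < region.end and g.end > region.start
    ]
    if not genes:
        return None
    ranks = [g.rank for g in genes]
    return min(ranks), max(ranks)


def map_regions(
    region_defs: Sequence[RegionDefinition],
    reference: GenomeTable,
    blocks_by_species: Mapping[str, Sequence[SyntenyBlock]],
    genomes: Mapping[str, GenomeTable],
    min_overlap: float = 0.5,
    merge_gap: int = 25,
) -> RegionCatalog:
    """Project reference region definitions into other genomes via synteny.

    A block projects a region when its reference-side rank span covers at
    least ``min_overlap`` of the region's gene span; the projected occurrence
    is placed at the subject-side ranks of the anchors inside the region, and
    occurrences of one region on one target chromosome closer than
    ``merge_gap`` ranks are merged. Regions with no syntenic coverage in a
    species are recorded in ``missing``.
    """
    ref_spans: dict[str, tuple[str, tuple[int, int]]] = {}
    for rd in region_defs:
        if rd.species != reference.species:
            raise ValidationError(
                f"region {rd.label!r} is on {rd.species!r}, not reference {reference.species!r}"
            )
        span = _region_rank_span(rd, reference)
        if span is not None:
            ref_spans[rd.label] = (rd.chromosome, span)

    catalog: dict[str, dict[str, list[RegionOccurrence]]] = {
        reference.species: _reference_occurrences(region_defs, reference)
    }
    missing: dict[str, list[str]] = {}

    for species, blocks in blocks_by_species.items():
        per_chrom: dict[str, list[RegionOccurrence]] = {}
        found: set[str] = set()
        raw: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        for label, (ref_chrom, (r0, r1)) in ref_spans.items():
            span_len = r1 - r0 + 1
            for b in blocks:
                if b.query_species == reference.species:
                    ref_is_query = True
                elif b.subject_species == reference.species:
                    ref_is_query = False
                else:
                    continue
                b_ref_chrom = b.query_chromosome if ref_is_query else b.subject_chromosome
                if b_ref_chrom != ref_chrom:
                    continue
                inside = [
                    a
                    for a in b.anchors
                    if r0 <= (a[0].rank if ref_is_query else a[1].rank) <= r1
                ]
                if len(inside) < min_overlap * span_len:
                    continue
                tgt_chrom = b.subject_chromosome if ref_is_query else b.query_chromosome
                tgt_ranks = [(a[1].rank if ref_is_query else a[0].rank) for a in inside]
                orient = "+" if b.orientation == "ascending" else "-"
                raw.setdefault((label, tgt_chrom), []).append(
                    (min(tgt_ranks), max(tgt_ranks), orient)
                )
                found.add(label)
        for (label, tgt_chrom), spans in raw.items():
            spans.sort()
            merged: list[list] = []
            for s0, s1, orient in spans:
                if merged and s0 - merged[-1][1] <= merge_gap:
                    merged[-1][1] = max(merged[-1][1], s1)
                    merged[-1][2].append(orient)
                else:
                    merged.append([s0, s1, [orient]])
            for s0, s1, orients in merged:
                orient = "+" if orients.count("+") >= orients.count("-") else "-"
                per_chrom.setdefault(tgt_chrom, []).append(
                    RegionOccurrence(label, tgt_chrom, s0, s1, orient)
                )
        for chrom in per_chrom:
            per_chrom[chrom].sort(key=lambda o: o.start)
        catalog[species] = per_chrom
        missing[species] = sorted(set(ref_spans) - found)

    return RegionCatalog(occurrences=catalog, missing=missing)


def _reference_occurrences(
    region_defs: Sequence[RegionDefinition], reference: GenomeTable
) -> dict[str, list[RegionOccurrence]]:
    per_chrom: dict[str, list[RegionOccurrence]] = {}
    for rd in region_defs:
        per_chrom.setdefault(rd.chromosome, []).append(
            RegionOccurrence(rd.label, rd.chromosome, rd.start, rd.end, "+")
        )
    for chrom in per_chrom:
        per_chrom[chrom].sort(key=lambda o: o.start)
    return per_chrom


# ---------------------------------------------------------------------------
# adjacencies
# ---------------------------------------------------------------------------

def extract_adjacencies(catalog: RegionCatalog, species: str) -> AdjacencyPattern:
    """Adjacencies between facing ends of consecutive region occurrences.

    A forward occurrence exposes its tail to the right and head to the left;
    a reversed occurrence the opposite. An end participating in more than one
    adjacency violates linearity and raises :class:`ValidationError`.
    """
    if species not in catalog.occurrences:
        raise ValidationError(f"species {species!r} not in catalog")
    adjacencies: set[Adjacency] = set()
    for chrom, occs in catalog.occurrences[species].items():
        for left, right in zip(occs, occs[1:]):
            end_left = TAIL if left.orientation == "+" else HEAD
            end_right = HEAD if right.orientation == "+" else TAIL
            adjacencies.add(adjacency(left.label, end_left, right.label, end_right))
    violations = _validate_linear(adjacencies, species)
    if violations:
        raise ValidationError(f"region end used twice in {species!r}: {violations[0]}")
    return AdjacencyPattern(name=species, adjacencies=frozenset(adjacencies))


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

PRESENT = "present"
ABSENT = "absent"
AMBIGUOUS = "ambiguous"


@dataclass
class AncestralReconstruction:
    """Parsimony states per tree node for every adjacency character."""

    tree: dendropy.Tree
    characters: list[Adjacency]
    states: dict[str, dict[Adjacency, str]]  # node key -> character -> state
    change_counts: dict[Adjacency, int]
    node_patterns: dict[str, AdjacencyPattern]
    linearity_violations: dict[str, list[tuple[str, str]]]

    @property
    def total_changes(self) -> int:
        return sum(self.change_counts.values())


def _node_key(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return "{" + ",".join(sorted(l.taxon.label for l in node.leaf_iter())) + "}"


def _sankoff_binary(
    tree: dendropy.Tree, leaf_state: Mapping[str, bool]
) -> tuple[dict[dendropy.Node, str], int]:
    """Unit-cost binary Sankoff with exact most-parsimonious state sets.

    Returns per-node state (present/absent/ambiguous, leaves included) and
    the minimal change count.
    """
    INF = float("inf")
    up: dict[dendropy.Node, tuple[float, float]] = {}  # (cost absent, cost present)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            present = leaf_state[node.taxon.label]
            up[node] = (INF, 0.0) if present else (0.0, INF)
        else:
            ca = cp = 0.0
            for child in node.child_nodes():
                a, p = up[child]
                ca += min(a, p + 1.0)
                cp += min(a + 1.0, p)
            up[node] = (ca, cp)

    root = tree.seed_node
    best = min(up[root])
    # outside costs: cost of the rest of the tree given a node's state
    down: dict[dendropy.Node, tuple[float, float]] = {root: (0.0, 0.0)}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent = node.parent_node
        pa, pp = down[parent]
        sib_a = sib_p = 0.0
        for sib in parent.child_nodes():
            if sib is node:
                continue
            a, p = up[sib]
            sib_a += min(a, p + 1.0)
            sib_p += min(a + 1.0, p)
        # parent-state cost excluding this child's subtree, plus the edge to it
        out_a = min(pa + sib_a, pp + sib_p + 1.0)
        out_p = min(pa + sib_a + 1.0, pp + sib_p)
        down[node] = (out_a, out_p)

    states: dict[dendropy.Node, str] = {}
    for node in tree.preorder_node_iter():
        a, p = up[node]
        oa, op = down[node]
        ok_a = a + oa <= best
        ok_p = p + op <= best
        if ok_a and ok_p:
            states[node] = AMBIGUOUS
        elif ok_p:
            states[node] = PRESENT
        else:
            states[node] = ABSENT
    return states, int(best)


def fitch_ancestral(
    patterns: Mapping[str, AdjacencyPattern], species_tree: dendropy.Tree
) -> AncestralReconstruction:
    """Reconstruct ancestral adjacency patterns on a rooted species tree.

    Every adjacency observed in at least one leaf is an independent binary
    character; per-node states are exact most-parsimonious sets (ties are
    ambiguous). Reconstructed node adjacency sets are validated for
    linearity; violations are recorded, not raised.
    """
    leaves = [l.taxon.label for l in species_tree.leaf_node_iter()]
    for leaf in leaves:
        if leaf not in patterns:
            raise ValidationError(f"leaf {leaf!r} has no adjacency pattern")
    characters = sorted(
        {adj for leaf in leaves for adj in patterns[leaf].adjacencies},
        key=lambda a: sorted(a),
    )
    states: dict[str, dict[Adjacency, str]] = {}
    change_counts: dict[Adjacency, int] = {}
    for char in characters:
        leaf_state = {leaf: char in patterns[leaf].adjacencies for leaf in leaves}
        node_states, changes = _sankoff_binary(species_tree, leaf_state)
        change_counts[char] = changes
        for node, st in node_states.items():
            states.setdefault(_node_key(node), {})[char] = st

    node_patterns: dict[str, AdjacencyPattern] = {}
    violations: dict[str, list[tuple[str, str]]] = {}
    for key, char_states in states.items():
        present = frozenset(c for c, st in char_states.items() if st == PRESENT)
        node_patterns[key] = AdjacencyPattern(name=key, adjacencies=present)
        v = _validate_linear(present, key)
        if v:
            violations[key] = v
    return AncestralReconstruction(
        tree=species_tree,
        characters=characters,
        states=states,
        change_counts=change_counts,
        node_patterns=node_patterns,
        linearity_violations=violations,
    )


def find_synapomorphies(
    recon: AncestralReconstruction, clade: str | Iterable[str]
) -> frozenset[Adjacency]:
    """Adjacencies present at a clade's ancestor and absent (not ambiguous)
    at its parent node. ``clade`` is an internal node label or a collection
    of the clade's leaf names."""
    if isinstance(clade, str):
        target_key = clade
        node = next(
            (n for n in recon.tree.preorder_node_iter() if _node_key(n) == clade), None
        )
    else:
        want = frozenset(clade)
        node = None
        for n in recon.tree.preorder_node_iter():
            if frozenset(l.taxon.label for l in n.leaf_iter()) == want:
                node = n
                break
        target_key = _node_key(node) if node is not None else str(sorted(want))
    if node is None:
        raise ValidationError(f"clade {target_key!r} not found in tree")
    if node.parent_node is None:
        raise ValidationError("the root has no parent; synapomorphies are undefined")
    node_states = recon.states[_node_key(node)]
    parent_states = recon.states[_node_key(node.parent_node)]
    return frozenset(
        c
        for c in recon.characters
        if node_states[c] == PRESENT and parent_states[c] == ABSENT
    )
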