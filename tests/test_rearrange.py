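"""Region projection, adjacency extraction and adjacency-character parsimony.

The parsimony brute-force oracle enumerates every assignment of
presence/absence to the internal nodes of a tree and takes the minimum
number of state changes over edges, which the reconstruction must match.
"""

import itertools

import numpy as np
import pytest

from paleosyn.model import RegionDefinition, ValidationError, read_tree
from paleosyn.pipeline import synteny_blocks_between
from paleosyn.rearrange import (
    AdjacencyPattern,
    RegionCatalog,
    adjacency,
    extract_adjacencies,
    find_synapomorphies,
    fitch_ancestral,
    map_regions,
)
from paleosyn.simulate import EvolutionScenario, Fusion, simulate_genomes

from conftest import ANGIOSPERM_TREE, REGION_LABELS, make_genome


class TestExtractAdjacencies:
    def test_forward_run_yields_facing_ends(self):
        cat = RegionCatalog.from_arrangements(
            {"sp": {"c": [("A1", "+"), ("A2", "+"), ("B1", "+"), ("B2", "+")]}}
        )
        pattern = extract_adjacencies(cat, "sp")
        assert pattern.adjacencies == frozenset(
            {
                adjacency("A1", "tail", "A2", "head"),
                adjacency("A2", "tail", "B1", "head"),
                adjacency("B1", "tail", "B2", "head"),
            }
        )

    def test_singleton_region_has_no_adjacency(self):
        cat = RegionCatalog.from_arrangements({"sp": {"c": [("E", "+")]}})
        assert extract_adjacencies(cat, "sp").adjacencies == frozenset()

    def test_reversed_occurrence_flips_facing_end(self):
        cat = RegionCatalog.from_arrangements({"sp": {"c": [("A1", "+"), ("A2", "-")]}})
        pattern = extract_adjacencies(cat, "sp")
        assert pattern.adjacencies == frozenset({adjacency("A1", "tail", "A2", "tail")})

    def test_end_reuse_violates_linearity(self):
        cat = RegionCatalog.from_arrangements(
            {"sp": {"c1": [("A1", "+"), ("A2", "+")], "c2": [("B1", "+"), ("A2", "+")]}}
        )
        with pytest.raises(ValidationError, match="used twice"):
            extract_adjacencies(cat, "sp")

    def test_relabelling_commutes(self):
        arrangement = {"c": [("A1", "+"), ("A2", "-"), ("B1", "+")]}
        rename = {"A1": "X", "A2": "Y", "B1": "Z"}
        cat = RegionCatalog.from_arrangements({"sp": arrangement})
        renamed_arr = {
            "c": [(rename[l], o) for l, o in arrangement["c"]]
        }
        cat2 = RegionCatalog.from_arrangements({"sp": renamed_arr})
        direct = extract_adjacencies(cat2, "sp").adjacencies
        mapped = frozenset(
            frozenset((rename[l], e) for l, e in adj)
            for adj in extract_adjacencies(cat, "sp").adjacencies
        )
        assert direct == mapped


def parsimony_bruteforce(tree, leaf_state):
    """Minimum changes over all internal assignments of a binary character."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for assignment in itertools.product((False, True), repeat=len(internals)):
        state = dict(zip(internals, assignment))
        for leaf in tree.leaf_node_iter():
            state[leaf] = leaf_state[leaf.taxon.label]
        changes = sum(
            1
            for node in tree.preorder_node_iter()
            if node.parent_node is not None and state[node] != state[node.parent_node]
        )
        best = changes if best is None else min(best, changes)
    return best


def random_tree(rng, n_leaves):
    names = [f"L{i}" for i in range(n_leaves)]
    nodes = list(names)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return read_tree(nodes[0] + ";")


class TestFitchAncestral:
    def test_shared_adjacency_present_everywhere(self):
        adj = adjacency("A1", "tail", "A2", "head")
        patterns = {
            leaf: AdjacencyPattern(leaf, frozenset({adj}))
            for leaf in ("w", "x", "y", "z")
        }
        tree = read_tree("((w,x),(y,z));")
        recon = fitch_ancestral(patterns, tree)
        assert recon.change_counts[adj] == 0
        assert all(states[adj] == "present" for states in recon.states.values())

    def test_change_counts_match_bruteforce(self):
        rng = np.random.default_rng(2024)
        adj = adjacency("R1", "tail", "R2", "head")
        for _ in range(40):
            n_leaves = int(rng.integers(3, 7))
            tree = random_tree(rng, n_leaves)
            leaf_state = {f"L{i}": bool(rng.integers(0, 2)) for i in range(n_leaves)}
            patterns = {
                leaf: AdjacencyPattern(
                    leaf, frozenset({adj}) if present else frozenset()
                )
                for leaf, present in leaf_state.items()
            }
            if not any(leaf_state.values()):
                continue  # character unobserved: no character to reconstruct
            recon = fitch_ancestral(patterns, tree)
            assert recon.change_counts[adj] == parsimony_bruteforce(tree, leaf_state)

    def test_missing_leaf_pattern_rejected(self):
        tree = read_tree("((w,x),(y,z));")
        patterns = {l: AdjacencyPattern(l, frozenset()) for l in ("w", "x", "y")}
        with pytest.raises(ValidationError, match="z"):
            fitch_ancestral(patterns, tree)

    def test_angiosperm_worked_example(self, angiosperm_patterns):
        """The printed ancestral patterns of the major angiosperm clades."""
        tree = read_tree(ANGIOSPERM_TREE)
        recon = fitch_ancestral(angiosperm_patterns, tree)
        assert recon.node_patterns["magmono"].linear_groups(REGION_LABELS) == [
            ["A1", "A2", "B1", "B2"],
            ["C1", "C2"],
            ["D1", "D2"],
            ["E"],
        ]
        assert recon.node_patterns["root"].linear_groups(REGION_LABELS) == [
            ["A1", "A2", "C1"],
            ["B1", "B2", "C2"],
            ["D1", "D2"],
            ["E"],
        ]
        assert recon.states["magmono"][adjacency("A2", "tail", "B1", "head")] == "present"
        assert recon.states["meso"][adjacency("A2", "tail", "B1", "head")] == "absent"
        assert not recon.linearity_violations

    def test_ambiguity_reported_not_resolved(self):
        # presence only in one of two basal leaves: the root state is a tie
        adj = adjacency("R1", "tail", "R2", "head")
        patterns = {
            "a": AdjacencyPattern("a", frozenset({adj})),
            "b": AdjacencyPattern("b", frozenset()),
        }
        tree = read_tree("(a,b)root;")
        recon = fitch_ancestral(patterns, tree)
        assert recon.states["root"][adj] == "ambiguous"


class TestSynapomorphies:
    def test_bb_c1_exchange_is_the_magmono_synapomorphy(self, angiosperm_patterns):
        tree = read_tree(ANGIOSPERM_TREE)
        recon = fitch_ancestral(angiosperm_patterns, tree)
        syn = find_synapomorphies(recon, "magmono")
        assert syn == frozenset(
            {
                adjacency("A2", "tail", "B1", "head"),
                adjacency("C1", "tail", "C2", "head"),
            }
        )

    def test_identical_leaves_give_empty_sets(self):
        adj = adjacency("A1", "tail", "A2", "head")
        patterns = {
            l: AdjacencyPattern(l, frozenset({adj})) for l in ("w", "x", "y", "z")
        }
        tree = read_tree("((w,x)wx,(y,z)yz)r;")
        recon = fitch_ancestral(patterns, tree)
        assert find_synapomorphies(recon, "wx") == frozenset()
        assert find_synapomorphies(recon, "yz") == frozenset()

    def test_ambiguous_parent_excluded(self):
        adj = adjacency("R1", "tail", "R2", "head")
        patterns = {
            "a": AdjacencyPattern("a", frozenset({adj})),
            "b": AdjacencyPattern("b", frozenset({adj})),
            "c": AdjacencyPattern("c", frozenset()),
        }
        tree = read_tree("((a,b)ab,c)root;")
        recon = fitch_ancestral(patterns, tree)
        # root is ambiguous (gain on ab stem vs loss on c stem)
        assert recon.states["root"][adj] == "ambiguous"
        assert find_synapomorphies(recon, "ab") == frozenset()

    def test_unknown_clade_rejected(self, angiosperm_patterns):
        tree = read_tree(ANGIOSPERM_TREE)
        recon = fitch_ancestral(angiosperm_patterns, tree)
        with pytest.raises(ValidationError, match="not found"):
            find_synapomorphies(recon, "nope")


class TestMapRegions:
    def _reference_with_regions(self):
        ref = make_genome("R", {"r1": 40, "r2": 40})
        regions = [
            RegionDefinition("R1", "R", "r1", 0, 20000),
            RegionDefinition("R2", "R", "r1", 20000, 40000),
            RegionDefinition("R3", "R", "r2", 0, 40000),
        ]
        return ref, regions

    def test_identity_projection(self):
        scenario = EvolutionScenario(
            tree="(R:0.3,T:0.3);", n_chromosomes=2, genes_per_chromosome=40, seed=5
        )
        result = simulate_genomes(scenario)
        ref, target = result.genomes["R"], result.genomes["T"]
        blocks = synteny_blocks_between(ref, target, result.hits)
        regions = [
            RegionDefinition("R1", "R", "chr1", 0, 20000),
            RegionDefinition("R2", "R", "chr1", 20000, 40000),
            RegionDefinition("R3", "R", "chr2", 0, 40000),
        ]
        catalog = map_regions(regions, ref, {"T": blocks}, {"T": target})
        order = [
            [o.label for o in occs]
            for chrom, occs in sorted(catalog.occurrences["T"].items())
        ]
        assert order == [["R1", "R2"], ["R3"]]
        assert catalog.missing["T"] == []

    def test_region_with_no_coverage_reported_missing(self):
        ref, regions = self._reference_with_regions()
        catalog = map_regions(regions, ref, {"T": []}, {})
        assert catalog.missing["T"] == ["R1", "R2", "R3"]

    def test_split_chromosome_preserves_order_within_parts(self):
        from paleosyn.simulate import Fission

        scenario = EvolutionScenario(
            tree="(R:0.3,T:0.3);",
            n_chromosomes=1,
            genes_per_chromosome=60,
            events={"T": [Fission("chr1", 30)]},
            seed=6,
        )
        result = simulate_genomes(scenario)
        ref, target = result.genomes["R"], result.genomes["T"]
        blocks = synteny_blocks_between(ref, target, result.hits)
        regions = [
            RegionDefinition("P", "R", "chr1", 0, 15000),
            RegionDefinition("Q", "R", "chr1", 15000, 30000),
            RegionDefinition("S", "R", "chr1", 30000, 45000),
            RegionDefinition("U", "R", "chr1", 45000, 60000),
        ]
        catalog = map_regions(regions, ref, {"T": blocks}, {"T": target})
        occ = {
            chrom: [o.label for o in occs]
            for chrom, occs in catalog.occurrences["T"].items()
        }
        assert occ == {"chr1a": ["P", "Q"], "chr1b": ["S", "U"]}


class TestSimulatedFusionRecovery:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_fusion_on_stem_is_sole_synapomorphy(self, seed):
        """A fusion simulated on one internal branch is recovered as exactly
        that adjacency, synapomorphic for the descendant clade."""
        scenario = EvolutionScenario(
            tree="(((W:0.3,X:0.3)wx:0.3,(Y:0.3,Z:0.3)yz:0.3)in:0.2,O:0.8);",
            n_chromosomes=3,
            genes_per_chromosome=40,
            events={"wx": [Fusion("chr1", "chr2")]},
            seed=seed,
        )
        result = simulate_genomes(scenario)
        ref = result.genomes["Y"]  # unfused reference
        others = [sp for sp in result.truth.leaf_names if sp != "Y"]
        regions = [
            RegionDefinition("R1", "Y", "chr1", 0, 40000),
            RegionDefinition("R2", "Y", "chr2", 0, 40000),
            RegionDefinition("R3", "Y", "chr3", 0, 40000),
        ]
        blocks_by = {
            sp: synteny_blocks_between(ref, result.genomes[sp], result.hits)
            for sp in others
        }
        catalog = map_regions(regions, ref, blocks_by, result.genomes)
        patterns = {
            sp: extract_adjacencies(catalog, sp) for sp in result.truth.leaf_names
        }
        tree = read_tree("(((W,X)wx,(Y,Z)yz)in,O)root;")
        recon = fitch_ancestral(patterns, tree)
        assert find_synapomorphies(recon, "wx") == frozenset(
            {adjacency("R1", "tail", "R2", "head")}
        )
        assert find_synapomorphies(recon, "yz") == frozenset()
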