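"""Forward simulator of genome evolution with known ground truth.

An ancestral genome (chromosomes of single-copy gene families) is propagated
down a rooted species tree whose branch lengths are synonymous-divergence
(Ks) units. Per-branch events model the processes the pipeline is meant to
detect: whole-genome duplication with per-gene fractionation (each duplicate
retained independently with probability rho), chromosome fusion, fission,
reciprocal translocation and inversion. Per-branch rate multipliers scale Ks
accumulation, emulating unequal substitution rates between lineages.

Every emitted artifact is a pure function of (scenario, seed): leaf genomes
as :class:`~paleosyn.model.GenomeTable` (gene i of a chromosome occupies
[1000*i, 1000*i + 500)), homolog hits for all within-family pairs with
bitscore a deterministic decreasing function of true Ks, and a
:class:`GroundTruth` carrying families, per-pair Ks, per-branch WGD counts
and the genome arrangement at every tree node.

Separate generators cover the other pipeline inputs: paired coding
sequences whose expected Nei–Gojobori dS equals the requested Ks
(:func:`evolve_cds`), gene trees with multispecies-coalescent discordance
(:func:`simulate_gene_trees`, concordant with probability 1 - (2/3)e^(-t)),
and module-structured expression matrices (:func:`simulate_expression`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import GenomeTable, HomologHit, read_tree


class ScenarioError(ValueError):
    """An event references state that does not exist when it applies."""


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Wgd:
    """Whole-genome duplication; each duplicated gene is retained with
    probability ``retention``; ``time_fraction`` places the event along the
    branch (0 = branch start) for paralog Ks accounting."""

    retention: float
    time_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.retention <= 1:
            raise ScenarioError(f"WGD retention must be in (0, 1], got {self.retention}")
        if not 0 <= self.time_fraction <= 1:
            raise ScenarioError("WGD time_fraction must be in [0, 1]")


@dataclass(frozen=True)
class Fusion:
    chrom_a: str
    chrom_b: str
    end_a: str = "tail"  # which end of chrom_a is joined
    end_b: str = "head"


@dataclass(frozen=True)
class Fission:
    chrom: str
    gene_index: int


@dataclass(frozen=True)
class Translocation:
    """Reciprocal translocation: tails beyond the breakpoints are swapped."""

    chrom_a: str
    chrom_b: str
    break_a: int
    break_b: int


@dataclass(frozen=True)
class Inversion:
    chrom: str
    start: int
    end: int


Event = Wgd | Fusion | Fission | Translocation | Inversion


@dataclass(frozen=True)
class EvolutionScenario:
    """Full specification of a simulated history.

    ``tree`` is Newick with branch lengths in Ks units; ``events`` and
    ``rates`` are keyed by the child-node label of the branch they apply to
    (leaf name, or internal-node label; unlabelled internal nodes are
    auto-labelled n1, n2, ... in preorder).
    """

    tree: str
    n_chromosomes: int = 4
    genes_per_chromosome: int = 150
    events: Mapping[str, Sequence[Event]] = field(default_factory=dict)
    rates: Mapping[str, float] = field(default_factory=dict)
    ks_noise_sd: float = 0.03
    seed: int = 0


# ---------------------------------------------------------------------------
# internal genome representation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Copy:
    family: int
    strand: str
    # lineage markers: (marker, ks at the split) — two copies diverged at the
    # ks recorded where their histories first differ
    history: tuple[tuple[str, float], ...]


def _flip(genes: list[_Copy]) -> list[_Copy]:
    return [
        replace(g, strand="-" if g.strand == "+" else "+") for g in reversed(genes)
    ]


class _Genome:
    def __init__(self, chromosomes: dict[str, list[_Copy]]):
        self.chromosomes = chromosomes

    def clone(self) -> "_Genome":
        return _Genome({name: list(genes) for name, genes in self.chromosomes.items()})

    def require(self, name: str, event: Event) -> list[_Copy]:
        if name not in self.chromosomes:
            raise ScenarioError(
                f"event {event!r} references missing chromosome {name!r} "
                f"(have {sorted(self.chromosomes)})"
            )
        return self.chromosomes[name]

    def arrangement(self) -> dict[str, list[tuple[int, str]]]:
        return {
            name: [(g.family, g.strand) for g in genes]
            for name, genes in sorted(self.chromosomes.items())
        }


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must rediscover."""

    families: dict[str, str]  # gene_id -> family_id
    pair_ks: dict[tuple[str, str], float]  # sorted gene-id pair -> true Ks
    wgd_counts: dict[str, int]  # branch (child-node label) -> WGD count
    node_arrangements: dict[str, dict[str, list[tuple[int, str]]]]
    leaf_names: list[str]


@dataclass
class SimulationResult:
    genomes: dict[str, GenomeTable]
    hits: list[HomologHit]
    truth: GroundTruth


def _label_nodes(tree) -> None:
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.sim_label = node.taxon.label
        elif node.label:
            node.sim_label = node.label
        else:
            counter += 1
            node.sim_label = f"n{counter}"


def _apply_structural(genome: _Genome, event: Event) -> None:
    if isinstance(event, Fusion):
        a = genome.require(event.chrom_a, event)
        b = genome.require(event.chrom_b, event)
        left = a if event.end_a == "tail" else _flip(a)
        right = b if event.end_b == "head" else _flip(b)
        del genome.chromosomes[event.chrom_a]
        del genome.chromosomes[event.chrom_b]
        genome.chromosomes[f"{event.chrom_a}+{event.chrom_b}"] = left + right
    elif isinstance(event, Fission):
        genes = genome.require(event.chrom, event)
        if not 0 < event.gene_index < len(genes):
            raise ScenarioError(f"fission index {event.gene_index} outside {event.chrom!r}")
        del genome.chromosomes[event.chrom]
        genome.chromosomes[f"{event.chrom}a"] = genes[: event.gene_index]
        genome.chromosomes[f"{event.chrom}b"] = genes[event.gene_index :]
    elif isinstance(event, Translocation):
        a = genome.require(event.chrom_a, event)
        b = genome.require(event.chrom_b, event)
        if not (0 < event.break_a < len(a) and 0 < event.break_b < len(b)):
            raise ScenarioError(f"translocation breakpoints outside chromosomes: {event!r}")
        genome.chromosomes[event.chrom_a] = a[: event.break_a] + b[event.break_b :]
        genome.chromosomes[event.chrom_b] = b[: event.break_b] + a[event.break_a :]
    elif isinstance(event, Inversion):
        genes = genome.require(event.chrom, event)
        if not (0 <= event.start < event.end <= len(genes)):
            raise ScenarioError(f"inversion span outside chromosome: {event!r}")
        genome.chromosomes[event.chrom] = (
            genes[: event.start] + _flip(genes[event.start : event.end]) + genes[event.end :]
        )
    else:  # pragma: no cover
        raise ScenarioError(f"unknown event {event!r}")


def simulate_genomes(scenario: EvolutionScenario) -> SimulationResult:
    """Run a scenario and emit leaf genomes, homolog hits, and ground truth."""
    rng = np.random.default_rng(scenario.seed)
    tree = read_tree(scenario.tree)
    _label_nodes(tree)

    ancestor = _Genome(
        {
            f"chr{c + 1}": [
                _Copy(
                    family=c * scenario.genes_per_chromosome + i,
                    strand="+",
                    history=(("root", 0.0),),
                )
                for i in range(scenario.genes_per_chromosome)
            ]
            for c in range(scenario.n_chromosomes)
        }
    )

    node_arrangements: dict[str, dict[str, list[tuple[int, str]]]] = {}
    wgd_counts: dict[str, int] = {}
    leaf_states: dict[str, tuple[_Genome, float]] = {}

    def descend(node, genome: _Genome, ks_so_far: float) -> None:
        label = node.sim_label
        node_arrangements[label] = genome.arrangement()
        if node.is_leaf():
            leaf_states[label] = (genome, ks_so_far)
            return
        for child in node.child_nodes():
            clabel = child.sim_label
            rate = scenario.rates.get(clabel, 1.0)
            length = (child.edge.length or 0.0) * rate
            child_genome = genome.clone()
            # speciation marker: lineages entering different children diverge here
            for name, genes in child_genome.chromosomes.items():
                child_genome.chromosomes[name] = [
                    replace(g, history=g.history + ((f"spec:{clabel}", ks_so_far),))
                    for g in genes
                ]
            n_wgd = 0
            for event in scenario.events.get(clabel, ()):
                if isinstance(event, Wgd):
                    n_wgd += 1
                    ks_at = ks_so_far + event.time_fraction * length
                    marker = f"wgd:{clabel}:{n_wgd}"
                    originals = {}
                    duplicates = {}
                    for name, genes in child_genome.chromosomes.items():
                        originals[name] = [
                            replace(g, history=g.history + ((marker + ":0", ks_at),))
                            for g in genes
                        ]
                        keep = rng.random(len(genes)) < event.retention
                        duplicates[f"{name}_w{n_wgd}"] = [
                            replace(g, history=g.history + ((marker + ":1", ks_at),))
                            for g, k in zip(genes, keep)
                            if k
                        ]
                    child_genome = _Genome({**originals, **duplicates})
                else:
                    _apply_structural(child_genome, event)
            wgd_counts[clabel] = n_wgd
            descend(child, child_genome, ks_so_far + length)

    descend(tree.seed_node, ancestor, 0.0)

    genomes: dict[str, GenomeTable] = {}
    families: dict[str, str] = {}
    leaf_of: dict[str, str] = {}
    copies_by_family: dict[int, list[tuple[str, _Copy, float]]] = {}
    for leaf in sorted(leaf_states):
        genome, total_ks = leaf_states[leaf]
        records = []
        counter = 0
        for chrom in sorted(genome.chromosomes):
            for i, g in enumerate(genome.chromosomes[chrom]):
                gene_id = f"{leaf}g{counter:05d}"
                counter += 1
                records.append(
                    (chrom, 1000 * i, 1000 * i + 500, g.strand, gene_id, f"F{g.family:05d}")
                )
                families[gene_id] = f"F{g.family:05d}"
                leaf_of[gene_id] = leaf
                copies_by_family.setdefault(g.family, []).append((gene_id, g, total_ks))
        genomes[leaf] = GenomeTable.from_records(leaf, records)

    pair_ks: dict[tuple[str, str], float] = {}
    hits: list[HomologHit] = []
    for family in sorted(copies_by_family):
        members = copies_by_family[family]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                id_a, copy_a, total_a = members[i]
                id_b, copy_b, total_b = members[j]
                ks_true = _divergence_ks(copy_a, copy_b, total_a, total_b)
                key = tuple(sorted((id_a, id_b)))
                pair_ks[key] = ks_true
                ks_noisy = max(0.0, ks_true + rng.normal(0.0, scenario.ks_noise_sd))
                bitscore = 100.0 + 400.0 * math.exp(-ks_noisy / 2.0)
                evalue = 10.0 ** (-bitscore / 10.0)
                sp_a, sp_b = leaf_of[id_a], leaf_of[id_b]
                hits.append(HomologHit(id_a, id_b, sp_a, sp_b, bitscore, evalue))
                hits.append(HomologHit(id_b, id_a, sp_b, sp_a, bitscore, evalue))

    truth = GroundTruth(
        families=families,
        pair_ks=pair_ks,
        wgd_counts=wgd_counts,
        node_arrangements=node_arrangements,
        leaf_names=sorted(leaf_states),
    )
    return SimulationResult(genomes=genomes, hits=hits, truth=truth)


def _divergence_ks(copy_a: _Copy, copy_b: _Copy, total_a: float, total_b: float) -> float:
    """Ks between two copies: branch lengths accumulated by each since their
    histories first diverged (at a speciation or duplication marker)."""
    ks_div = None
    for (ma, ka), (mb, kb) in zip(copy_a.history, copy_b.history):
        if ma != mb:
            ks_div = min(ka, kb)
            break
    if ks_div is None:
        # one history is a prefix of the other; diverged at the first extra marker
        longer = copy_a if len(copy_a.history) > len(copy_b.history) else copy_b
        shorter = copy_b if longer is copy_a else copy_a
        if len(longer.history) == len(shorter.history):
            return 0.0  # identical histories: the same copy
        ks_div = longer.history[len(shorter.history)][1]
    return (total_a - ks_div) + (total_b - ks_div)


# ---------------------------------------------------------------------------
# coding-sequence divergence
# ---------------------------------------------------------------------------

#: 4-fold degenerate codon prefixes whose first/second-position single
#: changes are always nonsynonymous: exactly one synonymous site per codon.
_FOURFOLD_PREFIXES = ("GC", "GG", "CC", "AC", "GT", "TC")
_BASES = "ACGT"


@dataclass(frozen=True)
class CdsPair:
    pair_id: str
    gene_a: str
    gene_b: str
    seq_a: str
    seq_b: str
    true_ks: float
    saturated: bool


def expected_ps(ks: float) -> float:
    """Expected proportion of synonymous differences for a given dS under
    the Jukes–Cantor model (inverse of the dS correction)."""
    return 0.75 * (1.0 - math.exp(-4.0 * ks / 3.0))


def evolve_cds(
    pairs: "GroundTruth | Mapping[tuple[str, str], float]",
    codon_length: int = 300,
    seed: int = 0,
) -> list[CdsPair]:
    """Emit, per homolog pair, two in-frame CDS whose expected Nei–Gojobori
    dS equals the pair's true Ks.

    Ancestral sequences are built from 4-fold degenerate codons with exactly
    one synonymous site each, and third positions diverge by a Jukes–Cantor
    process with difference probability (3/4)(1 - e^(-4k/3)). Pairs whose
    expected synonymous difference proportion is in the saturation zone
    (>= 0.7) are emitted flagged.
    """
    if codon_length % 3 != 0:
        raise ValueError(f"codon_length {codon_length} not divisible by 3")
    pair_map = pairs.pair_ks if isinstance(pairs, GroundTruth) else dict(pairs)
    rng = np.random.default_rng(seed)
    n_codons = codon_length // 3
    out: list[CdsPair] = []
    for idx, ((gene_a, gene_b), ks) in enumerate(sorted(pair_map.items())):
        prefixes = rng.choice(len(_FOURFOLD_PREFIXES), size=n_codons)
        thirds = rng.choice(4, size=n_codons)
        ancestral = "".join(
            _FOURFOLD_PREFIXES[p] + _BASES[t] for p, t in zip(prefixes, thirds)
        )
        p = expected_ps(ks)
        mutate = rng.random(n_codons) < p
        shifts = rng.integers(1, 4, size=n_codons)  # uniform over the 3 other bases
        derived = list(ancestral)
        for c in np.nonzero(mutate)[0]:
            pos = 3 * int(c) + 2
            derived[pos] = _BASES[(_BASES.index(derived[pos]) + int(shifts[c])) % 4]
        out.append(
            CdsPair(
                pair_id=f"p{idx:05d}",
                gene_a=gene_a,
                gene_b=gene_b,
                seq_a=ancestral,
                seq_b="".join(derived),
                true_ks=float(ks),
                saturated=p >= 0.7,
            )
        )
    return out


def write_paired_fasta(pairs: Iterable[CdsPair], path) -> None:
    """Write pairs as FASTA with ids ``<pair_id>|<gene>`` (two records per pair)."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f">{p.pair_id}|{p.gene_a}\n{p.seq_a}\n")
            fh.write(f">{p.pair_id}|{p.gene_b}\n{p.seq_b}\n")


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

_DEFAULT_GROUPS = {"G1": ("mag1",), "G2": ("mon1",), "G3": ("eud1",), "OUT": ("out1",)}
_SISTERS = {"T1": ("G2", "G3"), "T2": ("G1", "G3"), "T3": ("G1", "G2")}


def simulate_gene_trees(
    n_trees: int,
    internal_branch_t: float,
    groups: Mapping[str, Sequence[str]] | None = None,
    bs_distribution=None,
    seed: int = 0,
    species_topology: str = "T3",
) -> list[str]:
    """Draw gene-tree topologies under the multispecies coalescent for one
    internal branch of length ``internal_branch_t`` coalescent units.

    The species-tree resolution is drawn with probability
    1 - (2/3)e^(-t); each discordant resolution with (1/3)e^(-t). Support
    labels for the focal edge come from ``bs_distribution`` (an int, or a
    callable rng -> int; default 100). Returns Newick strings.
    """
    if internal_branch_t < 0:
        raise ValueError("internal branch length must be >= 0")
    if species_topology not in _SISTERS:
        raise ValueError(f"species_topology must be one of {sorted(_SISTERS)}")
    groups = {g: tuple(v) for g, v in (groups or _DEFAULT_GROUPS).items()}
    rng = np.random.default_rng(seed)
    p_concordant = 1.0 - (2.0 / 3.0) * math.exp(-internal_branch_t)
    p_each_discordant = (1.0 / 3.0) * math.exp(-internal_branch_t)
    alternatives = [t for t in _SISTERS if t != species_topology]
    topologies = [species_topology, *alternatives]
    probs = [p_concordant, p_each_discordant, p_each_discordant]

    def clade(group: str) -> str:
        names = groups[group]
        if len(names) == 1:
            return names[0]
        return "(" + ",".join(names) + ")100"

    def support() -> str:
        if bs_distribution is None:
            return "100"
        if callable(bs_distribution):
            return str(int(bs_distribution(rng)))
        return str(int(bs_distribution))

    draws = rng.choice(3, size=n_trees, p=probs)
    trees = []
    for d in draws:
        topo = topologies[int(d)]
        a, b = _SISTERS[topo]
        c, o = [g for g in ("G1", "G2", "G3") if g not in (a, b)][0], "OUT"
        trees.append(
            f"(({clade(a)},{clade(b)}){support()},({clade(c)},{clade(o)}){support()});"
        )
    return trees


def default_group_assignment(
    groups: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, str]:
    """Leaf -> group mapping matching :func:`simulate_gene_trees`' leaves."""
    groups = groups or _DEFAULT_GROUPS
    return {leaf: g for g, leaves in groups.items() for leaf in leaves}


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class SimulatedExpression:
    matrix: pd.DataFrame
    modules: dict[str, list[str]]


def simulate_expression(
    n_genes: int = 3000,
    n_samples: int = 14,
    module_sizes: Sequence[int] = (30, 30, 30),
    noise_sd: float = 0.3,
    seed: int = 0,
) -> SimulatedExpression:
    """Module-structured TPM-like matrix: genes of a module share a latent
    per-sample profile plus independent Gaussian noise on the log scale,
    exponentiated to non-negative values; background genes are pure noise
    (log-scale sd 1). Fourteen samples mirror a small multi-tissue RNA-seq
    panel."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if sum(module_sizes) > n_genes:
        raise ValueError("modules cannot exceed the gene count")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    log_expr = np.empty((n_genes, n_samples))
    baseline = rng.normal(math.log(20.0), 0.5, size=n_genes)
    modules: dict[str, list[str]] = {}
    cursor = 0
    for m, size in enumerate(module_sizes):
        latent = rng.normal(0.0, 1.0, size=n_samples)
        rows = slice(cursor, cursor + size)
        log_expr[rows] = (
            baseline[rows, None]
            + latent[None, :]
            + rng.normal(0.0, noise_sd, size=(size, n_samples))
        )
        modules[f"module{m + 1}"] = genes[cursor : cursor + size]
        cursor += size
    n_bg = n_genes - cursor
    log_expr[cursor:] = baseline[cursor:, None] + rng.normal(
        0.0, 1.0, size=(n_bg, n_samples)
    )
    matrix = pd.DataFrame(
        np.exp(log_expr), index=genes, columns=[f"s{j + 1:02d}" for j in range(n_samples)]
    )
    return SimulatedExpression(matrix=matrix, modules=modules)
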