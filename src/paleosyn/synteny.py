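"""Anchor filtering and collinear synteny-block chaining.

Homolog hits are first reduced to candidate anchors (top hits per query under
e-value and score cutoffs), then chained into collinear blocks by a dynamic
program over gene ranks: within each chromosome pair the highest-scoring
chain (score = anchor count) is repeatedly extracted, with consecutive
anchors at most ``max_gap`` ranks apart on both genomes and the subject rank
moving strictly monotonically (ascending or descending, so inversions form
descending blocks). Chains shorter than ``min_block_genes`` are discarded.

Tandem arrays (consecutive same-family genes within ``max_gap`` ranks on one
genome) are collapsed to their lowest-rank representative before chaining so
that local duplications do not inflate syntenic depth; the step is on by
default and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .model import GeneLocus, GenomeTable, HomologHit, ValidationError


@dataclass(frozen=True)
class AnchorFilterConfig:
    """Cutoffs applied to homolog hits before chaining."""

    max_hits_per_query: int = 10
    max_evalue: float = 1e-5
    min_score: float = 100.0

    def __post_init__(self) -> None:
        if self.max_hits_per_query < 1:
            raise ValidationError("max_hits_per_query must be >= 1")
        if self.max_evalue <= 0:
            raise ValidationError("max_evalue must be > 0")


@dataclass(frozen=True)
class ChainConfig:
    """Collinear-chaining parameters (gene-rank units)."""

    max_gap: int = 25
    min_block_genes: int = 11
    collapse_tandem: bool = True

    def __post_init__(self) -> None:
        if self.max_gap < 1:
            raise ValidationError("max_gap must be >= 1")
        if self.min_block_genes < 2:
            raise ValidationError("min_block_genes must be >= 2")


@dataclass
class SyntenyBlock:
    """A chained run of collinear anchor gene pairs between two genomes."""

    block_id: str
    query_species: str
    subject_species: str
    query_chromosome: str
    subject_chromosome: str
    anchors: list[tuple[GeneLocus, GeneLocus]]
    orientation: str  # "ascending" | "descending"

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def query_span(self) -> tuple[int, int]:
        ranks = [a[0].rank for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def subject_span(self) -> tuple[int, int]:
        ranks = [a[1].rank for a in self.anchors]
        return min(ranks), max(ranks)


def filter_anchors(
    hits: Iterable[HomologHit], config: AnchorFilterConfig = AnchorFilterConfig()
) -> list[HomologHit]:
    """Keep, per query gene, at most ``max_hits_per_query`` hits passing the
    e-value/score cutoffs, chosen by descending bitscore (ties by ascending
    evalue, then subject id). Output is sorted by query gene then rank order.
    """
    surviving = [
        h for h in hits if h.evalue <= config.max_evalue and h.bitscore >= config.min_score
    ]
    by_query: dict[tuple[str, str], list[HomologHit]] = {}
    for h in surviving:
        by_query.setdefault((h.query_species, h.query_gene), []).append(h)
    out: list[HomologHit] = []
    for key in sorted(by_query):
        ranked = sorted(by_query[key], key=lambda h: (-h.bitscore, h.evalue, h.subject_gene))
        out.extend(ranked[: config.max_hits_per_query])
    return out


def collapse_tandem_representative(
    genome: GenomeTable, max_gap: int
) -> dict[str, str]:
    """Map each gene to its tandem-array representative.

    Scanning each chromosome in rank order, a gene whose family was last seen
    within ``max_gap`` ranks maps to the lowest-rank member of that run;
    genes without a family id map to themselves.
    """
    mapping: dict[str, str] = {}
    for chrom, genes in genome.chromosomes.items():
        last_seen: dict[str, tuple[int, str]] = {}  # family -> (rank, representative)
        for g in genes:
            if g.family_id is None:
                mapping[g.gene_id] = g.gene_id
                continue
            prev = last_seen.get(g.family_id)
            if prev is not None and g.rank - prev[0] <= max_gap:
                mapping[g.gene_id] = prev[1]
                last_seen[g.family_id] = (g.rank, prev[1])
            else:
                mapping[g.gene_id] = g.gene_id
                last_seen[g.family_id] = (g.rank, g.gene_id)
    return mapping


def _best_chain(
    anchors: Sequence[tuple[int, int, int]], max_gap: int, direction: int
) -> list[int]:
    """Longest collinear chain over (qrank, srank, idx) anchors.

    ``direction`` +1 for ascending subject ranks, -1 for descending. Query
    ranks are strictly increasing along a chain and consecutive anchors differ
    by at most ``max_gap`` in both rank coordinates. Returns anchor indices
    into ``anchors`` in chain order. O(n^2) dynamic program; ties resolved
    toward the smaller starting query rank (via stable scan order).
    """
    n = len(anchors)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        qi, si, _ = anchors[i]
        for j in range(i):
            qj, sj, _ = anchors[j]
            if qj >= qi or qi - qj > max_gap:
                continue
            ds = (si - sj) * direction
            if ds <= 0 or ds > max_gap:
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: (best_len[i], -anchors[i][0])) if n else -1
    chain: list[int] = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    chain.reverse()
    return chain


def chain_anchors(
    genome_query: GenomeTable,
    genome_subject: GenomeTable,
    anchors: Iterable[HomologHit],
    config: ChainConfig = ChainConfig(),
) -> list[SyntenyBlock]:
    """Chain filtered anchors into collinear synteny blocks.

    Within each chromosome pair the highest-scoring chain is extracted
    greedily (score = anchor count, ascending vs descending whichever is
    longer; ascending preferred on ties), its anchors removed, and the search
    repeated until no chain reaches ``min_block_genes``. Each anchor belongs
    to at most one block. For a self-comparison the identity diagonal is
    excluded.
    """
    anchors = list(anchors)
    for h in anchors:
        if h.query_gene not in genome_query:
            raise ValidationError(f"anchor references unknown query gene {h.query_gene!r}")
        if h.subject_gene not in genome_subject:
            raise ValidationError(f"anchor references unknown subject gene {h.subject_gene!r}")

    q_map = s_map = None
    if config.collapse_tandem:
        q_map = collapse_tandem_representative(genome_query, config.max_gap)
        s_map = collapse_tandem_representative(genome_subject, config.max_gap)

    self_comparison = genome_query.species == genome_subject.species
    pairs: dict[tuple[str, str], dict[tuple[int, int], tuple[GeneLocus, GeneLocus]]] = {}
    for h in anchors:
        qg = genome_query[q_map[h.query_gene]] if q_map else genome_query[h.query_gene]
        sg = genome_subject[s_map[h.subject_gene]] if s_map else genome_subject[h.subject_gene]
        if self_comparison and qg.chromosome == sg.chromosome and qg.rank == sg.rank:
            continue
        key = (qg.chromosome, sg.chromosome)
        pairs.setdefault(key, {})[(qg.rank, sg.rank)] = (qg, sg)

    blocks: list[SyntenyBlock] = []
    counter = 0
    for (qchrom, schrom) in sorted(pairs):
        remaining = pairs[(qchrom, schrom)]
        while remaining:
            coords = sorted(remaining)
            indexed = [(q, s, i) for i, (q, s) in enumerate(coords)]
            asc = _best_chain(indexed, config.max_gap, +1)
            desc = _best_chain(indexed, config.max_gap, -1)
            chain, orientation = (asc, "ascending")
            if len(desc) > len(asc):
                chain, orientation = (desc, "descending")
            if len(chain) < config.min_block_genes:
                break
            counter += 1
            chosen = [coords[indexed[i][2]] for i in chain]
            blocks.append(
                SyntenyBlock(
                    block_id=f"block{counter:04d}",
                    query_species=genome_query.species,
                    subject_species=genome_subject.species,
                    query_chromosome=qchrom,
                    subject_chromosome=schrom,
                    anchors=[remaining[c] for c in chosen],
                    orientation=orientation,
                )
            )
            for c in chosen:
                del remaining[c]
    return blocks


def block_table(blocks: Iterable[SyntenyBlock]) -> pd.DataFrame:
    """One row per anchor pair, ordered by block id then query rank."""
    rows = []
    for b in sorted(blocks, key=lambda b: b.block_id):
        for qg, sg in sorted(b.anchors, key=lambda a: a[0].rank):
            rows.append(
                (
                    b.block_id,
                    b.query_species,
                    b.query_chromosome,
                    qg.gene_id,
                    qg.start,
                    qg.end,
                    qg.rank,
                    b.subject_species,
                    b.subject_chromosome,
                    sg.gene_id,
                    sg.start,
                    sg.end,
                    sg.rank,
                    b.orientation,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "block_id",
            "query_species",
            "query_chromosome",
            "query_gene",
            "query_start",
            "query_end",
            "query_rank",
            "subject_species",
            "subject_chromosome",
            "subject_gene",
            "subject_start",
            "subject_end",
            "subject_rank",
            "orientation",
        ],
    )
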