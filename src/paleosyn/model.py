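"""Shared domain types and readers/writers.

Every downstream stage (synteny chaining, depth profiling, Ks analysis,
rearrangement parsimony, quartet tallying, co-expression) consumes the types
defined here: ordered gene loci per chromosome (:class:`GenomeTable`),
homolog hit tables (:class:`HomologHit`), Newick trees, labelled chromosomal
region definitions (:class:`RegionDefinition`), and TPM-like expression
matrices (plain :class:`pandas.DataFrame`, genes x samples).

Conventions
-----------
* Coordinates are 0-based half-open base pairs.
* Gene *rank* is the 0-based position of a gene along its chromosome ordered
  by ascending start (ties by ascending end, then gene id); ranks are dense
  per (species, chromosome).
* Newick internal-node labels that parse as integers in [0, 100] are treated
  as bootstrap supports and stored on ``node.support``; other labels are kept
  as names.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# gene order
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLocus:
    """A single gene placed on a chromosome of one species."""

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int
    family_id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValidationError(f"negative coordinate for gene {self.gene_id!r}")
        if self.start >= self.end:
            raise ValidationError(
                f"start >= end for gene {self.gene_id!r} ({self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r} for gene {self.gene_id!r}")


class GenomeTable:
    """Ordered gene loci of one species, grouped by chromosome.

    Ranks within each chromosome form the dense set ``0..n-1``; gene ids are
    unique within the species.
    """

    def __init__(self, species: str, loci: Iterable[GeneLocus]):
        self.species = species
        self.chromosomes: dict[str, list[GeneLocus]] = {}
        self._by_id: dict[str, GeneLocus] = {}
        for locus in loci:
            if locus.species != species:
                raise ValidationError(
                    f"locus {locus.gene_id!r} belongs to {locus.species!r}, not {species!r}"
                )
            if locus.gene_id in self._by_id:
                raise ValidationError(f"duplicate gene_id {locus.gene_id!r}")
            self._by_id[locus.gene_id] = locus
            self.chromosomes.setdefault(locus.chromosome, []).append(locus)
        for chrom, genes in self.chromosomes.items():
            genes.sort(key=lambda g: g.rank)
            ranks = [g.rank for g in genes]
            if ranks != list(range(len(genes))):
                raise ValidationError(
                    f"ranks on {species}:{chrom} are not dense 0..n-1: {ranks[:5]}..."
                )

    @classmethod
    def from_records(
        cls,
        species: str,
        records: Sequence[tuple],
    ) -> "GenomeTable":
        """Build a table from (chromosome, start, end, strand, gene_id[, family_id])
        tuples, assigning ranks per chromosome by ascending start (ties by end,
        then gene id)."""
        by_chrom: dict[str, list[tuple]] = {}
        for rec in records:
            by_chrom.setdefault(rec[0], []).append(rec)
        loci: list[GeneLocus] = []
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: (int(r[1]), int(r[2]), str(r[4])))
            for rank, r in enumerate(recs):
                family = r[5] if len(r) > 5 and r[5] not in (None, "") else None
                loci.append(
                    GeneLocus(
                        gene_id=str(r[4]),
                        species=species,
                        chromosome=str(chrom),
                        start=int(r[1]),
                        end=int(r[2]),
                        strand=str(r[3]),
                        rank=rank,
                        family_id=family,
                    )
                )
        return cls(species, loci)

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneLocus:
        return self._by_id[gene_id]

    def get(self, gene_id: str) -> GeneLocus | None:
        return self._by_id.get(gene_id)

    def genes(self) -> Iterable[GeneLocus]:
        for chrom in sorted(self.chromosomes):
            yield from self.chromosomes[chrom]

    def n_genes(self, chromosome: str) -> int:
        return len(self.chromosomes[chromosome])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g.chromosome, g.start, g.end, g.strand, g.gene_id, g.family_id or "", g.rank)
            for g in self.genes()
        ]
        return pd.DataFrame(
            rows,
            columns=["chromosome", "start", "end", "strand", "gene_id", "family_id", "rank"],
        )


def read_gene_order(path: str | Path, species: str) -> GenomeTable:
    """Read a tab-separated gene-order file into a :class:`GenomeTable`.

    Columns: chromosome, start, end, strand, gene_id[, family_id]; coordinates
    are 0-based half-open. An empty file yields an empty, valid table.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}: line {lineno}: expected >= 5 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            records.append((parts[0], start, end, parts[3], parts[4], *parts[5:6]))
    return GenomeTable.from_records(species, records)


def write_gene_order(table: GenomeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in table.genes():
            fam = g.family_id if g.family_id is not None else ""
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.strand}\t{g.gene_id}\t{fam}\n")


# ---------------------------------------------------------------------------
# homolog hits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologHit:
    """One similarity hit between a query and a subject gene."""

    query_gene: str
    subject_gene: str
    query_species: str
    subject_species: str
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"negative evalue for {self.query_gene}/{self.subject_gene}")
        if self.bitscore <= 0:
            raise ValidationError(
                f"non-positive bitscore for {self.query_gene}/{self.subject_gene}"
            )


def read_homolog_hits(
    path: str | Path, query_species: str, subject_species: str
) -> list[HomologHit]:
    """Read a 12-column BLAST tabular (outfmt 6) file.

    Columns 1, 2, 11, 12 are query, subject, evalue, bitscore; the rest are
    ignored. Self-hits (query_gene == subject_gene) are dropped; remaining
    hits keep file order.
    """
    hits: list[HomologHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ParseError(f"{path}: line {lineno}: expected 12 columns, got {len(parts)}")
            try:
                evalue, bitscore = float(parts[10]), float(parts[11])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric evalue/bitscore") from exc
            if parts[0] == parts[1]:
                continue
            hits.append(
                HomologHit(
                    query_gene=parts[0],
                    subject_gene=parts[1],
                    query_species=query_species,
                    subject_species=subject_species,
                    bitscore=bitscore,
                    evalue=evalue,
                )
            )
    return hits


def write_homolog_hits(hits: Iterable[HomologHit], path: str | Path) -> None:
    """Write hits in the 12-column BLAST tabular dialect (filler alignment columns)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_gene}\t{h.subject_gene}\t100.0\t100\t0\t0\t1\t100\t1\t100"
                f"\t{h.evalue:g}\t{h.bitscore:g}\n"
            )


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def _attach_supports(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        node.support = None
        if node.is_leaf() or node.label is None:
            continue
        try:
            value = int(node.label)
        except ValueError:
            continue
        if 0 <= value <= 100:
            node.support = value
            node.label = None


def read_tree(source: str | Path) -> dendropy.Tree:
    """Parse a Newick tree from a path or a literal Newick string.

    Internal node labels that parse as integers in [0, 100] become bootstrap
    supports on ``node.support``. Duplicate leaf labels raise
    :class:`ValidationError`; malformed Newick raises :class:`ParseError`.
    """
    text = None
    if isinstance(source, (str, Path)):
        s = str(source)
        if s.lstrip().startswith("(") or s.rstrip().endswith(";"):
            text = s
        else:
            text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            case_sensitive_taxon_labels=True,
            taxon_namespace=dendropy.TaxonNamespace(is_case_sensitive=True),
        )
    except Exception as exc:  # dendropy raises assorted error types
        if "Duplicate taxon" in str(exc):
            raise ValidationError(f"duplicate leaf labels: {exc}") from exc
        raise ParseError(f"could not parse Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate leaf labels: {dupes}")
    _attach_supports(tree)
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionDefinition:
    """A labelled chromosomal interval (bp, 0-based half-open) on one species."""

    label: str
    species: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"region {self.label!r}: start >= end")


def read_regions(path: str | Path) -> list[RegionDefinition]:
    """Read a TSV of (label, species, chromosome, start, end)."""
    regions: list[RegionDefinition] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 columns")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            regions.append(RegionDefinition(parts[0], parts[1], parts[2], start, end))
    _check_region_overlaps(regions)
    return regions


def _check_region_overlaps(regions: Sequence[RegionDefinition]) -> None:
    by_key: dict[tuple, list[RegionDefinition]] = {}
    for r in regions:
        by_key.setdefault((r.label, r.species, r.chromosome), []).append(r)
    for key, group in by_key.items():
        group = sorted(group, key=lambda r: r.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValidationError(f"overlapping intervals for region {key[0]!r} on {key[2]}")


def write_regions(regions: Iterable[RegionDefinition], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.label}\t{r.species}\t{r.chromosome}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV of non-negative TPM-like values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression(df)
    return df


def validate_expression(df: pd.DataFrame) -> None:
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids in expression matrix: {dupes[:5]}")
    if (df.values < 0).any():
        raise ValidationError("expression matrix contains negative values")


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
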