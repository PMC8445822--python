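"""Syntenic depth profiles and depth-ratio WGD inference.

The syntenic depth of a reference gene is the number of distinct regions of
the other genome whose synteny-block spans cover it. Coverage is counted by
block rank span, not anchor membership: post-duplication gene loss
(fractionation) leaves anchor gaps inside genuinely duplicated regions, so
span coverage reflects how dotplot depth is read. Two blocks covering the
same reference gene are counted as the same copy when their spans on the
other genome overlap reciprocally by at least 50% (split blocks from one
copy must not inflate depth).

A whole-genome duplication doubles the modal depth seen from an unduplicated
reference, so reciprocal modal depths of 1:2, 1:4, 1:8 indicate one, two or
three rounds of lineage-specific WGD.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model import GenomeTable, ValidationError
from .synteny import SyntenyBlock


class InsufficientSyntenyError(ValueError):
    """No nonzero syntenic depth: a modal depth cannot be formed."""


@dataclass
class DepthProfile:
    """Per-gene syntenic depth of one reference genome against one query genome."""

    reference_species: str
    query_species: str
    depths: dict[str, np.ndarray]  # chromosome -> per-rank depth
    histogram: dict[int, int]
    modal_nonzero: int | None
    n_genes: int

    @property
    def fraction_at(self) -> dict[int, float]:
        return {d: c / self.n_genes for d, c in sorted(self.histogram.items())}

    @property
    def unaligned_fraction(self) -> float:
        return self.histogram.get(0, 0) / self.n_genes

    @property
    def modal_fraction(self) -> float | None:
        if self.modal_nonzero is None:
            return None
        return self.histogram[self.modal_nonzero] / self.n_genes


@dataclass(frozen=True)
class DepthRatio:
    """Reciprocal modal syntenic depths for a species pair.

    ``copies_a`` is the modal number of distinct A-genome regions covering a
    B gene (depth over reference B); ``copies_b`` the converse. The printed
    ratio ``A:B`` is ``copies_a:copies_b`` — a lineage that underwent k WGDs
    since divergence shows 2**k on its side.
    """

    species_a: str
    species_b: str
    copies_a: int
    copies_b: int
    fraction_a: float
    fraction_b: float

    def __str__(self) -> str:
        return f"{self.copies_a}:{self.copies_b}"


@dataclass(frozen=True)
class WgdRounds:
    rounds_a: int | None
    rounds_b: int | None
    candidates_a: tuple[int, int] | None = None
    candidates_b: tuple[int, int] | None = None


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if ov <= 0:
        return False
    return ov >= 0.5 * (a[1] - a[0] + 1) and ov >= 0.5 * (b[1] - b[0] + 1)


def _block_sides(block: SyntenyBlock, reference: GenomeTable):
    """Return (ref_chrom, ref_span, other_chrom, other_span) for a block."""
    if block.query_species == reference.species:
        return (
            block.query_chromosome,
            block.query_span,
            block.subject_chromosome,
            block.subject_span,
        )
    if block.subject_species == reference.species:
        return (
            block.subject_chromosome,
            block.subject_span,
            block.query_chromosome,
            block.query_span,
        )
    raise ValidationError(
        f"block {block.block_id} ({block.query_species}/{block.subject_species}) "
        f"does not involve reference species {reference.species!r}"
    )


def depth_profile(reference: GenomeTable, blocks: Iterable[SyntenyBlock]) -> DepthProfile:
    """Count, for every reference gene, the distinct query-genome regions
    covering it, and summarize the depth histogram and modal nonzero depth."""
    blocks = list(blocks)
    query_species: set[str] = set()
    per_chrom: dict[str, list[tuple[tuple[int, int], str, tuple[int, int]]]] = {}
    for b in blocks:
        ref_chrom, ref_span, other_chrom, other_span = _block_sides(b, reference)
        other = b.subject_species if b.query_species == reference.species else b.query_species
        query_species.add(other)
        per_chrom.setdefault(ref_chrom, []).append((ref_span, other_chrom, other_span))
    if len(query_species) > 1:
        raise ValidationError(f"blocks span multiple query species: {sorted(query_species)}")

    depths: dict[str, np.ndarray] = {}
    hist: Counter[int] = Counter()
    for chrom, genes in reference.chromosomes.items():
        n = len(genes)
        arr = np.zeros(n, dtype=int)
        covering = per_chrom.get(chrom, [])
        for rank in range(n):
            hits = [
                (oc, os)
                for (rs, oc, os) in covering
                if rs[0] <= rank <= rs[1]
            ]
            # cluster covering blocks that represent the same query-side copy
            clusters: list[list[tuple[str, tuple[int, int]]]] = []
            for oc, os in hits:
                merged = False
                for cl in clusters:
                    if any(c[0] == oc and _reciprocal_overlap(c[1], os) for c in cl):
                        cl.append((oc, os))
                        merged = True
                        break
                if not merged:
                    clusters.append([(oc, os)])
            arr[rank] = len(clusters)
        depths[chrom] = arr
        hist.update(arr.tolist())

    nonzero = {d: c for d, c in hist.items() if d > 0}
    modal = max(nonzero, key=lambda d: (nonzero[d], -d)) if nonzero else None
    return DepthProfile(
        reference_species=reference.species,
        query_species=query_species.pop() if query_species else "",
        depths=depths,
        histogram=dict(hist),
        modal_nonzero=modal,
        n_genes=len(reference),
    )


def depth_ratio(profile_ab: DepthProfile, profile_ba: DepthProfile) -> DepthRatio:
    """Form the reciprocal depth ratio from two profiles over the same pair.

    ``profile_ab`` has species A as reference (counting B regions over A);
    ``profile_ba`` the converse.
    """
    if (
        profile_ab.reference_species != profile_ba.query_species
        or profile_ab.query_species != profile_ba.reference_species
    ):
        raise ValidationError(
            "profiles are not reciprocal over one species pair: "
            f"{profile_ab.reference_species}/{profile_ab.query_species} vs "
            f"{profile_ba.reference_species}/{profile_ba.query_species}"
        )
    if profile_ab.modal_nonzero is None or profile_ba.modal_nonzero is None:
        raise InsufficientSyntenyError(
            "no nonzero syntenic depth on at least one side; cannot form a ratio"
        )
    return DepthRatio(
        species_a=profile_ab.reference_species,
        species_b=profile_ba.reference_species,
        copies_a=profile_ba.modal_nonzero,
        copies_b=profile_ab.modal_nonzero,
        fraction_a=profile_ba.modal_fraction or 0.0,
        fraction_b=profile_ab.modal_fraction or 0.0,
    )


def infer_wgd_rounds(ratio: DepthRatio) -> WgdRounds:
    """Convert modal depths to lineage-specific WGD rounds (log2 of each side).

    A modal depth that is not a power of two is reported with its two nearest
    power-of-two candidates (and a warning) rather than silently rounded.
    """

    def _side(copies: int) -> tuple[int | None, tuple[int, int] | None]:
        if copies >= 1 and (copies & (copies - 1)) == 0:
            return int(math.log2(copies)), None
        lo = 2 ** int(math.floor(math.log2(copies)))
        hi = lo * 2
        warnings.warn(
            f"modal depth {copies} is not a power of two; nearest candidates {lo} and {hi}",
            stacklevel=3,
        )
        return None, (lo, hi)

    rounds_a, cand_a = _side(ratio.copies_a)
    rounds_b, cand_b = _side(ratio.copies_b)
    return WgdRounds(rounds_a, rounds_b, cand_a, cand_b)
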