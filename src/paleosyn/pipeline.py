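"""Convenience chains over the module surface.

These helpers wire the standard inference chain — anchor filtering,
collinear chaining, reciprocal depth profiling — for one species pair, as a
caller would otherwise do by hand.
"""

from __future__ import annotations

from typing import Iterable

from .depth import DepthProfile, DepthRatio, depth_profile, depth_ratio
from .model import GenomeTable, HomologHit
from .synteny import AnchorFilterConfig, ChainConfig, SyntenyBlock, chain_anchors, filter_anchors


def synteny_blocks_between(
    genome_a: GenomeTable,
    genome_b: GenomeTable,
    hits: Iterable[HomologHit],
    anchor_config: AnchorFilterConfig = AnchorFilterConfig(),
    chain_config: ChainConfig = ChainConfig(),
) -> list[SyntenyBlock]:
    """Filter A->B hits to anchors and chain them into synteny blocks."""
    directed = [
        h
        for h in hits
        if h.query_species == genome_a.species and h.subject_species == genome_b.species
    ]
    anchors = filter_anchors(directed, anchor_config)
    return chain_anchors(genome_a, genome_b, anchors, chain_config)


def reciprocal_depth_ratio(
    genome_a: GenomeTable,
    genome_b: GenomeTable,
    hits: Iterable[HomologHit],
    anchor_config: AnchorFilterConfig = AnchorFilterConfig(),
    chain_config: ChainConfig = ChainConfig(),
) -> tuple[DepthRatio, DepthProfile, DepthProfile, list[SyntenyBlock]]:
    """Full chain for one species pair: blocks, reciprocal profiles, ratio.

    Blocks are chained once (A as query); both depth profiles read the same
    block set from their own side, as dotplot depth is read off one plot.
    """
    blocks = synteny_blocks_between(genome_a, genome_b, hits, anchor_config, chain_config)
    profile_a = depth_profile(genome_a, blocks)  # B-regions over reference A
    profile_b = depth_profile(genome_b, blocks)  # A-regions over reference B
    return depth_ratio(profile_a, profile_b), profile_a, profile_b, blocks
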