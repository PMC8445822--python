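"""Mutual-rank co-expression networks.

Genes passing a minimum-expression filter (TPM >= 1 in at least one sample
by default) are correlated pairwise by Pearson correlation across samples.
For gene a, rank_a(b) is the 1-based rank of b among a's partners by
descending correlation (ties by average rank, self excluded); the mutual
rank MR(a, b) = sqrt(rank_a(b) * rank_b(a)) is symmetric, and pairs with
MR <= 300 (default) are called co-expressed. Ranking is by signed
correlation, so strong anti-correlations rank last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import ValidationError, validate_expression

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoexpressionConfig:
    min_tpm: float = 1.0
    mr_threshold: float = 300.0

    def __post_init__(self) -> None:
        if self.min_tpm < 0:
            raise ValidationError("min_tpm must be >= 0")
        if self.mr_threshold < 1:
            raise ValidationError("mr_threshold must be >= 1")


def filter_expressed(
    matrix: pd.DataFrame, config: CoexpressionConfig = CoexpressionConfig()
) -> pd.DataFrame:
    """Drop genes that never reach ``min_tpm`` in any sample (boundary inclusive)."""
    validate_expression(matrix)
    keep = (matrix >= config.min_tpm).any(axis=1)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_expressed: removed %d of %d genes", removed, len(matrix))
    out = matrix.loc[keep]
    if out.empty:
        raise ValidationError("no gene passes the expression filter")
    return out


def _aligned_copy(arr: np.ndarray) -> np.ndarray:
    """64-byte-aligned copy: BLAS kernels pick identical code paths for
    identical data, so correlation output is byte-reproducible."""
    buf = np.empty(arr.size + 16, dtype=arr.dtype)
    offset = (-buf.ctypes.data % 64) // arr.itemsize
    out = buf[offset : offset + arr.size].reshape(arr.shape)
    out[...] = arr
    return out


def mutual_rank(matrix: pd.DataFrame) -> pd.DataFrame:
    """All-pairs PCC and mutual rank (pre-threshold).

    Requires >= 3 samples; zero-variance genes are excluded with a warning.
    Returns a DataFrame with one row per unordered pair (gene_a < gene_b):
    columns gene_a, gene_b, pcc, mr.
    """
    validate_expression(matrix)
    if matrix.shape[1] < 3:
        raise ValidationError(f"need >= 3 samples, got {matrix.shape[1]}")
    variances = matrix.var(axis=1, ddof=0)
    flat = variances[variances == 0].index.tolist()
    if flat:
        logger.warning("mutual_rank: excluding %d zero-variance genes", len(flat))
        matrix = matrix.drop(index=flat)
    genes = matrix.index.to_list()
    n = len(genes)
    if n < 2:
        raise ValidationError("fewer than 2 genes with variance; no pairs to rank")
    corr = np.corrcoef(_aligned_copy(matrix.to_numpy(dtype=float)))
    # self gets -inf so it ranks strictly last and partner ranks are 1..n-1
    ranked = corr.copy()
    np.fill_diagonal(ranked, -np.inf)
    ranks = rankdata(-ranked, axis=1, method="average")
    mr = np.sqrt(ranks * ranks.T)
    iu, ju = np.triu_indices(n, k=1)
    gene_arr = np.asarray(genes, dtype=object)
    return pd.DataFrame(
        {
            "gene_a": gene_arr[iu],
            "gene_b": gene_arr[ju],
            "pcc": corr[iu, ju],
            "mr": mr[iu, ju],
        }
    )


@dataclass
class CoexpressionNetwork:
    """Thresholded co-expression edges with per-gene neighbour lists."""

    edges: pd.DataFrame
    neighbours: dict[str, list[str]]

    def cluster(self, seed_gene: str) -> set[str]:
        """Connected component of ``seed_gene`` in the thresholded network."""
        if seed_gene not in self.neighbours:
            return {seed_gene}
        seen = {seed_gene}
        frontier = [seed_gene]
        while frontier:
            g = frontier.pop()
            for nb in self.neighbours.get(g, ()):
                if nb not in seen:
                    seen.add(nb)
                    frontier.append(nb)
        return seen


def build_network(
    edges: pd.DataFrame, config: CoexpressionConfig = CoexpressionConfig()
) -> CoexpressionNetwork:
    """Retain edges with MR <= threshold and index them by gene.

    Output ordering is deterministic (gene_a, gene_b), so identical input
    yields byte-identical edge tables.
    """
    kept = (
        edges.loc[edges["mr"] <= config.mr_threshold]
        .sort_values(["gene_a", "gene_b"], kind="mergesort")
        .reset_index(drop=True)
    )
    neighbours: dict[str, list[str]] = {}
    for a, b in zip(kept["gene_a"], kept["gene_b"]):
        neighbours.setdefault(a, []).append(b)
        neighbours.setdefault(b, []).append(a)
    return CoexpressionNetwork(edges=kept, neighbours=neighbours)
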