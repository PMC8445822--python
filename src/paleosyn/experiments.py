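"""Canned benchmark experiments at the package's reference study conditions.

Each experiment simulates inputs with the bundled generator at fixed,
documented conditions and runs the corresponding inference chain end to
end. They exist so that the same study-condition runs can be invoked from
scripts, examples and tests without re-specifying parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .depth import DepthRatio, WgdRounds, infer_wgd_rounds
from .ks import KsPeakModel, fit_ks_peaks, ks_density
from .pipeline import reciprocal_depth_ratio
from .quartets import QuartetTally, tally_quartets
from .simulate import (
    EvolutionScenario,
    Wgd,
    default_group_assignment,
    simulate_gene_trees,
    simulate_genomes,
)

#: Ks peak locations and widths of the reference three-peak paralog cohort
#: (the black-pepper-like triple-WGD signature).
KS_MIXTURE_MEANS = (0.11, 0.69, 0.91)
KS_MIXTURE_SDS = (0.05, 0.15, 0.15)


@dataclass(frozen=True)
class DepthExperimentResult:
    ratio: DepthRatio
    rounds: WgdRounds
    n_reference_genes: int

    @property
    def duplicated_modal_depth(self) -> int:
        """Modal depth of the (possibly) duplicated lineage, unduplicated
        genome as reference — the paper-style ratio with reference side 1."""
        return self.ratio.copies_b


def depth_ratio_experiment(
    n_wgd: int,
    seed: int,
    retention: float = 0.8,
    n_chromosomes: int = 4,
    genes_per_chromosome: int = 150,
) -> DepthExperimentResult:
    """Simulate a genome pair with ``n_wgd`` lineage-specific WGDs in lineage
    B after divergence (Ks 0.75 per branch, no structural events) and run the
    full anchor -> chain -> reciprocal-depth pipeline."""
    if not 0 <= n_wgd <= 3:
        raise ValueError("n_wgd must be in 0..3")
    fractions = [0.2, 0.5, 0.8]
    events = {"B": [Wgd(retention=retention, time_fraction=f) for f in fractions[:n_wgd]]}
    scenario = EvolutionScenario(
        tree="(A:0.75,B:0.75);",
        n_chromosomes=n_chromosomes,
        genes_per_chromosome=genes_per_chromosome,
        events=events,
        seed=seed,
    )
    result = simulate_genomes(scenario)
    ratio, profile_a, _, _ = reciprocal_depth_ratio(
        result.genomes["A"], result.genomes["B"], result.hits
    )
    return DepthExperimentResult(
        ratio=ratio,
        rounds=infer_wgd_rounds(ratio),
        n_reference_genes=profile_a.n_genes,
    )


def sample_ks_mixture(seed: int, n: int = 6000) -> np.ndarray:
    """Equal-weight truncated-normal (at 0) draws from the reference mixture."""
    rng = np.random.default_rng(seed)
    comp = rng.integers(0, len(KS_MIXTURE_MEANS), size=n)
    vals = rng.normal(np.take(KS_MIXTURE_MEANS, comp), np.take(KS_MIXTURE_SDS, comp))
    while (vals < 0).any():
        bad = vals < 0
        vals[bad] = rng.normal(
            np.take(KS_MIXTURE_MEANS, comp[bad]), np.take(KS_MIXTURE_SDS, comp[bad])
        )
    return vals


def ks_peak_experiment(seed: int, n: int = 6000) -> tuple[KsPeakModel, int]:
    """KDE (bandwidth 0.05) plus minimal-component Gaussian fitting of the
    reference Ks mixture; returns the selected model and the sample size."""
    vals = sample_ks_mixture(seed, n)
    density = ks_density(vals, bandwidth=0.05, ks_max=3.0)
    return fit_ks_peaks(density), n


def polytomy_experiment(seed: int, n_trees: int = 3000) -> QuartetTally:
    """Gene trees from a hard polytomy (focal branch length 0), classified
    and tallied."""
    trees = simulate_gene_trees(n_trees, internal_branch_t=0.0, seed=seed)
    return tally_quartets(trees, default_group_assignment())
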