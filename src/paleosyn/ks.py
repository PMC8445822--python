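"""Synonymous divergence (Ks) estimation, density smoothing and peak fitting.

Ks for a pair of in-frame coding sequences is estimated with the classic
Nei–Gojobori (1986) counting method under the standard genetic code:
synonymous site counts per codon are the per-position fractions of single
nucleotide changes that preserve the amino acid; observed differences are
apportioned to synonymous/nonsynonymous classes by equal-weight averaging
over all minimal mutational pathways (pathways through stop codons are
excluded); the proportion pS = Sd/S is corrected for multiple hits with the
Jukes–Cantor formula dS = -(3/4) ln(1 - (4/3) pS). Estimates with pS >= 3/4
are saturated and flagged invalid rather than raised.

Ks distributions of anchor-pair cohorts are smoothed by a Gaussian kernel
density (fixed bandwidth, boundary-reflected) and summarized by the smallest
Gaussian mixture whose least-squares fit to the density curve exceeds
R-squared 0.95, mirroring the manual multipeak-fit workflow used to read
WGD peaks off Ks curves. Peak locations across lineages with unequal
substitution rates are made comparable by rescaling each lineage so that its
divergence mode against a common reference species matches a shared target
(the geometric mean of the observed modes).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .model import ValidationError

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"


def _translate(codon: str) -> str | None:
    if codon in _STOPS:
        return None
    return _TABLE.forward_table.get(codon)


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon: sum over positions of the
    fraction of the three possible changes that preserve the amino acid.
    Changes producing stop codons count as nonsynonymous."""
    aa = _translate(codon)
    if aa is None:
        raise ValidationError(f"stop codon {codon!r} in coding sequence")
    total = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _translate(alt) == aa:
                syn += 1
        total += syn / 3.0
    return total


@lru_cache(maxsize=None)
def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    with equal weight over all minimal mutational pathways. Pathways whose
    intermediate codons are stops are excluded; if every pathway is blocked,
    all pathways are used with steps into/out of stops counted nonsynonymous.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        syn = nonsyn = 0.0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            aa_from, aa_to = _translate(current), _translate(nxt)
            if aa_to is None and nxt != codon_b and not allow_stops:
                return None
            if aa_from is not None and aa_from == aa_to:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        return syn, nonsyn

    results = [r for order in itertools.permutations(diff_pos) if (r := walk(order, False))]
    if not results:
        results = [walk(order, True) for order in itertools.permutations(diff_pos)]
    syn = sum(r[0] for r in results) / len(results)
    nonsyn = sum(r[1] for r in results) / len(results)
    return syn, nonsyn


@dataclass(frozen=True)
class KsEstimate:
    """Nei–Gojobori dS/dN estimate for one gene pair."""

    gene_a: str
    gene_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    ks: float  # nan when saturated
    kn: float  # nan when pn saturated
    valid: bool
    n_codons: int


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def nei_gojobori_ks(
    cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b"
) -> KsEstimate:
    """Estimate dS (Ks) and dN for two equal-length in-frame CDS.

    Codon columns containing gaps or ambiguity characters are dropped
    pairwise. A shared terminal stop codon is trimmed; internal stops raise
    :class:`ValidationError`. Saturation (pS >= 3/4) flags the estimate
    invalid instead of raising.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValidationError(f"sequence length mismatch: {len(a)} vs {len(b)}")
    if len(a) % 3 != 0:
        raise ValidationError(f"sequence length {len(a)} not divisible by 3")
    codons = [(a[i : i + 3], b[i : i + 3]) for i in range(0, len(a), 3)]
    if codons and (codons[-1][0] in _STOPS or codons[-1][1] in _STOPS):
        if codons[-1][0] in _STOPS and codons[-1][1] in _STOPS:
            codons = codons[:-1]
        else:
            raise ValidationError("terminal stop codon in only one sequence")

    S = N = Sd = Nd = 0.0
    used = 0
    for ca, cb in codons:
        if any(ch not in _BASES for ch in ca + cb):
            continue  # gap or ambiguity column, dropped pairwise
        if ca in _STOPS or cb in _STOPS:
            raise ValidationError(f"internal stop codon ({ca}/{cb})")
        S += (_syn_sites(ca) + _syn_sites(cb)) / 2.0
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
        used += 1
    N = 3.0 * used - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks, kn = _jc_correct(ps), _jc_correct(pn)
    return KsEstimate(
        gene_a=gene_a,
        gene_b=gene_b,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        ps=ps,
        pn=pn,
        ks=ks,
        kn=kn,
        valid=ps < 0.75,
        n_codons=used,
    )


# ---------------------------------------------------------------------------
# density and peak fitting
# ---------------------------------------------------------------------------

@dataclass
class KsDensity:
    """Gaussian-kernel Ks density on an even grid over [0, ks_max].

    The density is boundary-reflected at 0 and ``ks_max`` and scaled so its
    numerical integral equals the fraction of input values retained
    (values above ``ks_max`` are excluded and counted).
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    ks_max: float
    n_total: int
    n_retained: int

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_total


def ks_density(
    ks_values: Sequence[float],
    bandwidth: float = 0.05,
    ks_max: float = 3.0,
    grid_points: int = 512,
) -> KsDensity:
    values = np.asarray(ks_values, dtype=float)
    if values.size == 0:
        raise ValidationError("empty Ks value set")
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValidationError("Ks values must be finite and non-negative")
    retained = values[values <= ks_max]
    if retained.size == 0:
        raise ValidationError(f"no Ks values at or below ks_max={ks_max}")
    grid = np.linspace(0.0, ks_max, grid_points)
    dens = np.zeros_like(grid)
    for centers in (retained, -retained, 2.0 * ks_max - retained):
        z = (grid[:, None] - centers[None, :]) / bandwidth
        dens += np.exp(-0.5 * z * z).sum(axis=1)
    dens /= retained.size * bandwidth * math.sqrt(2.0 * math.pi)
    dens *= retained.size / values.size
    return KsDensity(
        grid=grid,
        density=dens,
        bandwidth=bandwidth,
        ks_max=ks_max,
        n_total=int(values.size),
        n_retained=int(retained.size),
    )


@dataclass
class KsPeakModel:
    """Gaussian mixture fitted to a smoothed Ks density curve.

    ``components`` holds (amplitude, mean, sigma) triples sorted by ascending
    mean of f(x) = sum_j a_j exp(-(x - mu_j)^2 / (2 sigma_j^2)). ``adequate``
    is False when no model up to ``max_components`` reached the R-squared
    threshold and the best-fitting model is returned instead.
    """

    components: list[tuple[float, float, float]]
    r_squared: float
    adequate: bool

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def means(self) -> list[float]:
        return [mu for _, mu, _ in self.components]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.zeros_like(x)
        for a, mu, s in self.components:
            y = y + a * np.exp(-((x - mu) ** 2) / (2.0 * s * s))
        return y


def _gauss_sum(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for i in range(0, len(params), 3):
        a, mu, s = params[i : i + 3]
        y = y + a * np.exp(-((x - mu) ** 2) / (2.0 * s * s))
    return y


def _initial_means(density: KsDensity, m: int) -> list[int]:
    """Grid indices of the m highest local maxima; padded with evenly spaced
    high-density grid points when the curve has fewer maxima."""
    idx, props = find_peaks(density.density, height=0.0)
    order = np.argsort(props["peak_heights"])[::-1]
    chosen = [int(idx[i]) for i in order[:m]]
    if len(chosen) < m:
        extra = np.argsort(density.density)[::-1]
        for i in extra:
            if all(abs(int(i) - c) > 3 for c in chosen):
                chosen.append(int(i))
            if len(chosen) == m:
                break
    return chosen[:m]


def fit_ks_peaks(
    density: KsDensity,
    max_components: int = 5,
    r2_threshold: float = 0.95,
    n_restarts: int = 4,
) -> KsPeakModel:
    """Fit the smallest adequate Gaussian mixture to a Ks density curve.

    For m = 1, 2, ... the mixture is fitted by bounded nonlinear least
    squares, initialized at the m highest local maxima of the density (sigma
    initialized to twice the kernel bandwidth) plus a fixed number of seeded
    jittered restarts; the first m whose best fit reaches ``r2_threshold`` is
    returned. If none does by ``max_components``, the best model is returned
    flagged inadequate.
    """
    x, y = density.grid, density.density
    ss_tot = float(((y - y.mean()) ** 2).sum())
    rng = np.random.default_rng(20210902)  # fixed: reported models are deterministic
    best_overall: KsPeakModel | None = None
    failures: list[str] = []
    for m in range(1, max_components + 1):
        peak_idx = _initial_means(density, m)
        base = []
        for i in peak_idx:
            base.extend([float(y[i]), float(x[i]), 2.0 * density.bandwidth])
        inits = [np.array(base)]
        for _ in range(n_restarts):
            jitter = rng.normal(1.0, 0.15, size=len(base))
            inits.append(np.clip(np.array(base) * jitter, 1e-8, None))
        lo = [1e-10, 0.0, 1e-4] * m
        hi = [max(10.0 * y.max(), 1.0), density.ks_max, density.ks_max] * m
        best_fit = None
        for p0 in inits:
            p0 = np.clip(p0, lo, hi)
            try:
                popt, _ = curve_fit(
                    _gauss_sum, x, y, p0=p0, bounds=(lo, hi), maxfev=20000
                )
            except (RuntimeError, ValueError) as exc:
                failures.append(f"m={m}: {exc}")
                continue
            ssr = float(((y - _gauss_sum(x, *popt)) ** 2).sum())
            if best_fit is None or ssr < best_fit[0]:
                best_fit = (ssr, popt)
        if best_fit is None:
            continue
        ssr, popt = best_fit
        r2 = 1.0 - ssr / ss_tot if ss_tot > 0 else 1.0
        components = sorted(
            [(float(popt[i]), float(popt[i + 1]), float(popt[i + 2])) for i in range(0, 3 * m, 3)],
            key=lambda c: c[1],
        )
        model = KsPeakModel(components=components, r_squared=r2, adequate=r2 > r2_threshold)
        if model.adequate:
            return model
        if best_overall is None or model.r_squared > best_overall.r_squared:
            best_overall = model
    if best_overall is None:
        raise RuntimeError("Gaussian peak fit failed on all starts: " + "; ".join(failures))
    return best_overall


# ---------------------------------------------------------------------------
# rate correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateCorrection:
    species: str
    scale: float
    corrected_means: tuple[float, ...]


def rate_correct(
    ks_peaks_by_species: Mapping[str, Sequence[float]],
    reference_modes: Mapping[str, float],
) -> dict[str, RateCorrection]:
    """Rescale per-species Ks peak locations so lineage rates are comparable.

    Each species i has an observed modal Ks against a common reference
    species; the target divergence is the geometric mean of those modes and
    species i's peaks are multiplied by c_i = target / mode_i. Peak ordering
    within a species is preserved (c_i > 0).
    """
    modes = []
    for sp in ks_peaks_by_species:
        if sp not in reference_modes:
            raise ValidationError(f"no reference divergence mode for species {sp!r}")
        mode = reference_modes[sp]
        if mode <= 0:
            raise ValidationError(f"non-positive reference mode for species {sp!r}")
        modes.append(mode)
    target = float(np.exp(np.mean(np.log(modes))))
    out: dict[str, RateCorrection] = {}
    for sp, peaks in ks_peaks_by_species.items():
        c = target / reference_modes[sp]
        out[sp] = RateCorrection(
            species=sp, scale=c, corrected_means=tuple(c * p for p in peaks)
        )
    return out
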