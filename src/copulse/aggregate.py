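"""Multi-taxa summary statistics: the aggregate SFS (genomic mode) and the
16 mitochondrial moment statistics (single-locus mode).

The aggregate SFS (aSFS) concatenates, over allele-frequency classes, the
per-class descending-sorted SNP proportions of ``n`` independent
single-population folded SFS.  Sorting within each frequency class
independently makes the summary invariant to taxon input order — exactly the
exchangeability the hierarchical model assumes — and a given position in the
vector does not track any one taxon across classes.

The single-locus mode computes, per taxon, the number of haplotypes,
haplotype diversity, nucleotide diversity and Tajima's D, and then the first
four moments (mean, variance, skewness, kurtosis) of each across taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .engine import FoldedSFS, HaplotypeBlock

__all__ = [
    "AggregateSFS",
    "MitoSummary",
    "MitoTaxonStats",
    "build_asfs",
    "asfs_matrix",
    "mito_taxon_stats",
    "mito_moments",
    "MITO_STAT_ORDER",
]

MITO_STAT_ORDER = ("n_haplotypes", "haplotype_diversity", "nucleotide_diversity", "tajimas_d")
_MOMENT_ORDER = ("mean", "variance", "skewness", "kurtosis")


@dataclass
class AggregateSFS:
    """Aggregate SFS vector of length ``n_taxa * n_classes``; entries within
    each frequency class are in non-increasing order."""

    values: np.ndarray
    n_taxa: int
    n_classes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_taxa * self.n_classes,):
            raise ValueError("aSFS length must be n_taxa * n_classes")
        blocks = self.values.reshape(self.n_classes, self.n_taxa)
        if np.any(np.diff(blocks, axis=1) > 1e-12):
            raise ValueError("aSFS entries must be non-increasing within each class")

    def class_block(self, cls: int) -> np.ndarray:
        """The sorted per-taxon proportions of frequency class ``cls`` (1-based)."""
        return self.values[(cls - 1) * self.n_taxa : cls * self.n_taxa]


@dataclass
class MitoSummary:
    """16 multi-taxa statistics: {mean, variance, skewness, kurtosis} of
    {K, H, pi, D} across taxa, in that fixed order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (16,):
            raise ValueError("MitoSummary must hold exactly 16 values")

    @staticmethod
    def labels() -> list[str]:
        return [f"{s}_{m}" for s in MITO_STAT_ORDER for m in _MOMENT_ORDER]


def asfs_matrix(proportions: np.ndarray) -> np.ndarray:
    """Vectorised aSFS construction.

    ``proportions`` has shape ``(n_sims, n_taxa, n_classes)`` (each taxon row
    summing to 1).  Returns ``(n_sims, n_taxa * n_classes)`` with, per
    simulation, the frequency classes in ascending order and the taxa sorted
    descending within each class.
    """
    proportions = np.asarray(proportions, dtype=float)
    if proportions.ndim != 3:
        raise ValueError("expected (n_sims, n_taxa, n_classes)")
    ranked = -np.sort(-proportions, axis=1)  # descending within class, per sim
    n_sims = proportions.shape[0]
    return ranked.transpose(0, 2, 1).reshape(n_sims, -1)


def build_asfs(sfs_list: list[FoldedSFS]) -> AggregateSFS:
    """Re-order a set of per-taxon folded SFS into a single aSFS.

    All spectra must share ``n_samples``.  Each SFS is normalised to
    proportions; for each frequency class independently the taxa's
    proportions are sorted descending, and classes are concatenated in
    ascending frequency order.
    """
    if len(sfs_list) < 2:
        raise ValueError("need at least two taxa to aggregate")
    n_samples = {s.n_samples for s in sfs_list}
    if len(n_samples) != 1:
        raise ValueError("all SFS must share n_samples")
    classes = {s.n_classes for s in sfs_list}
    n_classes = classes.pop()
    mat = np.stack([s.proportions for s in sfs_list])
    sums = mat.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("each taxon must contribute at least one SNP")
    mat = mat / sums
    values = asfs_matrix(mat[None, :, :])[0]
    return AggregateSFS(values, n_taxa=len(sfs_list), n_classes=n_classes)


@dataclass(frozen=True)
class MitoTaxonStats:
    """Single-taxon sequence summaries.  ``d_defined`` is False when there
    are no segregating sites, in which case D is reported as 0."""

    n_haplotypes: int
    haplotype_diversity: float
    nucleotide_diversity: float
    tajimas_d: float
    d_defined: bool = True


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def mito_taxon_stats(block: HaplotypeBlock) -> MitoTaxonStats:
    """Number of haplotypes K, haplotype diversity H, nucleotide diversity pi
    (mean pairwise differences per site) and Tajima's D for one taxon.

    ``H = (n/(n-1)) (1 - sum p_i^2)`` over haplotype frequencies (the
    unbiased correction).  With ``S = 0`` D is undefined and returned as 0
    with ``d_defined=False``.
    """
    n = block.n_samples
    if n < 2:
        raise ValueError("need at least two sequences")
    seqs = block.sequences
    S = block.n_sites
    # haplotype counting on row bytes
    _, counts = np.unique(seqs, axis=0, return_counts=True)
    k = len(counts)
    p = counts / n
    h = (n / (n - 1)) * (1.0 - np.sum(p**2))
    # mean pairwise differences: sum over sites of 2 * d * (n - d) / (n(n-1))
    derived = seqs.sum(axis=0)
    pair_diffs_total = float(np.sum(2.0 * derived * (n - derived)) / (n * (n - 1)))
    pi = pair_diffs_total / block.locus_length
    if S == 0:
        return MitoTaxonStats(k, float(h), pi, 0.0, d_defined=False)
    a1 = float(np.sum(1.0 / np.arange(1, n)))
    e1, e2 = _tajima_constants(n)
    denom = np.sqrt(e1 * S + e2 * S * (S - 1))
    d = (pair_diffs_total - S / a1) / denom if denom > 0 else 0.0
    return MitoTaxonStats(k, float(h), pi, float(d), d_defined=denom > 0)


def mito_moments(stats: list[MitoTaxonStats]) -> MitoSummary:
    """First four moments of each of the four per-taxon statistics across taxa.

    Variance uses divisor ``n - 1``; skewness and kurtosis are standardised
    central moments (kurtosis non-excess).  A zero-variance statistic maps
    skewness and kurtosis to 0 with a warning.
    """
    if len(stats) < 2:
        raise ValueError("need at least two taxa (variance undefined otherwise)")
    out = np.empty(16)
    cols = {
        "n_haplotypes": np.array([s.n_haplotypes for s in stats], dtype=float),
        "haplotype_diversity": np.array([s.haplotype_diversity for s in stats]),
        "nucleotide_diversity": np.array([s.nucleotide_diversity for s in stats]),
        "tajimas_d": np.array([s.tajimas_d for s in stats]),
    }
    for j, name in enumerate(MITO_STAT_ORDER):
        x = cols[name]
        mean = x.mean()
        var = x.var(ddof=1)
        if var == 0:
            warnings.warn(
                f"zero variance in {name}; skewness/kurtosis reported as 0",
                RuntimeWarning,
                stacklevel=2,
            )
            skew = kurt = 0.0
        else:
            skew = float(stats_skew(x))
            kurt = float(stats_kurtosis(x))
        out[4 * j : 4 * j + 4] = (mean, var, skew, kurt)
    return MitoSummary(out)


def mito_moments_matrix(taxon_stats: np.ndarray) -> np.ndarray:
    """Vectorised :func:`mito_moments` for a ``(n_sims, n_taxa, 4)`` array of
    per-taxon ``(K, H, pi, D)`` rows; returns ``(n_sims, 16)`` using the same
    moment conventions (zero-variance statistics map skew/kurtosis to 0,
    silently in this bulk form)."""
    x = np.asarray(taxon_stats, dtype=float)
    if x.ndim != 3 or x.shape[2] != 4 or x.shape[1] < 2:
        raise ValueError("expected (n_sims, n_taxa >= 2, 4)")
    mean = x.mean(axis=1)
    centred = x - mean[:, None, :]
    m2 = (centred**2).mean(axis=1)
    var = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(m2 > 0, (centred**3).mean(axis=1) / m2**1.5, 0.0)
        kurt = np.where(m2 > 0, (centred**4).mean(axis=1) / m2**2, 0.0)
    out = np.stack([mean, var, skew, kurt], axis=2)  # (n_sims, 4 stats, 4 moments)
    return out.reshape(x.shape[0], 16)


def stats_skew(x: np.ndarray) -> float:
    """Standardised third central moment (biased, population convention)."""
    return float(stats.skew(x, bias=True))


def stats_kurtosis(x: np.ndarray) -> float:
    """Standardised fourth central moment, non-excess."""
    return float(stats.kurtosis(x, fisher=False, bias=True))
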