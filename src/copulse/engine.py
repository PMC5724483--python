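"""Single-population coalescent engine for instantaneous size-change demographies.

The engine simulates folded site frequency spectra in the one-SNP-per-genealogy
("FREQ") setting, infinite-sites sequence blocks for single-locus data, and
exposes an analytic/Monte-Carlo expectation of the folded SFS used as a
validation oracle and as an opt-in approximate fast mode.

Conventions
-----------
* ``N`` is the number of gene copies (haploid size); while ``k`` ancestral
  lineages remain in a population of size ``M`` the coalescence rate is
  ``k(k-1)/(2M)`` per generation.
* Time runs backward from sampling in generations.  The population size is
  ``n_current`` for times ``< tau`` and ``epsilon * n_current`` for times
  ``>= tau`` (``epsilon < 1`` is a forward-time expansion, ``> 1`` a
  contraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "Demography",
    "FoldedSFS",
    "HaplotypeBlock",
    "SaturationError",
    "simulate_genealogy",
    "simulate_sfs_freq",
    "simulate_sfs_freq_batch",
    "expected_sfs",
    "simulate_sequences",
    "subtend_probabilities",
    "fold_spectrum",
    "write_sfs",
    "read_sfs",
    "read_dadi_sfs",
]


class SaturationError(RuntimeError):
    """Raised when infinite-sites mutations exceed the available locus length."""


@dataclass(frozen=True)
class Demography:
    """Single-population instantaneous size-change history.

    Parameters
    ----------
    n_current:
        Current effective population size in gene copies (haploid), ``>= 2``.
    epsilon:
        Ratio of ancestral to current size, ``> 0``.  ``epsilon = 1`` is a
        constant-size history.
    tau:
        Time of the instantaneous change, in generations, ``>= 0``.
    """

    n_current: int
    epsilon: float
    tau: int

    def __post_init__(self) -> None:
        if self.n_current < 2:
            raise ValueError(f"n_current must be >= 2, got {self.n_current}")
        if not np.isfinite(self.epsilon) or self.epsilon <= 0:
            raise ValueError(f"epsilon must be a finite positive real, got {self.epsilon}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")

    @property
    def n_ancestral(self) -> float:
        return self.epsilon * self.n_current


@dataclass
class FoldedSFS:
    """Folded site frequency spectrum as SNP proportions over minor-allele classes.

    ``proportions`` has length ``floor(n_samples / 2)`` covering minor-allele
    counts ``1 .. floor(n_samples/2)``; the monomorphic class is excluded.
    """

    proportions: np.ndarray
    n_samples: int
    n_snps: int

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        expected = self.n_samples // 2
        if self.proportions.shape != (expected,):
            raise ValueError(
                f"folded SFS for {self.n_samples} samples must have "
                f"{expected} classes, got shape {self.proportions.shape}"
            )
        if np.any(self.proportions < 0):
            raise ValueError("SFS proportions must be non-negative")
        if self.n_snps > 0 and not np.isclose(self.proportions.sum(), 1.0):
            raise ValueError("SFS proportions must sum to 1 when n_snps > 0")

    @property
    def n_classes(self) -> int:
        return self.n_samples // 2


@dataclass
class HaplotypeBlock:
    """Infinite-sites haplotype matrix: ``sequences[i, j]`` is the allele of
    sample ``i`` at segregating site ``j`` (0 ancestral, 1 derived)."""

    sequences: np.ndarray
    locus_length: int
    mu: float

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.int8)
        if self.sequences.ndim != 2:
            raise ValueError("sequences must be a 2-D matrix")
        if self.n_sites > self.locus_length:
            raise ValueError("more segregating sites than locus length")

    @property
    def n_samples(self) -> int:
        return self.sequences.shape[0]

    @property
    def n_sites(self) -> int:
        return self.sequences.shape[1]


# ---------------------------------------------------------------------------
# combinatorics


def subtend_probabilities(n_samples: int) -> np.ndarray:
    """Probability that a branch in the interval with ``k`` lineages subtends
    ``i`` of the ``n`` sampled leaves.

    Returns an array ``P`` of shape ``(n_samples + 1, n_samples - 1)`` with
    ``P[k, i-1] = C(n-i-1, k-2) / C(n-1, k-1)``, the classical result for the
    number of leaves below a random lineage of the Kingman coalescent at level
    ``k`` (rows ``k < 2`` are zero).
    """
    n = n_samples
    P = np.zeros((n + 1, n - 1))
    for k in range(2, n + 1):
        denom = comb(n - 1, k - 1)
        for i in range(1, n - k + 2):
            P[k, i - 1] = comb(n - i - 1, k - 2) / denom
    return P


def fold_spectrum(unfolded: np.ndarray) -> np.ndarray:
    """Fold a length ``n-1`` derived-class vector into ``floor(n/2)`` minor-allele
    classes (class ``i`` merged with ``n-i``; the middle class unmerged)."""
    unfolded = np.asarray(unfolded)
    n = unfolded.shape[-1] + 1
    half = n // 2
    folded = unfolded[..., :half].copy().astype(float)
    for i in range(1, half + 1):
        j = n - i
        if j != i and j <= n - 1:
            folded[..., i - 1] += unfolded[..., j - 1]
    return folded


# ---------------------------------------------------------------------------
# genealogy interval times


def _interval_durations(n_samples: int, demog: Demography, rng: np.random.Generator) -> np.ndarray:
    """Draw the coalescent interval durations ``T_k`` for ``k = n .. 2`` under
    the piecewise-constant demography (memoryless rescaling across ``tau``)."""
    n = n_samples
    Nc = float(demog.n_current)
    Na = float(demog.n_ancestral)
    tau = float(demog.tau)
    ratio = Na / Nc
    t = 0.0
    out = np.empty(n - 1)
    e = rng.standard_exponential(n - 1)
    for idx, k in enumerate(range(n, 1, -1)):
        c = 2.0 / (k * (k - 1.0))
        if t >= tau:
            dt = e[idx] * Na * c
        else:
            dt0 = e[idx] * Nc * c
            rem = tau - t
            dt = dt0 if dt0 <= rem else rem + (dt0 - rem) * ratio
        t += dt
        out[idx] = dt
    return out


def simulate_genealogy(
    n_samples: int, demog: Demography, rng: np.random.Generator
) -> np.ndarray:
    """Simulate one Kingman genealogy and return total branch length per
    derived-frequency class (classes ``1 .. n_samples - 1``, in generations).

    The class of a branch is the number of sampled leaves it subtends.  The
    topology is built by uniform pairwise merging; interval durations follow
    the piecewise-constant coalescence rate ``k(k-1)/(2M)``.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    durations = _interval_durations(n_samples, demog, rng)
    sizes = np.ones(n_samples, dtype=np.int64)
    lengths = np.zeros(n_samples - 1)
    for idx, k in enumerate(range(n_samples, 1, -1)):
        dt = durations[idx]
        np.add.at(lengths, sizes[:k] - 1, dt)
        a, b = rng.choice(k, size=2, replace=False)
        sizes[min(a, b)] += sizes[max(a, b)]
        sizes[max(a, b)] = sizes[k - 1]
    return lengths


# ---------------------------------------------------------------------------
# FREQ-setting SFS simulation (one SNP per independent genealogy)


@njit(cache=True, fastmath=True)
def _freq_kernel(n_cur, n_anc, tau, per_sfs, n_samples, sub_cum, cs, E, U1, U2):  # pragma: no cover
    """Per-genealogy folded-SFS counting kernel.

    For genealogy ``g``: interval durations come from ``E`` (unit
    exponentials, memoryless piecewise rescaling across ``tau[g]``); the
    single SNP's interval is chosen with probability proportional to
    ``k * T_k`` (the interval's share of total branch length) using ``U1``;
    the derived class within the interval is drawn from the cumulative
    subtend distribution ``sub_cum[k]`` using ``U2``.  Classes are folded and
    accumulated into one row per block of ``per_sfs`` genealogies.

    Arithmetic is single precision: durations enter only through the
    branch-length share of each interval, so float32 round-off is orders of
    magnitude below the Monte-Carlo noise of the class draw itself.
    """
    n_gene = n_cur.shape[0]
    n_sfs = n_gene // per_sfs
    nfold = n_samples // 2
    nlev = n_samples - 1
    counts = np.zeros((n_sfs, nfold), dtype=np.int64)
    w = np.empty(nlev, dtype=np.float32)
    for g in range(n_gene):
        t = np.float32(0.0)
        tot = np.float32(0.0)
        Nc = n_cur[g]
        Na = n_anc[g]
        tg = tau[g]
        ratio = Na / Nc
        base = g * nlev
        for idx in range(nlev):
            e = E[base + idx]
            if t >= tg:
                dt = e * Na * cs[idx]
            else:
                dt0 = e * Nc * cs[idx]
                rem = tg - t
                dt = dt0 if dt0 <= rem else rem + (dt0 - rem) * ratio
            t += dt
            tot += (n_samples - idx) * dt
            w[idx] = tot
        r = U1[g] * tot
        idx = 0
        while w[idx] < r:
            idx += 1
        k = n_samples - idx
        u = U2[g]
        i = 1
        while sub_cum[k, i - 1] < u:
            i += 1
        cls = i if i <= n_samples - i else n_samples - i
        counts[g // per_sfs, cls - 1] += 1
    return counts


_SUB_CUM_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _kernel_tables(n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative subtend distribution and per-level rate constants
    ``2/(k(k-1))`` for ``k = n .. 2``, as float32 kernel inputs."""
    tabs = _SUB_CUM_CACHE.get(n_samples)
    if tabs is None:
        cum = np.cumsum(subtend_probabilities(n_samples), axis=1)
        cum[:, -1] = 1.0 + 1e-6  # guard against float round-off in the search
        cs = np.array(
            [2.0 / (k * (k - 1.0)) for k in range(n_samples, 1, -1)],
            dtype=np.float32,
        )
        tabs = (cum.astype(np.float32), cs)
        _SUB_CUM_CACHE[n_samples] = tabs
    return tabs


def simulate_sfs_freq_batch(
    n_samples: int,
    n_genealogies: int,
    n_current: np.ndarray,
    epsilon: np.ndarray,
    tau: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one folded SFS (as counts) per demography row, each from
    ``n_genealogies`` independent genealogies contributing one SNP apiece.

    ``n_current``, ``epsilon`` and ``tau`` are parallel vectors, one entry per
    SFS.  Returns an integer matrix of shape ``(len(n_current), n_samples//2)``
    whose rows sum to ``n_genealogies``.

    Per genealogy the SNP class is exact: the coalescent interval is selected
    with probability equal to its share of total branch length and the class
    within the interval follows the leaves-subtended distribution of a random
    lineage.  Because Kingman topology is independent of interval durations,
    this reproduces the distribution obtained by dropping a uniform point on a
    fully realised tree, genealogy by genealogy.
    """
    n_current = np.ascontiguousarray(n_current, dtype=np.float64)
    epsilon = np.ascontiguousarray(epsilon, dtype=np.float64)
    tau = np.ascontiguousarray(tau, dtype=np.float64)
    if not (n_current.shape == epsilon.shape == tau.shape):
        raise ValueError("demography vectors must have equal length")
    if np.any(epsilon <= 0):
        raise ValueError("epsilon must be positive")
    if n_genealogies < 1:
        raise ValueError("n_genealogies must be >= 1")
    n_sfs = n_current.shape[0]
    per = np.repeat(n_current.astype(np.float32), n_genealogies)
    per_anc = np.repeat((n_current * epsilon).astype(np.float32), n_genealogies)
    per_tau = np.repeat(tau.astype(np.float32), n_genealogies)
    m = n_sfs * n_genealogies
    E = rng.standard_exponential(m * (n_samples - 1), dtype=np.float32)
    U1 = rng.random(m, dtype=np.float32)
    U2 = rng.random(m, dtype=np.float32)
    sub_cum, cs = _kernel_tables(n_samples)
    return _freq_kernel(
        per, per_anc, per_tau, n_genealogies, n_samples, sub_cum, cs, E, U1, U2
    )


def simulate_sfs_freq(
    n_samples: int,
    n_genealogies: int,
    demog: Demography,
    rng: np.random.Generator,
    method: str = "per-genealogy",
) -> FoldedSFS:
    """Simulate a folded SFS in the FREQ setting: ``n_genealogies`` independent
    genealogies, one SNP per genealogy, folded and normalised to proportions.

    ``method``:

    * ``"per-genealogy"`` (default, faithful): each genealogy's SNP class has
      probability equal to that genealogy's class share of branch length.
    * ``"tree"``: same distribution via explicitly realised topologies
      (slow; used for cross-validation of the default kernel).
    * ``"multinomial-approx"``: opt-in approximate fast mode that draws the
      whole SFS as a multinomial from the Monte-Carlo expectation
      ``E[l_i / l_tot]`` (see :func:`expected_sfs`).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    half = n_samples // 2
    if method == "per-genealogy":
        counts = simulate_sfs_freq_batch(
            n_samples,
            n_genealogies,
            np.array([demog.n_current]),
            np.array([demog.epsilon]),
            np.array([demog.tau]),
            rng,
        )[0]
    elif method == "tree":
        counts = np.zeros(half, dtype=np.int64)
        classes = np.arange(1, n_samples)
        for _ in range(n_genealogies):
            lengths = simulate_genealogy(n_samples, demog, rng)
            i = rng.choice(classes, p=lengths / lengths.sum())
            counts[min(i, n_samples - i) - 1] += 1
    elif method == "multinomial-approx":
        q = expected_sfs(n_samples, demog, rng=rng).proportions
        counts = rng.multinomial(n_genealogies, q)
    else:
        raise ValueError(f"unknown method {method!r}")
    return FoldedSFS(counts / counts.sum(), n_samples, n_genealogies)


def expected_sfs(
    n_samples: int,
    demog: Demography,
    n_replicates: int = 100_000,
    rng: np.random.Generator | None = None,
    estimator: str = "snp-share",
) -> FoldedSFS:
    """Expected folded SFS proportions under the demography.

    Two estimators are available and documented because they answer subtly
    different questions:

    * ``"snp-share"`` (default): ``E[l_i / l_tot]``, the expectation of the
      per-genealogy SNP class distribution — the quantity one-SNP-per-
      genealogy simulation (:func:`simulate_sfs_freq`) converges to.  It is
      estimated by high-replicate genealogy averaging: conditional on
      interval durations the class share is
      ``sum_k (k T_k / l_tot) P(class | k)`` with ``P`` the subtend
      distribution, which integrates out the topology exactly; only the
      durations are Monte-Carlo.
    * ``"branch-share"``: the classical length-ratio expectation
      ``E[l_i] / E[l_tot]``.  For a constant-size history this has the
      closed form ``1/i`` per unfolded class (Watterson/Fu weights); for a
      size change it is estimated from the same duration replicates.  Because
      the expectation of a ratio is not the ratio of expectations, the two
      estimators differ by a few percent in the singleton class even at
      constant size.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if estimator not in ("snp-share", "branch-share"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if estimator == "branch-share" and demog.epsilon == 1.0:
        unfolded = 1.0 / np.arange(1, n_samples)
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        P = subtend_probabilities(n_samples)
        ks = np.arange(n_samples, 1, -1)
        acc = np.zeros(n_samples - 1)  # per-interval weight accumulator
        chunk = 10_000
        done = 0
        while done < n_replicates:
            b = min(chunk, n_replicates - done)
            T = np.empty((b, n_samples - 1))
            for r in range(b):
                T[r] = _interval_durations(n_samples, demog, rng)
            W = T * ks  # per-interval total length
            if estimator == "snp-share":
                W /= W.sum(axis=1, keepdims=True)
            acc += W.sum(axis=0)
            done += b
        unfolded = acc @ P[ks]
    folded = fold_spectrum(unfolded)
    return FoldedSFS(folded / folded.sum(), n_samples, 0)


# ---------------------------------------------------------------------------
# infinite-sites sequence simulation (single-locus mode)


def simulate_sequences(
    n_samples: int,
    locus_length: int,
    mu: float,
    demog: Demography,
    rng: np.random.Generator,
) -> HaplotypeBlock:
    """Simulate an infinite-sites haplotype block for one locus.

    A Kingman genealogy is realised, mutations are Poisson with mean
    ``mu * locus_length * total branch length`` and dropped uniformly on
    branches; each mutation occupies a distinct site.  Raises
    :class:`SaturationError` if mutations exceed ``locus_length``.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if locus_length < 1:
        raise ValueError("locus_length must be >= 1")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    durations = _interval_durations(n_samples, demog, rng)
    # realise topology, recording (leaf-set, branch length) per lineage
    members: list[np.ndarray] = [np.array([i]) for i in range(n_samples)]
    branch_len = [0.0] * n_samples
    branches: list[tuple[np.ndarray, float]] = []
    for idx, k in enumerate(range(n_samples, 1, -1)):
        dt = durations[idx]
        for j in range(k):
            branch_len[j] += dt
        a, b = sorted(rng.choice(k, size=2, replace=False))
        branches.append((members[a], branch_len[a]))
        branches.append((members[b], branch_len[b]))
        members[a] = np.concatenate([members[a], members[b]])
        branch_len[a] = 0.0
        members[b] = members[k - 1]
        branch_len[b] = branch_len[k - 1]
        members.pop()
        branch_len.pop()
    lengths = np.array([ln for _, ln in branches])
    total = lengths.sum()
    n_mut = rng.poisson(mu * locus_length * total)
    if n_mut > locus_length:
        raise SaturationError(
            f"{n_mut} mutations exceed locus length {locus_length}; "
            "increase the locus or lower mu"
        )
    seqs = np.zeros((n_samples, n_mut), dtype=np.int8)
    if n_mut > 0:
        which = rng.choice(len(branches), size=n_mut, p=lengths / total)
        for site, bi in enumerate(which):
            seqs[branches[bi][0], site] = 1
    return HaplotypeBlock(seqs, locus_length, mu)


# ---------------------------------------------------------------------------
# plain-text SFS input/output


def write_sfs(sfs: FoldedSFS, path: str | Path) -> None:
    """Write a folded SFS as whitespace-separated proportions with a
    ``#n_samples=<k> n_snps=<m>`` header line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#n_samples={sfs.n_samples} n_snps={sfs.n_snps}\n")
        fh.write(" ".join(f"{p:.6g}" for p in sfs.proportions) + "\n")


def read_sfs(path: str | Path) -> FoldedSFS:
    """Read a folded SFS written by :func:`write_sfs`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '#n_samples=... n_snps=...' header")
        meta = dict(tok.split("=") for tok in header.lstrip("#").split())
        values = np.array(fh.read().split(), dtype=float)
    return FoldedSFS(values, int(meta["n_samples"]), int(meta["n_snps"]))


def read_dadi_sfs(path: str | Path) -> FoldedSFS:
    """Import a dadi-style single-population folded SFS text file.

    Expected layout: a first non-comment line ``<2n+1> folded`` (a leading
    dimension and the folding flag), a line of ``2n+1`` entries, and an
    optional mask line of 0/1 flags.  Masked entries and the monomorphic
    corners are dropped; the minor-allele classes are renormalised to
    proportions.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if len(lines) < 2:
        raise ValueError(f"{path}: not a dadi SFS file")
    header = lines[0].split()
    dim = int(header[0])
    if "unfolded" in header:
        raise ValueError(f"{path}: unfolded spectra are not supported")
    counts = np.array(lines[1].split(), dtype=float)
    if counts.size != dim:
        raise ValueError(f"{path}: expected {dim} entries, found {counts.size}")
    mask = None
    if len(lines) > 2:
        mask = np.array(lines[2].split(), dtype=int)
        if mask.size == dim:
            counts = np.where(mask == 1, 0.0, counts)
    n_samples = dim - 1
    half = n_samples // 2
    folded = counts[1 : half + 1].copy()
    total = folded.sum()
    if total <= 0:
        raise ValueError(f"{path}: no polymorphic SNPs after masking")
    n_snps = int(round(total))
    return FoldedSFS(folded / total, n_samples, n_snps)
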