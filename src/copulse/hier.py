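"""Hierarchical co-demographic model: hyperpriors over pulse counts and taxon
assignments, buffered event-time draws, and per-taxon parameter draws.

A realised history assigns ``n`` taxa to ``Psi`` instantaneous size-change
times, of which ``psi`` are synchronous pulses (>= 2 taxa each) and ``sigma``
are idiosyncratic (single-taxon) events, so ``Psi = psi + sigma``.  The
proportion of taxa in pulse ``j`` is ``zeta_s[j]`` (ordered most recent
first), their total is ``zeta_T``, and the taxon-count conversions are
``S = zeta_s * n`` and ``S_T = zeta_T * n``.  A pulse buffer ``beta`` keeps
all event times pairwise more than ``beta`` generations apart.

Three hyperprior schemes are supported:

* ``"zeta-t"`` — psi restricted to {0, 1} with a discrete hyperprior on
  zeta_T; Psi and sigma are conditioned on zeta_T
  (``Psi = 1 + n - S_T`` when psi = 1).
* ``"psi"`` — a discrete uniform hyperprior on psi; within each psi every
  admissible zeta_T is weighted equally, and within each zeta_T every
  admissible zeta_s combination equally.  Per-psi fixed zeta_s tables are
  supported.
* ``"crp"`` — all set partitions of the n taxa weighted equally (the
  Dirichlet-process / Chinese-restaurant construction); psi counts blocks of
  size >= 2 and sigma the singletons.

``"custom"`` applies min/max constraints on zeta_T / zeta_s on top of the
``"psi"`` enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, factorial

import numpy as np

__all__ = [
    "BufferInfeasibleError",
    "HyperPriorSpec",
    "CoDemoDraw",
    "TaxonParams",
    "ParamSummary",
    "build_hyperprior",
    "admissible_intervals",
    "apply_buffer",
    "draw_codemo",
    "draw_event_times",
    "draw_taxon_params",
    "summarize_params",
]


class BufferInfeasibleError(RuntimeError):
    """Raised when the buffered admissible set for a time draw is empty."""

    def __init__(self, n_placed: int):
        super().__init__(
            f"no admissible times remain after placing {n_placed} buffered events"
        )
        self.n_placed = n_placed


# ---------------------------------------------------------------------------
# hyperprior specification


@dataclass(frozen=True)
class _Atom:
    """One discrete hyperprior cell: a pulse count and an (unordered)
    multiset of pulse proportions, with its hyperprior weight."""

    psi: int
    zeta_s: tuple[float, ...]
    weight: float

    @property
    def zeta_t(self) -> float:
        return float(sum(self.zeta_s))


@dataclass
class HyperPriorSpec:
    """Fully enumerated hyperprior over pulse counts and taxon assignments.

    Parameters
    ----------
    n_taxa:
        Number of taxa ``n`` (>= 2).
    scheme:
        ``"zeta-t"``, ``"psi"``, ``"crp"`` or ``"custom"`` (see module docs).
    psi_support:
        Discrete support for psi (ignored by ``"crp"``).
    zeta_t_grid:
        For ``"zeta-t"``: discrete support of zeta_T given psi = 1.
    fixed_zeta:
        Optional per-psi fixed zeta_s multisets, e.g. ``{2: (0.5, 0.5)}``;
        the multiset is shuffled across time-ordered pulses per draw.
    zeta_constraints:
        Optional dict with any of ``min_zeta_t``, ``max_zeta_t``,
        ``min_zeta_s``, ``max_zeta_s`` applied when enumerating atoms.
    tau_prior:
        Inclusive integer range ``(lo, hi)`` for event times, in generations.
    epsilon_prior:
        Continuous uniform range for the expansion size-change ratio.
    contraction_epsilon_prior:
        Continuous uniform range for contraction taxa; when ``None`` the
        reciprocal of an ``epsilon_prior`` draw is used.
    n_prior:
        Inclusive integer range for current population size (gene copies).
    beta:
        Pulse buffer in generations; ``beta_overrides`` maps specific psi
        values to alternative buffers (e.g. a reduced buffer when psi = 0).
    scenario_partition:
        Per-taxon scenario tags (``"expansion"`` / ``"contraction"``);
        defaults to all-expansion.
    buffer_idiosyncratic:
        Whether idiosyncratic times participate in buffering (default True).
    """

    n_taxa: int
    scheme: str = "psi"
    psi_support: tuple[int, ...] = (0, 1)
    zeta_t_grid: tuple[float, ...] | None = None
    fixed_zeta: dict[int, tuple[float, ...]] | None = None
    zeta_constraints: dict[str, float] | None = None
    tau_prior: tuple[int, int] = (5_000, 250_000)
    epsilon_prior: tuple[float, float] = (0.01, 0.10)
    contraction_epsilon_prior: tuple[float, float] | None = None
    n_prior: tuple[int, int] = (50_000, 250_000)
    beta: int = 0
    beta_overrides: dict[int, int] = field(default_factory=dict)
    scenario_partition: tuple[str, ...] | None = None
    buffer_idiosyncratic: bool = True
    atoms: tuple[_Atom, ...] = ()

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.tau_prior[0] >= self.tau_prior[1]:
            raise ValueError("tau prior must satisfy lo < hi")
        if self.beta < 0 or any(b < 0 for b in self.beta_overrides.values()):
            raise ValueError("beta must be >= 0")
        if any(p < 0 or p > self.n_taxa for p in self.psi_support):
            raise ValueError("psi_support must lie in {0..n_taxa}")
        if self.scenario_partition is not None:
            if len(self.scenario_partition) != self.n_taxa:
                raise ValueError("scenario_partition must have one tag per taxon")
            bad = set(self.scenario_partition) - {"expansion", "contraction"}
            if bad:
                raise ValueError(f"unknown scenario tags: {bad}")
        if self.fixed_zeta:
            for psi, zs in self.fixed_zeta.items():
                st = sum(zs) * self.n_taxa
                if abs(st - round(st)) > 1e-9:
                    raise ValueError(
                        f"fixed zeta_s for psi={psi} implies non-integer taxon count"
                    )

    def beta_for(self, psi: int) -> int:
        return self.beta_overrides.get(psi, self.beta)

    def scenarios(self) -> tuple[str, ...]:
        if self.scenario_partition is not None:
            return self.scenario_partition
        return ("expansion",) * self.n_taxa


def _partitions_min2(total: int, parts: int, lo: int = 2) -> list[tuple[int, ...]]:
    """Integer partitions of ``total`` into exactly ``parts`` parts, each >= lo
    (non-increasing order)."""
    if parts == 0:
        return [()] if total == 0 else []
    out = []
    for first in range(min(total - lo * (parts - 1), total), lo - 1, -1):
        for rest in _partitions_min2(total - first, parts - 1, lo):
            if not rest or first >= rest[0]:
                out.append((first,) + rest)
    return out


def _set_partition_count(sizes: tuple[int, ...], n: int) -> int:
    """Number of set partitions of n labelled taxa with the given block-size
    multiset."""
    count = factorial(n)
    for s in sizes:
        count //= factorial(s)
    mult: dict[int, int] = {}
    for s in sizes:
        mult[s] = mult.get(s, 0) + 1
    for m in mult.values():
        count //= factorial(m)
    return count


def _admissible(zs: tuple[float, ...], constraints: dict[str, float] | None) -> bool:
    if not constraints:
        return True
    zt = sum(zs)
    if zt < constraints.get("min_zeta_t", -np.inf) - 1e-12:
        return False
    if zt > constraints.get("max_zeta_t", np.inf) + 1e-12:
        return False
    for z in zs:
        if z < constraints.get("min_zeta_s", -np.inf) - 1e-12:
            return False
        if z > constraints.get("max_zeta_s", np.inf) + 1e-12:
            return False
    return True


def build_hyperprior(config: dict) -> HyperPriorSpec:
    """Construct a :class:`HyperPriorSpec` and enumerate its discrete atoms.

    ``config`` is a flat mapping with at least ``n_taxa`` and ``scheme``; the
    remaining keys mirror the :class:`HyperPriorSpec` fields.  Raises
    ``ValueError`` when the constraints leave no admissible hyperprior cell.
    """
    cfg = dict(config)
    scheme = cfg.get("scheme", "psi")
    n = int(cfg["n_taxa"])
    constraints = cfg.get("zeta_constraints")
    fixed = cfg.get("fixed_zeta")
    psi_support = tuple(sorted(int(p) for p in cfg.get("psi_support", (0, 1))))

    atoms: list[_Atom] = []
    if scheme == "zeta-t":
        if any(p not in (0, 1) for p in psi_support):
            raise ValueError("the zeta-T-conditioned scheme requires psi in {0, 1}")
        grid = cfg.get("zeta_t_grid")
        if grid is None:
            grid = tuple(s / n for s in range(2, n + 1))
        cells: dict[int, list[tuple[float, ...]]] = {}
        if 0 in psi_support:
            cells[0] = [()]
        if 1 in psi_support:
            ok = []
            for zt in grid:
                st = zt * n
                if abs(st - round(st)) > 1e-9:
                    raise ValueError(f"zeta_T={zt} implies non-integer taxon count")
                if round(st) < 2:
                    continue
                if _admissible((float(zt),), constraints):
                    ok.append((float(zt),))
            cells[1] = ok
        # equal weight per psi, equal weight per zeta_T cell within psi
        for psi, zlist in cells.items():
            if not zlist:
                continue
            for zs in zlist:
                atoms.append(_Atom(psi, zs, 1.0 / len(cells) / len(zlist)))
    elif scheme in ("psi", "custom"):
        per_psi: dict[int, list[tuple[tuple[float, ...], float]]] = {}
        for psi in psi_support:
            if fixed and psi in fixed:
                zs = tuple(sorted((float(z) for z in fixed[psi]), reverse=True))
                if _admissible(zs, constraints):
                    per_psi[psi] = [(zs, 1.0)]
                continue
            if psi == 0:
                if _admissible((), constraints) or not constraints:
                    per_psi[psi] = [((), 1.0)]
                continue
            # enumerate S_T cells, then zeta_s combinations within each
            by_st: dict[int, list[tuple[float, ...]]] = {}
            for s_t in range(2 * psi, n + 1):
                combos = []
                for sizes in _partitions_min2(s_t, psi):
                    zs = tuple(s / n for s in sizes)
                    if _admissible(zs, constraints):
                        combos.append(zs)
                if combos:
                    by_st[s_t] = combos
            if by_st:
                entries = []
                for s_t, combos in by_st.items():
                    for zs in combos:
                        entries.append((zs, 1.0 / len(by_st) / len(combos)))
                per_psi[psi] = entries
        for psi, entries in per_psi.items():
            for zs, w in entries:
                atoms.append(_Atom(psi, zs, w / len(per_psi)))
    elif scheme == "crp":
        total = 0
        raw: list[tuple[int, tuple[float, ...], int]] = []
        for n_blocks in range(1, n + 1):
            for sizes in _partitions_min2(n, n_blocks, lo=1):
                cnt = _set_partition_count(sizes, n)
                pulses = tuple(s / n for s in sizes if s >= 2)
                if not _admissible(pulses, constraints):
                    continue
                raw.append((sum(1 for s in sizes if s >= 2), pulses, cnt))
                total += cnt
        for psi, zs, cnt in raw:
            atoms.append(_Atom(psi, zs, cnt / total))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    if not atoms:
        raise ValueError("hyperprior constraints leave no admissible combination")

    return HyperPriorSpec(
        n_taxa=n,
        scheme=scheme,
        psi_support=psi_support,
        zeta_t_grid=tuple(cfg["zeta_t_grid"]) if cfg.get("zeta_t_grid") else None,
        fixed_zeta={int(k): tuple(v) for k, v in fixed.items()} if fixed else None,
        zeta_constraints=dict(constraints) if constraints else None,
        tau_prior=tuple(int(v) for v in cfg.get("tau_prior", (5_000, 250_000))),
        epsilon_prior=tuple(float(v) for v in cfg.get("epsilon_prior", (0.01, 0.10))),
        contraction_epsilon_prior=(
            tuple(float(v) for v in cfg["contraction_epsilon_prior"])
            if cfg.get("contraction_epsilon_prior")
            else None
        ),
        n_prior=tuple(int(v) for v in cfg.get("n_prior", (50_000, 250_000))),
        beta=int(cfg.get("beta", 0)),
        beta_overrides={int(k): int(v) for k, v in cfg.get("beta_overrides", {}).items()},
        scenario_partition=(
            tuple(cfg["scenario_partition"]) if cfg.get("scenario_partition") else None
        ),
        buffer_idiosyncratic=bool(cfg.get("buffer_idiosyncratic", True)),
        atoms=tuple(atoms),
    )


# ---------------------------------------------------------------------------
# realised draws


@dataclass
class CoDemoDraw:
    """One realised hierarchical draw.

    ``zeta_s`` is ordered by pulse time (most recent first) in lock-step with
    ``tau_s`` (ascending); ``zeta`` appends the idiosyncratic proportions
    ``1/n`` each; ``tau_i`` holds idiosyncratic times ascending.
    """

    Psi: int
    psi: int
    sigma: int
    zeta_t: float
    zeta_s: tuple[float, ...]
    zeta: tuple[float, ...]
    S_T: int
    S: tuple[int, ...]
    tau_s: tuple[int, ...]
    tau_i: tuple[int, ...]
    n_taxa: int

    def validate(self) -> None:
        n = self.n_taxa
        assert self.Psi == self.psi + self.sigma, "Psi must equal psi + sigma"
        assert abs(self.zeta_t - sum(self.zeta_s)) < 1e-9
        assert self.psi == 0 or all(2 / n - 1e-9 <= z <= 1 + 1e-9 for z in self.zeta_s)
        assert abs(self.S_T - self.zeta_t * n) < 1e-9 and isinstance(self.S_T, int)
        assert n == self.S_T + self.sigma
        assert self.S == tuple(round(z * n) for z in self.zeta_s)
        assert len(self.tau_s) == self.psi and len(self.tau_i) == self.sigma
        assert all(a < b for a, b in zip(self.tau_s, self.tau_s[1:]))
        assert all(a < b for a, b in zip(self.tau_i, self.tau_i[1:]))
        assert self.zeta == self.zeta_s + (1 / n,) * self.sigma

    def min_event_separation(self) -> float:
        times = sorted(self.tau_s + self.tau_i)
        if len(times) < 2:
            return np.inf
        return min(b - a for a, b in zip(times, times[1:]))


@dataclass
class TaxonParams:
    """Per-taxon parameter vectors.  ``pulse_id[t]`` labels taxon ``t``'s
    event: pulses ``1..psi`` by recency, idiosyncratic events ``psi+1..Psi``."""

    tau: np.ndarray
    epsilon: np.ndarray
    n_e: np.ndarray
    pulse_id: np.ndarray

    def __post_init__(self) -> None:
        lens = {len(self.tau), len(self.epsilon), len(self.n_e), len(self.pulse_id)}
        if len(lens) != 1:
            raise ValueError("per-taxon vectors must share a length")


@dataclass(frozen=True)
class ParamSummary:
    """Dispersion index ``omega_tau = Var(tau)/E(tau)`` (sample variance,
    divisor n-1) and mean event time ``e_tau``."""

    omega_tau: float
    e_tau: float


def admissible_intervals(
    tau_prior: tuple[int, int], existing_times: list[int] | tuple[int, ...], beta: int
) -> list[tuple[int, int]]:
    """Inclusive integer intervals of the prior range remaining after removing
    the closed window ``[t - beta, t + beta]`` around each existing time."""
    lo, hi = int(tau_prior[0]), int(tau_prior[1])
    intervals = [(lo, hi)]
    for t in existing_times:
        w_lo, w_hi = t - beta, t + beta
        nxt = []
        for a, b in intervals:
            if w_hi < a or w_lo > b:
                nxt.append((a, b))
                continue
            if a < w_lo:
                nxt.append((a, w_lo - 1))
            if b > w_hi:
                nxt.append((w_hi + 1, b))
        intervals = nxt
    return intervals


def apply_buffer(
    tau_prior: tuple[int, int],
    existing_times: list[int] | tuple[int, ...],
    beta: int,
    rng: np.random.Generator,
) -> int:
    """Draw one event time uniformly from the buffered admissible set.

    The admissible set is the integer prior range minus the union of closed
    windows ``[t - beta, t + beta]`` around already-placed times (for
    ``beta = 0`` only the placed points themselves are excluded).  Raises
    :class:`BufferInfeasibleError` when the set is empty.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    intervals = admissible_intervals(tau_prior, existing_times, beta)
    sizes = np.array([b - a + 1 for a, b in intervals], dtype=np.int64)
    total = int(sizes.sum())
    if total <= 0:
        raise BufferInfeasibleError(len(existing_times))
    u = int(rng.integers(0, total))
    cum = np.cumsum(sizes)
    seg = int(np.searchsorted(cum, u, side="right"))
    offset = u - (cum[seg - 1] if seg > 0 else 0)
    return intervals[seg][0] + int(offset)


def draw_event_times(
    n_events: int,
    tau_prior: tuple[int, int],
    beta: int,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> list[int]:
    """Sequentially draw ``n_events`` mutually buffered times; on dead ends
    (the sequential draws painted themselves into a corner) the whole
    sequence is retried, up to ``max_retries`` times."""
    for _ in range(max_retries):
        times: list[int] = []
        try:
            for _ in range(n_events):
                times.append(apply_buffer(tau_prior, times, beta, rng))
            return times
        except BufferInfeasibleError:
            continue
    raise BufferInfeasibleError(len(times))


def draw_codemo(spec: HyperPriorSpec, rng: np.random.Generator) -> CoDemoDraw:
    """Draw one realised co-demographic history from the hyperprior.

    An atom (psi and zeta_s multiset) is drawn by hyperprior weight; the
    multiset is shuffled, pulse and idiosyncratic times are drawn with the
    psi-specific buffer, and zeta_s is re-ordered so that ``zeta_s[0]``
    pertains to the most recent pulse.
    """
    if not spec.atoms:
        raise ValueError("spec has no enumerated atoms; use build_hyperprior")
    weights = np.array([a.weight for a in spec.atoms])
    atom = spec.atoms[rng.choice(len(spec.atoms), p=weights / weights.sum())]
    n = spec.n_taxa
    psi = atom.psi
    zs = list(atom.zeta_s)
    rng.shuffle(zs)
    S = tuple(int(round(z * n)) for z in zs)
    S_T = sum(S)
    sigma = n - S_T
    Psi = psi + sigma
    beta = spec.beta_for(psi)

    if spec.buffer_idiosyncratic:
        times = draw_event_times(Psi, spec.tau_prior, beta, rng)
        pulse_times, idio_times = times[:psi], times[psi:]
    else:
        pulse_times = draw_event_times(psi, spec.tau_prior, beta, rng)
        idio_times = []
        for _ in range(sigma):
            idio_times.append(
                apply_buffer(spec.tau_prior, idio_times, 0, rng)
            )
    order = np.argsort(pulse_times)
    tau_s = tuple(int(pulse_times[i]) for i in order)
    zeta_s = tuple(float(zs[i]) for i in order)
    S_sorted = tuple(S[i] for i in order)
    tau_i = tuple(sorted(int(t) for t in idio_times))

    draw = CoDemoDraw(
        Psi=Psi,
        psi=psi,
        sigma=sigma,
        zeta_t=float(sum(zeta_s)),
        zeta_s=zeta_s,
        zeta=zeta_s + (1.0 / n,) * sigma,
        S_T=S_T,
        S=S_sorted,
        tau_s=tau_s,
        tau_i=tau_i,
        n_taxa=n,
    )
    return draw


def draw_taxon_params(
    draw: CoDemoDraw, spec: HyperPriorSpec, rng: np.random.Generator
) -> TaxonParams:
    """Assign taxa to events and draw nuisance parameters.

    A uniform random permutation allocates ``S[j]`` taxa to pulse ``j`` and
    one taxon to each idiosyncratic event; every taxon independently draws
    ``epsilon`` (from its scenario's prior) and ``N``.
    """
    n = draw.n_taxa
    if spec.n_taxa != n:
        raise ValueError("draw and spec disagree on n_taxa")
    perm = rng.permutation(n)
    tau = np.empty(n, dtype=np.int64)
    pulse_id = np.empty(n, dtype=np.int64)
    pos = 0
    for j, (s, t) in enumerate(zip(draw.S, draw.tau_s), start=1):
        idx = perm[pos : pos + s]
        tau[idx] = t
        pulse_id[idx] = j
        pos += s
    for j, t in enumerate(draw.tau_i, start=draw.psi + 1):
        idx = perm[pos]
        tau[idx] = t
        pulse_id[idx] = j
        pos += 1

    eps = np.empty(n)
    for t_idx, tag in enumerate(spec.scenarios()):
        if tag == "expansion":
            eps[t_idx] = rng.uniform(*spec.epsilon_prior)
        elif spec.contraction_epsilon_prior is not None:
            eps[t_idx] = rng.uniform(*spec.contraction_epsilon_prior)
        else:
            eps[t_idx] = 1.0 / rng.uniform(*spec.epsilon_prior)
    n_e = rng.integers(spec.n_prior[0], spec.n_prior[1] + 1, size=n)
    return TaxonParams(tau=tau, epsilon=eps, n_e=n_e, pulse_id=pulse_id)


def summarize_params(params: TaxonParams) -> ParamSummary:
    """Dispersion index and mean of the taxon event times.

    ``omega_tau = Var(tau) / E(tau)`` with the sample variance (divisor
    ``n - 1``); undefined (rejected) when ``E(tau) = 0``.
    """
    tau = np.asarray(params.tau, dtype=float)
    if tau.size < 2:
        raise ValueError("need at least two taxa to summarise")
    mean = tau.mean()
    if mean == 0:
        raise ValueError("omega_tau undefined: mean event time is zero")
    return ParamSummary(omega_tau=float(tau.var(ddof=1) / mean), e_tau=float(mean))
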