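"""Reference-table construction: hierarchical draws coupled to the coalescent
engine and the aSFS, with counter-based per-simulation random substreams.

Every simulation ``i`` of a run with root seed ``s`` consumes its own
generator seeded from ``SeedSequence(s, spawn_key=(i,))``, so a run is
bit-reproducible and can be sharded by index range: shards written separately
concatenate to exactly the rows a single run would produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aggregate import asfs_matrix, mito_moments_matrix, mito_taxon_stats
from .engine import Demography, SaturationError, simulate_sequences, simulate_sfs_freq_batch
from .hier import HyperPriorSpec, draw_codemo, draw_taxon_params, summarize_params
from .inference import ReferenceTable

__all__ = [
    "SimulationBatch",
    "simulate_batch",
    "simulate_mito_batch",
    "simulate_reference_table",
    "psi_to_capital",
    "spec_fingerprint",
]

LABEL_COLUMNS = ("Psi", "psi", "sigma", "zeta_T")
SUMMARY_COLUMNS = ("omega_tau", "e_tau")


def psi_to_capital(psi: np.ndarray, n_taxa: int) -> np.ndarray:
    """Convert pulse counts to total event counts for estimation in the
    all-taxa-assigned design: ``psi = 0`` (full idiosyncrasy) maps to
    ``Psi = n``; any ``psi = k > 0`` with ``zeta_T = 1`` maps to ``Psi = k``."""
    psi = np.asarray(psi)
    return np.where(psi == 0, n_taxa, psi)


def spec_fingerprint(spec: HyperPriorSpec) -> str:
    """Stable hash of the hyperprior specification for provenance records."""
    import hashlib
    import json

    payload = {
        "n_taxa": spec.n_taxa,
        "scheme": spec.scheme,
        "psi_support": list(spec.psi_support),
        "zeta_t_grid": list(spec.zeta_t_grid) if spec.zeta_t_grid else None,
        "fixed_zeta": {str(k): list(v) for k, v in (spec.fixed_zeta or {}).items()},
        "zeta_constraints": spec.zeta_constraints,
        "tau_prior": list(spec.tau_prior),
        "epsilon_prior": list(spec.epsilon_prior),
        "contraction_epsilon_prior": (
            list(spec.contraction_epsilon_prior)
            if spec.contraction_epsilon_prior
            else None
        ),
        "n_prior": list(spec.n_prior),
        "beta": spec.beta,
        "beta_overrides": {str(k): v for k, v in spec.beta_overrides.items()},
        "scenario_partition": (
            list(spec.scenario_partition) if spec.scenario_partition else None
        ),
        "buffer_idiosyncratic": spec.buffer_idiosyncratic,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class SimulationBatch:
    """Raw per-simulation output prior to aggregation.

    ``taxon_data`` is ``(n_sims, n_taxa, k)``: folded-SFS proportions per
    taxon in genomic mode (``k = n_classes``), or the per-taxon sequence
    summaries ``(K, H, pi, D)`` in single-locus mode (``k = 4``).
    """

    taxon_data: np.ndarray
    labels: dict[str, np.ndarray]
    param_summaries: dict[str, np.ndarray]
    taxon_params: dict[str, np.ndarray]  # tau / epsilon / N, each (n_sims, n_taxa)
    n_samples: int
    n_genealogies: int
    mode: str = "asfs"

    @property
    def sfs_proportions(self) -> np.ndarray:
        if self.mode != "asfs":
            raise AttributeError("not a genomic-mode batch")
        return self.taxon_data


def _sim_rng(seed: int, index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(index,))
    return np.random.Generator(np.random.SFC64(ss))


def simulate_batch(
    spec: HyperPriorSpec,
    n_sims: int,
    seed: int,
    n_samples: int = 20,
    n_genealogies: int = 5_000,
    first_index: int = 0,
    fixed_psi: int | None = None,
) -> SimulationBatch:
    """Simulate ``n_sims`` hierarchical draws and their per-taxon folded SFS.

    ``first_index`` offsets the per-simulation substream counter so that
    shards covering disjoint index ranges reproduce a single contiguous run.
    ``fixed_psi`` conditions the hyperprior on one pulse-count value (used
    for designs with a set number of simulations per psi value).
    """
    n = spec.n_taxa
    half = n_samples // 2
    spec = _condition_on_psi(spec, fixed_psi)
    props = np.empty((n_sims, n, half))
    labels = {k: np.empty(n_sims) for k in LABEL_COLUMNS}
    summaries = {k: np.empty(n_sims) for k in SUMMARY_COLUMNS}
    taxon = {
        "tau": np.empty((n_sims, n)),
        "epsilon": np.empty((n_sims, n)),
        "N": np.empty((n_sims, n)),
    }
    for i in range(n_sims):
        rng = _sim_rng(seed, first_index + i)
        draw = draw_codemo(spec, rng)
        params = draw_taxon_params(draw, spec, rng)
        summary = summarize_params(params)
        counts = simulate_sfs_freq_batch(
            n_samples,
            n_genealogies,
            params.n_e.astype(float),
            params.epsilon,
            params.tau.astype(float),
            rng,
        )
        props[i] = counts / counts.sum(axis=1, keepdims=True)
        labels["Psi"][i] = draw.Psi
        labels["psi"][i] = draw.psi
        labels["sigma"][i] = draw.sigma
        labels["zeta_T"][i] = draw.zeta_t
        summaries["omega_tau"][i] = summary.omega_tau
        summaries["e_tau"][i] = summary.e_tau
        taxon["tau"][i] = params.tau
        taxon["epsilon"][i] = params.epsilon
        taxon["N"][i] = params.n_e
    return SimulationBatch(
        taxon_data=props,
        labels=labels,
        param_summaries=summaries,
        taxon_params=taxon,
        n_samples=n_samples,
        n_genealogies=n_genealogies,
    )


def simulate_mito_batch(
    spec: HyperPriorSpec,
    n_sims: int,
    seed: int,
    n_samples: int = 20,
    locus_length: int = 1_000,
    mu: float = 1e-7,
    first_index: int = 0,
    fixed_psi: int | None = None,
    max_retries: int = 20,
) -> SimulationBatch:
    """Simulate the single-locus mode: one sequence block per taxon per
    simulation, summarised per taxon as ``(K, H, pi, D)``.

    A saturated locus (more infinite-sites mutations than sites) is redrawn
    up to ``max_retries`` times before the error propagates.  The 16
    multi-taxa moment statistics are computed at aggregation time
    (:func:`copulse.aggregate.mito_moments_matrix`).
    """
    spec = _condition_on_psi(spec, fixed_psi)
    n = spec.n_taxa
    data = np.empty((n_sims, n, 4))
    labels = {k: np.empty(n_sims) for k in LABEL_COLUMNS}
    summ = {k: np.empty(n_sims) for k in SUMMARY_COLUMNS}
    taxon = {k: np.empty((n_sims, n)) for k in ("tau", "epsilon", "N")}
    for i in range(n_sims):
        rng = _sim_rng(seed, first_index + i)
        draw = draw_codemo(spec, rng)
        params = draw_taxon_params(draw, spec, rng)
        s = summarize_params(params)
        for t in range(n):
            demog = Demography(
                int(params.n_e[t]), float(params.epsilon[t]), int(params.tau[t])
            )
            for attempt in range(max_retries):
                try:
                    block = simulate_sequences(n_samples, locus_length, mu, demog, rng)
                    break
                except SaturationError:
                    if attempt == max_retries - 1:
                        raise
            st = mito_taxon_stats(block)
            data[i, t] = (
                st.n_haplotypes,
                st.haplotype_diversity,
                st.nucleotide_diversity,
                st.tajimas_d,
            )
        labels["Psi"][i] = draw.Psi
        labels["psi"][i] = draw.psi
        labels["sigma"][i] = draw.sigma
        labels["zeta_T"][i] = draw.zeta_t
        summ["omega_tau"][i] = s.omega_tau
        summ["e_tau"][i] = s.e_tau
        taxon["tau"][i] = params.tau
        taxon["epsilon"][i] = params.epsilon
        taxon["N"][i] = params.n_e
    return SimulationBatch(
        taxon_data=data,
        labels=labels,
        param_summaries=summ,
        taxon_params=taxon,
        n_samples=n_samples,
        n_genealogies=1,
        mode="mito",
    )


def _condition_on_psi(spec: HyperPriorSpec, fixed_psi: int | None) -> HyperPriorSpec:
    if fixed_psi is None:
        return spec
    from .hier import _Atom

    atoms = tuple(a for a in spec.atoms if a.psi == fixed_psi)
    if not atoms:
        raise ValueError(f"no hyperprior mass on psi={fixed_psi}")
    total = sum(a.weight for a in atoms)
    atoms = tuple(_Atom(a.psi, a.zeta_s, a.weight / total) for a in atoms)
    return HyperPriorSpec(**{**spec.__dict__, "atoms": atoms})


def simulate_reference_table(
    spec: HyperPriorSpec,
    seed: int,
    n_per_psi: int | None = None,
    n_total: int | None = None,
    n_samples: int = 20,
    n_genealogies: int = 5_000,
    convert_psi: bool = False,
    mode: str = "asfs",
    locus_length: int = 1_000,
    mu: float = 1e-7,
) -> ReferenceTable:
    """Simulate a reference table of multi-taxa summaries under the hyperprior.

    ``mode="asfs"`` (genomic) summarises each simulation as the aggregate
    SFS; ``mode="mito"`` (single-locus) as the 16 moment statistics.
    Exactly one of ``n_per_psi`` (a set number of simulations per pulse-count
    value, the stratified experimental design) or ``n_total`` (free draws
    from the full hyperprior) must be given.  With ``convert_psi`` the
    ``"Psi"`` label column is replaced by the all-taxa-assigned conversion
    (``psi = 0 -> Psi = n_taxa``), the scale used for estimation in designs
    where ``zeta_T`` is fixed at 1 for every ``psi > 0``.
    """
    if (n_per_psi is None) == (n_total is None):
        raise ValueError("give exactly one of n_per_psi or n_total")
    if mode not in ("asfs", "mito"):
        raise ValueError(f"unknown mode {mode!r}")
    plan = (
        [(psi, n_per_psi, i * n_per_psi) for i, psi in enumerate(spec.psi_support)]
        if n_per_psi is not None
        else [(None, n_total, 0)]
    )
    parts, labels_parts, summ_parts = [], [], []
    for fixed_psi, count, offset in plan:
        if mode == "asfs":
            b = simulate_batch(
                spec,
                count,
                seed,
                n_samples=n_samples,
                n_genealogies=n_genealogies,
                first_index=offset,
                fixed_psi=fixed_psi,
            )
            parts.append(asfs_matrix(b.sfs_proportions))
            labels_parts.append(b.labels)
            summ_parts.append(b.param_summaries)
        else:
            b = simulate_mito_batch(
                spec,
                count,
                seed,
                n_samples=n_samples,
                locus_length=locus_length,
                mu=mu,
                first_index=offset,
                fixed_psi=fixed_psi,
            )
            parts.append(mito_moments_matrix(b.taxon_data))
            labels_parts.append(b.labels)
            summ_parts.append(b.param_summaries)
    labels = {
        k: np.concatenate([p[k] for p in labels_parts]) for k in LABEL_COLUMNS
    }
    summaries = {
        k: np.concatenate([p[k] for p in summ_parts]) for k in SUMMARY_COLUMNS
    }
    if convert_psi:
        labels["Psi"] = psi_to_capital(labels["psi"], spec.n_taxa).astype(float)
    return ReferenceTable(
        summaries=np.concatenate(parts),
        labels=labels,
        param_summaries=summaries,
        provenance={
            "spec": spec_fingerprint(spec),
            "seed": seed,
            "mode": mode,
            "n_samples": n_samples,
            "n_genealogies": n_genealogies,
            "psi_converted": convert_psi,
        },
    )
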