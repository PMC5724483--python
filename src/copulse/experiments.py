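"""Canonical simulation-experiment designs and runners.

The flagship design is the buffered co-expansion experiment: n = 10 taxa,
20 haploid samples per taxon, 5,000 SNP genealogies per SFS, a pulse buffer
of 30,000 generations (reduced to 10,000 for the full-idiosyncrasy case
``psi = 0``, which the narrower prior range cannot buffer as widely), priors
``tau ~ U{5,000, 250,000}``, ``epsilon ~ U(0.01, 0.10)`` and
``N ~ U{50,000, 250,000}``.  All taxa are assigned to events
(``zeta_T = 1`` for every ``psi > 0``, split evenly across pulses), so pulse
counts are converted to total event counts for estimation:
``psi = 0 -> Psi = 10`` and ``psi = k > 0 -> Psi = k``.

``run_truncated_experiment`` performs the leave-one-out cross-validation of
Psi estimation (random forest and ABC model selection) for a truncated
hyperprior ``psi ~ U{0, psi_max}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hier import HyperPriorSpec, build_hyperprior
from .pipeline import simulate_reference_table
from .validation import CVReport, loo_crossval

__all__ = [
    "EVEN_ZETA_SPLITS",
    "truncated_design",
    "run_truncated_experiment",
    "TruncatedExperimentResult",
]

# Even distribution of zeta_T = 1.0 across the zeta_s vector for each pulse
# count (taxon counts must be whole, so psi = 3 and 4 use the closest uneven
# splits, shuffled across time-ordered pulses per simulation).
EVEN_ZETA_SPLITS: dict[int, tuple[float, ...]] = {
    1: (1.0,),
    2: (0.5, 0.5),
    3: (0.4, 0.3, 0.3),
    4: (0.3, 0.3, 0.2, 0.2),
    5: (0.2, 0.2, 0.2, 0.2, 0.2),
}


def truncated_design(
    psi_max: int,
    beta: int = 30_000,
    beta_psi0: int | None = 10_000,
    n_taxa: int = 10,
) -> HyperPriorSpec:
    """Hyperprior for the ``psi ~ U{0, psi_max}`` co-expansion design with all
    taxa assigned to events and the even zeta splits."""
    if not 1 <= psi_max <= 5:
        raise ValueError("psi_max must be in 1..5 for the even-split table")
    overrides = {}
    if beta_psi0 is not None and beta_psi0 != beta:
        overrides[0] = beta_psi0
    return build_hyperprior(
        {
            "n_taxa": n_taxa,
            "scheme": "psi",
            "psi_support": tuple(range(psi_max + 1)),
            "fixed_zeta": {k: EVEN_ZETA_SPLITS[k] for k in range(1, psi_max + 1)},
            "tau_prior": (5_000, 250_000),
            "epsilon_prior": (0.01, 0.10),
            "n_prior": (50_000, 250_000),
            "beta": beta,
            "beta_overrides": overrides,
        }
    )


@dataclass
class TruncatedExperimentResult:
    """Scores of one leave-one-out run of the truncated design."""

    rf: CVReport
    abc: CVReport
    seed: int
    design: dict = field(default_factory=dict)

    @property
    def rf_r(self) -> float:
        return self.rf.scores["rf"][0]

    @property
    def rf_rmse(self) -> float:
        return self.rf.scores["rf"][1]

    @property
    def abc_mean_r(self) -> float:
        return self.abc.scores["mean"][0]


def run_truncated_experiment(
    seed: int,
    psi_max: int = 1,
    n_per_psi: int = 5_000,
    pods_per_value: int = 20,
    n_retained: int = 1_500,
    n_genealogies: int = 5_000,
    n_samples: int = 20,
    beta: int = 30_000,
    beta_psi0: int | None = 10_000,
    rf_per_class: int = 1_000,
    table=None,
) -> TruncatedExperimentResult:
    """Leave-one-out Psi-estimation cross-validation on the truncated design.

    Simulates ``n_per_psi`` aSFS per pulse-count value (unless a prebuilt
    ``table`` is supplied), selects ``pods_per_value`` PODs per Psi value,
    and scores random-forest prediction and ABC model selection (tolerance
    chosen so that ``n_retained`` simulations are retained).
    """
    spec = truncated_design(psi_max, beta=beta, beta_psi0=beta_psi0)
    if table is None:
        table = simulate_reference_table(
            spec,
            seed,
            n_per_psi=n_per_psi,
            n_samples=n_samples,
            n_genealogies=n_genealogies,
            convert_psi=True,
        )
    tolerance = n_retained / table.n_sims
    rng_rf = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2**20,)))
    rng_abc = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2**20,)))
    rf = loo_crossval(
        table,
        pods_per_value,
        "rf",
        rng_rf,
        value_column="Psi",
        rf_options={"per_class": rf_per_class},
    )
    abc = loo_crossval(
        table,
        pods_per_value,
        "abc-model",
        rng_abc,
        value_column="Psi",
        tolerance=tolerance,
    )
    return TruncatedExperimentResult(
        rf=rf,
        abc=abc,
        seed=seed,
        design={
            "psi_max": psi_max,
            "n_per_psi": n_per_psi,
            "table_size": table.n_sims,
            "pods_per_value": pods_per_value,
            "tolerance": tolerance,
            "n_genealogies": n_genealogies,
            "beta": beta,
            "beta_psi0": beta_psi0,
        },
    )
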