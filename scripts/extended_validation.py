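#!/usr/bin/env python
"""Extended (hours-long) validation experiments.

These runs reproduce, at one-tenth of the original reference-table sizes,
the orderings of the pulse-buffer and inferential-framework comparisons:

1. Pulse-buffer comparison (``--experiment buffer``): three leave-one-out
   cross-validations of Psi estimation under ``psi ~ U{0, 5}`` — on an
   unbuffered (beta = 0) table, on a buffered (beta = 30,000) table, and the
   cross-design run (unbuffered PODs against the buffered table).  Expected
   orderings: hRF r improves from the unbuffered to the buffered table, the
   cross-design run falls between, and the hABC posterior-mean estimate of
   E(tau) scores r > 0.9.

2. Framework comparison (``--experiment frameworks``): on the buffered
   table, hRF versus hABC mean and both versus their PLS-transformed
   variants (PLS is expected to degrade accuracy).

Run from the repository root, e.g.::

    python scripts/extended_validation.py --experiment buffer --seed 1 \
        --per-psi 10000 --out scratch/buffer.json

With ``--per-psi 10000`` (60,000-row tables) the buffer experiment takes
roughly 1-2 h on one CPU; pass a smaller value for a faster, noisier run.
"""

from __future__ import annotations

import argparse
import json
import time
from pathlib import Path

import numpy as np

from copulse.experiments import truncated_design
from copulse.inference import pls_transform, ReferenceTable
from copulse.pipeline import simulate_reference_table
from copulse.validation import loo_crossval


def _table(beta: int, beta_psi0, per_psi: int, seed: int):
    spec = truncated_design(5, beta=beta, beta_psi0=beta_psi0)
    return simulate_reference_table(
        spec, seed, n_per_psi=per_psi, convert_psi=True
    )


def buffer_experiment(per_psi: int, seed: int) -> dict:
    results: dict = {}
    t0 = time.time()
    unbuffered = _table(0, None, per_psi, seed)
    buffered = _table(30_000, 10_000, per_psi, seed + 1)
    print(f"simulated two {unbuffered.n_sims}-row tables [{time.time()-t0:.0f}s]",
          flush=True)
    tol = min(1.0, 1_500 / buffered.n_sims)
    designs = {
        "beta0": dict(table=unbuffered, pod_table=None),
        "beta30000": dict(table=buffered, pod_table=None),
        "cross_beta0_pods_on_beta30000": dict(table=buffered, pod_table=unbuffered),
    }
    for name, kw in designs.items():
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(hash(name) % 2**31,)))
        rf = loo_crossval(kw["table"], 20, "rf", rng, pod_table=kw["pod_table"])
        abc = loo_crossval(
            kw["table"], 20, "abc-model", rng, tolerance=tol,
            pod_table=kw["pod_table"],
        )
        etau = loo_crossval(
            kw["table"], 50, "abc-param", rng, value_column="e_tau",
            tolerance=tol, pod_table=kw["pod_table"], stratify=False,
        )
        results[name] = {
            "rf": rf.scores["rf"],
            "abc_mean": abc.scores["mean"],
            "abc_median": abc.scores["median"],
            "abc_mode": abc.scores["mode"],
            "e_tau_mean": etau.scores["mean"],
        }
        print(f"{name}: rf r={rf.scores['rf'][0]:.3f} "
              f"abc mean r={abc.scores['mean'][0]:.3f} "
              f"E(tau) mean r={etau.scores['mean'][0]:.3f}", flush=True)
    results["orderings"] = {
        "rf_buffered_gt_unbuffered": results["beta30000"]["rf"][0]
        > results["beta0"]["rf"][0],
        "cross_between": results["beta0"]["rf"][0]
        <= results["cross_beta0_pods_on_beta30000"]["rf"][0]
        <= results["beta30000"]["rf"][0],
        "e_tau_r_above_0.9": results["beta30000"]["e_tau_mean"][0] > 0.9,
    }
    return results


def frameworks_experiment(per_psi: int, seed: int) -> dict:
    table = _table(30_000, 10_000, per_psi, seed)
    tol = min(1.0, 1_500 / table.n_sims)
    rng = np.random.default_rng(seed)
    rf = loo_crossval(table, 20, "rf", rng)
    abc = loo_crossval(table, 20, "abc-model", rng, tolerance=tol)
    # PLS-transformed variants: fit on a training subset, transform the rest
    n_train = min(10_000, table.n_sims // 6)
    rng2 = np.random.default_rng(seed + 1)
    train = rng2.choice(table.n_sims, size=n_train, replace=False)
    rest = np.setdiff1d(np.arange(table.n_sims), train)
    rest_x, _, fitted = pls_transform(
        table.summaries[train],
        table.labels["Psi"][train],
        table.summaries[rest],
        table.summaries[:1],
    )
    pls_table = ReferenceTable(
        rest_x, labels={"Psi": table.labels["Psi"][rest]}
    )
    rf_pls = loo_crossval(pls_table, 20, "rf", np.random.default_rng(seed + 2))
    abc_pls = loo_crossval(
        pls_table, 20, "abc-model", np.random.default_rng(seed + 2),
        tolerance=min(1.0, 1_500 / pls_table.n_sims),
    )
    out = {
        "rf": rf.scores["rf"],
        "abc_mean": abc.scores["mean"],
        "rf_pls": rf_pls.scores["rf"],
        "abc_pls_mean": abc_pls.scores["mean"],
        "pls_components": fitted.n_components,
        "orderings": {
            "rf_ge_abc_mean": rf.scores["rf"][0] >= abc.scores["mean"][0],
            "pls_degrades_rf": rf_pls.scores["rf"][0] <= rf.scores["rf"][0],
            "pls_degrades_abc": abc_pls.scores["mean"][0] <= abc.scores["mean"][0],
        },
    }
    for k, v in out.items():
        print(k, v, flush=True)
    return out


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--experiment", choices=["buffer", "frameworks"],
                        required=True)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--per-psi", type=int, default=10_000)
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()
    fn = buffer_experiment if args.experiment == "buffer" else frameworks_experiment
    results = fn(args.per_psi, args.seed)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(results, indent=1))


if __name__ == "__main__":
    main()
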