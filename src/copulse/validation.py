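"""Cross-validation machinery: pseudo-observed datasets (PODs), leave-one-out
and cross-design experiments, and Pearson-r / RMSE scoring.

A POD is a simulation with recorded true hyperparameter and
parameter-summary values used to score an estimator.  Leave-one-out
cross-validation treats reference-table rows as PODs: for ABC each POD is
excluded from its own reference set, while for the random forest the
selected PODs are collectively removed once and a single forest serves all
of them — the two exclusion rules are deliberately asymmetric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .hier import HyperPriorSpec
from .inference import (
    ReferenceTable,
    abc_model_select,
    abc_reject,
    rf_predict,
    rf_train,
)
from .pipeline import simulate_reference_table

__all__ = ["CVReport", "generate_pods", "loo_crossval", "score"]


@dataclass
class CVReport:
    """Per-POD truths and estimates with summary scores.

    ``estimates`` maps estimator names (``"rf"`` or ``"mean"`` / ``"median"``
    / ``"mode"`` for ABC) to per-POD estimates; ``scores`` maps the same
    names to ``(pearson_r, rmse)``.
    """

    method: str
    truths: np.ndarray
    estimates: dict[str, np.ndarray]
    scores: dict[str, tuple[float, float]]
    metadata: dict = field(default_factory=dict)

    def to_text(self) -> str:
        names = list(self.estimates)
        lines = ["\t".join(["pod", "truth"] + names)]
        for i, t in enumerate(self.truths):
            vals = [f"{self.estimates[n][i]:.6g}" for n in names]
            lines.append("\t".join([str(i), f"{t:.6g}"] + vals))
        for n in names:
            r, rmse = self.scores[n]
            lines.append(f"# {n}: pearson_r={r:.6g} rmse={rmse:.6g}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "truths": self.truths.tolist(),
                "estimates": {k: v.tolist() for k, v in self.estimates.items()},
                "scores": {k: list(v) for k, v in self.scores.items()},
                "metadata": self.metadata,
            },
            indent=1,
        )

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.write_text(self.to_text())
        path.with_suffix(path.suffix + ".json").write_text(self.to_json())


def score(estimates: np.ndarray, truths: np.ndarray) -> tuple[float, float]:
    """Pearson's r and RMSE of estimates against true values.

    ``r`` is reported as ``nan`` when either vector has zero variance.
    """
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if estimates.shape != truths.shape or estimates.size < 2:
        raise ValueError("need equal-length vectors with at least two entries")
    rmse = float(np.sqrt(np.mean((estimates - truths) ** 2)))
    if np.ptp(estimates) == 0 or np.ptp(truths) == 0:
        return float("nan"), rmse
    r = float(stats.pearsonr(estimates, truths).statistic)
    return r, rmse


def generate_pods(
    spec: HyperPriorSpec,
    count: int,
    seed: int,
    n_samples: int = 20,
    n_genealogies: int = 5_000,
    per_psi: bool = False,
    convert_psi: bool = False,
) -> ReferenceTable:
    """Simulate independent PODs (as a small reference table with recorded
    truths).  With ``per_psi`` the count applies per pulse-count value."""
    if per_psi:
        return simulate_reference_table(
            spec,
            seed,
            n_per_psi=count,
            n_samples=n_samples,
            n_genealogies=n_genealogies,
            convert_psi=convert_psi,
        )
    return simulate_reference_table(
        spec,
        seed,
        n_total=count,
        n_samples=n_samples,
        n_genealogies=n_genealogies,
        convert_psi=convert_psi,
    )


def _stratified_pod_indices(
    values: np.ndarray, pods_per_value: int, rng: np.random.Generator
) -> np.ndarray:
    idx = []
    for v in np.unique(values):
        pool = np.flatnonzero(values == v)
        if pool.size < pods_per_value:
            raise ValueError(
                f"label value {v} has only {pool.size} rows for "
                f"{pods_per_value} PODs"
            )
        idx.append(rng.choice(pool, size=pods_per_value, replace=False))
    return np.concatenate(idx)


def loo_crossval(
    table: ReferenceTable,
    pods_per_value: int,
    method: str,
    rng: np.random.Generator,
    value_column: str = "Psi",
    tolerance: float | None = None,
    pod_table: ReferenceTable | None = None,
    stratify: bool = True,
    rf_options: dict | None = None,
) -> CVReport:
    """Cross-validate an estimator of ``value_column`` on a reference table.

    ``method`` is ``"rf"`` (random-forest regression), ``"abc-model"``
    (rejection model selection over discrete values) or ``"abc-param"``
    (rejection parameter-summary estimation).  PODs are selected stratified
    by the discrete values of ``value_column`` (or uniformly at random when
    ``stratify`` is False, in which case ``pods_per_value`` is the total).

    When ``pod_table`` is given the PODs come from it while the full
    ``table`` serves as the reference set (the cross-design experiment, e.g.
    unbuffered PODs against a buffered table); otherwise PODs are
    leave-one-out rows of ``table`` itself.
    """
    source = pod_table if pod_table is not None else table
    truths_all = source.column(value_column).astype(float)
    if stratify:
        pod_idx = _stratified_pod_indices(truths_all, pods_per_value, rng)
    else:
        pod_idx = rng.choice(source.n_sims, size=pods_per_value, replace=False)
    truths = truths_all[pod_idx]
    targets = source.summaries[pod_idx]
    internal = pod_table is None

    metadata = {
        "value_column": value_column,
        "n_pods": int(pod_idx.size),
        "pods_per_value": pods_per_value if stratify else None,
        "table_size": table.n_sims,
        "tolerance": tolerance,
        "cross_design": not internal,
    }

    if method == "rf":
        opts = dict(rf_options or {})
        if internal:
            keep = np.setdiff1d(np.arange(table.n_sims), pod_idx)
            train = table.subset(keep)
        else:
            train = table
        model = rf_train(train, rng, label=value_column, **opts)
        est = rf_predict(model, targets)
        estimates = {"rf": est}
        metadata["n_trees"] = model.n_trees
        metadata["train_size"] = train.n_sims
    elif method in ("abc-model", "abc-param"):
        if tolerance is None:
            raise ValueError("ABC methods require a tolerance")
        fn = abc_model_select if method == "abc-model" else abc_reject
        names = ("mean", "median", "mode")
        estimates = {n: np.empty(pod_idx.size) for n in names}
        for j, (row, target) in enumerate(zip(pod_idx, targets)):
            if internal:
                keep = np.concatenate(
                    [np.arange(row), np.arange(row + 1, table.n_sims)]
                )
                ref = table.subset(keep)
            else:
                ref = table
            res = fn(target, ref, tolerance, value_column)
            for n in names:
                estimates[n][j] = res.point_estimates[n]
    else:
        raise ValueError(f"unknown method {method!r}")

    scores = {n: score(v, truths) for n, v in estimates.items()}
    return CVReport(
        method=method,
        truths=truths,
        estimates=estimates,
        scores=scores,
        metadata=metadata,
    )
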