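"""Hierarchical inference on reference tables: ABC rejection (hyperparameter
estimation, model selection, parameter-summary estimation), random-forest
regression with class-balanced cycle subsampling, and an optional PLS
transformation of the summary space.

The ABC path is the simple rejection algorithm: summaries are standardised
per statistic by the median absolute deviation of the reference column,
simulations are ranked by Euclidean distance to the target, and the nearest
``round(tolerance * n_sims)`` are retained.  Point estimates are the mean,
median and mode of the retained label values; for discrete labels each value
is treated as a separate model and the retained-count proportions form the
category posterior.

The random-forest path is regression on the numeric label: ``n_cycles``
cycles each fit ``trees_per_cycle`` trees on a class-balanced subsample
(``per_class`` simulations per label value, subsample replaced between
cycles); the prediction is the mean over all trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "ReferenceTable",
    "PosteriorResult",
    "HierRandomForest",
    "abc_reject",
    "abc_model_select",
    "rf_train",
    "rf_predict",
    "pls_transform",
    "default_split_candidates",
]


@dataclass
class ReferenceTable:
    """Simulated summaries paired with hyperparameter draws.

    ``summaries`` is ``(n_sims, n_stats)``; ``labels`` maps label names
    (e.g. ``"Psi"``) to per-simulation values; ``param_summaries`` holds
    per-simulation parameter summaries (e.g. ``"omega_tau"``, ``"e_tau"``).
    """

    summaries: np.ndarray
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    param_summaries: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.summaries = np.asarray(self.summaries, dtype=float)
        if self.summaries.ndim != 2:
            raise ValueError("summaries must be (n_sims, n_stats)")
        if not np.all(np.isfinite(self.summaries)):
            raise ValueError("summaries contain missing values")
        n = self.n_sims
        for name, v in {**self.labels, **self.param_summaries}.items():
            arr = np.asarray(v)
            if arr.shape != (n,):
                raise ValueError(f"column {name!r} length {arr.shape} != {n} rows")
            if not np.all(np.isfinite(arr.astype(float))):
                raise ValueError(f"column {name!r} contains missing values")

    @property
    def n_sims(self) -> int:
        return self.summaries.shape[0]

    @property
    def n_stats(self) -> int:
        return self.summaries.shape[1]

    def column(self, name: str) -> np.ndarray:
        if name in self.labels:
            return np.asarray(self.labels[name])
        if name in self.param_summaries:
            return np.asarray(self.param_summaries[name])
        raise KeyError(name)

    def subset(self, idx: np.ndarray) -> "ReferenceTable":
        return ReferenceTable(
            self.summaries[idx],
            {k: np.asarray(v)[idx] for k, v in self.labels.items()},
            {k: np.asarray(v)[idx] for k, v in self.param_summaries.items()},
            dict(self.provenance),
        )


@dataclass
class PosteriorResult:
    """Retained-simulation posterior from ABC rejection."""

    accepted_indices: np.ndarray
    retained_values: np.ndarray
    tolerance: float
    point_estimates: dict[str, float]
    category_posteriors: dict[float, float] | None = None


def _scale_factors(summaries: np.ndarray) -> np.ndarray:
    """Per-statistic MAD of the reference columns; zero MADs fall back to the
    standard deviation, then to 1 (constant columns carry no distance)."""
    mad = stats.median_abs_deviation(summaries, axis=0)
    sd = summaries.std(axis=0)
    scale = np.where(mad > 0, mad, sd)
    return np.where(scale > 0, scale, 1.0)


def _retain(
    target: np.ndarray, summaries: np.ndarray, tolerance: float
) -> np.ndarray:
    target = np.asarray(target, dtype=float).ravel()
    if target.shape[0] != summaries.shape[1]:
        raise ValueError("target length must equal the number of statistics")
    if not (0 < tolerance <= 1):
        raise ValueError("tolerance must lie in (0, 1]")
    n = summaries.shape[0]
    n_keep = int(round(tolerance * n))
    if n_keep < 1:
        raise ValueError(f"tolerance {tolerance} retains zero of {n} simulations")
    scale = _scale_factors(summaries)
    d2 = np.sum(((summaries - target) / scale) ** 2, axis=1)
    order = np.argsort(d2, kind="stable")
    return order[:n_keep]


def _mode_continuous(values: np.ndarray) -> float:
    """Posterior mode via a Gaussian KDE (Silverman bandwidth) evaluated on a
    512-point grid over the retained range."""
    if np.ptp(values) == 0:
        return float(values[0])
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def abc_reject(
    target: np.ndarray,
    table: ReferenceTable,
    tolerance: float,
    value_column: str,
) -> PosteriorResult:
    """Simple ABC rejection for a continuous quantity.

    Retains the ``round(tolerance * n_sims)`` simulations nearest to
    ``target`` in MAD-standardised Euclidean distance and reports the mean,
    median and KDE mode of the retained ``value_column`` values.
    """
    idx = _retain(target, table.summaries, tolerance)
    vals = table.column(value_column).astype(float)[idx]
    return PosteriorResult(
        accepted_indices=idx,
        retained_values=vals,
        tolerance=tolerance,
        point_estimates={
            "mean": float(vals.mean()),
            "median": float(np.median(vals)),
            "mode": _mode_continuous(vals),
        },
    )


def abc_model_select(
    target: np.ndarray,
    table: ReferenceTable,
    tolerance: float,
    value_column: str = "Psi",
) -> PosteriorResult:
    """ABC rejection model selection over the discrete values of a label.

    Each discrete value is a separate model; the category posterior is the
    retained-count proportion per value.  The numeric values are exploited
    for the mean and median point estimates; the mode is the
    highest-posterior category (ties broken toward the lowest value).
    """
    idx = _retain(target, table.summaries, tolerance)
    vals = table.column(value_column).astype(float)[idx]
    cats, counts = np.unique(vals, return_counts=True)
    post = counts / counts.sum()
    mode = float(cats[np.argmax(post)])  # argmax takes the first (lowest) on ties
    return PosteriorResult(
        accepted_indices=idx,
        retained_values=vals,
        tolerance=tolerance,
        point_estimates={
            "mean": float(vals.mean()),
            "median": float(np.median(vals)),
            "mode": mode,
        },
        category_posteriors={float(c): float(p) for c, p in zip(cats, post)},
    )


def default_split_candidates(n_stats: int) -> int:
    """Default number of split-candidate variables: ``max(floor(n/3), 1)``,
    the regression-forest convention (33 for a 100-bin aSFS)."""
    return max(n_stats // 3, 1)


@dataclass
class HierRandomForest:
    """A hierarchical random forest: the pooled trees of ``n_cycles``
    class-balanced training cycles."""

    forests: list[RandomForestRegressor]
    n_stats: int
    label: str

    @property
    def n_trees(self) -> int:
        return sum(f.n_estimators for f in self.forests)


def rf_train(
    table: ReferenceTable,
    rng: np.random.Generator,
    label: str = "Psi",
    n_cycles: int = 100,
    trees_per_cycle: int = 10,
    per_class: int = 1000,
    max_features: int | None = None,
) -> HierRandomForest:
    """Train the cycle-subsampled regression forest.

    Each cycle draws ``per_class`` simulations per distinct label value
    (without replacement when possible; with replacement and a warning when a
    class is smaller than ``per_class``), fits ``trees_per_cycle`` regression
    trees on the balanced subsample, and returns the subsample to the pool.
    """
    y = table.column(label).astype(float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two distinct label values")
    if max_features is None:
        max_features = default_split_candidates(table.n_stats)
    by_class = {c: np.flatnonzero(y == c) for c in classes}
    for c, idx in by_class.items():
        if idx.size < per_class:
            warnings.warn(
                f"class {c} has {idx.size} < {per_class} rows; "
                "subsampling with replacement",
                RuntimeWarning,
                stacklevel=2,
            )
    forests = []
    for _ in range(n_cycles):
        rows = np.concatenate(
            [
                rng.choice(idx, size=per_class, replace=idx.size < per_class)
                for idx in by_class.values()
            ]
        )
        forest = RandomForestRegressor(
            n_estimators=trees_per_cycle,
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(table.summaries[rows], y[rows])
        forests.append(forest)
    return HierRandomForest(forests, table.n_stats, label)


def rf_predict(model: HierRandomForest, targets: np.ndarray) -> np.ndarray:
    """Mean prediction over all trees for each target row."""
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.shape[1] != model.n_stats:
        raise ValueError("target length must match the training statistics")
    preds = np.stack([f.predict(targets) for f in model.forests])
    return preds.mean(axis=0)


@dataclass
class PLSTransform:
    """Fitted latent-component projection retaining the smallest number of
    components whose cumulative explained summary-variance reaches the
    threshold."""

    model: PLSRegression
    n_components: int
    explained: np.ndarray  # cumulative explained X-variance per component

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.model.transform(np.asarray(X, dtype=float))[:, : self.n_components]


def pls_transform(
    train_x: np.ndarray,
    train_y: np.ndarray,
    rest_x: np.ndarray,
    targets: np.ndarray,
    var_threshold: float = 0.95,
    max_components: int | None = None,
) -> tuple[np.ndarray, np.ndarray, PLSTransform]:
    """Fit a PLS regression of the labels on a training subset of summaries
    and project the remaining rows and the targets onto the leading
    components.

    The component count is the smallest whose cumulative explained variance
    of the (scaled) training summaries reaches ``var_threshold``; rank
    deficiency truncates the count with a warning.  Returns the transformed
    ``rest_x``, transformed ``targets`` and the fitted transform.
    """
    train_x = np.asarray(train_x, dtype=float)
    train_y = np.asarray(train_y, dtype=float).ravel()
    if max_components is None:
        max_components = min(train_x.shape[1], train_x.shape[0] - 1, 50)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on near-null residuals
        model = PLSRegression(n_components=max_components, scale=True)
        model.fit(train_x, train_y)
    T = model.x_scores_
    P = model.x_loadings_
    x_mean = train_x.mean(axis=0)
    x_std = train_x.std(axis=0, ddof=1)
    x_std[x_std == 0] = 1.0
    Xs = (train_x - x_mean) / x_std
    total_ss = np.sum(Xs**2)
    cum = np.empty(T.shape[1])
    recon = np.zeros_like(Xs)
    for a in range(T.shape[1]):
        recon += np.outer(T[:, a], P[:, a])
        cum[a] = 1.0 - np.sum((Xs - recon) ** 2) / total_ss
    reached = np.flatnonzero(cum >= var_threshold)
    if reached.size == 0:
        warnings.warn(
            f"rank-deficient summaries: {cum[-1]:.3f} < {var_threshold} variance "
            f"explained with {T.shape[1]} components; using all",
            RuntimeWarning,
            stacklevel=2,
        )
        n_comp = T.shape[1]
    else:
        n_comp = int(reached[0]) + 1
    fitted = PLSTransform(model, n_comp, cum)
    return fitted.transform(rest_x), fitted.transform(np.atleast_2d(targets)), fitted
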