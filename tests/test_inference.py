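"""ABC rejection, hierarchical random forest and PLS transformation checks."""

import numpy as np
import pytest

from copulse.inference import (
    ReferenceTable,
    abc_model_select,
    abc_reject,
    default_split_candidates,
    pls_transform,
    rf_predict,
    rf_train,
)


def _table(n_sims=2_000, n_stats=8, seed=0, discrete=True):
    rng = np.random.default_rng(seed)
    y = (
        rng.integers(1, 5, size=n_sims).astype(float)
        if discrete
        else rng.uniform(0, 1, size=n_sims)
    )
    X = rng.normal(size=(n_sims, n_stats))
    X[:, 0] += y  # encode some signal
    return ReferenceTable(X, labels={"Psi": y}, param_summaries={"omega_tau": y * 2})


class TestAbcReject:
    def test_retained_count_exact_at_paper_bookkeeping(self):
        # 0.0025 of 600,000 rows retains exactly 1,500
        rng = np.random.default_rng(1)
        X = rng.normal(size=(600_000, 2))
        table = ReferenceTable(X, labels={"Psi": np.zeros(600_000)})
        res = abc_reject(np.zeros(2), table, 0.0025, "Psi")
        assert len(res.accepted_indices) == 1_500

    def test_tolerance_one_keeps_everything(self):
        table = _table(500)
        res = abc_reject(np.zeros(8), table, 1.0, "Psi")
        assert len(res.accepted_indices) == 500
        assert res.point_estimates["mean"] == pytest.approx(
            table.labels["Psi"].mean()
        )

    def test_self_match_always_retained(self):
        table = _table(1_000)
        target = table.summaries[123]
        res = abc_reject(target, table, 0.01, "Psi")
        assert 123 in res.accepted_indices

    def test_distances_non_decreasing_to_boundary(self):
        table = _table(1_000)
        target = np.zeros(8)
        res = abc_reject(target, table, 0.05, "Psi")
        from copulse.inference import _scale_factors

        scale = _scale_factors(table.summaries)
        d = np.sqrt((((table.summaries - target) / scale) ** 2).sum(axis=1))
        retained = np.sort(d[res.accepted_indices])
        rest = np.delete(d, res.accepted_indices)
        assert retained[-1] <= rest.min() + 1e-12

    def test_affine_rescaling_invariance(self):
        table = _table(800)
        target = table.summaries[5]
        base = abc_reject(target, table, 0.05, "Psi")
        scale = np.arange(1, 9) * 10.0
        shift = np.linspace(-3, 3, 8)
        rescaled = ReferenceTable(
            table.summaries * scale + shift, labels=dict(table.labels)
        )
        res = abc_reject(target * scale + shift, rescaled, 0.05, "Psi")
        np.testing.assert_array_equal(
            np.sort(base.accepted_indices), np.sort(res.accepted_indices)
        )

    def test_zero_retention_rejected(self):
        table = _table(100)
        with pytest.raises(ValueError):
            abc_reject(np.zeros(8), table, 0.001, "Psi")


class TestAbcModelSelect:
    def test_unanimity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 3))
        X[:100] += 50  # two well-separated clusters
        y = np.repeat([1.0, 10.0], 100)
        table = ReferenceTable(X, labels={"Psi": y})
        res = abc_model_select(X[150] + 0.01, table, 0.1, "Psi")
        assert res.category_posteriors[10.0] == pytest.approx(1.0)
        assert res.point_estimates["mean"] == 10.0
        assert res.point_estimates["mode"] == 10.0

    def test_even_split_point_estimates_and_tie_rule(self):
        # retained {1, 1, 10, 10}: mean 5.5, median 5.5, mode -> lowest value
        vals = np.array([1.0, 1.0, 10.0, 10.0])
        X = np.zeros((4, 2))
        table = ReferenceTable(X, labels={"Psi": vals})
        res = abc_model_select(np.zeros(2), table, 1.0, "Psi")
        assert res.point_estimates["mean"] == pytest.approx(5.5)
        assert res.point_estimates["median"] == pytest.approx(5.5)
        assert res.point_estimates["mode"] == 1.0

    def test_posterior_sums_to_one(self):
        table = _table(2_000)
        res = abc_model_select(table.summaries[0], table, 0.05, "Psi")
        assert sum(res.category_posteriors.values()) == pytest.approx(1.0)


class TestRandomForest:
    def test_default_split_candidates(self):
        assert default_split_candidates(100) == 33
        assert default_split_candidates(2) == 1

    def test_constant_labels_predict_constant(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 5))
        table = ReferenceTable(X, labels={"Psi": np.repeat([2.0, 2.0], 150)})
        with pytest.raises(ValueError):
            rf_train(table, rng)

    def test_noiseless_linear_label_recovered(self):
        rng = np.random.default_rng(4)
        y = np.repeat([1.0, 2.0, 3.0], 400)
        X = rng.normal(size=(1_200, 6))
        X[:, 2] = y  # label encoded in one column, noiseless
        table = ReferenceTable(X, labels={"Psi": y})
        model = rf_train(table, rng, per_class=100, n_cycles=10)
        held = rng.normal(size=(60, 6))
        truth = np.repeat([1.0, 2.0, 3.0], 20)
        held[:, 2] = truth
        pred = rf_predict(model, held)
        from copulse.validation import score

        r, _ = score(pred, truth)
        assert r > 0.99

    def test_predictions_within_label_range(self):
        table = _table(600)
        rng = np.random.default_rng(5)
        model = rf_train(table, rng, per_class=50, n_cycles=5)
        pred = rf_predict(model, np.random.default_rng(6).normal(size=(50, 8)) * 10)
        assert np.all(pred >= 1.0) and np.all(pred <= 4.0)

    def test_small_class_warns_and_samples_with_replacement(self):
        table = _table(120)
        with pytest.warns(RuntimeWarning):
            rf_train(table, np.random.default_rng(7), per_class=100, n_cycles=2)

    def test_bit_reproducible_given_seed(self):
        table = _table(600)
        targets = np.random.default_rng(9).normal(size=(20, 8))
        preds = []
        for _ in range(2):
            model = rf_train(
                table, np.random.default_rng(8), per_class=50, n_cycles=5
            )
            preds.append(rf_predict(model, targets))
        np.testing.assert_array_equal(preds[0], preds[1])


class TestPlsTransform:
    def test_single_varying_direction_needs_one_component(self):
        rng = np.random.default_rng(10)
        t = rng.normal(size=500)
        direction = np.array([1.0, -2.0, 0.5, 3.0])
        X = np.outer(t, direction) + 1e-9 * rng.normal(size=(500, 4))
        rest, targets, fitted = pls_transform(X, t, X[:50], X[:2])
        assert fitted.n_components == 1
        assert rest.shape == (50, 1)

    def test_variance_accounting_reaches_threshold(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=400)
        X = rng.normal(size=(400, 12))
        X[:, 0] += y
        _, _, fitted = pls_transform(X, y, X, X[:1], var_threshold=0.95)
        assert fitted.explained[fitted.n_components - 1] >= 0.95

    def test_component_count_monotone_in_threshold(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=300)
        X = rng.normal(size=(300, 10))
        counts = [
            pls_transform(X, y, X, X[:1], var_threshold=v)[2].n_components
            for v in (0.5, 0.8, 0.95)
        ]
        assert counts == sorted(counts)


class TestReferenceTable:
    def test_row_count_agreement_enforced(self):
        with pytest.raises(ValueError):
            ReferenceTable(np.zeros((5, 2)), labels={"Psi": np.zeros(4)})

    def test_missing_values_rejected(self):
        X = np.zeros((5, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            ReferenceTable(X)
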