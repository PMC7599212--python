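"""Maximum-entropy model: features, fitting, evaluation and thresholds."""

import numpy as np
import pytest

from enmflow import synth
from enmflow.grid import GridTransform, RasterGrid, RasterStack
from enmflow.maxent import (
    FeatureBasis,
    FittedModel,
    MaxentConfig,
    compute_auc,
    compute_thresholds,
    evaluate_candidate,
    fit_maxent,
    omission_rate,
    permutation_importance_table,
    predict_raw,
    resolve_auto,
    sample_background,
    sedi,
    split_subsample,
)


def _bg(landscape, n, seed):
    return sample_background(landscape.env_stack, n, seed)[0]


class TestFeatures:
    def _basis(self, fc, k=3, m=50, n=200, seed=0):
        X = np.random.default_rng(seed).normal(size=(n, k))
        return FeatureBasis.fit(X, [f"v{i}" for i in range(k)], fc, m)

    @pytest.mark.parametrize("fc,expected", [("L", 3), ("LQ", 6), ("LQP", 9)])
    def test_feature_counts(self, fc, expected):
        basis = self._basis(fc)
        assert len(basis.feature_names) == expected

    @pytest.mark.parametrize(
        "m,expected", [(5, "L"), (12, "LQ"), (40, "LQH"), (120, "LQHP")]
    )
    def test_auto_schedule(self, m, expected):
        assert resolve_auto(m) == expected

    def test_constant_variable_drops_quadratic(self):
        X = np.random.default_rng(0).normal(size=(100, 2))
        X[:, 1] = 3.0
        basis = FeatureBasis.fit(X, ["a", "b"], "LQ", 50)
        assert "Q(b)" not in basis.feature_names
        assert "L(b)" in basis.feature_names

    def test_hinge_features_nonnegative(self):
        basis = self._basis("LQH")
        X = np.random.default_rng(1).normal(size=(50, 3))
        F = basis.transform(X)
        hinge_cols = [i for i, k in enumerate(basis.feature_kinds) if k == "hinge"]
        assert (F[:, hinge_cols] >= 0).all()

    def test_standardization_from_background(self):
        X = np.random.default_rng(2).normal(loc=5, scale=2, size=(500, 1))
        basis = FeatureBasis.fit(X, ["a"], "L", 50)
        F = basis.transform(X)
        assert abs(F.mean()) < 1e-9 and abs(F.std() - 1) < 1e-9


class TestAUC:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_all_ties(self):
        assert compute_auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_enumerated_pairs(self):
        # presences {0.9, 0.1} vs background {0.5, 0.5}: 2 wins, 2 losses
        assert compute_auc([0.9, 0.1], [0.5, 0.5]) == 0.5

    def test_monotone_invariance(self):
        rng = np.random.default_rng(3)
        p, b = rng.normal(1, 1, 30), rng.normal(0, 1, 100)
        assert compute_auc(p, b) == pytest.approx(compute_auc(np.exp(p), np.exp(b)))

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([], [0.5])


class TestThresholds:
    def test_mtp_is_min_training_score(self):
        ts = compute_thresholds([0.2, 0.5, 0.9], [0.3], [0.1, 0.6])
        assert ts.mtp == 0.2

    def test_p10_on_twenty_evenly_spaced_scores(self):
        train = np.arange(1, 21) * 0.05
        ts = compute_thresholds(train, [0.5], np.linspace(0, 1, 50))
        assert ts.p10 == pytest.approx(0.15)

    def test_p10_omission_contract(self):
        rng = np.random.default_rng(4)
        train = rng.uniform(size=57)
        ts = compute_thresholds(train, [0.5], rng.uniform(size=100))
        assert (train < ts.p10).mean() <= 0.10
        assert ts.mtp <= ts.p10

    def test_p10_falls_back_to_mtp_below_ten(self):
        with pytest.warns(UserWarning):
            ts = compute_thresholds([0.3, 0.5, 0.7], [0.5], [0.2, 0.8])
        assert ts.p10 == ts.mtp

    def test_ets_balances_sensitivity_and_specificity(self):
        rng = np.random.default_rng(5)
        test = rng.normal(1, 1, 200)
        bg = rng.normal(0, 1, 500)
        ts = compute_thresholds(test, test, bg)
        sens = (test >= ts.ets).mean()
        spec = (bg < ts.ets).mean()
        # brute-force optimum: no candidate threshold does better
        cand = np.unique(np.concatenate([test, bg]))
        best = min(abs((test >= t).mean() - (bg < t).mean()) for t in cand)
        assert abs(sens - spec) == pytest.approx(best)

    def test_ets_on_identical_distributions(self):
        vals = np.linspace(0, 1, 100)
        ts = compute_thresholds(vals, vals, vals)
        sens = (vals >= ts.ets).mean()
        spec = (vals < ts.ets).mean()
        assert abs(sens - spec) <= 0.02  # within one step of equality


class TestOmission:
    @pytest.mark.parametrize(
        "t,expected", [(0.5, 2 / 3), (0.0, 0.0), (1.01, 1.0)]
    )
    def test_fraction_below_threshold(self, t, expected):
        assert omission_rate([0.1, 0.4, 0.8], t) == pytest.approx(expected)


class TestSEDI:
    def test_zero_when_hit_equals_false_alarm(self):
        assert sedi(0.3, 0.3) == pytest.approx(0.0)

    def test_reference_value(self):
        assert sedi(0.9, 0.1) == pytest.approx(0.9125, abs=5e-4)

    def test_perfect_skill_limit(self):
        assert sedi(1 - 1e-6, 1e-6) > 0.99

    def test_boundary_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            v = sedi(1.0, 0.1)
        assert -1 <= v <= 1


class TestFit:
    def test_training_raw_sums_to_one(self, landscape, occurrences, fast_config):
        bg = _bg(landscape, 2000, 7)
        model = fit_maxent(landscape.env_stack, occurrences.cells[:40], bg,
                           fast_config, seed=7)
        assert model.raw_on_training().sum() == pytest.approx(1.0, abs=1e-6)

    def test_uniform_species_shrinks_to_zero(self, landscape):
        """With no environmental signal the L1 penalty keeps coefficients
        near zero."""
        rng = np.random.default_rng(8)
        valid = np.column_stack(np.nonzero(landscape.env_stack.valid_mask))
        pres = valid[rng.choice(len(valid), 100, replace=False)]
        bg = _bg(landscape, 5000, 8)
        cfg = MaxentConfig(feature_class="L", n_background=5000)
        model = fit_maxent(landscape.env_stack, pres, bg, cfg, seed=8)
        assert np.abs(model.coefficients).max() < 0.1

    def test_informative_sign_recovered(self, landscape, fast_config):
        tpl = synth.SpeciesTemplate("s", {"v1": (2.0, 0.0)}, prevalence=80)
        hits = 0
        for s in range(10):
            occ = synth.generate_species_occurrences(landscape, tpl, seed=40 + s)
            bg = _bg(landscape, 2000, 40 + s)
            model = fit_maxent(landscape.env_stack, occ.cells, bg, fast_config, 40 + s)
            i = model.basis.feature_names.index("L(v1)")
            hits += model.coefficients[i] > 0
        assert hits >= 9

    def test_penalty_monotonicity(self, landscape, occurrences):
        """Raising the regularization multiplier never raises total |lambda|."""
        bg = _bg(landscape, 2000, 9)
        norms = []
        for rm in (0.5, 1.0, 2.0, 4.0):
            cfg = MaxentConfig(feature_class="LQ", rm=rm, n_background=2000)
            m = fit_maxent(landscape.env_stack, occurrences.cells[:50], bg, cfg, 9)
            norms.append(np.abs(m.coefficients).sum())
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_too_few_presences_rejected(self, landscape, fast_config):
        bg = _bg(landscape, 500, 1)
        with pytest.raises(ValueError):
            fit_maxent(landscape.env_stack, bg[:3], bg, fast_config, 1)

    def test_serialization_round_trip(self, landscape, occurrences, fast_config):
        bg = _bg(landscape, 1000, 11)
        model = fit_maxent(landscape.env_stack, occurrences.cells[:30], bg,
                           fast_config, 11)
        back = FittedModel.from_json(model.to_json())
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        assert back.calibration_ranges == model.calibration_ranges
        surf_a = predict_raw(model, landscape.env_stack)
        surf_b = predict_raw(back, landscape.env_stack)
        np.testing.assert_allclose(surf_a.values, surf_b.values)


class TestPredict:
    def test_surface_sums_to_one(self, landscape, occurrences, fast_config):
        bg = _bg(landscape, 1000, 12)
        model = fit_maxent(landscape.env_stack, occurrences.cells[:30], bg,
                           fast_config, 12)
        surf = predict_raw(model, landscape.env_stack)
        assert surf.values[surf.valid_mask].sum() == pytest.approx(1.0, abs=1e-6)

    def test_doubling_cells_halves_values(self, landscape, occurrences, fast_config):
        bg = _bg(landscape, 1000, 13)
        model = fit_maxent(landscape.env_stack, occurrences.cells[:30], bg,
                           fast_config, 13)
        small = landscape.env_stack
        big_layers = {
            n: RasterGrid(
                np.tile(g.values, (2, 1)),
                GridTransform(0, 2 * small.shape[0] * 0.1, 0.1, 0.1),
            )
            for n, g in small.layers.items()
        }
        big = RasterStack(big_layers, small.descriptor_map)
        s_small = predict_raw(model, small)
        s_big = predict_raw(model, big)
        np.testing.assert_allclose(
            s_big.values[: small.shape[0]], s_small.values / 2, rtol=1e-9
        )

    def test_missing_variable_named_in_error(self, landscape, occurrences, fast_config):
        bg = _bg(landscape, 500, 14)
        model = fit_maxent(landscape.env_stack, occurrences.cells[:30], bg,
                           fast_config, 14)
        partial = landscape.env_stack.subset(["v1", "v2"])
        with pytest.raises(KeyError, match="v3"):
            predict_raw(model, partial)


class TestSplits:
    def test_seventy_thirty(self):
        tr, te = split_subsample(10, 0.7, 1, seed=0)[0]
        assert len(tr) == 7 and len(te) == 3

    def test_replicates_differ_and_seed_reproduces(self):
        s1 = split_subsample(50, 0.7, 5, seed=1)
        s2 = split_subsample(50, 0.7, 5, seed=1)
        assert not np.array_equal(s1[0][0], s1[1][0])
        for (a, _), (b, _) in zip(s1, s2):
            np.testing.assert_array_equal(a, b)


class TestImportance:
    def test_single_variable_model_gets_100(self, landscape, occurrences, fast_config):
        sub = landscape.env_stack.subset(["v1"])
        bg = _bg(landscape, 1000, 15)
        model = fit_maxent(sub, occurrences.cells[:40], bg, fast_config, 15)
        table = permutation_importance_table(model, 0)
        assert table["v1"] == pytest.approx(100.0)

    def test_informative_variable_dominates(self, landscape, occurrences, fast_config):
        bg = _bg(landscape, 2000, 16)
        model = fit_maxent(landscape.env_stack, occurrences.cells, bg, fast_config, 16)
        table = permutation_importance_table(model, 0)
        assert max(table, key=table.get) == "v1"
        assert sum(table.values()) == pytest.approx(100.0)

    def test_symmetric_variables_split_evenly(self, landscape, fast_config):
        tpl = synth.SpeciesTemplate("s", {"v1": (1.5, 0.0), "v2": (1.5, 0.0)},
                                    prevalence=150)
        shares = []
        for s in range(5):
            occ = synth.generate_species_occurrences(landscape, tpl, seed=60 + s)
            bg = _bg(landscape, 2000, 60 + s)
            model = fit_maxent(landscape.env_stack, occ.cells, bg, fast_config, 60 + s)
            shares.append(permutation_importance_table(model, s)["v1"])
        assert 40 <= np.mean(shares) <= 60


class TestEvaluate:
    def test_report_shapes_and_bounds(self, landscape, occurrences, fast_config):
        report, models = evaluate_candidate(
            landscape.env_stack, occurrences.cells, fast_config, seed=17
        )
        assert len(models) == fast_config.n_replicates
        assert all(0 <= a <= 1 for a in report.auc_test)
        assert all(0 <= o <= 1 for k in report.omission for o in report.omission[k])
        # MTP omission on training data is zero by construction: every
        # training score is >= its own minimum
        for m, ts in zip(models, report.thresholds):
            surf = predict_raw(m, landscape.env_stack)
            tr = surf.values[m.presence_cells[:, 0], m.presence_cells[:, 1]]
            assert (tr < ts.mtp).mean() == 0.0
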