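"""Fit statistics, regression, uncertainty and model-discrimination tests."""

from __future__ import annotations

import numpy as np
import pytest

import hcshkin as hk
from hcshkin.estimation import linearized_covariance
from hcshkin.kinetics import get_mechanism


def _toy_dataset(obs_by_test: dict[str, np.ndarray]) -> hk.KineticDataset:
    tests = []
    for test_id, obs in obs_by_test.items():
        times = tuple(30.0 * i for i in range(len(obs)))
        tests.append(
            hk.TestSpec(
                test_id, 120.0, 0.8, times[-1], times,
                hk.Composition.from_array(obs[0]),
            )
        )
    return hk.KineticDataset(tests, dict(obs_by_test))


def _fake_fit(mech_id: str, r2: float, fingerprint: str = "fp") -> hk.FitResult:
    mech = get_mechanism(mech_id)
    params = hk.ParameterVector.from_dict(
        mech_id, {lab: (1.0, 1.0) for lab in mech.constant_labels}
    )
    ssr = 1.0 - r2  # with SST = 1
    return hk.FitResult(
        mechanism_id=mech_id,
        params=params,
        ssr_global=ssr,
        sst=1.0,
        r_squared=r2,
        ssr_table={("A", "Test 3"): ssr},
        param_std=None,
        param_std_pct=None,
        diagnostics={},
        dataset_fingerprint=fingerprint,
    )


class TestStatistics:
    def test_ssr_zero_for_perfect_predictions(self):
        obs = np.array([[0.1, 0.2, 0.6, 0.1], [0.05, 0.15, 0.6, 0.2]])
        data = _toy_dataset({"Test 3": obs})
        preds = {"Test 3": obs.copy()}
        assert hk.ssr_global(data, preds) == 0.0
        for comp in hk.COMPONENTS:
            assert hk.ssr_component(data, preds, comp, "Test 3") == 0.0

    def test_ssr_uniform_residual(self):
        # residual 0.1 on each of 4 components of one sample -> 0.04
        obs = np.array([[0.1, 0.2, 0.6, 0.1], [0.1, 0.2, 0.6, 0.1]])
        pred = obs.copy()
        pred[1] += 0.1
        data = _toy_dataset({"Test 3": obs})
        assert hk.ssr_global(data, {"Test 3": pred}) == pytest.approx(0.04)
        for comp in hk.COMPONENTS:
            assert hk.ssr_component(
                data, {"Test 3": pred}, comp, "Test 3"
            ) == pytest.approx(0.01)

    def test_ssr_additivity_over_tests_and_components(self, rng):
        obs = {
            "Test 3": rng.dirichlet(np.ones(4), size=3),
            "Test 4": rng.dirichlet(np.ones(4), size=4),
        }
        preds = {k: np.clip(v + rng.normal(0, 0.01, v.shape), 0, 1)
                 for k, v in obs.items()}
        data = _toy_dataset(obs)
        total = hk.ssr_global(data, preds)
        per_test = [
            hk.ssr_global(_toy_dataset({t: obs[t]}), {t: preds[t]})
            for t in obs
        ]
        assert total == pytest.approx(sum(per_test), rel=1e-12)
        cells = [
            hk.ssr_component(data, preds, comp, t)
            for comp in hk.COMPONENTS
            for t in obs
        ]
        assert total == pytest.approx(sum(cells), rel=1e-12)

    def test_sst_constant_observations_is_zero(self):
        obs = np.tile([0.25, 0.25, 0.25, 0.25], (3, 1))
        assert hk.sst(_toy_dataset({"Test 3": obs})) == 0.0

    def test_sst_matches_direct_grand_mean_formula(self, rng):
        obs = {"Test 3": rng.dirichlet(np.ones(4), size=5)}
        data = _toy_dataset(obs)
        stacked = obs["Test 3"].ravel()
        assert hk.sst(data) == pytest.approx(
            float(((stacked - stacked.mean()) ** 2).sum())
        )

    def test_r_squared_identity_and_domain(self):
        assert hk.r_squared(0.0, 4.78) == 1.0
        assert hk.r_squared(4.78, 4.78) == 0.0
        assert hk.r_squared(3.82e-2, 4.78) == pytest.approx(0.992, abs=5e-4)
        with pytest.raises(ValueError):
            hk.r_squared(1.0, 0.0)

    def test_misaligned_predictions_rejected(self):
        obs = np.tile([0.25, 0.25, 0.25, 0.25], (3, 1))
        data = _toy_dataset({"Test 3": obs})
        with pytest.raises(ValueError):
            hk.ssr_global(data, {"Test 3": obs[:2]})
        with pytest.raises(ValueError):
            hk.ssr_global(data, {"other": obs})
        with pytest.raises(ValueError):
            hk.ssr_component(data, {"Test 3": obs}, "E", "Test 3")

    def test_dataset_invariants(self):
        with pytest.raises(ValueError):
            hk.KineticDataset([], {})
        bad = np.array([[0.5, 0.5, 0.2, 0.2], [0.25, 0.25, 0.25, 0.25]])
        with pytest.raises(ValueError):
            _toy_dataset({"Test 3": bad})  # sum 1.4 beyond raw tolerance


class TestFit:
    def test_noiseless_refit_from_truth_recovers_perfectly(
        self, fit_d_truth_start
    ):
        assert fit_d_truth_start.ssr_global <= 1e-8
        assert fit_d_truth_start.r_squared >= 0.9999

    def test_multistart_prediction_recovery(
        self, fit_d_multistart_noiseless, noiseless_data, true_params
    ):
        """Random multistart on noiseless data recovers the generating
        trajectories (prediction recovery; elementwise parameter recovery
        is not asserted because some directions are sloppy)."""
        res = fit_d_multistart_noiseless
        assert res.ssr_global <= 1e-6
        for test in noiseless_data.tests:
            fitted = hk.predict_at_samples("d", res.params, test)
            generating = hk.predict_at_samples("d", true_params, test)
            assert np.abs(fitted - generating).max() <= 1e-3

    def test_fit_identities_and_diagnostics(self, fit_d_noisy):
        res = fit_d_noisy
        assert res.r_squared == pytest.approx(
            1.0 - res.ssr_global / res.sst, abs=1e-12
        )
        assert sum(res.ssr_table.values()) == pytest.approx(
            res.ssr_global, rel=1e-12
        )
        assert len(res.ssr_table) == 12  # 4 components x 3 tests
        # the returned optimum is the best over all recorded starts
        assert res.ssr_global <= min(res.diagnostics["start_costs"]) + 1e-12
        assert res.diagnostics["seed"] == 42

    def test_noisy_fit_close_to_generating_model(
        self, fit_d_noisy, noisy_data, true_params
    ):
        assert fit_d_noisy.r_squared >= 0.98
        preds = {
            t.test_id: hk.predict_at_samples("d", true_params, t)
            for t in noisy_data.tests
        }
        r2_truth = hk.r_squared(
            hk.ssr_global(noisy_data, preds), hk.sst(noisy_data)
        )
        assert abs(fit_d_noisy.r_squared - r2_truth) <= 0.01

    def test_no_starts_requested_raises(self, noiseless_data):
        with pytest.raises(ValueError):
            hk.fit("d", noiseless_data, hk.FitOptions(n_multistart=0))


class TestUncertainty:
    def test_matches_closed_form_linear_regression(self):
        # y = a t: var(a_hat) = s^2 / sum(t^2)
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        jac = t[:, None]
        ssr = 0.02
        var, flags = linearized_covariance(jac, ssr, len(t))
        s2 = ssr / (len(t) - 1)
        assert var[0] == pytest.approx(s2 / float((t**2).sum()), rel=1e-6)
        assert not flags.any()

    def test_rank_deficiency_flagged_infinite(self):
        t = np.linspace(1, 5, 8)
        jac = np.column_stack([t, t])  # duplicated parameter
        with pytest.warns(RuntimeWarning):
            var, flags = linearized_covariance(jac, 0.1, len(t))
        assert flags.any()
        assert np.isinf(var).all()

    def test_zero_residual_fit_has_zero_std(
        self, noiseless_data, true_params
    ):
        perfect = hk.FitResult(
            mechanism_id="d",
            params=true_params,
            ssr_global=0.0,
            sst=hk.sst(noiseless_data),
            r_squared=1.0,
            ssr_table={
                (c, t.test_id): 0.0
                for c in hk.COMPONENTS
                for t in noiseless_data.tests
            },
            param_std=None,
            param_std_pct=None,
            diagnostics={},
            dataset_fingerprint=noiseless_data.fingerprint(),
        )
        std, pct = hk.parameter_uncertainty(perfect, noiseless_data)
        assert np.all(std == 0.0)
        assert np.all(pct == 0.0)

    def test_fit_reports_percent_std(self, fit_d_noisy):
        assert fit_d_noisy.param_std is not None
        finite = np.isfinite(fit_d_noisy.param_std)
        assert finite.any()
        np.testing.assert_allclose(
            fit_d_noisy.param_std_pct[finite],
            100.0
            * fit_d_noisy.param_std[finite]
            / np.abs(fit_d_noisy.params.values[finite]),
        )


class TestCompareModels:
    def test_parsimony_breaks_near_ties(self):
        fits = [_fake_fit("f", 0.986), _fake_fit("c", 0.989),
                _fake_fit("d", 0.992)]
        ranking = hk.compare_models(fits).ranking
        assert [f.mechanism_id for f in ranking] == ["d", "c", "f"]
        # d (14 params) wins over c (18) within the 0.005 band; c vs f
        # differ by 0.003 so the 18-parameter fit still precedes the
        # 22-parameter one

    def test_equal_r2_smaller_model_wins(self):
        fits = [_fake_fit("a", 0.99), _fake_fit("d", 0.99)]
        assert hk.compare_models(fits).best.mechanism_id == "d"

    def test_single_fit_is_trivial_ranking(self):
        comparison = hk.compare_models([_fake_fit("d", 0.9)])
        assert comparison.best.mechanism_id == "d"
        assert len(comparison.summary_rows()) == 1

    def test_mixed_datasets_rejected(self):
        with pytest.raises(ValueError):
            hk.compare_models(
                [_fake_fit("d", 0.9, "fp1"), _fake_fit("a", 0.9, "fp2")]
            )

    def test_generating_mechanism_wins_on_its_own_data(
        self, fit_d_noisy, fit_a_noisy, fit_b_noisy
    ):
        comparison = hk.compare_models([fit_a_noisy, fit_b_noisy, fit_d_noisy])
        assert comparison.best.mechanism_id == "d"
        rows = comparison.summary_rows()
        assert rows[0]["mechanism"] == "d"
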