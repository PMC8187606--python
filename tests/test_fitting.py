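"""Least-squares estimation: round trips, noise studies, failure modes,
model selection and replicate aggregation."""

import dataclasses

import numpy as np
import pytest

from lemfold import (
    Conditions,
    DenaturationCurve,
    IllConditionedError,
    SyntheticConfig,
    ThermalParams,
    ThreeStateParams,
    TwoStateParams,
    aggregate_replicates,
    fit_thermal,
    fit_three_state,
    fit_two_state,
    select_model,
    simulate_curves,
    simulate_refolding_branch,
    thermal_signal,
    three_state_signal,
    two_state_signal,
)


def _chem_curve(params, x, cond=Conditions(), kind="urea"):
    if isinstance(params, ThreeStateParams):
        y = three_state_signal(params, x, cond)
    else:
        y = two_state_signal(params, x, cond)
    return DenaturationCurve(kind, x, y)


class TestNoiseFreeRoundTrips:
    """At zero noise the global optimum is the generating truth exactly."""

    def test_two_state(self, urea_cd_truth, cond):
        curve = _chem_curve(urea_cd_truth, np.arange(0, 8.01, 0.25), cond)
        result = fit_two_state(curve, cond)
        for name, truth in dataclasses.asdict(urea_cd_truth).items():
            assert getattr(result.params, name) == pytest.approx(truth, rel=1e-6, abs=1e-8)
        assert result.derived["Dm"]["value"] == pytest.approx(4.3, rel=1e-6)

    def test_three_state(self, gdnhcl_cd_params, cond):
        curve = _chem_curve(gdnhcl_cd_params, np.arange(0, 6.01, 0.25), cond, "gdnhcl")
        result = fit_three_state(curve, cond)
        for name, truth in dataclasses.asdict(gdnhcl_cd_params).items():
            assert getattr(result.params, name) == pytest.approx(truth, rel=1e-6, abs=1e-8)
        assert result.derived["Dm_NI"]["value"] == pytest.approx(1.5 / 0.9, rel=1e-6)
        assert result.derived["dG_IU0"]["value"] == pytest.approx(2.8, rel=1e-6)

    def test_thermal(self, melt_cd_truth):
        x = np.arange(293.15, 363.16, 1.0)
        curve = DenaturationCurve("temperature", x, thermal_signal(melt_cd_truth, x))
        result = fit_thermal(curve)
        for name, truth in dataclasses.asdict(melt_cd_truth).items():
            assert getattr(result.params, name) == pytest.approx(truth, rel=1e-6, abs=1e-8)
        assert result.derived["Tm_C"]["value"] == pytest.approx(43.3, abs=1e-4)


class TestNoisyRecovery:
    def test_two_state_replicate_midpoint(self, urea_cd_truth, cond):
        """Triplicates at 2% amplitude noise recover the 4.3 M midpoint."""
        cfg = SyntheticConfig(model="two_state", truth=urea_cd_truth, seed=42)
        results = [fit_two_state(c, cond) for c in simulate_curves(cfg, cond)]
        summary = aggregate_replicates(results)
        assert summary.mean["Dm"] == pytest.approx(4.3, abs=0.4)
        assert summary.sem["Dm"] < 0.4

    def test_two_state_median_relative_error(self, urea_cd_truth, cond):
        """Median relative error of dG0 and m stays below 15% at 2% noise."""
        x = np.linspace(0, 8, 30)
        clean = two_state_signal(urea_cd_truth, x, cond)
        rng = np.random.default_rng(2024)
        errs_dg, errs_m = [], []
        for _ in range(50):
            y = clean + rng.normal(0, 0.02 * np.ptp(clean), size=x.shape)
            r = fit_two_state(DenaturationCurve("urea", x, y), cond)
            errs_dg.append(abs(r.params.dG0 - urea_cd_truth.dG0) / urea_cd_truth.dG0)
            errs_m.append(abs(r.params.m - urea_cd_truth.m) / urea_cd_truth.m)
        assert np.median(errs_dg) <= 0.15
        assert np.median(errs_m) <= 0.15

    def test_midpoint_error_shrinks_with_noise(self, urea_cd_truth, cond):
        """The Dm estimator is consistent: less noise, less error (on average)."""
        mean_err = []
        for noise in (0.04, 0.01, 0.0025):
            errs = []
            for seed in range(10):
                cfg = SyntheticConfig(
                    model="two_state", truth=urea_cd_truth,
                    noise_sd=noise, n_replicates=1, seed=seed,
                )
                r = fit_two_state(simulate_curves(cfg, cond)[0], cond)
                errs.append(abs(r.derived["Dm"]["value"] - 4.3))
            mean_err.append(np.mean(errs))
        assert mean_err[0] >= mean_err[1] >= mean_err[2]

    def test_three_state_curve_recovered_within_noise(self, gdnhcl_fluor_params, cond):
        """The fitted three-state curve tracks the truth to a few noise SD.

        The individual dG magnitudes of overlapping three-state
        transitions are weakly identified at this noise level (a steeper
        first transition plus a retuned second can mimic the truth), so
        the meaningful recovery statement is in curve space.
        """
        cfg = SyntheticConfig(model="three_state", truth=gdnhcl_fluor_params, seed=42)
        grid = np.arange(0, 6.01, 0.05)
        truth_curve = three_state_signal(gdnhcl_fluor_params, grid, cond)
        for curve in simulate_curves(cfg, cond):
            result = fit_three_state(curve, cond)
            fitted = three_state_signal(result.params, grid, cond)
            assert np.max(np.abs(fitted - truth_curve)) < 4 * 0.02
            # derived values stay consistent with the core identities
            assert result.params.Dm_NU * result.params.m_NU == pytest.approx(
                result.params.dG_NU0, rel=1e-10
            )

    def test_two_state_data_under_three_state_model(self, urea_cd_truth, cond):
        """Fitting three-state to two-state data leaves the intermediate empty."""
        cfg = SyntheticConfig(
            model="two_state", truth=urea_cd_truth, seed=9, n_replicates=1
        )
        curve = simulate_curves(cfg, cond)[0]
        result = fit_three_state(curve, cond)
        from lemfold import population_profile

        prof = population_profile(result.params, np.arange(0, 8.01, 0.1), cond)
        assert prof.max_f_I <= 0.05


class TestOracleEquivalence:
    def test_optimizer_not_beaten_by_brute_force_grid(self, cond):
        """SSR at the optimum <= best SSR on a 10^4 grid with truth baselines."""
        truth = TwoStateParams(dG0=3.0, m=1.0, a1=1.0, b1=-0.01, c1=0.1, p1=0.01)
        x = np.linspace(0, 8, 17)
        rng = np.random.default_rng(5)
        y = two_state_signal(truth, x, cond) + rng.normal(0, 0.02, size=x.shape)
        result = fit_two_state(DenaturationCurve("urea", x, y), cond)

        dg_grid = np.linspace(0.5, 8.0, 100)
        m_grid = np.linspace(0.2, 2.5, 100)
        best = np.inf
        for dg in dg_grid:
            g = dg - np.outer(m_grid, x)  # m varies down the rows
            k = np.exp(np.clip(-g / cond.rt, -700, 700))
            f_u = k / (1 + k)
            s = (truth.a1 + truth.b1 * x) * (1 - f_u) + (truth.c1 + truth.p1 * x) * f_u
            best = min(best, float(np.min(np.sum((s - y) ** 2, axis=1))))
        assert result.ssr <= best + 1e-12


class TestFailureModes:
    def test_monotone_line_is_ill_conditioned(self, cond):
        x = np.linspace(0, 8, 33)
        with pytest.raises(IllConditionedError):
            fit_two_state(DenaturationCurve("urea", x, 2 * x), cond)

    def test_flat_refolding_branch_is_ill_conditioned(self, melt_cd_truth):
        cfg = SyntheticConfig(model="thermal", truth=melt_cd_truth, noise_sd=0.01, seed=3)
        with pytest.raises(IllConditionedError):
            fit_thermal(simulate_refolding_branch(cfg))

    def test_too_few_points(self, cond):
        tiny = DenaturationCurve("urea", np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError, match="at least"):
            fit_two_state(tiny, cond)
        with pytest.raises(ValueError, match="at least"):
            fit_three_state(tiny, cond)

    def test_perturbant_kind_checked(self, cond, melt_cd_truth):
        x = np.arange(293.15, 363.16, 1.0)
        melt = DenaturationCurve("temperature", x, thermal_signal(melt_cd_truth, x))
        with pytest.raises(ValueError, match="urea/gdnhcl"):
            fit_two_state(melt, cond)
        chem = DenaturationCurve("urea", np.arange(9.0), np.arange(9.0))
        with pytest.raises(ValueError, match="temperature"):
            fit_thermal(chem)


class TestModelSelection:
    def test_two_state_data_preferred_by_majority(self, urea_cd_truth, cond):
        votes = []
        for seed in range(1, 11):
            cfg = SyntheticConfig(
                model="two_state", truth=urea_cd_truth, seed=seed, n_replicates=1
            )
            votes.append(select_model(simulate_curves(cfg, cond)[0], cond).recommended)
        assert votes.count("two_state") > 5

    def test_separated_three_state_data_preferred_by_majority(self, cond):
        truth = ThreeStateParams(
            dG_NI0=3.0, m_NI=2.0, dG_NU0=8.0, m_NU=3.2, a1=1.0, c1=0.55, e1=0.0
        )
        votes = []
        for seed in range(1, 11):
            cfg = SyntheticConfig(model="three_state", truth=truth, seed=seed, n_replicates=1)
            votes.append(select_model(simulate_curves(cfg, cond)[0], cond).recommended)
        assert votes.count("three_state") > 5

    def test_short_curve_rejected(self, cond):
        tiny = DenaturationCurve("urea", np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError, match="insufficient points"):
            select_model(tiny, cond)


class TestAggregateReplicates:
    def _result(self, dm, cond):
        truth = TwoStateParams(dG0=dm * 0.8, m=0.8, a1=1.0, c1=0.05)
        curve = _chem_curve(truth, np.arange(0, 8.01, 0.5), cond)
        return fit_two_state(curve, cond)

    def test_sem_of_hand_computed_example(self, cond):
        results = [self._result(dm, cond) for dm in (4.0, 4.3, 4.6)]
        summary = aggregate_replicates(results)
        assert summary.mean["Dm"] == pytest.approx(4.3, abs=1e-4)
        assert summary.sem["Dm"] == pytest.approx(0.173, abs=2e-3)

    def test_identical_results_have_zero_sem(self, cond):
        results = [self._result(4.3, cond) for _ in range(3)]
        summary = aggregate_replicates(results)
        assert summary.sem["Dm"] == pytest.approx(0.0, abs=1e-9)

    def test_single_result_lacks_sem(self, cond):
        summary = aggregate_replicates([self._result(4.3, cond)])
        assert summary.sem is None
        assert summary.mean["Dm"] == pytest.approx(4.3, abs=1e-4)

    def test_mixed_models_rejected(self, cond, melt_cd_truth):
        x = np.arange(293.15, 363.16, 1.0)
        melt = fit_thermal(DenaturationCurve("temperature", x, thermal_signal(melt_cd_truth, x)))
        with pytest.raises(ValueError, match="mixed"):
            aggregate_replicates([self._result(4.3, cond), melt])
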