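"""Parameter estimation: closed-form rate fits and multi-start recovery."""

import numpy as np
import pytest

from crkinetics.errors import (
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
)
from crkinetics.fitting import (
    fit_haldane,
    fit_rate_constant,
    fit_tertiary,
    r_squared,
)
from crkinetics.growth import TimeSeries
from crkinetics.models import (
    HaldaneParams,
    MonodBase,
    SubstrateState,
    TertiaryMonodParams,
    haldane_mu,
    rate_law_predict,
    RateLawParams,
)
from crkinetics.synthetic import generate_mu_dataset

from conftest import CR_HALDANE, GLUCOSE_HALDANE, HCIF_HALDANE, haldane_design


def crvi(times, values):
    return TimeSeries(times=tuple(times), values=tuple(values), quantity="crvi")


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self):
        obs = [1.0, 2.0, 3.0]
        assert r_squared(obs, [2.0, 2.0, 2.0]) == pytest.approx(0.0)

    def test_hand_arithmetic_example(self):
        # SS_res = 1, SS_tot = 2 -> 0.5
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_degenerate_observations_rejected(self):
        with pytest.raises(DegenerateDataError):
            r_squared([2, 2, 2], [1, 2, 3])


class TestRateConstant:
    def test_first_order_noise_free_recovery(self):
        t = np.arange(0.0, 97.0, 12.0)
        series = crvi(t, rate_law_predict(RateLawParams("first", 0.057, 10.0), t))
        fit = fit_rate_constant(series, "first")
        assert fit.k == pytest.approx(0.057, rel=1e-10)
        assert fit.C0_used == pytest.approx(10.0, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_second_order_noise_free_recovery(self):
        t = np.arange(0.0, 97.0, 12.0)
        series = crvi(t, rate_law_predict(RateLawParams("second", 0.126, 25.0), t))
        fit = fit_rate_constant(series, "second")
        assert fit.k == pytest.approx(0.126, rel=1e-10)
        assert fit.C0_used == pytest.approx(25.0, rel=1e-10)

    def test_no_decay_pair_degenerates_to_zero(self):
        fit = fit_rate_constant(crvi([0.0, 10.0], [10.0, 10.0]), "first")
        assert fit.k == 0.0
        assert fit.r_squared == 0.0

    @pytest.mark.parametrize("c1", [8.0, 5.0, 1.0])
    def test_two_point_closed_form_oracle(self, c1):
        # with two points the regression is exact: k = ln(C0/C1)/t1
        c0, t1 = 10.0, 24.0
        fit = fit_rate_constant(crvi([0.0, t1], [c0, c1]), "first")
        assert fit.k == pytest.approx(np.log(c0 / c1) / t1, rel=1e-12)

    def test_nondetects_excluded_from_transform(self):
        t = np.arange(0.0, 121.0, 12.0)
        c = 10.0 * np.exp(-0.057 * t)
        c[c < 0.05] = 0.0  # complete reduction: zeros the log cannot accept
        fit = fit_rate_constant(crvi(t, c), "first")
        assert fit.k == pytest.approx(0.057, rel=1e-10)
        assert fit.n_points == int(np.sum(c > 0.05))

    def test_all_nondetect_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_rate_constant(crvi([0.0, 12.0], [0.0, 0.0]), "first")

    def test_growth_clipped_to_zero_rate(self):
        fit = fit_rate_constant(crvi([0.0, 12.0, 24.0], [1.0, 2.0, 4.0]), "first")
        assert fit.k == 0.0

    def test_noisy_median_recovery_within_15_percent(self):
        t = np.arange(0.0, 97.0, 12.0)
        clean = rate_law_predict(RateLawParams("first", 0.057, 10.0), t)
        rng = np.random.default_rng(42)
        ks = []
        for _ in range(50):
            noisy = clean * (1 + 0.05 * rng.standard_normal(t.size))
            ks.append(fit_rate_constant(crvi(t, np.abs(noisy)), "first").k)
        assert np.median(ks) == pytest.approx(0.057, rel=0.15)


class TestHaldaneFit:
    @pytest.mark.parametrize(
        "truth", [GLUCOSE_HALDANE, CR_HALDANE, HCIF_HALDANE],
        ids=["glucose", "crvi", "hcif"],
    )
    def test_noise_free_recovery(self, truth):
        data = generate_mu_dataset(truth, haldane_design(truth), 0.0, seed=0)
        res = fit_haldane(data, n_starts=20, seed=0)
        assert res.converged
        assert res.params.mu_max == pytest.approx(truth.mu_max, rel=0.005)
        assert res.params.K_I == pytest.approx(truth.K_I, rel=0.02)
        assert res.r_squared >= 0.999

    def test_null_signal_flagged_degenerate(self):
        data = [(s, 0.0) for s in (1.0, 5.0, 20.0, 80.0, 200.0)]
        res = fit_haldane(data, n_starts=5, seed=1)
        assert res.degenerate
        assert res.params.mu_max <= 1e-5  # driven to the lower bound

    def test_too_few_distinct_levels_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_haldane([(1.0, 0.1), (1.0, 0.1), (2.0, 0.2), (2.0, 0.2)])

    def test_objective_nonincreasing_in_n_starts(self):
        truth = GLUCOSE_HALDANE
        data = generate_mu_dataset(truth, haldane_design(truth), 0.10, seed=9)
        norms = [
            fit_haldane(data, n_starts=n, seed=7).residual_norm
            for n in (1, 3, 10, 20)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_noisy_median_recovery_within_15_percent(self):
        truth = GLUCOSE_HALDANE
        design = haldane_design(truth)
        ests = []
        for rep in range(50):
            data = generate_mu_dataset(truth, design, 0.05, seed=2000 + rep)
            p = fit_haldane(data, n_starts=5, seed=rep).params
            ests.append((p.mu_max, p.K_S, p.K_I))
        med = np.median(ests, axis=0)
        assert med[0] == pytest.approx(truth.mu_max, rel=0.15)
        assert med[2] == pytest.approx(truth.K_I, rel=0.15)


class TestTertiaryFit:
    def test_noise_free_factorial_recovery(self, tertiary_truth, factorial_design):
        data = generate_mu_dataset(tertiary_truth, factorial_design, 0.0, seed=3)
        res = fit_tertiary(data, tertiary_truth, n_starts=20, seed=3)
        assert res.converged
        for name, truth_val in tertiary_truth.interactions().items():
            fitted = res.params.interactions()[name]
            assert fitted == pytest.approx(truth_val, rel=0.05), name
        assert res.r_squared >= 0.999

    def test_zero_interactions_recovered_at_bound(
        self, tertiary_truth, factorial_design
    ):
        null = tertiary_truth.with_interactions(np.zeros(9))
        data = generate_mu_dataset(null, factorial_design, 0.0, seed=5)
        res = fit_tertiary(data, null, n_starts=5, seed=5)
        assert all(v <= 1e-6 for v in res.params.interactions().values())

    def test_base_params_stay_frozen(self, tertiary_truth, factorial_design):
        # perturbing only the generator's interaction constants never moves
        # the recovered base parameters: they are not free
        for scale in (0.5, 2.0):
            gen = tertiary_truth.with_interactions(
                scale * np.array(list(tertiary_truth.interactions().values()))
            )
            data = generate_mu_dataset(gen, factorial_design, 0.0, seed=11)
            res = fit_tertiary(data, tertiary_truth, n_starts=3, seed=11)
            assert res.params.base_C == tertiary_truth.base_C
            assert res.params.base_P == tertiary_truth.base_P
            assert res.params.base_h == tertiary_truth.base_h

    def test_too_few_observations_rejected(self, tertiary_truth):
        obs = [(SubstrateState(1, 1, 1), 0.01)] * 9
        with pytest.raises(InsufficientDataError):
            fit_tertiary(obs, tertiary_truth)

    def test_identifiability_warning_for_flat_substrate(self, tertiary_truth):
        design = [SubstrateState(c, p, 1000.0)
                  for c in (100.0, 1000.0, 4000.0) for p in (10.0, 50.0, 100.0)
                  for _ in (0, 1)]
        data = generate_mu_dataset(tertiary_truth, design, 0.0, seed=2)
        res = fit_tertiary(data, tertiary_truth, n_starts=2, seed=2)
        assert any("S_h" in w for w in res.warnings)

    def test_noisy_median_recovery_within_15_percent(self):
        truth = TertiaryMonodParams(
            base_C=MonodBase(0.12, 500.0), base_P=MonodBase(0.15, 300.0),
            base_h=MonodBase(0.18, 400.0),
            K2_C=2.0, K3_C=1.0, K4_C=0.002,
            K2_P=1.5, K3_P=0.8, K4_P=0.001,
            K2_h=1.2, K3_h=2.5, K4_h=0.0015,
        )
        grid = (0.0, 100.0, 500.0, 2000.0)
        design = [SubstrateState(c, p, h)
                  for c in grid for p in grid for h in grid]
        ests = []
        for rep in range(50):
            data = generate_mu_dataset(truth, design, 0.05, seed=1000 + rep)
            res = fit_tertiary(data, truth, n_starts=3, seed=rep)
            ests.append(list(res.params.interactions().values()))
        med = np.median(ests, axis=0)
        tru = np.array(list(truth.interactions().values()))
        assert np.all(np.abs(med - tru) / tru < 0.15)
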