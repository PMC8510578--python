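"""Learning-model likelihoods, fitting, selection, and profile intervals."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from larvalearn import GenerativeConfig, simulate_experiment
from larvalearn.models import (
    MODEL_REGISTRY,
    AllOrNoneModel,
    QuantizedLearningModel,
    compare_models,
    fit_model,
    gaussian_density,
    log_likelihood,
    preference_table,
    trained_fraction,
    untrained_fraction_curve,
    variance_model,
)


def sim_table(seed=0, n_per_dose=30, doses=(0, 1, 2, 3, 4, 5, 10, 20), **cfg_kw):
    cfg = GenerativeConfig(cycle_doses={d: n_per_dose for d in doses}, seed=seed, **cfg_kw)
    groups, _ = simulate_experiment(cfg)
    return preference_table(groups)


class TestDensityAndVariance:
    def test_standard_normal_peak(self):
        assert gaussian_density(0.0, 0.0, 1.0) == pytest.approx(0.398942, abs=1e-6)

    def test_peak_closed_form_and_symmetry(self):
        for mu, sigma in [(0.3, 0.1), (0.5, 0.02)]:
            assert gaussian_density(mu, mu, sigma) == pytest.approx(
                1.0 / math.sqrt(2 * math.pi * sigma**2)
            )
            assert gaussian_density(mu + 0.07, mu, sigma) == pytest.approx(
                gaussian_density(mu - 0.07, mu, sigma)
            )

    def test_matches_scipy_norm(self, rng):
        x = rng.normal(size=50)
        assert np.allclose(gaussian_density(x, 0.3, 0.2), sps.norm.pdf(x, 0.3, 0.2))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_density(0.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "p,n,st,expected", [(0.5, 10, 1.0, 0.025), (0.5, 10, 0.8, 0.016)]
    )
    def test_variance_arithmetic(self, p, n, st, expected):
        assert variance_model(p, n, st) == pytest.approx(expected)

    def test_variance_floor_at_degenerate_mean(self):
        assert variance_model(0.0, 10, 1.0) == pytest.approx(1e-6)
        assert variance_model(1.0, 10, 1.0) == pytest.approx(1e-6)

    def test_zero_decisions_rejected(self):
        with pytest.raises(ValueError):
            variance_model(0.5, 0, 1.0)


class TestLogLikelihood:
    def one_obs(self, p=0.5, n=10, dose=0):
        return pd.DataFrame({"dose": [dose, dose], "p": [p, p], "n": [n, n]})

    def test_collapsed_mixture_closed_form(self):
        """With both component means at the observation and sigma_tilde=1 the
        quantized log density per larva is log N(0.5; 0.5, sqrt(0.025))."""
        X = self.one_obs()
        theta = {"mu_u": 0.5, "mu_t": 0.5, "sigma_tilde": 1.0, "f_u": (0.5,)}
        ll = log_likelihood(X, "quantized", theta)
        expected = math.log(1.0 / math.sqrt(2 * math.pi * 0.025))
        assert ll == pytest.approx(2 * expected, abs=1e-9)
        assert expected == pytest.approx(0.9255, abs=1e-4)

    def test_mixture_degeneracy_fu_one(self, rng):
        X = sim_table(seed=2, n_per_dose=10, doses=(0, 2))
        theta_q = {"mu_u": 0.3, "mu_t": 0.6, "sigma_tilde": 0.9, "f_u": (1.0, 1.0)}
        theta_s = {"mu": (0.3, 0.3), "sigma_tilde": 0.9}
        assert log_likelihood(X, "quantized", theta_q) == pytest.approx(
            log_likelihood(X, "shifting_mean", theta_s), abs=1e-8
        )

    def test_all_or_none_nests_in_quantized(self):
        """Setting f_u(n_c)=lambda**n_c makes the two likelihoods identical."""
        X = sim_table(seed=3, n_per_dose=12, doses=(0, 1, 5, 20))
        lam = 0.62
        theta_a = {"mu_u": 0.27, "mu_t": 0.52, "sigma_tilde": 0.9, "lam": lam}
        theta_q = {"mu_u": 0.27, "mu_t": 0.52, "sigma_tilde": 0.9,
                   "f_u": tuple(lam**d for d in (0, 1, 5, 20))}
        assert log_likelihood(X, "all_or_none", theta_a) == pytest.approx(
            log_likelihood(X, "quantized", theta_q), abs=1e-8
        )

    def test_invalid_theta_rejected(self):
        X = self.one_obs()
        with pytest.raises(ValueError):
            log_likelihood(X, "quantized",
                           {"mu_u": 1.2, "mu_t": 0.5, "sigma_tilde": 1.0, "f_u": (0.5,)})
        with pytest.raises(ValueError):
            log_likelihood(X, "all_or_none",
                           {"mu_u": 0.3, "mu_t": 0.5, "sigma_tilde": -1.0, "lam": 0.5})


class TestParameterCounts:
    def test_table_counts_at_eight_doses(self):
        expected = {"shifting_mean": 9, "graded": 16, "quantized": 11,
                    "three_cluster": 20, "all_or_none": 4}
        for name, k in expected.items():
            assert MODEL_REGISTRY[name]()._n_params(8) == k


class TestFitting:
    def test_information_criteria_identities(self):
        X = sim_table(seed=4, n_per_dose=15, doses=(0, 2, 20))
        f = fit_model(X, "all_or_none", n_starts=3)
        assert f.aic_ == pytest.approx(2 * f.k_ - 2 * f.loglik_)
        assert f.bic_ == pytest.approx(f.k_ * math.log(f.n_obs_) - 2 * f.loglik_)
        assert f.n_obs_ == len(X)

    def test_refit_deterministic(self):
        X = sim_table(seed=5, n_per_dose=12, doses=(0, 2, 20))
        f1 = fit_model(X, "quantized", n_starts=4, random_state=7)
        f2 = fit_model(X, "quantized", n_starts=4, random_state=7)
        assert f1.theta_ == f2.theta_
        assert f1.loglik_ == f2.loglik_

    def test_mixture_dominates_single_component(self):
        """On single-dose data the free two-Gaussian mixture cannot do worse
        than the single Gaussian at the same sigma_tilde."""
        X = sim_table(seed=6, n_per_dose=40, doses=(2,))
        q = fit_model(X, "quantized", n_starts=6)
        s = fit_model(X, "shifting_mean", n_starts=6)
        assert q.loglik_ >= s.loglik_ - 1e-6

    def test_all_or_none_parameter_recovery(self):
        """Truth mu_u=0.27, mu_t=0.52, lambda=0.6 at 300 larvae/dose is
        recovered within a few percent."""
        X = sim_table(seed=8, n_per_dose=300)
        f = fit_model(X, "all_or_none", n_starts=5)
        assert f.theta_["lam"] == pytest.approx(0.6, abs=0.05)
        assert f.theta_["mu_u"] == pytest.approx(0.27, abs=0.02)
        assert f.theta_["mu_t"] == pytest.approx(0.52, abs=0.02)

    def test_sigma_tilde_consistency_iid_choices(self):
        """With independent choices (no serial correlation) the fitted
        variance scale is ~1."""
        X = sim_table(seed=9, n_per_dose=400, doses=(0, 20), serial_delta=0.0)
        f = fit_model(X, "quantized", n_starts=5)
        assert f.theta_["sigma_tilde"] == pytest.approx(1.0, abs=0.1)

    def test_single_dose_degenerate_design_runs(self):
        X = sim_table(seed=10, n_per_dose=25, doses=(0,))
        tab, fits = compare_models(X, ["all_or_none", "quantized"], n_starts=3)
        assert set(tab["model"]) == {"all_or_none", "quantized"}
        assert np.isfinite(tab["delta_bic"]).all()

    def test_sklearn_get_set_params_roundtrip(self):
        est = AllOrNoneModel(n_starts=3, random_state=5)
        params = est.get_params()
        assert params["n_starts"] == 3
        est2 = AllOrNoneModel().set_params(**params)
        assert est2.random_state == 5


class TestComparison:
    def test_identical_specs_zero_deltas(self):
        X = sim_table(seed=11, n_per_dose=15, doses=(0, 2, 20))
        tab, _ = compare_models(X, ["all_or_none"], n_starts=3)
        assert tab["delta_logP"].iloc[0] == 0.0
        assert tab["delta_aic"].iloc[0] == 0.0

    def test_nesting_inequalities(self):
        X = sim_table(seed=12, n_per_dose=20, doses=(0, 1, 2, 5, 20))
        tab, fits = compare_models(
            X, ["all_or_none", "quantized", "three_cluster"], n_starts=3
        )
        assert fits["all_or_none"].loglik_ <= fits["quantized"].loglik_ + 1e-6
        assert fits["quantized"].loglik_ <= fits["three_cluster"].loglik_ + 1e-6

    def test_selects_all_or_none_on_switchlike_data(self):
        X = sim_table(seed=13, n_per_dose=60)
        tab, _ = compare_models(X, n_starts=2)
        best = tab.loc[tab["delta_bic"].idxmin(), "model"]
        assert best == "all_or_none"

    def test_graded_data_prefers_unimodal_models(self):
        X = sim_table(seed=14, n_per_dose=60, mode="graded")
        tab, _ = compare_models(X, ["all_or_none", "shifting_mean", "graded"], n_starts=2)
        best = tab.loc[tab["delta_bic"].idxmin(), "model"]
        assert best in ("shifting_mean", "graded")


class TestTrainedFraction:
    def fixed(self):
        return dict(mu_u=0.27, mu_t=0.52, sigma_tilde=0.9)

    def test_all_trained_hits_upper_boundary(self):
        X = pd.DataFrame({"p": [0.52] * 30, "n": [200] * 30})
        est = trained_fraction(X, **self.fixed())
        assert est.f0 > 0.97
        assert est.hi == 1.0

    def test_flat_profile_when_means_equal(self):
        X = pd.DataFrame({"p": [0.3, 0.4, 0.35], "n": [20, 20, 20]})
        est = trained_fraction(X, mu_u=0.4, mu_t=0.4, sigma_tilde=1.0)
        assert est.lo == 0.0 and est.hi == 1.0

    def test_interval_contains_point(self):
        X = sim_table(seed=15, n_per_dose=40, doses=(2,))[["p", "n"]]
        est = trained_fraction(X, **self.fixed())
        assert est.lo <= est.f0 <= est.hi

    def test_interval_matches_grid_scan(self, rng):
        """Profile endpoints agree with a dense grid scan of the profile
        log-likelihood within the grid resolution."""
        from larvalearn.models import _log_norm, _profile_loglik, variance_model as vm

        for seed in range(5):
            X = sim_table(seed=40 + seed, n_per_dose=40, doses=(2,))[["p", "n"]]
            est = trained_fraction(X, **self.fixed())
            p, n = X["p"].to_numpy(), X["n"].to_numpy()
            lu = _log_norm(p, 0.27, vm(0.27, n, 0.9))
            lt = _log_norm(p, 0.52, vm(0.52, n, 0.9))
            fs = np.linspace(0, 1, 2001)
            g = np.array([_profile_loglik(f, lu, lt) for f in fs])
            inside = fs[g >= g.max() - 0.5]
            assert est.lo == pytest.approx(inside.min(), abs=1e-3)
            assert est.hi == pytest.approx(inside.max(), abs=1e-3)

    def test_width_shrinks_with_group_size(self):
        widths = []
        for n_per in (15, 60, 240):
            ws = []
            for seed in range(8):
                X = sim_table(seed=60 + seed, n_per_dose=n_per, doses=(2,))[["p", "n"]]
                est = trained_fraction(X, **self.fixed())
                ws.append(est.hi - est.lo)
            widths.append(np.mean(ws))
        assert widths[0] > widths[1] > widths[2]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            trained_fraction(pd.DataFrame({"p": [], "n": []}), **self.fixed())


class TestUntrainedCurve:
    def test_memoryless_overlay_arithmetic(self):
        X = sim_table(seed=16, n_per_dose=25, doses=(0, 1, 2))
        aon = fit_model(X, "all_or_none", n_starts=3)
        lam = aon.theta_["lam"]
        assert np.allclose(aon.untrained_fractions([0, 1, 2]), [1, lam, lam**2])
        assert aon.untrained_fractions([0])[0] == 1.0

    def test_quantized_curve_tracks_exponential_decay(self):
        """Per-dose untrained fractions from the quantized fit bracket the
        memoryless prediction for most doses on switch-like data."""
        X = sim_table(seed=17, n_per_dose=120)
        tab, fits = compare_models(X, ["all_or_none", "quantized"], n_starts=3)
        curve = untrained_fraction_curve(X, fits["quantized"], fits["all_or_none"])
        lam = fits["all_or_none"].theta_["lam"]
        hits = sum(
            row.f_untrained_lo - 0.02 <= lam**row.dose <= row.f_untrained_hi + 0.02
            for row in curve.itertuples()
        )
        assert hits >= 6  # of 8 doses
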