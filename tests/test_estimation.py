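"""Objective arithmetic, global fitting, profiles, and goodness of fit."""

import numpy as np
import pytest

import photodyn as P
from photodyn.estimate import DEFAULT_WEIGHTS, objective, profile_threshold


@pytest.fixture(scope="module")
def clean_fit(chamber_dataset_clean):
    return P.fit(chamber_dataset_clean, seed=2, population=45, maxiter=25)


class TestObjective:
    def test_zero_on_self_simulated_data(self, params, chamber_dataset_clean):
        o = objective((params.ku, params.kd, params.c3),
                      chamber_dataset_clean, params)
        assert o == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_in_an_costs_its_weight(self, params, chamber_dataset_clean):
        ds = chamber_dataset_clean
        # An_m does not feed the initial state, so a uniform +1 shift
        # costs exactly its weight: 0.6 · 1²
        shifted = P.GasExchangeDataset(
            trace=ds.trace, gtc_m=ds.gtc_m, ci_m=ds.ci_m, An_m=ds.An_m + 1.0)
        o = objective((params.ku, params.kd, params.c3), shifted, params)
        assert o == pytest.approx(0.6, rel=1e-6)

    def test_conductance_shift_costs_its_weight(self, params, chamber_dataset_clean):
        ds = chamber_dataset_clean
        # shift gtc_m only after the initial record so the init is unchanged
        gtc = ds.gtc_m.copy()
        gtc[1:] += 0.1
        shifted = P.GasExchangeDataset(trace=ds.trace, gtc_m=gtc,
                                       ci_m=ds.ci_m, An_m=ds.An_m)
        o = objective((params.ku, params.kd, params.c3), shifted, params)
        assert o == pytest.approx(0.2 * 0.01 * (ds.N - 1) / ds.N, rel=1e-6)

    def test_matches_weighted_residual_sum(self, params, chamber_dataset):
        """The objective is the plain weighted per-record residual sum."""
        ds = chamber_dataset
        o = objective((params.ku, params.kd, params.c3), ds, params)
        res = P.simulate(ds.trace, params, ds.initial_state())
        w_g, w_c, w_a = DEFAULT_WEIGHTS
        manual = (
            w_g * np.sum((res.gtc - ds.gtc_m) ** 2)
            + w_c * np.sum((res.ci - ds.ci_m) ** 2)
            + w_a * np.sum((res.An - ds.An_m) ** 2)
        ) / ds.N
        assert o == pytest.approx(manual, rel=1e-12)

    def test_descends_toward_generating_triple(self, params, chamber_dataset_clean):
        """On noise-free data the objective shrinks toward the truth."""
        truth = np.array([params.ku, params.kd, params.c3])
        for scale in (1.5, 1.2, 1.05):
            far = objective(truth * [scale, 1, 1], chamber_dataset_clean, params)
            near = objective(truth * [(scale - 1) / 2 + 1, 1, 1],
                             chamber_dataset_clean, params)
            assert far > near > 0.0


class TestFit:
    def test_requires_enough_records(self, params, chamber_dataset_clean):
        short = P.GasExchangeDataset(
            trace=P.EnvironmentTrace(
                t=chamber_dataset_clean.trace.t[:50],
                I=chamber_dataset_clean.trace.I[:50],
                Tl=chamber_dataset_clean.trace.Tl[:50],
                ca=chamber_dataset_clean.trace.ca[:50]),
            gtc_m=chamber_dataset_clean.gtc_m[:50],
            ci_m=chamber_dataset_clean.ci_m[:50],
            An_m=chamber_dataset_clean.An_m[:50])
        with pytest.raises(ValueError, match="100"):
            P.fit(short, seed=0)

    def test_noise_free_recovery(self, params, clean_fit):
        assert clean_fit.estimates["ku"] == pytest.approx(params.ku, rel=0.02)
        assert clean_fit.estimates["kd"] == pytest.approx(params.kd, rel=0.02)
        assert clean_fit.estimates["c3"] == pytest.approx(params.c3, abs=0.02)
        assert clean_fit.objective < 1e-3

    def test_seeded_determinism(self, chamber_dataset):
        a = P.fit(chamber_dataset, seed=3, population=30, maxiter=8)
        b = P.fit(chamber_dataset, seed=3, population=30, maxiter=8)
        assert a.estimates == b.estimates
        assert a.objective == b.objective

    def test_estimates_within_bounds(self, clean_fit):
        for name, value in clean_fit.estimates.items():
            lo, hi = clean_fit.bounds[name]
            assert lo <= value <= hi

    def test_recovery_median_under_noise(self, params):
        """Median relative ku error < 5% over 10 noisy replicates."""
        errs = []
        for rep in range(10):
            spec = P.IrradianceProfileSpec(mode="chamber_fluctuating",
                                           duration=3600, seed=100 + rep)
            trace = P.generate_environment(spec)
            ds = P.generate_gas_exchange(trace, params, P.NoiseSpec(seed=200 + rep))
            r = P.fit(ds, seed=rep, population=45, maxiter=25)
            errs.append(abs(r.estimates["ku"] - params.ku) / params.ku)
        assert np.median(errs) < 0.05

    def test_asymmetric_model_beats_symmetric_constraint(self, params,
                                                         chamber_dataset_clean):
        """Forcing ku = kd on data generated with ku ≠ kd costs accuracy."""
        r_sym = P.fit(chamber_dataset_clean, seed=2, population=45, maxiter=25,
                      symmetric=True)
        r_asym = P.fit(chamber_dataset_clean, seed=2, population=45, maxiter=25)
        assert r_sym.objective > 10 * max(r_asym.objective, 1e-12)


class TestProfileLikelihood:
    def test_profile_minimum_at_estimate_and_interval_contains_it(
            self, params, chamber_dataset, clean_fit):
        fit_res = P.fit(chamber_dataset, seed=4, population=45, maxiter=25)
        ku_hat = fit_res.estimates["ku"]
        grid = np.linspace(ku_hat - 30, ku_hat + 30, 9)
        prof = P.profile_likelihood(chamber_dataset, "ku", grid,
                                    fixed=params, fit_result=fit_res)
        i_min = int(np.argmin(prof.objective))
        assert abs(prof.grid[i_min] - ku_hat) <= (grid[1] - grid[0])
        lo, hi = prof.interval
        assert lo <= ku_hat <= hi

    def test_profile_unimodal_on_noise_free_data(self, params,
                                                 chamber_dataset_clean):
        grid = np.linspace(120.0, 260.0, 8)
        prof = P.profile_likelihood(chamber_dataset_clean, "ku", grid, fixed=params)
        i_min = int(np.argmin(prof.objective))
        assert prof.objective[i_min] < 1e-3
        assert np.all(np.diff(prof.objective[: i_min + 1]) <= 0)
        assert np.all(np.diff(prof.objective[i_min:]) >= 0)

    def test_threshold_formula(self):
        from scipy import stats
        thr = profile_threshold(2.0, 1000)
        assert thr == pytest.approx(2.0 * (1 + stats.f.ppf(0.95, 1, 997) / 997))

    def test_unknown_parameter_rejected(self, chamber_dataset):
        with pytest.raises(ValueError):
            P.profile_likelihood(chamber_dataset, "Vcmax", np.linspace(90, 110, 5))


class TestGoodness:
    def test_identical_series_perfect_scores(self, params, chamber_dataset_clean):
        ds = chamber_dataset_clean
        res = P.simulate(ds.trace, params, ds.initial_state())
        g = P.goodness(ds, res)
        assert g["RMSE_An"] == pytest.approx(0.0, abs=1e-9)
        assert g["R2_An"] == pytest.approx(1.0, abs=1e-9)

    def test_constant_offset_gives_unit_rmse(self, params, chamber_dataset_clean):
        ds = chamber_dataset_clean
        res = P.simulate(ds.trace, params, ds.initial_state())
        shifted = P.GasExchangeDataset(trace=ds.trace, gtc_m=ds.gtc_m,
                                       ci_m=ds.ci_m, An_m=res.An + 1.0)
        assert P.goodness(shifted, res)["RMSE_An"] == pytest.approx(1.0, rel=1e-9)

    def test_rmse_of_pure_noise_equals_its_sigma(self, params):
        """Replica of the estimation protocol with σ_An = 0.75 noise."""
        spec = P.IrradianceProfileSpec(seed=21, duration=7200)
        trace = P.generate_environment(spec)
        noise = P.NoiseSpec(sigma_An=0.75, sigma_gtc=0.0, sigma_ci=0.0, seed=22)
        ds = P.generate_gas_exchange(trace, params, noise)
        res = P.simulate(ds.trace, params)
        assert P.goodness(ds, res)["RMSE_An"] == pytest.approx(0.75, rel=0.05)

    def test_zero_variance_series_rejected(self, params, chamber_dataset_clean):
        ds = chamber_dataset_clean
        res = P.simulate(ds.trace, params, ds.initial_state())
        flat = P.GasExchangeDataset(trace=ds.trace, gtc_m=ds.gtc_m,
                                    ci_m=ds.ci_m, An_m=np.full(ds.N, 5.0))
        with pytest.raises(ValueError, match="variance"):
            P.goodness(flat, res)
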