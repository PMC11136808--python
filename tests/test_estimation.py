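"""MAP eta recovery, pooled fixed-effect fits and identifiability
profiles on synthetic data."""

import numpy as np
import pytest

from balopk.dataset import SamplingScheme, generate_dataset
from balopk.estimation import (
    FitSpec,
    _predict,
    _prepare_subject,
    fit_pooled,
    map_ebe,
    neg2ll,
    profile_objective,
)
from balopk.model import Covariates, resolve_individual
from balopk.simulate import DosingRegimen, simulate_individual

DAY1_RICH = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)


def _simulated_frame(theta, subject_frame, regimen, obs_times, eta,
                     noise_sd=0.0, sid=1, rng=None):
    ip = resolve_individual(theta, Covariates(), eta)
    grid = np.unique(np.concatenate([[0.0], obs_times]))
    prof = simulate_individual(regimen, ip, grid=grid)
    dv = prof.conc_at(obs_times)
    if noise_sd:
        dv = dv * (1.0 + noise_sd * rng.standard_normal(dv.shape))
    return _frame(subject_frame, regimen, obs_times, dv, sid)


def _frame(subject_frame, regimen, obs_times, dv, sid):
    return subject_frame(regimen, obs_times, dv, sid=sid)


class TestMapEbe:
    def test_recovers_etas_from_noiseless_rich_data(self, theta, subject_frame,
                                                    build_pk_dataset):
        eta_true = np.array([0.25, -0.2, 0.1])
        regimen = DosingRegimen.oral_qd(12.0, 1)
        ds = build_pk_dataset([_simulated_frame(
            theta, subject_frame, regimen, np.array(DAY1_RICH), eta_true)])
        eta_hat = map_ebe(ds, theta, error_model="proportional",
                          sigma2_prop=1e-4)
        assert np.max(np.abs(eta_hat - eta_true)) < 1e-3

    def test_all_blq_shrinks_to_prior_mode(self, theta, subject_frame,
                                           build_pk_dataset):
        regimen = DosingRegimen.oral_qd(12.0, 1)
        ds = build_pk_dataset([subject_frame(regimen, [2.0, 4.0],
                                             [0.01, 0.02])])
        assert np.all(map_ebe(ds, theta) == 0.0)

    def test_sparse_design_shrinks_eta_spread(self, theta, subject_frame,
                                              build_pk_dataset):
        """Three samples per subject cannot support the full eta spread:
        empirical-Bayes estimates are pulled toward zero."""
        n = 40
        rng = np.random.default_rng(8)
        true = rng.standard_normal((n, 3)) * np.sqrt(theta.omegas)
        regimen = DosingRegimen.oral_qd(10.0, 1)
        obs_times = np.array([2.0, 4.0, 6.0])
        frames = []
        for i in range(n):
            ip = resolve_individual(theta, Covariates(), true[i])
            grid = np.concatenate([[0.0], obs_times])
            prof = simulate_individual(regimen, ip, grid=grid)
            dv = prof.conc[1:] * (1 + 0.2 * rng.standard_normal(3))
            frames.append(subject_frame(regimen, obs_times, dv, sid=i + 1))
        ds = build_pk_dataset(frames)
        ebes = np.array([map_ebe(ds, theta, sid=i + 1) for i in range(n)])
        assert np.var(ebes) < np.var(true)
        assert np.std(ebes[:, 1]) < np.std(true[:, 1])  # V0 strongly shrunk


@pytest.fixture(scope="module")
def iv_noiseless_dataset(theta, subject_frame, build_pk_dataset):
    regimen = DosingRegimen.iv_infusions([50.0], [0.0], 1.0)
    obs = np.array([2.0, 6.0, 12.0, 24.0, 48.0])
    ip = resolve_individual(theta, Covariates())
    prof = simulate_individual(regimen, ip,
                               grid=np.concatenate([[0.0], obs]))
    return build_pk_dataset([subject_frame(regimen, obs, prof.conc[1:])])


class TestPooledFit:
    def test_clearance_recovered_from_noiseless_iv_data(self, theta,
                                                        iv_noiseless_dataset):
        spec = FitSpec(free={"CL": 12.0}, error_model="proportional",
                       sigma2_prop=1e-4, n_starts=2)
        fit = fit_pooled(iv_noiseless_dataset, spec, theta0=theta)
        # typical adult CL_i includes the (near-unity) maturation factor
        expected = 8.52 * float(np.round(1 / (1 + np.exp(-0.267 * (30 - 5.34))), 6))
        assert fit.estimates["CL"] == pytest.approx(expected, rel=2e-3)
        assert fit.converged

    def test_duplicated_records_double_objective_not_estimates(
            self, theta, iv_noiseless_dataset, build_pk_dataset):
        df = iv_noiseless_dataset.df
        dup = df.copy()
        dup["ID"] = 2
        ds2 = build_pk_dataset([df, dup])
        spec = FitSpec(free={"CL": 10.0}, error_model="proportional",
                       sigma2_prop=0.01, n_starts=1)
        f1 = fit_pooled(iv_noiseless_dataset, spec, theta0=theta)
        f2 = fit_pooled(ds2, spec, theta0=theta)
        assert f2.estimates["CL"] == pytest.approx(f1.estimates["CL"], rel=1e-4)
        assert f2.objective == pytest.approx(2.0 * f1.objective, rel=1e-4)

    def test_bias_vanishes_with_noise(self, theta, subject_frame,
                                      build_pk_dataset):
        """Common random numbers across noise levels: the clearance bias
        scales down with the residual noise."""
        regimen = DosingRegimen.iv_infusions([50.0], [0.0], 1.0)
        obs = np.array([2.0, 6.0, 12.0, 24.0, 48.0])
        ip = resolve_individual(theta, Covariates())
        pred = simulate_individual(
            regimen, ip, grid=np.concatenate([[0.0], obs])).conc[1:]
        z = np.random.default_rng(21).standard_normal(len(obs))
        biases = []
        for sd in (0.10, 0.05, 0.01):
            ds = build_pk_dataset([subject_frame(regimen, obs,
                                                 pred * (1 + sd * z))])
            fit = fit_pooled(ds, FitSpec(free={"CL": 10.0},
                                         error_model="proportional",
                                         sigma2_prop=sd ** 2, n_starts=1),
                             theta0=theta)
            biases.append(abs(fit.estimates["CL"] / ip.CL_i - 1.0))
        assert biases[0] > biases[2]
        assert biases[2] < 0.01

    def test_single_dose_level_flags_identifiability(self, theta,
                                                     iv_noiseless_dataset):
        spec = FitSpec(free={"CL": 10.0, "VL_A50": 3.36},
                       error_model="proportional", sigma2_prop=0.01,
                       n_starts=1)
        fit = fit_pooled(iv_noiseless_dataset, spec, theta0=theta)
        assert any("non-identifiable" in f for f in fit.flags)

    def test_objective_trace_monotone(self, theta, iv_noiseless_dataset):
        spec = FitSpec(free={"CL": 20.0}, error_model="proportional",
                       sigma2_prop=0.01, n_starts=1)
        fit = fit_pooled(iv_noiseless_dataset, spec, theta0=theta)
        assert all(b <= a + 1e-6 for a, b in zip(fit.trace, fit.trace[1:]))

    def test_shared_likelihood_kernel(self, theta, iv_noiseless_dataset):
        """The pooled objective at fixed parameters equals the kernel
        evaluated on the same predictions (one likelihood code path)."""
        prep = _prepare_subject(iv_noiseless_dataset, 1)
        opts = {"method": "LSODA", "rtol": 1e-6, "atol": 1e-9}
        pred = _predict(prep, theta, np.zeros(3), opts)
        direct = neg2ll(prep["dv"], pred, prep["tad"], theta,
                        "proportional", 0.01)
        prof = profile_objective(
            iv_noiseless_dataset,
            FitSpec(free={"CL": theta.CL}, error_model="proportional",
                    sigma2_prop=0.01, n_starts=1),
            "CL", [theta.CL], theta0=theta)
        assert prof.objective.iloc[0] == pytest.approx(direct, rel=1e-9)


@pytest.fixture(scope="module")
def multidose_day1_dataset(theta):
    import pandas as pd

    scheme = SamplingScheme(name="day1", obs_times=DAY1_RICH[:-1], n_doses=1,
                            doses=(5.0, 12.0, 52.0))
    cov = pd.DataFrame({"age": [30.0] * 3, "weight": [76.0] * 3,
                        "sex": ["M"] * 3, "fed": [True] * 3})
    ds = generate_dataset(cov, scheme, theta=theta, seed=5,
                          etas=np.zeros((3, 3)), noiseless=True)
    rng = np.random.default_rng(7)
    obs = ds.df.EVID == 0
    ds.df.loc[obs, "DV"] *= 1 + 0.03 * rng.standard_normal(obs.sum())
    ds.df.loc[obs, "BLQ"] = (ds.df.loc[obs, "DV"] < 0.05).astype(int)
    return ds


class TestProfileObjective:
    def test_minimum_at_fitted_estimate(self, theta, multidose_day1_dataset):
        spec = FitSpec(free={"CL": 8.52, "V0": 565.0, "VL_A50": 3.36},
                       error_model="proportional", sigma2_prop=0.0009,
                       n_starts=1)
        fit = fit_pooled(multidose_day1_dataset, spec, theta0=theta)
        est = fit.estimates["VL_A50"]
        prof = profile_objective(multidose_day1_dataset, spec, "VL_A50",
                                 [0.6 * est, est, 1.6 * est], theta0=theta)
        assert prof.objective.idxmin() == 1

    def test_multidose_data_identify_binding_capacity(self, theta,
                                                      multidose_day1_dataset,
                                                      build_pk_dataset):
        """The half-saturation amount is sharply identified by a dose
        range; a single dose level constrains it far more weakly."""
        spec = FitSpec(free={"CL": 8.52, "V0": 565.0, "VL_A50": 3.36},
                       error_model="proportional", sigma2_prop=0.0009,
                       n_starts=1)
        grid = [3.36 * f for f in (0.5, 1.0, 1.5)]
        multi = profile_objective(multidose_day1_dataset, spec, "VL_A50",
                                  grid, theta0=theta)
        single_df = multidose_day1_dataset.df
        single = build_pk_dataset([single_df[single_df.ID == 2]])
        single_prof = profile_objective(single, spec, "VL_A50", grid,
                                        theta0=theta)
        span_multi = multi.objective.max() - multi.objective.min()
        span_single = single_prof.objective.max() - single_prof.objective.min()
        assert span_multi > 3.84
        assert span_multi > span_single


class TestFitSpecValidation:
    def test_requires_free_parameters(self):
        with pytest.raises(ValueError):
            FitSpec(free={})

    def test_initials_must_be_positive_and_within_bounds(self):
        with pytest.raises(ValueError):
            FitSpec(free={"CL": -1.0})
        with pytest.raises(ValueError):
            FitSpec(free={"CL": 5.0}, bounds={"CL": (6.0, 10.0)})
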