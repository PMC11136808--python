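"""Simulation-engine tests: closed-form oracles, mass balance, exposure
metrics and population summaries."""

import math

import numpy as np
import pytest

from balopk.model import Covariates, resolve_individual
from balopk.population import PopulationSpec
from balopk.simulate import (
    DoseEvent,
    DosingRegimen,
    RepeatingDose,
    dose_proportionality_scan,
    percentile_bands,
    simulate_individual,
    simulate_population,
    steady_state_metrics,
)

#: Published 5th-95th percentile concentration ranges (ng/mL) under the
#: 50/25/15 mg daily 60-min infusions, used as a typical-subject oracle.
IV_REFERENCE_RANGES = {
    1.0: (215.0, 566.0), 24.0: (23.0, 147.0), 25.0: (176.0, 392.0),
    48.0: (17.0, 149.0), 49.0: (107.0, 268.0), 72.0: (12.0, 117.0),
    96.0: (3.0, 57.0),
}


class TestRegimenContainers:
    def test_events_validated(self):
        with pytest.raises(ValueError):
            DoseEvent(time=-1.0, amount=10.0)
        with pytest.raises(ValueError):
            DoseEvent(time=0.0, amount=0.0)
        with pytest.raises(ValueError):
            DoseEvent(time=0.0, amount=10.0, route="iv_infusion")  # no duration
        with pytest.raises(ValueError):
            DosingRegimen(())
        with pytest.raises(ValueError):
            DosingRegimen((DoseEvent(24.0, 5.0), DoseEvent(0.0, 5.0)))

    def test_yaml_round_trip(self, tmp_path):
        reg = DosingRegimen.iv_infusions([50, 25], [0, 24], 1.0)
        path = tmp_path / "regimen.yaml"
        reg.to_yaml(path)
        assert DosingRegimen.from_yaml(path) == reg


class TestLinearLimitOracle:
    """With VLmax ~ 0 and Kgut ~ 0 the model is a linear one-compartment
    system with closed-form IV solution."""

    def test_iv_infusion_matches_closed_form(self, linear_ip):
        R0, dur = 50.0, 1.0
        k = linear_ip.CL_i / linear_ip.V0_i
        grid = np.linspace(0.0, 24.0, 97)
        prof = simulate_individual(
            DosingRegimen.iv_infusions([R0 * dur], [0.0], dur), linear_ip,
            grid=grid)
        c_inf = 1000.0 * R0 / linear_ip.CL_i
        expected = np.where(
            grid <= dur,
            c_inf * (1 - np.exp(-k * grid)),
            c_inf * (1 - np.exp(-k * dur)) * np.exp(-k * (grid - dur)))
        sel = grid > 0
        assert np.allclose(prof.conc[sel], expected[sel], rtol=1e-3)
        assert np.max(np.abs(prof.conc[sel] / expected[sel] - 1)) < 1e-3

    def test_oral_superposition(self, linear_ip):
        grid = np.arange(0.0, 120.1, 0.5)
        single = simulate_individual(
            DosingRegimen((DoseEvent(0.0, 5.0),)), linear_ip, grid=grid)
        double = simulate_individual(
            DosingRegimen((DoseEvent(0.0, 5.0), DoseEvent(24.0, 5.0))),
            linear_ip, grid=grid)
        shifted = np.interp(grid - 24.0, grid, single.conc, left=0.0)
        combo = single.conc + shifted
        sel = combo > 1e-3
        assert np.max(np.abs(double.conc[sel] - combo[sel])
                      / np.maximum(combo[sel], 1e-9)) < 1e-3

    def test_steady_state_auc_equals_dose_over_clearance(self, linear_ip):
        # tighter interval tolerance: the 46-h half-life leaves ~0.6% of
        # the accumulation outstanding at the default 0.5% stop rule
        m = steady_state_metrics(RepeatingDose(10.0, fed=True), linear_ip,
                                 tol=5e-4, max_intervals=90)
        assert m.AUC_tau == pytest.approx(1000.0 * 10.0 / linear_ip.CL_i,
                                          rel=5e-3)
        assert m.F_tau == pytest.approx(1.0, rel=5e-3)


class TestMassBalance:
    def test_iv_auc_times_clearance_recovers_dose(self, typical_ip):
        grid = np.arange(0.0, 801.0, 1.0)
        for dose in (15.0, 50.0):
            prof = simulate_individual(
                DosingRegimen.iv_infusions([dose], [0.0], 1.0), typical_ip,
                grid=grid)
            assert prof.cum_auc[-1] / 1000.0 * typical_ip.CL_i == pytest.approx(
                dose, rel=1e-3)

    def test_turnover_state_stays_in_unit_interval(self, typical_ip):
        prof = simulate_individual(DosingRegimen.oral_qd(52.0, 14), typical_ip,
                                   grid=np.arange(0.0, 430.0, 1.0))
        At = prof.states["At"]
        assert np.all(At > 0.0)
        assert np.all(At <= 1.0 + 1e-9)

    def test_gut_availability_in_unit_interval_and_nondecreasing(self, typical_ip):
        prof = simulate_individual(DosingRegimen.oral_qd(10.0, 5), typical_ip,
                                   grid=np.arange(0.0, 121.0, 1.0))
        F = prof.F_interval
        assert np.all((F > 0.0) & (F <= 1.0))
        assert np.all(np.diff(F) >= -1e-6)


class TestEmergentHalfLife:
    def test_terminal_half_life_at_low_amounts(self, typical_ip):
        # washout tail after a small IV dose: t1/2 -> ln2*V0/CL ~ 46 h
        grid = np.arange(0.0, 400.0, 2.0)
        prof = simulate_individual(
            DosingRegimen.iv_infusions([1.0], [0.0], 1.0), typical_ip, grid=grid)
        sel = (grid >= 200) & (grid <= 350)
        slope = np.polyfit(grid[sel], np.log(prof.conc[sel]), 1)[0]
        assert math.log(2) / -slope == pytest.approx(
            math.log(2) * typical_ip.V0_i / typical_ip.CL_i, rel=0.03)
        assert 45.0 <= math.log(2) * typical_ip.V0_i / typical_ip.CL_i <= 47.0

    def test_half_life_shortens_at_saturating_amounts(self, typical_ip):
        # immediately after a 50 mg infusion Ac >> VL_A50: t1/2 ~ 9 h
        grid = np.arange(0.0, 12.1, 0.1)
        prof = simulate_individual(
            DosingRegimen.iv_infusions([50.0], [0.0], 1.0), typical_ip, grid=grid)
        sel = (grid >= 2) & (grid <= 6)
        slope = np.polyfit(grid[sel], np.log(prof.conc[sel]), 1)[0]
        assert math.log(2) / -slope == pytest.approx(9.0, abs=1.5)


class TestTypicalIvReference:
    def test_typical_subject_inside_published_bands(self, typical_ip,
                                                    iv_reference_regimen):
        times = np.array(sorted(IV_REFERENCE_RANGES))
        prof = simulate_individual(iv_reference_regimen, typical_ip,
                                   grid=np.concatenate([[0.0], times]))
        for t, c in zip(times, prof.conc[1:]):
            lo, hi = IV_REFERENCE_RANGES[t]
            assert lo <= c <= hi, f"typical conc {c:.0f} at {t} h outside band"

    def test_iv_profile_ignores_fed_status_and_absorption(self, theta,
                                                          iv_reference_regimen):
        grid = np.array([0.0, 1.0, 24.0, 72.0])
        fed = resolve_individual(theta, Covariates(fed=True))
        fasted = resolve_individual(theta, Covariates(fed=False))
        fast_gut = resolve_individual(theta.with_(Kgut=10.0, MTT=1.0),
                                      Covariates())
        ref = simulate_individual(iv_reference_regimen, fed, grid=grid).conc
        for other in (fasted, fast_gut):
            got = simulate_individual(iv_reference_regimen, other, grid=grid).conc
            assert np.allclose(got, ref, rtol=1e-9)


class TestSteadyState:
    def test_grid_refinement_stable(self, typical_ip):
        coarse = steady_state_metrics(RepeatingDose(10.0), typical_ip,
                                      points_per_interval=97)
        fine = steady_state_metrics(RepeatingDose(10.0), typical_ip,
                                    points_per_interval=193)
        assert fine.AUC_tau == pytest.approx(coarse.AUC_tau, rel=1e-3)

    def test_fed_reference_availability(self, typical_ip):
        m = steady_state_metrics(RepeatingDose(10.0, fed=True), typical_ip)
        assert 0.8 < m.F_tau < 1.0

    def test_nonconvergence_raises(self, typical_ip):
        with pytest.raises(RuntimeError):
            steady_state_metrics(RepeatingDose(10.0), typical_ip,
                                 tol=1e-9, max_intervals=16)

    def test_low_dose_accumulates_more_and_longer(self, typical_ip):
        """Smaller doses approach steady state more slowly and
        accumulate more (exposure-dependent half-life)."""
        days = {}
        acc = {}
        for dose in (1.5, 50.0):
            grid = np.arange(0.0, 60 * 24.0 + 1, 24.0)
            prof = simulate_individual(DosingRegimen.oral_qd(dose, 60),
                                       typical_ip, grid=grid)
            trough = prof.conc[1:]
            reached = trough >= 0.98 * trough[-1]
            days[dose] = int(np.argmax(reached)) + 1
            acc[dose] = trough[-1] / trough[0]
        assert days[1.5] > days[50.0]
        assert acc[1.5] > acc[50.0]


class TestDoseProportionality:
    def test_reference_normalisation_and_monotonicity(self, typical_ip):
        df = dose_proportionality_scan([1.5, 5.0, 10.0, 50.0], typical_ip)
        ratios = df.set_index("dose")["ratio_vs_reference"]
        assert ratios[10.0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(ratios.to_numpy()) > 0)
        assert ratios[1.5] >= 0.90
        assert ratios[50.0] <= 1.15

    def test_out_of_range_dose_rejected(self, typical_ip):
        with pytest.raises(ValueError):
            dose_proportionality_scan([0.5], typical_ip)


class TestPopulationSimulation:
    def test_zero_variability_equals_typical(self, theta, typical_ip,
                                             iv_reference_regimen):
        quiet = theta.with_(omega_CL=0.0, omega_V0=0.0, omega_MTT=0.0)
        grid = np.array([0.0, 1.0, 24.0, 72.0])
        res = simulate_population(PopulationSpec.fixed_adult(n=1),
                                  iv_reference_regimen, n=1, seed=3,
                                  theta=quiet, grid=grid)
        ref = simulate_individual(iv_reference_regimen, typical_ip, grid=grid)
        assert np.allclose(res.conc[0], ref.conc, rtol=1e-4)

    def test_seed_reproducibility(self, iv_reference_regimen):
        grid = np.array([0.0, 1.0, 24.0])
        kw = dict(n=5, grid=grid)
        a = simulate_population(PopulationSpec.fixed_adult(n=5),
                                iv_reference_regimen, seed=11, **kw)
        b = simulate_population(PopulationSpec.fixed_adult(n=5),
                                iv_reference_regimen, seed=11, **kw)
        c = simulate_population(PopulationSpec.fixed_adult(n=5),
                                iv_reference_regimen, seed=12, **kw)
        assert np.array_equal(a.conc, b.conc)
        assert not np.array_equal(a.conc, c.conc)

    def test_bands_collapse_without_variability(self, theta,
                                                iv_reference_regimen):
        quiet = theta.with_(omega_CL=0.0, omega_V0=0.0, omega_MTT=0.0)
        res = simulate_population(PopulationSpec.fixed_adult(n=25),
                                  iv_reference_regimen, n=25, seed=0,
                                  theta=quiet, grid=np.array([0.0, 1.0, 24.0]))
        bands = percentile_bands(res)
        assert np.allclose(bands["p5"], bands["p95"], rtol=1e-9)

    def test_relative_band_width_grows_with_time(self, iv_reference_regimen):
        res = simulate_population(PopulationSpec.fixed_adult(n=80),
                                  iv_reference_regimen, n=80, seed=4,
                                  grid=np.array([0.0, 1.0, 96.0]))
        bands = percentile_bands(res)
        rel = ((bands["p95"] - bands["p5"]) / bands["p50"]).to_numpy()
        assert rel[2] > rel[1]

    def test_minimum_subjects_for_bands(self, iv_reference_regimen):
        res = simulate_population(PopulationSpec.fixed_adult(n=5),
                                  iv_reference_regimen, n=5, seed=0,
                                  grid=np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            percentile_bands(res)
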