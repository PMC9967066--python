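"""Chamber mass-balance emission reconstruction and emission factors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import puffbox as pb
from puffbox.refdata import reported_ef


def brute_force_tp(times, conc, volume_cm3, beta, window):
    """Independent discrete mass-balance oracle: explicit python loop."""
    dt = times[1] - times[0]
    tp = 0.0
    for i in range(1, len(times)):
        if window.t_start_s + 1e-12 < times[i] <= window.t_stop_s + 1e-12:
            tp += volume_cm3 * (conc[i] - conc[i - 1] * np.exp(-beta * dt))
    return tp


def total_trace(times, totals, grid):
    """Wrap a total-concentration trace as a single-bin tuple input."""
    return (times, totals)


class TestTotalEmission:
    def test_single_step_beta_zero(self, static_chamber, grid):
        """beta=0: a 0 -> 100 #/cm^3 step in 6 m^3 emits 6e8 particles."""
        times = np.arange(0.0, 50.0, 10.0)
        totals = np.array([0.0, 100.0, 100.0, 100.0, 100.0])
        tp = pb.total_emission(
            (times, totals), static_chamber, 0.0, pb.EmissionWindow(0.0, 40.0)
        )
        assert tp == pytest.approx(6e8, rel=1e-12)

    def test_telescoping_identity_beta_zero(self, static_chamber, pod_run):
        """beta=0 collapses the sum to V_c (C(t_stop) - C(t_start))."""
        w = pb.EmissionWindow(0.0, float(pod_run.times[-1]))
        tp = pb.total_emission(pod_run, static_chamber, 0.0, w)
        expected = static_chamber.volume_cm3 * (pod_run.total()[-1] - pod_run.total()[0])
        assert tp == pytest.approx(expected, rel=1e-9)

    def test_constant_concentration_replenishment(self, static_chamber):
        """Constant C under loss beta implies a source replacing the loss."""
        beta, dt, n = 2e-4, 10.0, 120
        times = dt * np.arange(n + 1)
        totals = np.full(n + 1, 500.0)
        w = pb.EmissionWindow(0.0, float(times[-1]))
        tp = pb.total_emission((times, totals), static_chamber, beta, w)
        expected = static_chamber.volume_cm3 * 500.0 * (1 - np.exp(-beta * dt)) * n
        assert tp == pytest.approx(expected, rel=1e-12)
        oracle = brute_force_tp(times, totals, static_chamber.volume_cm3, beta, w)
        assert tp == pytest.approx(oracle, rel=1e-9)

    def test_matches_brute_force_oracle_on_simulation(self, static_chamber, pod_run, pod_schedule):
        w = pb.default_emission_window(pod_run, pod_schedule.puff_times_s)
        tp = pb.total_emission(pod_run, static_chamber, 1.34e-4, w)
        oracle = brute_force_tp(
            pod_run.times, pod_run.total(), static_chamber.volume_cm3, 1.34e-4, w
        )
        assert tp == pytest.approx(oracle, rel=1e-9)

    @pytest.mark.parametrize(
        "source_fn, schedule_fn, beta, n_puffs",
        [
            (pb.pod_source, lambda: pb.regular_schedule(20, 180.0, start_s=60.0), 1.34e-4, 20),
            (pb.mod_source, lambda: pb.regular_schedule(4, 3600.0, start_s=60.0), 2.20e-4, 4),
        ],
        ids=["pod-20-puffs", "mod-4-puffs"],
    )
    def test_recovers_known_per_puff_source(self, static_chamber, source_fn, schedule_fn, beta, n_puffs):
        """Simulation with known injection E recovers n_puffs*E within 1%."""
        schedule = schedule_fn()
        source = source_fn()
        series = pb.simulate_chamber(
            static_chamber, schedule, source, beta_dep_per_s=beta,
            dt_s=10.0, t_end_s=schedule.puff_times_s[-1] + 7200.0,
        )
        w = pb.default_emission_window(series, schedule.puff_times_s)
        tp = pb.total_emission(series, static_chamber, beta, w)
        assert tp == pytest.approx(n_puffs * source.number_per_puff, rel=0.01)

    def test_per_bin_additivity(self, static_chamber, mod_run, mod_schedule):
        """Summed per-bin TP equals TP on the total trace."""
        w = pb.default_emission_window(mod_run, mod_schedule.puff_times_s)
        per_bin = pb.total_emission(mod_run, static_chamber, 2.2e-4, w, per_bin=True)
        total = pb.total_emission(
            (mod_run.times, mod_run.total()), static_chamber, 2.2e-4, w
        )
        assert per_bin.sum() == pytest.approx(total, rel=1e-9)

    def test_decay_compensated_variant_bounds_reconstruct(self, static_chamber, pod_run, pod_schedule):
        """The alternative reading differs by exactly e^(beta dt) per interval."""
        w = pb.default_emission_window(pod_run, pod_schedule.puff_times_s)
        beta = 1.34e-4
        base = pb.total_emission(pod_run, static_chamber, beta, w)
        alt = pb.total_emission(pod_run, static_chamber, beta, w, variant="decay_compensated")
        assert alt == pytest.approx(base * np.exp(beta * pod_run.dt_s), rel=1e-9)
        assert alt > base

    def test_window_outside_series_rejected(self, static_chamber, pod_run):
        with pytest.raises(ValueError, match="window"):
            pb.total_emission(
                pod_run, static_chamber, 0.0,
                pb.EmissionWindow(0.0, float(pod_run.times[-1]) + 100.0),
            )

    def test_negative_beta_rejected(self, static_chamber, pod_run):
        with pytest.raises(ValueError, match="beta"):
            pb.total_emission(pod_run, static_chamber, -1e-5, pb.EmissionWindow(0.0, 100.0))


class TestEmissionFactor:
    def test_simple_division(self):
        res = pb.emission_factor(6e8, 20)
        assert res.ef_number_per_puff == pytest.approx(3e7, rel=1e-12)
        assert res.dilution_factor == 1.0

    def test_dilution_linearity(self):
        base = pb.emission_factor(1e10, 10, dilution_factor=1.0)
        doubled = pb.emission_factor(1e10, 10, dilution_factor=2.0)
        assert doubled.ef_number_per_puff == pytest.approx(
            2 * base.ef_number_per_puff, rel=1e-12
        )

    def test_zero_puffs_rejected(self):
        with pytest.raises(ValueError):
            pb.emission_factor(1e10, 0)

    def test_end_to_end_recovery_static_and_dynamic(self, static_chamber, dynamic_chamber):
        """simulate -> fit_decay -> total_emission -> EF recovers the source
        within 5% in both scenarios (noiseless, dt = 10 s)."""
        for chamber in (static_chamber, dynamic_chamber):
            schedule = pb.regular_schedule(20, 180.0, start_s=60.0)
            source = pb.pod_source()
            series = pb.simulate_chamber(
                chamber, schedule, source, beta_dep_per_s=1.34e-4,
                dt_s=10.0, t_end_s=schedule.puff_times_s[-1] + 7200.0,
            )
            fit = pb.fit_decay(series, pb.pick_decay_window(series, schedule))
            w = pb.default_emission_window(series, schedule.puff_times_s)
            tp = pb.total_emission(series, chamber, fit, w)
            res = pb.emission_factor(tp, 20, chamber.dilution_factor)
            truth = source.number_per_puff * chamber.dilution_factor
            assert res.ef_number_per_puff == pytest.approx(truth, rel=0.05)


class TestNumberToMass:
    def test_hundred_nm_spheres(self):
        """6e10 particles at 100 nm and 1 g/cm^3 weigh 31.4 ug."""
        grid = pb.SizeGrid(np.array([100.0 / 1.1, 100.0 * 1.1]))
        counts = np.array([6e10])
        # bin midpoint is exactly 100 nm by geometric symmetry
        assert grid.bin_mids[0] == pytest.approx(100.0, rel=1e-12)
        mass = pb.number_to_mass(counts, grid)
        assert mass == pytest.approx(6e10 * np.pi / 6 * (1e-5) ** 3 * 1e6, rel=1e-12)
        assert mass == pytest.approx(31.4, rel=0.001)

    def test_zero_particles(self, grid):
        assert pb.number_to_mass(np.zeros(grid.n_bins), grid) == 0.0

    @given(
        d_nm=st.floats(10.0, 5000.0),
        rho=st.floats(0.5, 2.0),
        count=st.floats(1.0, 1e12),
    )
    @settings(derandomize=True, max_examples=50)
    def test_homogeneity_in_diameter_density_count(self, d_nm, rho, count):
        """Mass scales cubically in diameter, linearly in density and count."""

        def mass(d, r, c):
            g = pb.SizeGrid(np.array([d / 1.05, d * 1.05]))
            return pb.number_to_mass(np.array([c]), g, pb.MassConversionSpec(r))

        base = mass(d_nm, rho, count)
        assert mass(2 * d_nm, rho, count) == pytest.approx(8 * base, rel=1e-9)
        assert mass(d_nm, 2 * rho, count) == pytest.approx(2 * base, rel=1e-9)
        assert mass(d_nm, rho, 2 * count) == pytest.approx(2 * base, rel=1e-9)

    def test_grid_mismatch_rejected(self, grid):
        with pytest.raises(ValueError, match="match"):
            pb.number_to_mass(np.zeros(grid.n_bins + 1), grid)


class TestScenarioRatio:
    def test_identity_and_metric_mismatch(self):
        assert pb.scenario_ratio(5.0, 5.0) == 1.0
        with pytest.raises(ValueError, match="metric"):
            pb.scenario_ratio(1.0, 2.0, metric_a="number", metric_b="mass_ug")

    def test_reported_ventilation_multipliers(self):
        """Reported per-device EFs give the stated scenario multipliers."""
        pod_n = pb.scenario_ratio(
            reported_ef("unventilated", "pod", "number_per_puff"),
            reported_ef("ventilated", "pod", "number_per_puff"),
            rounding="nearest_int",
        )
        mod_m = pb.scenario_ratio(
            reported_ef("unventilated", "mod", "mass_ug_per_puff"),
            reported_ef("ventilated", "mod", "mass_ug_per_puff"),
            rounding="nearest_int",
        )
        assert pod_n == 9
        assert mod_m == 14
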