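"""Chamber forward model: conservation, analytic decay, instrument model."""

import numpy as np
import pytest

import puffbox as pb
from puffbox.chamber import OPS_CEILING_PER_CM3


def one_puff_series(scenario, beta_dep=0.0, dt_s=100.0, t_end=2400.0):
    schedule = pb.PuffSchedule(np.array([0.0]))
    source = pb.pod_source(1e10)
    return pb.simulate_chamber(
        scenario, schedule, source, beta_dep_per_s=beta_dep, dt_s=dt_s, t_end_s=t_end
    )


class TestSimulateChamber:
    def test_empty_schedule_stays_zero(self, static_chamber):
        series = pb.simulate_chamber(
            static_chamber, pb.PuffSchedule(np.array([])), pb.pod_source(), t_end_s=600.0
        )
        assert np.all(series.conc == 0)

    def test_single_puff_conserved_without_losses(self, static_chamber):
        """One puff with no losses steps to N/V_c and stays constant."""
        series = one_puff_series(static_chamber)
        total = series.total() * static_chamber.volume_cm3
        np.testing.assert_allclose(total, 1e10, rtol=1e-9)

    def test_ventilated_decay_matches_closed_form(self):
        """At 3/h ACH and no deposition, C(t) = C(0+) e^(-t/1200 s)."""
        scenario = pb.ChamberScenario(ach=3.0, label="dynamic")
        series = one_puff_series(scenario)
        c0 = series.total()[0]
        expected = c0 * np.exp(-series.times / 1200.0)
        np.testing.assert_allclose(series.total(), expected, rtol=1e-9)
        at_tau = series.total()[series.times == 1200.0][0]
        np.testing.assert_allclose(at_tau, c0 / np.e, rtol=1e-9)

    def test_number_conserved_across_many_puffs(self, static_chamber):
        """With zero losses, airborne number equals cumulative injection."""
        schedule = pb.regular_schedule(5, 300.0, start_s=100.0)
        series = pb.simulate_chamber(
            static_chamber, schedule, pb.pod_source(2e9), dt_s=50.0, t_end_s=2000.0
        )
        injected = 2e9 * np.searchsorted(
            schedule.puff_times_s, series.times, side="right"
        )
        np.testing.assert_allclose(
            series.total() * static_chamber.volume_cm3, injected, rtol=1e-9
        )

    def test_interpuff_decay_matches_exponential_oracle(self, pod_run, pod_schedule):
        """Between puffs every sample lies on the analytic e^(-kt) curve."""
        k = 1.34e-4  # static: no ventilation, deposition only
        total = pod_run.total()
        t = pod_run.times
        last_puff = pod_schedule.puff_times_s[-1]
        tail = t >= last_puff
        c_ref = total[tail][0]
        t_ref = t[tail][0]
        np.testing.assert_allclose(
            total[tail], c_ref * np.exp(-k * (t[tail] - t_ref)), rtol=1e-9
        )

    def test_seed_determinism_and_noise_variation(self, static_chamber):
        schedule = pb.regular_schedule(3, 200.0, start_s=50.0)
        kwargs = dict(
            beta_dep_per_s=1e-4, dt_s=20.0, t_end_s=1000.0, noise=pb.NoiseSpec(gsd=1.05)
        )
        a = pb.simulate_chamber(static_chamber, schedule, pb.pod_source(), seed=42, **kwargs)
        b = pb.simulate_chamber(static_chamber, schedule, pb.pod_source(), seed=42, **kwargs)
        c = pb.simulate_chamber(static_chamber, schedule, pb.pod_source(), seed=43, **kwargs)
        assert np.array_equal(a.conc, b.conc)
        assert not np.array_equal(a.conc, c.conc)

    def test_staircase_accumulation(self, pod_run, pod_schedule):
        """Noiseless static run: post-puff concentration climbs puff over puff."""
        idx = np.searchsorted(pod_run.times, pod_schedule.puff_times_s)
        post_puff = pod_run.total()[idx]
        assert np.all(np.diff(post_puff) > 0)

    def test_per_bin_deposition_vector(self, static_chamber, grid):
        """A per-bin loss vector makes large bins decay faster."""
        beta = np.where(grid.bin_mids > 300.0, 5e-4, 1e-4)
        schedule = pb.PuffSchedule(np.array([0.0]))
        series = pb.simulate_chamber(
            static_chamber, schedule, pb.mod_source(), beta_dep_per_s=beta,
            dt_s=100.0, t_end_s=3600.0, grid=grid,
        )
        small = series.conc[:, grid.bin_mids <= 300.0].sum(axis=1)
        large = series.conc[:, grid.bin_mids > 300.0].sum(axis=1)
        assert large[-1] / large[0] < small[-1] / small[0]

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(beta_dep_per_s=-1e-4), "beta_dep"),
            (dict(dt_s=0.0), "dt_s"),
            (dict(t_end_s=100.0), "horizon"),
        ],
    )
    def test_invalid_inputs_rejected(self, static_chamber, kwargs, match):
        schedule = pb.regular_schedule(2, 200.0, start_s=50.0)
        base = dict(dt_s=10.0, t_end_s=1000.0)
        base.update(kwargs)
        with pytest.raises(ValueError, match=match):
            pb.simulate_chamber(static_chamber, schedule, pb.pod_source(), **base)


class TestApplyInstrument:
    def test_below_ceiling_untouched(self, pod_run):
        out = pb.apply_instrument(pod_run, ceiling_per_cm3=np.inf)
        assert np.array_equal(out.conc, pod_run.conc)
        assert not out.saturated.any()

    def test_clipping_flags_at_detection_limit(self, grid):
        conc = np.full((3, grid.n_bins), 10.0)
        conc[1, 0] = 5000.0
        series = pb.ConcSeries(np.array([0.0, 1.0, 2.0]), grid, conc)
        out = pb.apply_instrument(series, ceiling_per_cm3=OPS_CEILING_PER_CM3)
        assert out.conc[1, 0] == 3000.0
        assert out.saturated[1, 0]
        assert out.saturated.sum() == 1
        assert np.array_equal(np.delete(out.conc, 1 * grid.n_bins), np.delete(conc, 1 * grid.n_bins))

    def test_rejects_nonpositive_ceiling(self, pod_run):
        with pytest.raises(ValueError):
            pb.apply_instrument(pod_run, ceiling_per_cm3=0.0)


class TestStitchGrids:
    @staticmethod
    def _pair(times=None):
        times = times if times is not None else np.arange(0.0, 50.0, 10.0)
        smps = pb.default_smps_grid(8)
        ops = pb.default_ops_grid(4)
        a = pb.ConcSeries(times, smps, np.ones((times.size, 8)))
        b = pb.ConcSeries(times, ops, 2 * np.ones((times.size, 4)))
        return a, b

    def test_concatenates_bins_and_conserves_total(self):
        a, b = self._pair()
        out = pb.stitch_grids(a, b)
        assert out.grid.n_bins == 12
        assert out.grid.instrument_label == "composite"
        np.testing.assert_allclose(out.total(), a.total() + b.total())

    def test_misaligned_timestamps_rejected(self):
        a, _ = self._pair()
        _, b = self._pair(times=np.arange(5.0, 55.0, 10.0))
        with pytest.raises(ValueError, match="timestamps"):
            pb.stitch_grids(a, b)

    def test_gapped_grids_rejected(self):
        times = np.arange(0.0, 30.0, 10.0)
        a = pb.ConcSeries(times, pb.default_smps_grid(4), np.ones((3, 4)))
        gapped = pb.ConcSeries(times, pb.log_grid(400, 10000, 4), np.ones((3, 4)))
        with pytest.raises(ValueError, match="abut"):
            pb.stitch_grids(a, gapped)
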