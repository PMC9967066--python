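import numpy as np
import pytest

import puffbox as pb


@pytest.fixture(scope="session")
def grid():
    return pb.composite_grid()


@pytest.fixture(scope="session")
def static_chamber():
    return pb.ChamberScenario(volume_Vc_m3=6.0, ach=0.0, label="static")


@pytest.fixture(scope="session")
def dynamic_chamber():
    return pb.ChamberScenario(
        volume_Vc_m3=6.0,
        ach=3.0,
        label="dynamic",
        dilution_flow_eags_lpm=2.5,
        dilution_flow_chamber_lpm=1.25,
    )


@pytest.fixture(scope="session")
def pod_schedule():
    """20 puffs every 3 min, starting at 60 s (small-puff-number static run)."""
    return pb.regular_schedule(20, 180.0, start_s=60.0)


@pytest.fixture(scope="session")
def mod_schedule():
    """4 puffs once per hour (large-particle device static run)."""
    return pb.regular_schedule(4, 3600.0, start_s=60.0)


@pytest.fixture(scope="session")
def pod_run(static_chamber, pod_schedule):
    """Noiseless static pod simulation with a 2 h post-vaping decay tail."""
    series = pb.simulate_chamber(
        static_chamber,
        pod_schedule,
        pb.pod_source(),
        beta_dep_per_s=1.34e-4,
        dt_s=10.0,
        t_end_s=pod_schedule.puff_times_s[-1] + 7200.0,
    )
    return series


@pytest.fixture(scope="session")
def mod_run(static_chamber, mod_schedule):
    series = pb.simulate_chamber(
        static_chamber,
        mod_schedule,
        pb.mod_source(),
        beta_dep_per_s=2.20e-4,
        dt_s=10.0,
        t_end_s=mod_schedule.puff_times_s[-1] + 7200.0,
    )
    return series


@pytest.fixture
def sample_config(tmp_path):
    """A minimal static-pod pipeline config on disk."""
    cfg = """
seed: 7
scenario:
  volume_Vc_m3: 6.0
  ach: 0.0
  label: static
schedule:
  n_puffs: 20
  interval_s: 180.0
  start_s: 60.0
  profile: {volume_mL: 55.0, duration_s: 3.0}
source:
  number_per_puff: 4.92e10
  modes:
    - {weight: 1.0, gmd_nm: 100.0, gsd: 1.7}
simulation:
  beta_dep_per_s: 1.34e-4
  dt_s: 10.0
  t_end_s: 10680.0
  noise: {gsd: 1.02, poisson: false}
device:
  device_type: pod
"""
    path = tmp_path / "config.yaml"
    path.write_text(cfg)
    return path
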