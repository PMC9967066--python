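"""Canonical synthetic vaping-experiment setups.

Four standard runs pair the two device types with the two ventilation
scenarios the chamber supports:

* ``pod_static``: 20 puffs (5 per hour-long group, 3 min apart) into the
  static chamber — the small-puff-number characterization run.
* ``mod_static``: 4 puffs one hour apart, keeping the optical sizer
  below its detection ceiling for the large-mode device.
* ``pod_dynamic`` / ``mod_dynamic``: 20 puffs at 3 min spacing under
  3 1/h ventilation with a 2x generator-to-chamber dilution split.

Per-puff source strengths default to the reported device-average
emission factors so simulated concentration levels are realistic;
deposition rates default to the reported per-device loss coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chamber import ChamberScenario, NoiseSpec, SourceSpec, mod_source, pod_source
from .puffs import PuffSchedule, regular_schedule
from .refdata import REPORTED_BETA_PER_S


@dataclass(frozen=True)
class StudyRun:
    """One synthetic vaping experiment: who puffs, where, how often."""

    name: str
    device: str
    scenario: ChamberScenario
    schedule: PuffSchedule
    source: SourceSpec
    beta_dep_per_s: float
    dt_s: float = 10.0

    @property
    def t_end_s(self) -> float:
        """Horizon: schedule end plus a 2 h decay tail for the loss fit."""
        return float(self.schedule.puff_times_s[-1]) + 7200.0


def _grouped_pod_schedule() -> PuffSchedule:
    """20 puffs in 4 hourly groups of 5, 3 min apart within a group."""
    times = np.concatenate(
        [60.0 + 3600.0 * g + 180.0 * np.arange(5) for g in range(4)]
    )
    return PuffSchedule(times)


def static_scenario() -> ChamberScenario:
    return ChamberScenario(volume_Vc_m3=6.0, ach=0.0, label="static")


def dynamic_scenario() -> ChamberScenario:
    return ChamberScenario(
        volume_Vc_m3=6.0,
        ach=3.0,
        label="dynamic",
        dilution_flow_eags_lpm=2.5,
        dilution_flow_chamber_lpm=1.25,
    )


def study_runs() -> dict[str, StudyRun]:
    return {
        "pod_static": StudyRun(
            "pod_static", "pod", static_scenario(), _grouped_pod_schedule(),
            pod_source(), REPORTED_BETA_PER_S["pod"],
        ),
        "mod_static": StudyRun(
            "mod_static", "mod", static_scenario(),
            regular_schedule(4, 3600.0, start_s=60.0),
            mod_source(), REPORTED_BETA_PER_S["mod"],
        ),
        "pod_dynamic": StudyRun(
            "pod_dynamic", "pod", dynamic_scenario(),
            regular_schedule(20, 180.0, start_s=60.0),
            pod_source(), REPORTED_BETA_PER_S["pod"],
        ),
        "mod_dynamic": StudyRun(
            "mod_dynamic", "mod", dynamic_scenario(),
            regular_schedule(20, 180.0, start_s=60.0),
            mod_source(), REPORTED_BETA_PER_S["mod"],
        ),
    }


DEFAULT_NOISE = NoiseSpec(gsd=1.05, poisson=False)
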