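"""Reconstruct emission factors and compare ventilation scenarios.

Applies the discrete chamber mass balance to each simulated run using
its fitted loss coefficient, converts per-bin number emissions to mass
(unit-density spheres), and divides by puff count (and multiplies by
the dilution factor for the dynamic chamber) to obtain per-puff
emission factors.  Also computes the scenario multipliers and mg/puff
conversions from the reported device-average EFs, which are inputs to
this analysis.  Writes results/emission_factors.csv and
results/reported_ratios.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from puffbox import (
    ConcSeries,
    default_emission_window,
    emission_factor,
    fit_decay,
    number_to_mass,
    pick_decay_window,
    scenario_ratio,
    total_emission,
)
from puffbox.refdata import reported_ef
from puffbox.studies import study_runs


def compute_efs(sim_dir: Path) -> pd.DataFrame:
    rows = []
    for name, run in sorted(study_runs().items()):
        series = ConcSeries.from_csv(
            sim_dir / f"{name}.csv", sim_dir / f"{name}_saturation.csv"
        )
        fit = fit_decay(series, pick_decay_window(series, run.schedule, lag_s=120.0))
        window = default_emission_window(series, run.schedule.puff_times_s, lag_s=120.0)
        per_bin = total_emission(
            series, run.scenario, max(fit.beta_per_s, 0.0), window, per_bin=True
        )
        tp_mass = number_to_mass(np.clip(per_bin, 0, None), series.grid)
        res = emission_factor(
            float(per_bin.sum()), run.schedule.n_puffs,
            dilution_factor=run.scenario.dilution_factor,
            beta_used_per_s=fit.beta_per_s, scenario_label=run.scenario.label,
            tp_mass_ug=tp_mass,
        )
        truth = run.source.number_per_puff * run.scenario.dilution_factor
        rows.append(
            {
                "run": name,
                "device": run.device,
                "scenario": run.scenario.label,
                "ef_number_per_puff": res.ef_number_per_puff,
                "source_number_per_puff": truth,
                "number_rel_error": res.ef_number_per_puff / truth - 1.0,
                "ef_mass_ug_per_puff": res.ef_mass_ug_per_puff,
                "dilution_factor": res.dilution_factor,
                "beta_per_s": res.beta_used_per_s,
            }
        )
        print(
            f"{name}: EF_N = {res.ef_number_per_puff:.3e} #/puff "
            f"(source {truth:.3e}, {100 * rows[-1]['number_rel_error']:+.1f}%), "
            f"EF_M = {res.ef_mass_ug_per_puff:.3g} ug/puff"
        )
    return pd.DataFrame(rows)


def reported_ratios() -> pd.DataFrame:
    """Scenario multipliers and mg/puff values from the reported EFs."""
    rows = [
        {
            "quantity": "pod_number_unventilated_over_ventilated",
            "value": scenario_ratio(
                reported_ef("unventilated", "pod", "number_per_puff"),
                reported_ef("ventilated", "pod", "number_per_puff"),
                rounding="nearest_int",
            ),
        },
        {
            "quantity": "mod_number_unventilated_over_ventilated",
            "value": scenario_ratio(
                reported_ef("unventilated", "mod", "number_per_puff"),
                reported_ef("ventilated", "mod", "number_per_puff"),
                rounding="nearest_int",
            ),
        },
        {
            "quantity": "mod_mass_unventilated_over_ventilated",
            "value": scenario_ratio(
                reported_ef("unventilated", "mod", "mass_ug_per_puff"),
                reported_ef("ventilated", "mod", "mass_ug_per_puff"),
                rounding="nearest_int",
            ),
        },
        {
            "quantity": "pod_mass_ventilated_over_unventilated",
            "value": scenario_ratio(
                reported_ef("ventilated", "pod", "mass_ug_per_puff"),
                reported_ef("unventilated", "pod", "mass_ug_per_puff"),
                rounding="nearest_int",
            ),
        },
        {
            "quantity": "pod_unventilated_mass_ef_mg_per_puff",
            "value": reported_ef("unventilated", "pod", "mass_ug_per_puff") / 1000.0,
        },
        {
            "quantity": "mod_unventilated_mass_ef_mg_per_puff",
            "value": reported_ef("unventilated", "mod", "mass_ug_per_puff") / 1000.0,
        },
    ]
    df = pd.DataFrame(rows)
    for row in rows:
        print(f"{row['quantity']}: {row['value']:g}")
    return df


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    compute_efs(args.sim_dir).to_csv(
        args.out_dir / "emission_factors.csv", index=False, float_format="%.8g"
    )
    reported_ratios().to_csv(
        args.out_dir / "reported_ratios.csv", index=False, float_format="%.8g"
    )
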