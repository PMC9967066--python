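"""Estimate per-run loss coefficients from post-vaping decay.

Reads the simulated series from step 01, selects the decay window
(last puff + 120 s mixing lag to the end, truncated at saturation) and
fits log-linear OLS.  In the static chamber the fitted beta is pure
deposition; in the dynamic chamber it absorbs ventilation (3/3600 1/s)
plus deposition.  Writes results/loss_coefficients.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from puffbox import ConcSeries, fit_decay, pick_decay_window
from puffbox.studies import study_runs


def fit_all(sim_dir: Path, out_csv: Path) -> pd.DataFrame:
    rows = []
    for name, run in sorted(study_runs().items()):
        series = ConcSeries.from_csv(
            sim_dir / f"{name}.csv", sim_dir / f"{name}_saturation.csv"
        )
        window = pick_decay_window(series, run.schedule, lag_s=120.0)
        fit = fit_decay(series, window)
        expected = run.beta_dep_per_s + run.scenario.lambda_per_s
        rows.append(
            {
                "run": name,
                "device": run.device,
                "scenario": run.scenario.label,
                "beta_per_s": fit.beta_per_s,
                "expected_beta_per_s": expected,
                "rel_error": fit.beta_per_s / expected - 1.0,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
            }
        )
        print(
            f"{name}: beta = {fit.beta_per_s:.3e} 1/s "
            f"(configured {expected:.3e}, r^2 = {fit.r_squared:.4f})"
        )
    df = pd.DataFrame(rows)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_csv, index=False, float_format="%.8g")
    return df


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/loss_coefficients.csv"))
    args = ap.parse_args()
    fit_all(args.sim_dir, args.out)
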