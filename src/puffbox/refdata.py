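"""Reported device-average emission factors used as analysis inputs.

The chamber study this package models reports per-puff emission factors
(mean +/- standard error over replicates) for a pod-type and a mod-type
device under an unventilated (static, n=4) and a ventilated (dynamic,
n=3) chamber scenario.  These printed values are the inputs to the
scenario-ratio and unit-conversion analyses; they are not produced by
this package's simulations.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # scenario, device, metric, ef_mean, ef_se, n_replicates
    ("unventilated", "pod", "number_per_puff", 4.92e10, 0.70e10, 4),
    ("unventilated", "mod", "number_per_puff", 1.72e10, 0.08e10, 4),
    ("unventilated", "pod", "mass_ug_per_puff", 2.58e2, 0.60e2, 4),
    ("unventilated", "mod", "mass_ug_per_puff", 1.50e4, 0.06e4, 4),
    ("ventilated", "pod", "number_per_puff", 5.54e9, 2.11e9, 3),
    ("ventilated", "mod", "number_per_puff", 5.00e9, 1.91e9, 3),
    ("ventilated", "pod", "mass_ug_per_puff", 1.71e3, 1.00e3, 3),
    ("ventilated", "mod", "mass_ug_per_puff", 1.09e3, 0.64e3, 3),
]

# Reported average loss coefficients (1/s) from post-vaping decay.
REPORTED_BETA_PER_S = {"mod": 2.20e-4, "pod": 1.34e-4}

# Reported lognormal mode locations (nm): pod unimodal ~100 nm; mod
# bimodal with an Aitken and an accumulation mode.
REPORTED_MODE_GMD_NM = {"pod": (100.0,), "mod": (58.2, 794.0)}


def reported_emission_factors() -> pd.DataFrame:
    """Reported EFs as a tidy frame (one row per scenario/device/metric)."""
    return pd.DataFrame(
        _ROWS,
        columns=["scenario", "device", "metric", "ef_mean", "ef_se", "n_replicates"],
    )


def reported_ef(scenario: str, device: str, metric: str) -> float:
    """Look up one reported mean EF value."""
    df = reported_emission_factors()
    sel = df[
        (df.scenario == scenario) & (df.device == device) & (df.metric == metric)
    ]
    if sel.empty:
        raise KeyError(f"no reported EF for ({scenario}, {device}, {metric})")
    return float(sel.ef_mean.iloc[0])
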