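# Methods

## The measurement problem

Machine-vaping a pod- or mod-type e-cigarette into a well-mixed
exposure chamber and watching size-resolved particle concentrations
rise and decay lets one invert the chamber record into what the device
actually emitted: total particles per experiment (TP), per-puff
emission factors (EF) in number and mass, and the lognormal structure
of the emitted size distribution. This package implements that
inversion, plus the forward chamber model used to generate synthetic
instrument data for validating it.

## Chamber box model

Each diameter bin `i` obeys the single-zone mass balance

    dC_i/dt = S_i(t)/V_c − (λ + β_dep,i) · C_i

with `C_i` the number concentration (#/cm³), `V_c` the chamber volume
(6 m³ by default, converted to cm³ internally), `λ = ACH/3600` the
ventilation rate (1/s), and `β_dep,i` a first-order deposition rate.
A puff is injected as an instantaneous well-mixed impulse `E_i/V_c`:
the 3 s puff duration and the generator's 1 L pre-mixing volume are
orders of magnitude below chamber time scales (minutes to hours), so
between puffs every bin is a pure exponential and the solution is
analytic per interval — no ODE stepping error enters the simulator.

Instrument emulation: bins above 300 nm (the optical-sizer range) are
clipped at a detection ceiling of 3000 #/cm³ and flagged. Noise is
multiplicative lognormal (default geometric SD 1.05, a typical
scan-to-scan repeatability for sizing instruments), with optional
Poisson counting noise; noise is applied to the deterministic solution
before clipping. Default grids are 32 log-spaced bins over 7–300 nm
(mobility sizer) and 16 over 0.3–10 µm (optical sizer), abutting at
300 nm so the composite grid concatenates without overlap.

What the generator does *not* emulate: coagulation, condensation and
hygroscopic growth. Real chamber data show the geometric mean diameter
drifting upward as small particles accumulate; the simulator's GMD is
constant between puffs. Passing recovery tests therefore demonstrate
estimator correctness under first-order dynamics, not robustness to
aerosol microphysics.

## Loss-coefficient estimation

After the last puff the total concentration decays as
`C(t) = C₀ e^{−βt}` where the empirical `β` lumps ventilation and
deposition (no attempt is made to separate them — the estimate is
operational, matching how emission-testing protocols use it). `β` is
minus the OLS slope of `ln C` on `t`; for a clean exponential this is
exact, and a nonlinear least-squares variant is available behind a
flag for traces where the log transform would bias the fit. `β`
carries units of 1/s: a first-order loss coefficient must be an
inverse time for the mass balance to be dimensionally consistent.

The default decay window runs from the last puff plus a 120 s mixing
lag to the end of the series, truncated before the first saturated
scan. Negative estimates (growing concentration) are retained but
flagged non-physical rather than silently clamped.

## Emission reconstruction

Over one sampling interval `Δt`, the concentration carried over from
the previous sample is `C(t−Δt)·e^{−βΔt}`; any excess must have been
emitted:

    TP = Σ_i V_c · ( C(t_i) − C(t_{i−1}) · e^{−βΔt} )

summed over intervals inside the emission window (default: one sample
before the first puff to the last puff plus the mixing lag). With
`β = 0` the sum telescopes to `V_c·(C(t_stop) − C(t_start))`, which is
used as an identity test. An alternative estimator with an extra
`e^{−βΔt}` divisor per interval is provided behind
`variant="decay_compensated"`; the two differ by the factor `e^{βΔt}`
(≈ 1.001 at β ≈ 1e−4/s, Δt = 10 s) and the reconstruction form is the
default because it telescopes exactly and recovers known sources to
machine precision in simulation. Negative interval increments are
summed as-is by default (unbiased under symmetric noise); a
clip-at-zero mode exists.

The emission factor is `EF = dilution_factor · TP / n_puffs`. The
dilution factor — generator inflow over chamber inflow — rescales
chamber-derived emissions to generator output when part of the output
is diverted to other sampling; it defaults to 1 (static chamber) and
applies identically to number and mass, being a flow ratio.

Mass conversion assumes spherical particles of density 1 g/cm³
(PG/VG droplets are close to unit density): per-bin mass is
`N_i·(π/6)d_i³ρ` at the geometric bin midpoint, reported in µg.

## Size-distribution deconvolution

Distributions are expressed as `dN/dlogDp = N_i / log₁₀(d_{i+1}/d_i)`.
Moment GMD/GSD use bin-midpoint log-diameter moments. The mixture fit
minimizes least squares of a 1- or 2-mode lognormal model against
`dN/dlogDp` at bin midpoints, in linear concentration space (matching
how such fits are judged visually); bounds keep GMDs within a factor
of two of the grid and GSDs in [1.01, 4].

Initialization is deterministic: moments for one mode; for two modes,
a split at the deepest internal minimum of the 3-point-smoothed curve
with quantile fallback, then per-side moments. Automatic mode-count
selection fits both models and accepts the second mode only on very
strong evidence — ΔBIC ≥ 10 (the Kass–Raftery cutoff) — and only when
the fitted modes are ≥ 0.25 decades apart with the minor mode holding
≥ 2% of the number. Without the resolution requirements, a second
lognormal acts as a refinement term for discretization error and BIC
alone over-selects it. Non-convergence is reported in the result
object, never silently.

## Synthetic study conditions

The canonical runs (`puffbox.studies`) mirror the characterization
experiments the package is built around: a 6 m³ chamber; static
(0 ACH) runs with 20 pod puffs (4 hourly groups of 5, 3 min apart) or
4 mod puffs an hour apart; dynamic (3 1/h ACH) runs with 20 puffs at
3 min spacing and a 2× dilution split. Sources are the reported
device modes — pod: one mode at 100 nm (GSD 1.7); mod: Aitken 58.2 nm
plus accumulation 794 nm (GSD 1.6 each, number split 97/3 so number is
Aitken-dominated and mass accumulation-dominated, the usual structure
for sub-ohm devices). Per-puff number strengths default to the
reported device-average EFs (4.92×10¹⁰ pod, 1.72×10¹⁰ mod) and
deposition rates to the reported loss coefficients (1.34×10⁻⁴ and
2.20×10⁻⁴ 1/s), so simulated traces sit at realistic concentrations.
Simulations sample at Δt = 10 s with a 2 h decay tail — large enough
for sub-percent EF recovery, small enough that the full analysis chain
runs in seconds.

The simulated absolute *mass* EFs do not reproduce the reported mass
EFs: mass depends on the full upper tail of the true distribution,
which the two-mode number model with a truncated 10 µm grid does not
constrain. Reported-EF arithmetic (scenario ratios, unit conversions)
therefore uses the reported values themselves as inputs
(`puffbox.refdata`), not simulation output.

## Statistics

Replicate = one vaping experiment. Groups are summarized as mean ±
standard error (`sd/√n`; flagged undefined at n = 1). Two-group
comparison is a two-sided t-test at α = 0.05; Welch's
unequal-variance form is the default (variances differ strongly
across device types), Student's pooled form by flag; tests are
unpaired. Zero-variance groups with different means are reported as
degenerate with p = 0. A 1000-replicate null simulation calibrates
the observed type-I error to 3–7% at α = 0.05.

## Known limitations

* First-order, size-independent losses by default (a per-bin vector is
  accepted); no deposition theory, no coagulation/condensation, so GMD
  drift and number-loss-by-coagulation are outside the model.
* The power-ageing analysis is exercised on synthetic traces only; the
  per-fraction power/EF correlation has no published raw data to
  validate against.
* The optical sizer's optical-to-geometric diameter mapping is not
  modelled; the ceiling is the only instrument artefact emulated.
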