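# Methods

## The Power Consumption Index

A pacemaker battery is characterised by its usable capacity to the elective
replacement indicator, C (ampere-hours), and the device by its total average
current drain I (microamperes). The Power Consumption Index is the
capacity-normalised hourly consumption,

    PCI = t · I / C,   t = 1 h,

numerically I[µA] / C[Ah] under these units. Longevity follows as the
reciprocal scaled to years:

    L = 10⁶ / (PCI · 8760).

The year is taken as exactly 365 × 24 = 8760 hours; no leap-year correction.
All internal arithmetic is double precision; display rounding is one decimal
year for longevities and two decimal µA for currents.

## Current decomposition

`total = background + Σ_chambers pacing + Σ options`, enforced as an
invariant of `CurrentBreakdown` to 1e-9 µA.

**Background current** is device housekeeping (sensing, logic, standby
telemetry) and is taken from the device registry. Where both a
manual-reported and a regression-modelled value exist, the modelled value is
the working default and the reported one is retained as metadata, because
the modelled value is the one consistent with the rest of the energy budget.

**Pacing current** uses an Ohmic delivery model with a discrete charge-pump
converter. The lead-side charge per pulse is Q = V·t_pulse/R (µC for V in
volts, t in ms, R in Ω). The pump ratio m is the smallest available ratio
with m·V_battery ≥ V_pulse, from the default set {0.5, 1, 1.5, 2, 3}
(fractional doubler/tripler topologies; manufacturers do not publish their
ratio sets, so this is an engineering default, overridable per device). The
battery-side channel current is

    I_ch = Q · (rate/60) · pacing_fraction · m   [µA].

At the reference settings (60 bpm, 0.4 ms, 500 Ω, 100 % pacing) this gives
2.0 µA at 2.5 V output (m = 1 for 2.8–3.25 V batteries) and 4.2 µA at 3.5 V
(m = 1.5) — inside the published cross-device bands 1.98 ± 0.12 µA and
4.37 ± 0.24 µA. No additional conversion-efficiency factor is applied; the
regression slope in the inference module absorbs any such factor when real
tables are fitted.

The model is linear in rate, pulse width and pacing fraction, inversely
proportional to impedance, and piecewise in amplitude with jumps only at
pump-ratio boundaries. Multipoint pacing (MPP) delivers two left-ventricular
pulses per cycle and exactly doubles the LV channel current.

**Option currents** are stored per device as (low, mid, high) triples; the
midpoint is the arithmetic centre of the published range and is the default
working value (`level="low"/"high"` select the ends). Conventions:

* RF and Bluetooth remote monitoring scale linearly with transmissions per
  year, normalised to the 2/yr baseline at which table values are quoted;
  daily fixed-schedule telemetry (1.75 µA) ignores the count.
* Daily capture management costs nothing; beat-to-beat capture management
  costs a fixed 1 µA. Both apply the managed-output amplitude (default
  target 1 V) to every channel when active — the benefit side of the
  algorithm. The breakeven therefore sits near a 60 % pacing burden at
  2.5 V programmed output, and at low burdens once the programmed output
  exceeds 2.5 V.
* Ventricular-pacing-avoidance algorithms act purely through the pacing
  fraction, at no intrinsic current.
* Standard electrogram storage is free for most manufacturers (embedded in
  background); one manufacturer's devices carry explicit standard and
  pre-arrhythmia storage costs.
* The leadless dual-chamber backgrounds include the inter-capsule
  communication share; its published range is stored for reference and not
  re-added.

Chamber composition by category: SR and leadless-V pace the right ventricle
only; DR adds an independent atrial channel; CRT-P paces A + RV + LV with
MPP applying to LV only; leadless-A is atrial only. Profiles whose channel
set does not match the device category are rejected.

## Inference from manual longevity tables

Each manual row (settings, declared longevity L) implies a total current
I = 10⁶·C/(L·8760). The background current is the intercept of an ordinary
least-squares regression of implied current on the model's per-channel
pacing-current features (charge × rate × fraction × pump ratio, expected
slope 1). OLS runs on the *current* scale because the physics is additive
there; fit quality is additionally reported in longevity space as the mean
and standard deviation of (modelled/declared − 1), the scale on which
manuals are read. The OLS itself is delegated to statsmodels.

Design handling: fewer than two rows, or a rank-deficient design (e.g. no
pacing variation), raises an inference error recommending more varied rows;
an explicitly empty design degrades to the mean implied current. Negative
fitted intercepts are reported and flagged, never clipped — a silently
clipped value would hide a mis-specified table.

Option currents are recovered exactly by reciprocal differencing,
ΔI = 10⁶·C·(1/L_on − 1/L_off)/8760, the algebraic inverse of adding a
constant current.

## Synthetic manual tables

The true manufacturer tables are not redistributable, so the fixtures
generate stand-ins from known currents via the energy model and round the
declared longevities to 0.1 years (manual precision). The fixed 18-row
design crosses amplitudes {1.5, 2.5, 3.5} V × fractions {0.15, 0.5, 1.0} ×
impedances {500, 900} Ω; the randomised generator draws amplitude from those
three programming levels and fraction/impedance uniformly from [0.15, 1] and
[450, 950] Ω, giving independent tables across seeds for repeated-recovery
experiments. On 500 such 12-row tables the background estimate is unbiased
within 0.05 µA, every per-table error is below 0.15 µA, the longevity-space
spread stays within a few percent, and R² exceeds 0.9 — the suite asserts
these. What this shows is that the estimator is correct and stable under
rounding noise; it does not validate the physical assumptions against real
manuals, whose row sets and idiosyncrasies are richer.

## Cohort simulation

Patients are described by age, indication (sinus node dysfunction,
intermittent AV block, complete AV block), per-chamber capture thresholds, a
relative lead-impedance factor, pacing-fraction jitter, remote-monitoring
eligibility and remaining life. The example configuration uses indication
mix 45/35/20 %, age ~ N(76, 9) truncated to [50, 100], threshold ~
N(1.25, 0.35) V truncated to [0.5, 3], impedance factor ~ N(1, 0.2)
truncated to [0.5, 2], and fraction jitter ~ N(0, 0.05) truncated to
±0.15 — values chosen once as clinically typical defaults. Truncated
normals are sampled by rejection.

Programming rules: programmed amplitude is twice the capture threshold
(clamped to [1, 5] V); atrial pacing 70 % for SND and 30 % for AVB;
ventricular pacing 90 % for single-chamber devices and complete AVB, 29 %
on dual-chamber devices with AAI/DDD-type avoidance versus 47 % otherwise;
CRT-P is 100 % biventricular with 50 % atrial pacing. Remote monitoring is
enabled with the configured adoption probability (default 50 %) on
current-generation devices only, choosing the technology the device offers.
Leadless capsules use ~600/~300 Ω ventricular/atrial leads and a 0.25 ms
pulse for the transcatheter Micra versus 0.4 ms for Aveir capsules.

**Progressive AV disease.** For intermittent AVB the ventricular fraction
grows at 1.5 %/yr (configurable), saturating at 100 %. Longevity is then
obtained by integrating the charge budget in monthly steps using the
midpoint fraction per step and linear interpolation inside the final step;
because total current is affine in the ventricular fraction, the slope is
obtained from a single extra model evaluation. With zero progression the
integration reduces exactly to the closed form; against the analytic
quadratic solution the monthly step is accurate to well under a hundredth
of a step, which the suite checks.

**Censoring and estimation.** Remaining life comes from a configurable
model: conditional Gompertz (default a = 1e-4, b = 0.085 per year — modal
death age ≈ 79), a tabulated (age, expectation) table sampled
exponentially, or an immortal table for uncensored experiments. The event
time is min(longevity, remaining life); depletion is observed only if the
battery runs out first. Survival is estimated by Kaplan–Meier (lifelines)
with pointwise 95 % intervals from Greenwood's variance formula, computed
from the risk table; the linear Greenwood form is used rather than
log-transformed intervals for transparency, clipped to [0, 1].

**Randomness.** One seed per cohort, with an independent child stream per
patient index (`SeedSequence.spawn`), so growing a cohort preserves earlier
patients and two devices simulated on the same seed share the identical
pool (common random numbers, paired comparisons). Remote eligibility is
stored as the resolved Bernoulli outcome so that zero-variance
configurations yield literally identical patients.

**Sensitivity.** Longevity spread under current uncertainty multiplies each
component by independent unit-mean lognormal noise of chosen relative sd
and summarises the longevity distribution; with ~3.5 % component noise the
sd/nominal ratio comes out near 3 %, first-order equal to the
component-weighted input sd (delta method), and the suite verifies that
relation.

Problem sizes in the shipped tests were chosen for desk-scale runs: the
regression study uses 500 tables of 12 rows; the confidence-interval
scaling check uses cohorts of 10³, 10⁴ and 10⁵ patients at three grid
quantiles, verifying the ~1/√n shrinkage of the Greenwood half-width.

## Known limitations

* The charge-pump ratio set and the conversion-efficiency treatment are
  engineering defaults; real converters differ by manufacturer and the
  published band checks constrain, but do not uniquely identify, them.
* Battery behaviour near depletion (voltage droop, ERI-to-end-of-service)
  and rate-adaptive pacing dynamics are out of scope; the programmed rate
  is used as-is.
* Registry option tables are populated from published ranges at the
  manufacturer level; per-model feature lists are approximations, and a
  profile activating an option a device lacks fails loudly rather than
  guessing.
* The cohort distributions are declared defaults, not estimates fitted to
  any registry; survival curves are therefore projections of the model
  under stated conditions, not forecasts validated against observed device
  survival.
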