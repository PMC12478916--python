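"""Monte-Carlo patient cohorts and device survival curves.

A fictitious patient pool is drawn from configurable distributions (age,
pacing indication, capture thresholds, lead impedance, pacing-fraction
variability). Each patient is programmed onto a device following simple
clinical conventions — atrial pacing 70% for sinus node dysfunction (SND)
and 30% for atrio-ventricular block (AVB); ventricular pacing 29% when an
AAI/DDD-type pacing-avoidance algorithm is available versus 47% otherwise;
90% for single-chamber ventricular pacing; biventricular 100% for CRT-P —
and the energy model converts the resulting drain to a projected device
longevity. Patients with intermittent AVB accrue ventricular pacing at a
configurable rate per year (progressive conduction disease), handled by a
stepped charge integration. Device observation ends at the patient's death,
producing right-censored event times; Kaplan-Meier estimation with Greenwood
pointwise confidence intervals yields the product survival curve.

Randomness uses one seed per cohort with an independent child stream per
patient index, so enlarging a cohort never reshuffles earlier patients and
device comparisons on the same seed are paired (common random numbers).
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Literal, Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import (
    CaptureMode,
    Chamber,
    DeviceCategory,
    PacingChannelSettings,
    ProgrammingProfile,
    RemoteMode,
    RvpaMode,
    compute_pci,
    pci_to_longevity,
    total_current,
    HOURS_PER_YEAR,
    UA_H_PER_AH,
)
from .errors import ConfigurationError, DomainError
from .registry import DeviceSpec, Generation, OptionId

#: Default annual increase in ventricular pacing fraction for intermittent
#: AVB (progressive A-V node disease).
DEFAULT_AVB_PROGRESSION_PER_YEAR = 0.015

#: Default monthly step for the charge integration under progression.
DEFAULT_INTEGRATION_STEP_YEARS = 1.0 / 12.0


class Indication(str, Enum):
    SND = "snd"
    INTERMITTENT_AVB = "intermittent_avb"
    COMPLETE_AVB = "complete_avb"


# ---------------------------------------------------------------------------
# Distributions and configuration
# ---------------------------------------------------------------------------


class DistSpec(BaseModel):
    """A named univariate distribution for a cohort parameter.

    Families: ``constant`` (value), ``uniform`` (low, high), ``normal``
    (mean, sd, optionally truncated to [low, high] by rejection), ``beta``
    (a, b scaled to [low, high]).
    """

    model_config = ConfigDict(frozen=True)

    family: Literal["constant", "uniform", "normal", "beta"]
    params: dict[str, float]

    def sample(self, rng: np.random.Generator) -> float:
        p = self.params
        try:
            if self.family == "constant":
                return p["value"]
            if self.family == "uniform":
                return float(rng.uniform(p["low"], p["high"]))
            if self.family == "normal":
                low = p.get("low", -math.inf)
                high = p.get("high", math.inf)
                if p["sd"] < 0:
                    raise ConfigurationError("normal sd must be >= 0")
                if p["sd"] == 0:
                    return float(min(max(p["mean"], low), high))
                for _ in range(10_000):
                    x = rng.normal(p["mean"], p["sd"])
                    if low <= x <= high:
                        return float(x)
                raise ConfigurationError(
                    f"truncated normal rejection failed for {p}"
                )
            if self.family == "beta":
                u = rng.beta(p["a"], p["b"])
                return float(p["low"] + (p["high"] - p["low"]) * u)
        except KeyError as exc:
            raise ConfigurationError(
                f"distribution {self.family!r} missing parameter {exc}"
            ) from exc
        raise ConfigurationError(f"unknown distribution family {self.family!r}")


class LifeTable(BaseModel):
    """Remaining-life model used for censoring at death.

    ``gompertz``: mortality hazard a*exp(b*age); remaining life is sampled
    from the conditional distribution given survival to the current age.
    ``tabulated``: (age, expected remaining years) pairs, sampled
    exponentially around the interpolated expectation. ``immortal``: no
    deaths (no censoring).
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["gompertz", "tabulated", "immortal"] = "gompertz"
    gompertz_a: float = Field(default=1e-4, gt=0)
    gompertz_b: float = Field(default=0.085, gt=0)
    ages: tuple[float, ...] = ()
    remaining_years: tuple[float, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "LifeTable":
        if self.kind == "tabulated":
            if len(self.ages) != len(self.remaining_years) or len(self.ages) < 2:
                raise ValueError("tabulated life table needs >= 2 (age, years) pairs")
            if list(self.ages) != sorted(self.ages):
                raise ValueError("life-table ages must be ascending")
            if any(r <= 0 for r in self.remaining_years):
                raise ValueError("remaining years must be positive")
        return self

    def expected_remaining(self, age: float) -> float:
        if self.kind == "immortal":
            return math.inf
        if self.kind == "tabulated":
            return float(np.interp(age, self.ages, self.remaining_years))
        a, b = self.gompertz_a, self.gompertz_b
        # numeric expectation of the conditional Gompertz remaining life
        t = np.linspace(0, 60, 1201)
        surv = np.exp(-(a / b) * (np.exp(b * (age + t)) - np.exp(b * age)))
        return float(np.trapezoid(surv, t))

    def sample_remaining(self, age: float, rng: np.random.Generator) -> float:
        if self.kind == "immortal":
            return math.inf
        if self.kind == "tabulated":
            mean = self.expected_remaining(age)
            return float(max(rng.exponential(mean), 1e-9))
        a, b = self.gompertz_a, self.gompertz_b
        u = rng.uniform()
        # invert S(t | age) = exp(-(a/b) (e^{b(age+t)} - e^{b age}))
        t = math.log(math.exp(b * age) - (b / a) * math.log(u)) / b - age
        return max(t, 1e-9)


class CohortConfig(BaseModel):
    """Everything needed to draw a reproducible fictitious patient pool."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(ge=1)
    seed: int = Field(ge=0)
    indication_mix: dict[Indication, float]
    age: DistSpec
    threshold: DistSpec
    impedance_factor: DistSpec
    fraction_jitter: DistSpec
    remote_adoption: float = Field(default=0.5, ge=0.0, le=1.0)
    avb_vp_progression_rate: float = Field(
        default=DEFAULT_AVB_PROGRESSION_PER_YEAR, ge=0.0
    )
    life_table: LifeTable = LifeTable()

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        total = sum(self.indication_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"indication mix must sum to 1, got {total}")
        if any(p < 0 or p > 1 for p in self.indication_mix.values()):
            raise ValueError("indication probabilities must lie in [0, 1]")
        return self


class PatientProfile(BaseModel):
    """One fictitious patient: demographics, thresholds and draw variables."""

    model_config = ConfigDict(frozen=True)

    age: float = Field(gt=18, lt=110)
    indication: Indication
    thresholds: dict[Chamber, float]
    impedance_factor: float = Field(gt=0)
    fraction_jitter: dict[Chamber, float]
    remote_eligible: bool
    remaining_life: float = Field(gt=0)


class DeviceEvent(BaseModel):
    """A device follow-up outcome: depletion (observed) or censoring at death."""

    model_config = ConfigDict(frozen=True)

    time: float = Field(gt=0)
    observed: bool


class SurvivalCurve(BaseModel):
    """Kaplan-Meier product survival curve with Greenwood 95% intervals."""

    model_config = ConfigDict(frozen=True)

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    censored: tuple[int, ...]
    ci_low: tuple[float, ...]
    ci_high: tuple[float, ...]

    @model_validator(mode="after")
    def _check(self) -> "SurvivalCurve":
        s = np.asarray(self.survival)
        if s.size == 0:
            raise ValueError("empty survival curve")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if abs(self.survival[0] - 1.0) > 1e-12 and self.times[0] == 0.0:
            raise ValueError("survival at time 0 must be 1")
        lo, hi = np.asarray(self.ci_low), np.asarray(self.ci_high)
        if np.any(lo > s + 1e-12) or np.any(hi < s - 1e-12):
            raise ValueError("confidence band must bracket the estimate")
        return self


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------


def _patient_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sample_cohort(config: CohortConfig) -> list[PatientProfile]:
    """Draw ``config.n`` patients, bit-reproducibly for a given (config, seed).

    Patient i is driven by the i-th child stream of the cohort seed, so
    increasing ``n`` extends the pool without changing earlier patients.
    """
    indications = list(config.indication_mix)
    probs = np.array([config.indication_mix[i] for i in indications])
    patients: list[PatientProfile] = []
    for rng in _patient_rngs(config.seed, config.n):
        age = config.age.sample(rng)
        indication = indications[rng.choice(len(indications), p=probs)]
        thresholds = {c: config.threshold.sample(rng) for c in Chamber}
        impedance_factor = config.impedance_factor.sample(rng)
        jitter = {c: config.fraction_jitter.sample(rng) for c in Chamber}
        remote_eligible = bool(rng.uniform() < config.remote_adoption)
        remaining = config.life_table.sample_remaining(age, rng)
        patients.append(
            PatientProfile(
                age=age,
                indication=indication,
                thresholds=thresholds,
                impedance_factor=impedance_factor,
                fraction_jitter=jitter,
                remote_eligible=remote_eligible,
                remaining_life=remaining,
            )
        )
    return patients


# ---------------------------------------------------------------------------
# Programming derivation
# ---------------------------------------------------------------------------

#: Manufacturers offering AAI/DDD-type mode-switching pacing avoidance.
_AAI_DDD_MANUFACTURERS = {"Biotronik", "Microport", "Medtronic"}

_BASE_RATE_BPM = 60.0
_CONVENTIONAL_IMPEDANCE = 500.0
_LEADLESS_V_IMPEDANCE = 600.0
_LEADLESS_A_IMPEDANCE = 300.0
_SAFETY_MARGIN = 2.0  # programmed amplitude = margin x capture threshold
_AMPLITUDE_FLOOR, _AMPLITUDE_CAP = 1.0, 5.0


def _clip01(x: float) -> float:
    return min(max(x, 0.0), 1.0)


def derive_profile(
    patient: PatientProfile, device: DeviceSpec, config: CohortConfig
) -> ProgrammingProfile:
    """Programme a device for a patient following the cohort conventions."""
    category = device.category
    required = {
        DeviceCategory.SR: (Chamber.RV,),
        DeviceCategory.DR: (Chamber.A, Chamber.RV),
        DeviceCategory.CRT_P: (Chamber.A, Chamber.RV, Chamber.LV),
        DeviceCategory.LEADLESS_V: (Chamber.RV,),
        DeviceCategory.LEADLESS_A: (Chamber.A,),
    }[category]

    leadless = category in (DeviceCategory.LEADLESS_V, DeviceCategory.LEADLESS_A)
    pulse_width = 0.25 if (leadless and "micra" in device.name.lower()) else 0.4

    rvpa = RvpaMode.OFF
    if category is DeviceCategory.DR:
        rvpa = (
            RvpaMode.AAI_DDD
            if device.manufacturer in _AAI_DDD_MANUFACTURERS
            else RvpaMode.HYSTERESIS
        )

    atrial_base = 0.70 if patient.indication is Indication.SND else 0.30
    if category is DeviceCategory.CRT_P:
        fractions = {Chamber.A: 0.5, Chamber.RV: 1.0, Chamber.LV: 1.0}
    elif category in (DeviceCategory.SR, DeviceCategory.LEADLESS_V):
        fractions = {Chamber.RV: 0.90}
    elif category is DeviceCategory.LEADLESS_A:
        fractions = {Chamber.A: atrial_base}
    else:  # DR
        if patient.indication is Indication.COMPLETE_AVB:
            ventricular = 0.90
        elif rvpa is RvpaMode.AAI_DDD:
            ventricular = 0.29
        else:
            ventricular = 0.47
        fractions = {Chamber.A: atrial_base, Chamber.RV: ventricular}

    channels = {}
    for chamber in required:
        if leadless:
            base_imp = (
                _LEADLESS_A_IMPEDANCE if chamber is Chamber.A
                else _LEADLESS_V_IMPEDANCE
            )
        else:
            base_imp = _CONVENTIONAL_IMPEDANCE
        amplitude = min(
            max(_SAFETY_MARGIN * patient.thresholds[chamber], _AMPLITUDE_FLOOR),
            _AMPLITUDE_CAP,
        )
        channels[chamber] = PacingChannelSettings(
            rate=_BASE_RATE_BPM,
            amplitude=amplitude,
            pulse_width=pulse_width,
            impedance=base_imp * patient.impedance_factor,
            pacing_fraction=_clip01(
                fractions[chamber] + patient.fraction_jitter[chamber]
            ),
        )

    remote_mode = RemoteMode.OFF
    if device.generation is Generation.CURRENT and patient.remote_eligible:
        if OptionId.REMOTE_BLUETOOTH in device.options:
            remote_mode = RemoteMode.BLUETOOTH
        elif OptionId.REMOTE_DAILY_FIXED in device.options:
            remote_mode = RemoteMode.DAILY_FIXED
        elif OptionId.REMOTE_RF in device.options:
            remote_mode = RemoteMode.RF

    return ProgrammingProfile(
        channels=channels,
        remote_mode=remote_mode,
        rvpa_mode=rvpa,
        capture_mode=CaptureMode.OFF,
    )


# ---------------------------------------------------------------------------
# Longevity with progressive ventricular pacing
# ---------------------------------------------------------------------------


def patient_longevity(
    device: DeviceSpec,
    profile: ProgrammingProfile,
    progression: float = 0.0,
    step: float = DEFAULT_INTEGRATION_STEP_YEARS,
) -> float:
    """Projected battery longevity (years) under a possibly drifting profile.

    With ``progression`` > 0 the ventricular pacing fraction at time t is
    min(1, f0 + progression * t); the battery charge budget is integrated in
    steps of ``step`` years with linear interpolation inside the final step.
    With no progression this reduces exactly to the closed-form reciprocal
    of the PCI.
    """
    if step <= 0:
        raise DomainError("integration step must be positive")
    capacity = device.battery.capacity_to_eri
    breakdown = total_current(device, profile)
    nominal = pci_to_longevity(compute_pci(breakdown.total, capacity))

    rv = profile.channels.get(Chamber.RV)
    if progression <= 0 or rv is None or rv.pacing_fraction >= 1.0:
        return nominal

    # total current is affine in the RV pacing fraction; get the slope from
    # a second evaluation at full pacing
    f0 = rv.pacing_fraction
    full_profile = profile.model_copy(
        update={
            "channels": {
                **profile.channels,
                Chamber.RV: rv.model_copy(update={"pacing_fraction": 1.0}),
            }
        }
    )
    i_full = total_current(device, full_profile).total
    i0 = breakdown.total
    slope = (i_full - i0) / (1.0 - f0)  # µA per unit of pacing fraction

    budget = UA_H_PER_AH * capacity  # µA·h
    saturation_t = (1.0 - f0) / progression
    used = 0.0
    t = 0.0
    while True:
        f_mid = f0 + progression * min(t + step / 2.0, saturation_t)
        current = i0 + slope * (min(f_mid, 1.0) - f0)
        increment = current * HOURS_PER_YEAR * step
        if used + increment >= budget:
            return t + step * (budget - used) / increment
        used += increment
        t += step
        if t > 200:  # defensive: no pacemaker battery outlasts this
            return t


# ---------------------------------------------------------------------------
# Censoring and survival estimation
# ---------------------------------------------------------------------------


def censor_events(
    longevities: Sequence[float], remaining_life: Sequence[float]
) -> list[DeviceEvent]:
    """Right-censor device lifetimes at patient death.

    The event time is min(longevity, remaining life); the event is observed
    (battery depletion) iff the battery depletes first.
    """
    if len(longevities) != len(remaining_life):
        raise DomainError("longevities and remaining_life must have equal length")
    return [
        DeviceEvent(time=min(l, r), observed=l <= r)
        for l, r in zip(longevities, remaining_life)
    ]


def survival_curve(
    events: Sequence[DeviceEvent], grid: Optional[Sequence[float]] = None
) -> SurvivalCurve:
    """Kaplan-Meier product survival curve with Greenwood 95% intervals.

    ``grid`` defaults to the observed event times (with t=0 prepended).
    """
    if not events:
        raise DomainError("need at least one event")
    times = np.array([e.time for e in events])
    observed = np.array([e.observed for e in events], dtype=bool)

    kmf = KaplanMeierFitter()
    if grid is None:
        grid_arr = np.unique(np.concatenate([[0.0], times]))
    else:
        grid_arr = np.unique(np.concatenate([[0.0], np.asarray(grid, float)]))
    kmf.fit(times, event_observed=observed, timeline=grid_arr)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()

    # Greenwood variance: S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    table = kmf.event_table
    n_i = table["at_risk"].to_numpy(float)
    d_i = table["observed"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            (d_i > 0) & (n_i > d_i), d_i / (n_i * (n_i - d_i)), 0.0
        )
        # a step where everyone at risk dies drives S to 0 (variance 0)
    cum = np.cumsum(terms)
    event_times = table.index.to_numpy(float)
    idx = np.searchsorted(event_times, grid_arr, side="right") - 1
    var_factor = np.where(idx >= 0, cum[np.clip(idx, 0, None)], 0.0)
    se = surv * np.sqrt(var_factor)
    ci_low = np.clip(surv - 1.959963984540054 * se, 0.0, 1.0)
    ci_high = np.clip(surv + 1.959963984540054 * se, 0.0, 1.0)

    at_risk = np.array([(times >= t).sum() for t in grid_arr])
    censored = np.array([((times <= t) & ~observed).sum() for t in grid_arr])
    return SurvivalCurve(
        times=tuple(float(t) for t in grid_arr),
        survival=tuple(float(s) for s in surv),
        at_risk=tuple(int(v) for v in at_risk),
        censored=tuple(int(v) for v in censored),
        ci_low=tuple(float(v) for v in ci_low),
        ci_high=tuple(float(v) for v in ci_high),
    )


# ---------------------------------------------------------------------------
# Sensitivity of longevity to current fluctuations
# ---------------------------------------------------------------------------


def current_sensitivity(
    device: DeviceSpec,
    profile: ProgrammingProfile,
    perturbation_sd: float,
    reps: int,
    seed: int,
) -> dict[str, float]:
    """Longevity spread under multiplicative lognormal noise on each current.

    Every component (background, each pacing channel, each option) is
    multiplied by an independent unit-mean lognormal factor with the given
    relative standard deviation; the longevity distribution is summarised as
    mean, sd and sd over the nominal (unperturbed) longevity.
    """
    if perturbation_sd < 0:
        raise DomainError("perturbation sd must be >= 0")
    if reps < 1:
        raise DomainError("need at least one replicate")
    breakdown = total_current(device, profile)
    components = np.array(
        [breakdown.background]
        + list(breakdown.pacing_per_channel.values())
        + list(breakdown.options.values())
    )
    capacity = device.battery.capacity_to_eri
    nominal = pci_to_longevity(compute_pci(breakdown.total, capacity))

    rng = np.random.default_rng(seed)
    if perturbation_sd == 0:
        totals = np.full(reps, breakdown.total)
    else:
        sigma2 = math.log1p(perturbation_sd**2)
        noise = rng.lognormal(
            -sigma2 / 2.0, math.sqrt(sigma2), size=(reps, components.size)
        )
        totals = noise @ components
    longevities = UA_H_PER_AH * capacity / (totals * HOURS_PER_YEAR)
    mean = float(np.mean(longevities))
    if reps > 1 and perturbation_sd > 0:
        sd = float(np.std(longevities, ddof=1))
    else:
        sd = 0.0
    return {
        "nominal_years": nominal,
        "mean_years": mean,
        "sd_years": sd,
        "sd_over_nominal": sd / nominal,
    }


# ---------------------------------------------------------------------------
# End-to-end simulation
# ---------------------------------------------------------------------------


def simulate_device(
    device: DeviceSpec,
    config: CohortConfig,
    patients: Optional[list[PatientProfile]] = None,
    grid: Optional[Sequence[float]] = None,
) -> SurvivalCurve:
    """Survival curve of one device over a cohort (shared pool if given)."""
    if patients is None:
        patients = sample_cohort(config)
    longevities = []
    for patient in patients:
        profile = derive_profile(patient, device, config)
        progression = (
            config.avb_vp_progression_rate
            if patient.indication is Indication.INTERMITTENT_AVB
            else 0.0
        )
        longevities.append(patient_longevity(device, profile, progression))
    events = censor_events(longevities, [p.remaining_life for p in patients])
    return survival_curve(events, grid=grid)


def simulate_devices(
    devices: Sequence[DeviceSpec],
    config: CohortConfig,
    grid: Optional[Sequence[float]] = None,
) -> dict[str, SurvivalCurve]:
    """Survival curves for several devices over one shared patient pool."""
    patients = sample_cohort(config)
    return {
        d.name: simulate_device(d, config, patients=patients, grid=grid)
        for d in devices
    }
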