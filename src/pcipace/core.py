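"""The pacemaker energy model.

A cardiac implantable electronic device (CIED) drains its battery through
three kinds of current: a *background* current (housekeeping, sensing,
telemetry standby), a *pacing* current (the battery-side cost of delivering
stimulation pulses), and currents from *optional features* (rate sensors,
electrogram storage, remote monitoring, capture-management algorithms).

The Power Consumption Index normalises the total drain by battery capacity:

    PCI = t * I / C        with t = 1 hour, I in microamperes, C in Ah,

so PCI is the (scaled) fraction of usable capacity consumed per hour, and its
reciprocal gives the projected device longevity:

    L [years] = 1e6 / (PCI * 8760).

Pacing current is modelled as an Ohmic pulse delivered through a discrete
charge-pump voltage converter: the lead-side charge per pulse is
V * t_pulse / R, and the battery-side drain multiplies that charge by the
smallest available pump ratio m such that m * V_battery >= V_pulse.
"""

from __future__ import annotations

import math
import warnings
from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError, DomainError
from .registry import DeviceCategory, DeviceSpec, OptionId

# ---------------------------------------------------------------------------
# Unit conventions and model constants
# ---------------------------------------------------------------------------

#: Hours per year used throughout the PCI <-> longevity conversion (365 * 24,
#: no leap-year correction).
HOURS_PER_YEAR = 8760.0

#: Microampere-hours contained in one ampere-hour.
UA_H_PER_AH = 1e6

#: Default set of discrete charge-pump ratios (fractional doubler/tripler
#: topologies common in implantable pulse generators).
DEFAULT_MULTIPLIERS: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 3.0)

#: Remote-monitoring currents in device tables are quoted at this
#: transmissions-per-year baseline; RF and Bluetooth modes scale linearly.
REMOTE_BASELINE_TRANSMISSIONS_PER_YEAR = 2.0


class Chamber(str, Enum):
    """Paced chamber: atrium, right ventricle, left ventricle."""

    A = "A"
    RV = "RV"
    LV = "LV"


class IegmMode(str, Enum):
    OFF = "off"
    STANDARD = "standard"
    PREARRHYTHMIA = "prearrhythmia"


class RemoteMode(str, Enum):
    OFF = "off"
    RF = "rf"
    BLUETOOTH = "bluetooth"
    DAILY_FIXED = "daily_fixed"


class CaptureMode(str, Enum):
    OFF = "off"
    DAILY = "daily"
    BEAT_TO_BEAT = "beat_to_beat"


class RvpaMode(str, Enum):
    """Right-ventricular-pacing avoidance algorithm family."""

    OFF = "off"
    AAI_DDD = "aai_ddd"
    HYSTERESIS = "hysteresis"


#: Chambers a profile must provide for each device category.
CATEGORY_CHANNELS: dict[DeviceCategory, frozenset[Chamber]] = {
    DeviceCategory.SR: frozenset({Chamber.RV}),
    DeviceCategory.DR: frozenset({Chamber.A, Chamber.RV}),
    DeviceCategory.CRT_P: frozenset({Chamber.A, Chamber.RV, Chamber.LV}),
    DeviceCategory.LEADLESS_V: frozenset({Chamber.RV}),
    DeviceCategory.LEADLESS_A: frozenset({Chamber.A}),
}


# ---------------------------------------------------------------------------
# Programming types
# ---------------------------------------------------------------------------


class PacingChannelSettings(BaseModel):
    """Programmed stimulation parameters for one pacing channel.

    rate is in beats per minute, amplitude in volts, pulse_width in
    milliseconds, impedance in ohms; pacing_fraction is the fraction of
    cardiac cycles actually paced on this channel.
    """

    model_config = ConfigDict(frozen=True)

    rate: float = Field(gt=20, lt=200)
    amplitude: float = Field(gt=0.5, lt=8)
    pulse_width: float = Field(gt=0.05, lt=2)
    impedance: float = Field(gt=100, lt=3000)
    pacing_fraction: float = Field(ge=0.0, le=1.0)


class ProgrammingProfile(BaseModel):
    """A full device programming: per-chamber pacing settings plus feature flags."""

    model_config = ConfigDict(frozen=True)

    channels: dict[Chamber, PacingChannelSettings]
    mv_sensor_on: bool = False
    iegm_mode: IegmMode = IegmMode.OFF
    remote_mode: RemoteMode = RemoteMode.OFF
    remote_transmissions_per_year: float = Field(
        default=REMOTE_BASELINE_TRANSMISSIONS_PER_YEAR, ge=0
    )
    capture_mode: CaptureMode = CaptureMode.OFF
    managed_output_target: Optional[float] = None
    rvpa_mode: RvpaMode = RvpaMode.OFF
    mpp_on: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ProgrammingProfile":
        if not self.channels:
            raise ValueError("a programming profile needs at least one channel")
        if self.mpp_on and Chamber.LV not in self.channels:
            raise ValueError("mpp_on requires an LV channel")
        if self.managed_output_target is not None and self.managed_output_target <= 0:
            raise ValueError("managed_output_target must be positive")
        return self


class CurrentBreakdown(BaseModel):
    """Battery current split into its contributions, all in microamperes."""

    model_config = ConfigDict(frozen=True)

    background: float = Field(ge=0)
    pacing_per_channel: dict[Chamber, float]
    options: dict[OptionId, float]
    total: float

    @model_validator(mode="after")
    def _check(self) -> "CurrentBreakdown":
        if any(v < 0 for v in self.pacing_per_channel.values()):
            raise ValueError("pacing currents must be non-negative")
        if any(v < 0 for v in self.options.values()):
            raise ValueError("option currents must be non-negative")
        s = (
            self.background
            + sum(self.pacing_per_channel.values())
            + sum(self.options.values())
        )
        if abs(self.total - s) > 1e-9:
            raise ValueError(f"total {self.total} != component sum {s}")
        return self


class PCIResult(BaseModel):
    """PCI index, the longevity it implies, and the underlying current split."""

    model_config = ConfigDict(frozen=True)

    pci: float = Field(gt=0)
    longevity_years: float = Field(gt=0)
    breakdown: CurrentBreakdown

    @model_validator(mode="after")
    def _check(self) -> "PCIResult":
        expected = UA_H_PER_AH / (self.pci * HOURS_PER_YEAR)
        if abs(self.longevity_years - expected) > 1e-9 * max(1.0, expected):
            raise ValueError("longevity inconsistent with PCI")
        return self


# ---------------------------------------------------------------------------
# Pacing current
# ---------------------------------------------------------------------------


def pacing_charge_per_pulse(
    amplitude: float, pulse_width: float, impedance: float
) -> float:
    """Lead-side charge of one Ohmic stimulation pulse, in microcoulombs.

    Q = V * t / R; with V in volts, t in milliseconds and R in ohms the
    product V*t/R is in millicoulomb-per-kiloohm units, i.e. exactly
    microcoulombs after the factor 1000.
    """
    if amplitude <= 0 or impedance <= 0:
        raise DomainError("amplitude and impedance must be positive")
    if pulse_width < 0:
        raise DomainError("pulse width cannot be negative")
    return amplitude * pulse_width / impedance * 1000.0


def select_multiplier(
    amplitude: float,
    battery_voltage: float,
    allowed: tuple[float, ...] = DEFAULT_MULTIPLIERS,
) -> float:
    """Smallest charge-pump ratio able to synthesise the pulse amplitude.

    Returns the smallest allowed ratio m with m * battery_voltage >= amplitude.
    If even the largest ratio is insufficient the largest is returned with a
    warning (the device would deliver a clipped pulse).
    """
    if amplitude <= 0 or battery_voltage <= 0:
        raise DomainError("voltages must be positive")
    if not allowed:
        raise DomainError("allowed multiplier set must be non-empty")
    for m in allowed:
        if m * battery_voltage >= amplitude:
            return m
    warnings.warn(
        f"amplitude {amplitude} V exceeds the largest pump ratio at "
        f"{battery_voltage} V battery; using {allowed[-1]}",
        stacklevel=2,
    )
    return allowed[-1]


def channel_pacing_current(
    settings: PacingChannelSettings,
    battery_voltage: float,
    allowed: tuple[float, ...] = DEFAULT_MULTIPLIERS,
) -> float:
    """Battery-side average pacing current of one channel, in microamperes.

    I = Q_pulse * (rate/60 Hz) * pacing_fraction * pump_ratio. Linear in
    rate, pulse width and pacing fraction; inversely proportional to lead
    impedance; piecewise in amplitude with jumps at pump-ratio boundaries.
    """
    q = pacing_charge_per_pulse(
        settings.amplitude, settings.pulse_width, settings.impedance
    )
    m = select_multiplier(settings.amplitude, battery_voltage, allowed)
    return q * (settings.rate / 60.0) * settings.pacing_fraction * m


def apply_managed_output(
    settings: PacingChannelSettings, target: float
) -> PacingChannelSettings:
    """Replace the programmed amplitude by the managed-output target voltage."""
    if target <= 0:
        raise DomainError("managed output target must be positive")
    return settings.model_copy(update={"amplitude": target})


def mpp_adjustment(lv_current: float, mpp_on: bool) -> float:
    """Multipoint pacing delivers two LV pulses per cycle, doubling LV current."""
    if lv_current < 0:
        raise DomainError("pacing current cannot be negative")
    return 2.0 * lv_current if mpp_on else lv_current


# ---------------------------------------------------------------------------
# Option currents
# ---------------------------------------------------------------------------

_LEVELS = ("low", "mid", "high")


def option_currents(
    device: DeviceSpec, profile: ProgrammingProfile, level: str = "mid"
) -> dict[OptionId, float]:
    """Currents drawn by the profile's active optional features, in µA.

    Each active option reads the device's stored current (``level`` selects
    the low/mid/high estimate). RF and Bluetooth remote monitoring scale
    linearly with the programmed transmissions per year (table values are at
    2/yr); daily fixed-schedule telemetry is transmission-count independent.
    Beat-to-beat capture management adds its fixed cost here — its
    output-reduction benefit enters through the managed output amplitude.
    """
    if level not in _LEVELS:
        raise DomainError(f"level must be one of {_LEVELS}")

    active: list[tuple[OptionId, float]] = []
    if profile.mv_sensor_on:
        active.append((OptionId.MV_SENSOR, 1.0))
    if profile.iegm_mode is IegmMode.STANDARD:
        active.append((OptionId.IEGM_STANDARD, 1.0))
    elif profile.iegm_mode is IegmMode.PREARRHYTHMIA:
        active.append((OptionId.IEGM_PREARRHYTHMIA, 1.0))
    tx_scale = (
        profile.remote_transmissions_per_year / REMOTE_BASELINE_TRANSMISSIONS_PER_YEAR
    )
    if profile.remote_mode is RemoteMode.RF:
        active.append((OptionId.REMOTE_RF, tx_scale))
    elif profile.remote_mode is RemoteMode.BLUETOOTH:
        active.append((OptionId.REMOTE_BLUETOOTH, tx_scale))
    elif profile.remote_mode is RemoteMode.DAILY_FIXED:
        active.append((OptionId.REMOTE_DAILY_FIXED, 1.0))
    if profile.capture_mode is CaptureMode.DAILY:
        active.append((OptionId.CAPTURE_DAILY, 1.0))
    elif profile.capture_mode is CaptureMode.BEAT_TO_BEAT:
        active.append((OptionId.CAPTURE_BEAT_TO_BEAT, 1.0))

    out: dict[OptionId, float] = {}
    for option, scale in active:
        if option not in device.options:
            raise ConfigurationError(
                f"option {option.value!r} is not available on device {device.name!r}"
            )
        out[option] = getattr(device.options[option], level) * scale
    return out


# ---------------------------------------------------------------------------
# Total current and the PCI <-> longevity conversion
# ---------------------------------------------------------------------------


def total_current(
    device: DeviceSpec, profile: ProgrammingProfile, level: str = "mid"
) -> CurrentBreakdown:
    """Decompose the device's battery drain under a programming profile."""
    required = CATEGORY_CHANNELS[device.category]
    provided = frozenset(profile.channels)
    if provided != required:
        raise ConfigurationError(
            f"device category {device.category.value} requires channels "
            f"{sorted(c.value for c in required)}, profile provides "
            f"{sorted(c.value for c in provided)}"
        )

    managed = (
        profile.capture_mode is not CaptureMode.OFF
        and profile.managed_output_target is not None
    )
    pacing: dict[Chamber, float] = {}
    for chamber, settings in profile.channels.items():
        if managed:
            settings = apply_managed_output(settings, profile.managed_output_target)
        current = channel_pacing_current(
            settings, device.battery.nominal_voltage, device.allowed_multipliers
        )
        if chamber is Chamber.LV:
            current = mpp_adjustment(current, profile.mpp_on)
        pacing[chamber] = current

    options = option_currents(device, profile, level=level)
    total = device.background_current + sum(pacing.values()) + sum(options.values())
    return CurrentBreakdown(
        background=device.background_current,
        pacing_per_channel=pacing,
        options=options,
        total=total,
    )


def compute_pci(total: float, capacity: float) -> float:
    """PCI index from total current (µA) and capacity to ERI (Ah).

    Under the one-hour normalisation the index is numerically I/C.
    """
    if total <= 0 or capacity <= 0:
        raise DomainError("current and capacity must be positive")
    return total / capacity


def pci_to_longevity(pci: float) -> float:
    """Projected longevity in years implied by a PCI index value."""
    if pci <= 0 or not math.isfinite(pci):
        raise DomainError("PCI must be positive and finite")
    return UA_H_PER_AH / (pci * HOURS_PER_YEAR)


def longevity_to_current(longevity: float, capacity: float) -> float:
    """Total current (µA) implied by a longevity (years) and capacity (Ah).

    Exact algebraic inverse of compute_pci followed by pci_to_longevity.
    """
    if longevity <= 0 or capacity <= 0:
        raise DomainError("longevity and capacity must be positive")
    return UA_H_PER_AH * capacity / (longevity * HOURS_PER_YEAR)


def project_longevity(
    device: DeviceSpec, profile: ProgrammingProfile, level: str = "mid"
) -> PCIResult:
    """End-to-end evaluation: current breakdown, PCI index and longevity."""
    breakdown = total_current(device, profile, level=level)
    pci = compute_pci(breakdown.total, device.battery.capacity_to_eri)
    return PCIResult(
        pci=pci, longevity_years=pci_to_longevity(pci), breakdown=breakdown
    )
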