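"""Synthetic inputs: manual longevity tables, nominal profiles, cohort configs.

The true manufacturer longevity tables behind the regression analysis are not
redistributable, so the test bed generates stand-in tables from *known*
background and option currents with the energy model itself, then rounds the
declared longevities to manual precision (0.1 years by default). Recovery of
the known currents from those tables is the module's acid test.

Also provides the nominal per-category programming profiles (60 bpm, 2.5 V,
0.4 ms, 500 ohms conventions; leadless variants) and a complete example
cohort configuration.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .cohort import (
    DEFAULT_AVB_PROGRESSION_PER_YEAR,
    CohortConfig,
    DistSpec,
    Indication,
    LifeTable,
)
from .core import (
    DEFAULT_MULTIPLIERS,
    HOURS_PER_YEAR,
    UA_H_PER_AH,
    Chamber,
    IegmMode,
    PacingChannelSettings,
    ProgrammingProfile,
    RemoteMode,
    RvpaMode,
    channel_pacing_current,
    mpp_adjustment,
)
from .inference import ManualLongevityTable, ManualTableRow
from .registry import BatterySpec, OptionId


class SyntheticManualSpec(BaseModel):
    """Recipe for a synthetic manual table with known ground-truth currents."""

    model_config = ConfigDict(frozen=True)

    true_background: float = Field(gt=0)
    true_option_currents: dict[OptionId, float] = Field(default_factory=dict)
    grid: tuple[ProgrammingProfile, ...] = Field(min_length=1)
    rounding: float = Field(default=0.1, ge=0)
    seed: int = 0


def _true_total_current(
    spec: SyntheticManualSpec, profile: ProgrammingProfile, voltage: float
) -> float:
    pacing = 0.0
    for chamber, settings in profile.channels.items():
        current = channel_pacing_current(settings, voltage, DEFAULT_MULTIPLIERS)
        if chamber is Chamber.LV:
            current = mpp_adjustment(current, profile.mpp_on)
        pacing += current
    option = 0.0
    if profile.mv_sensor_on:
        option += spec.true_option_currents.get(OptionId.MV_SENSOR, 0.0)
    if profile.iegm_mode is IegmMode.STANDARD:
        option += spec.true_option_currents.get(OptionId.IEGM_STANDARD, 0.0)
    elif profile.iegm_mode is IegmMode.PREARRHYTHMIA:
        option += spec.true_option_currents.get(OptionId.IEGM_PREARRHYTHMIA, 0.0)
    if profile.remote_mode is RemoteMode.RF:
        option += spec.true_option_currents.get(OptionId.REMOTE_RF, 0.0)
    elif profile.remote_mode is RemoteMode.BLUETOOTH:
        option += spec.true_option_currents.get(OptionId.REMOTE_BLUETOOTH, 0.0)
    elif profile.remote_mode is RemoteMode.DAILY_FIXED:
        option += spec.true_option_currents.get(OptionId.REMOTE_DAILY_FIXED, 0.0)
    return spec.true_background + pacing + option


def synth_manual_table(
    spec: SyntheticManualSpec, battery: BatterySpec
) -> ManualLongevityTable:
    """Declared-longevity table computed from the spec's true currents.

    Longevities are rounded to the nearest multiple of ``spec.rounding``
    (0 disables rounding). Deterministic: the grid fully determines the rows.
    """
    rows = []
    for profile in spec.grid:
        total = _true_total_current(spec, profile, battery.nominal_voltage)
        longevity = UA_H_PER_AH * battery.capacity_to_eri / (total * HOURS_PER_YEAR)
        if spec.rounding > 0:
            longevity = round(longevity / spec.rounding) * spec.rounding
        rows.append(
            ManualTableRow(settings=profile, declared_longevity=longevity)
        )
    return ManualLongevityTable(battery=battery, rows=tuple(rows))


def _sr_profile(
    amplitude: float, fraction: float, impedance: float,
    rate: float = 60.0, pulse_width: float = 0.4,
) -> ProgrammingProfile:
    return ProgrammingProfile(
        channels={
            Chamber.RV: PacingChannelSettings(
                rate=rate,
                amplitude=amplitude,
                pulse_width=pulse_width,
                impedance=impedance,
                pacing_fraction=fraction,
            )
        }
    )


def conventional_manual_grid() -> tuple[ProgrammingProfile, ...]:
    """Fixed full-rank 18-row single-chamber design.

    Amplitudes {1.5, 2.5, 3.5} V x pacing fractions {0.15, 0.5, 1.0} x
    impedances {500, 900} ohms.
    """
    return tuple(
        _sr_profile(a, f, r)
        for a in (1.5, 2.5, 3.5)
        for f in (0.15, 0.5, 1.0)
        for r in (500.0, 900.0)
    )


def random_manual_grid(
    n_rows: int, seed: int
) -> tuple[ProgrammingProfile, ...]:
    """Randomised single-chamber design for repeated-recovery experiments.

    Amplitude drawn from the common programming levels {1.5, 2.5, 3.5} V,
    pacing fraction uniform on [0.15, 1], impedance uniform on [450, 950] ohms.
    """
    rng = np.random.default_rng(seed)
    return tuple(
        _sr_profile(
            float(rng.choice([1.5, 2.5, 3.5])),
            float(rng.uniform(0.15, 1.0)),
            float(rng.uniform(450.0, 950.0)),
        )
        for _ in range(n_rows)
    )


def nominal_profiles(leadless_output: float = 2.5) -> dict[str, ProgrammingProfile]:
    """Per-category nominal programming.

    Conventional devices: 60 bpm, 2.5 V, 0.4 ms, 500 ohms. SR paces the
    ventricle 90% of the time; DR uses the population-average 51% atrial
    fraction and 47% ventricular (29% where AAI/DDD pacing avoidance applies,
    keyed ``DR_rvpa``); CRT-P is 100% biventricular with 50% atrial pacing.
    Leadless capsules use ~600/~300 ohm ventricular/atrial leads, 0.25 ms
    pulses for the Micra transcatheter device and 0.4 ms for the Aveir
    capsules, at the chosen output voltage (1.5 or 2.5 V in practice).
    """
    conv = dict(rate=60.0, amplitude=2.5, pulse_width=0.4, impedance=500.0)
    dr_channels = lambda vp: {
        Chamber.A: PacingChannelSettings(**conv, pacing_fraction=0.51),
        Chamber.RV: PacingChannelSettings(**conv, pacing_fraction=vp),
    }
    return {
        "SR": _sr_profile(2.5, 0.90, 500.0),
        "DR": ProgrammingProfile(channels=dr_channels(0.47)),
        "DR_rvpa": ProgrammingProfile(
            channels=dr_channels(0.29), rvpa_mode=RvpaMode.AAI_DDD
        ),
        "CRT-P": ProgrammingProfile(
            channels={
                Chamber.A: PacingChannelSettings(**conv, pacing_fraction=0.5),
                Chamber.RV: PacingChannelSettings(**conv, pacing_fraction=1.0),
                Chamber.LV: PacingChannelSettings(**conv, pacing_fraction=1.0),
            }
        ),
        "micra": _sr_profile(
            leadless_output, 0.90, 600.0, pulse_width=0.25
        ),
        "aveir_v": _sr_profile(leadless_output, 0.90, 600.0, pulse_width=0.4),
        "aveir_a": ProgrammingProfile(
            channels={
                Chamber.A: PacingChannelSettings(
                    rate=60.0,
                    amplitude=leadless_output,
                    pulse_width=0.4,
                    impedance=300.0,
                    pacing_fraction=0.51,
                )
            }
        ),
    }


def example_cohort_config(n: int, seed: int) -> CohortConfig:
    """A complete, documented cohort configuration.

    Indication mix 45% SND / 35% intermittent AVB / 20% complete AVB; age
    truncated normal (76 ± 9, 50-100); capture threshold truncated normal
    (1.25 ± 0.35 V, 0.5-3), programmed at a 2x safety margin; impedance
    a unit-mean relative factor (sd 0.2); pacing-fraction jitter ± 5 points.
    Remote adoption 50% (current-generation devices only); intermittent-AVB
    ventricular pacing progresses 1.5%/year; Gompertz remaining-life model.
    """
    return CohortConfig(
        n=n,
        seed=seed,
        indication_mix={
            Indication.SND: 0.45,
            Indication.INTERMITTENT_AVB: 0.35,
            Indication.COMPLETE_AVB: 0.20,
        },
        age=DistSpec(
            family="normal",
            params={"mean": 76.0, "sd": 9.0, "low": 50.0, "high": 100.0},
        ),
        threshold=DistSpec(
            family="normal",
            params={"mean": 1.25, "sd": 0.35, "low": 0.5, "high": 3.0},
        ),
        impedance_factor=DistSpec(
            family="normal",
            params={"mean": 1.0, "sd": 0.2, "low": 0.5, "high": 2.0},
        ),
        fraction_jitter=DistSpec(
            family="normal",
            params={"mean": 0.0, "sd": 0.05, "low": -0.15, "high": 0.15},
        ),
        remote_adoption=0.5,
        avb_vp_progression_rate=DEFAULT_AVB_PROGRESSION_PER_YEAR,
        life_table=LifeTable(kind="gompertz"),
    )
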