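import pytest

import pcipace as p


@pytest.fixture(scope="session")
def registry() -> list[p.DeviceSpec]:
    return p.builtin_registry()


@pytest.fixture(scope="session")
def profiles() -> dict[str, p.ProgrammingProfile]:
    return p.nominal_profiles()


@pytest.fixture()
def sr_device() -> p.DeviceSpec:
    """A generic single-chamber device with a 2.8 V battery and known options."""
    return p.DeviceSpec(
        name="Test SR",
        manufacturer="Acme",
        category=p.DeviceCategory.SR,
        generation=p.Generation.CURRENT,
        battery=p.BatterySpec(nominal_voltage=2.8, capacity_to_eri=1.0),
        background_current=6.0,
        options={
            p.OptionId.MV_SENSOR: p.OptionCurrent(low=0.69, mid=0.73, high=0.77),
            p.OptionId.REMOTE_RF: p.OptionCurrent.from_range(1.14, 1.75),
            p.OptionId.REMOTE_DAILY_FIXED: p.OptionCurrent.fixed(1.75),
            p.OptionId.CAPTURE_BEAT_TO_BEAT: p.OptionCurrent.fixed(1.0),
            p.OptionId.CAPTURE_DAILY: p.OptionCurrent.fixed(0.0),
        },
    )


def sr_profile(
    amplitude: float = 2.5,
    fraction: float = 1.0,
    impedance: float = 500.0,
    rate: float = 60.0,
    pulse_width: float = 0.4,
    **flags,
) -> p.ProgrammingProfile:
    return p.ProgrammingProfile(
        channels={
            p.Chamber.RV: p.PacingChannelSettings(
                rate=rate,
                amplitude=amplitude,
                pulse_width=pulse_width,
                impedance=impedance,
                pacing_fraction=fraction,
            )
        },
        **flags,
    )


@pytest.fixture()
def degenerate_config() -> p.CohortConfig:
    """All-constant cohort: every patient identical, nobody dies."""
    const = lambda v: p.DistSpec(family="constant", params={"value": v})
    return p.CohortConfig(
        n=50,
        seed=11,
        indication_mix={
            p.Indication.SND: 0.0,
            p.Indication.INTERMITTENT_AVB: 0.0,
            p.Indication.COMPLETE_AVB: 1.0,
        },
        age=const(75.0),
        threshold=const(1.25),
        impedance_factor=const(1.0),
        fraction_jitter=const(0.0),
        remote_adoption=0.0,
        avb_vp_progression_rate=0.0,
        life_table=p.LifeTable(kind="immortal"),
    )
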