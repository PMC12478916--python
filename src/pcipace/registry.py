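"""Device specifications: battery, background current and option currents.

Houses the domain types describing a cardiac implantable electronic device
(CIED) from the battery-budget point of view, JSON/CSV interchange, and a
built-in registry of representative single-chamber (SR), dual-chamber (DR),
CRT-P and leadless pacemaker models from the five major manufacturers, with
their published nominal battery voltages, capacities to the elective
replacement indicator (ERI), and background currents (both the
manual-reported figure, where available, and the regression-modelled working
value).

Option currents that manufacturers quote as ranges are stored as
(low, mid, high) triples with mid the arithmetic midpoint; model computations
default to mid and can be pointed at either end.
"""

from __future__ import annotations

import json
import math
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import DomainError, FormatError


class DeviceCategory(str, Enum):
    SR = "SR"
    DR = "DR"
    CRT_P = "CRT-P"
    LEADLESS_V = "leadless-V"
    LEADLESS_A = "leadless-A"


class Generation(str, Enum):
    PREVIOUS = "previous"
    CURRENT = "current"


class OptionId(str, Enum):
    """Optional-feature identifiers with a current cost."""

    MV_SENSOR = "mv_sensor"
    IEGM_STANDARD = "iegm_standard"
    IEGM_PREARRHYTHMIA = "iegm_prearrhythmia"
    REMOTE_RF = "remote_rf"
    REMOTE_BLUETOOTH = "remote_bluetooth"
    REMOTE_DAILY_FIXED = "remote_daily_fixed"
    CAPTURE_BEAT_TO_BEAT = "capture_beat_to_beat"
    CAPTURE_DAILY = "capture_daily"
    INTERCAPSULE_COMM = "intercapsule_comm"


class BatterySpec(BaseModel):
    """Battery chemistry summary: nominal voltage (V) and capacity to ERI (Ah)."""

    model_config = ConfigDict(frozen=True)

    nominal_voltage: float = Field(gt=2.0, lt=4.0)
    capacity_to_eri: float = Field(gt=0.05, lt=2.5)


class OptionCurrent(BaseModel):
    """A (low, mid, high) current estimate for one optional feature, in µA."""

    model_config = ConfigDict(frozen=True)

    low: float = Field(ge=0)
    mid: float = Field(ge=0)
    high: float = Field(ge=0)

    @model_validator(mode="after")
    def _ordered(self) -> "OptionCurrent":
        if not (self.low <= self.mid <= self.high):
            raise ValueError("option current triple must satisfy low <= mid <= high")
        return self

    @classmethod
    def from_range(cls, low: float, high: float) -> "OptionCurrent":
        return cls(low=low, mid=(low + high) / 2.0, high=high)

    @classmethod
    def fixed(cls, value: float) -> "OptionCurrent":
        return cls(low=value, mid=value, high=value)


OptionCurrentTable = dict[OptionId, OptionCurrent]

#: Standard fractional charge-pump ratios assumed for every device.
DEFAULT_ALLOWED_MULTIPLIERS: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 3.0)


class DeviceSpec(BaseModel):
    """One CIED model as seen by the energy budget.

    ``background_current`` is the working value used by all computations (the
    regression-modelled figure); where a manufacturer also states a background
    current in the manual it is retained as ``reported_background_current``.
    """

    model_config = ConfigDict(frozen=True)

    name: str = Field(min_length=1)
    manufacturer: str = Field(min_length=1)
    category: DeviceCategory
    generation: Generation
    battery: BatterySpec
    background_current: float = Field(gt=0, lt=20)
    reported_background_current: Optional[float] = Field(default=None, gt=0)
    options: OptionCurrentTable = Field(default_factory=dict)
    allowed_multipliers: tuple[float, ...] = DEFAULT_ALLOWED_MULTIPLIERS

    @model_validator(mode="after")
    def _check(self) -> "DeviceSpec":
        m = self.allowed_multipliers
        if not m or any(x <= 0 for x in m) or list(m) != sorted(m):
            raise ValueError("allowed_multipliers must be positive and ascending")
        if not math.isfinite(self.background_current):
            raise ValueError("background_current must be finite")
        return self


# ---------------------------------------------------------------------------
# Interchange: JSON (canonical) and flat CSV
# ---------------------------------------------------------------------------


def _spec_to_record(spec: DeviceSpec) -> dict:
    return {
        "name": spec.name,
        "manufacturer": spec.manufacturer,
        "category": spec.category.value,
        "generation": spec.generation.value,
        "battery": {
            "nominal_voltage_V": spec.battery.nominal_voltage,
            "capacity_to_eri_Ah": spec.battery.capacity_to_eri,
        },
        "background_current_uA": spec.background_current,
        "reported_background_current_uA": spec.reported_background_current,
        "options": {
            opt.value: {"low": oc.low, "mid": oc.mid, "high": oc.high}
            for opt, oc in spec.options.items()
        },
        "allowed_multipliers": list(spec.allowed_multipliers),
    }


def _spec_from_record(rec: dict, where: str) -> DeviceSpec:
    try:
        battery = rec["battery"]
        return DeviceSpec(
            name=rec["name"],
            manufacturer=rec["manufacturer"],
            category=DeviceCategory(rec["category"]),
            generation=Generation(rec["generation"]),
            battery=BatterySpec(
                nominal_voltage=battery["nominal_voltage_V"],
                capacity_to_eri=battery["capacity_to_eri_Ah"],
            ),
            background_current=rec["background_current_uA"],
            reported_background_current=rec.get("reported_background_current_uA"),
            options={
                OptionId(k): OptionCurrent(**v)
                for k, v in (rec.get("options") or {}).items()
            },
            allowed_multipliers=tuple(
                rec.get("allowed_multipliers", DEFAULT_ALLOWED_MULTIPLIERS)
            ),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{where}: missing or malformed field: {exc}") from exc
    except (ValidationError, ValueError) as exc:
        name = rec.get("name", "<unnamed>")
        raise FormatError(f"{where} (device {name!r}): {exc}") from exc


_CSV_BASE_COLUMNS = [
    "name",
    "manufacturer",
    "category",
    "generation",
    "nominal_voltage_V",
    "capacity_to_eri_Ah",
    "background_current_uA",
    "reported_background_current_uA",
    "allowed_multipliers",
]


def _specs_to_frame(specs: list[DeviceSpec]) -> pd.DataFrame:
    rows = []
    for spec in specs:
        row: dict = {
            "name": spec.name,
            "manufacturer": spec.manufacturer,
            "category": spec.category.value,
            "generation": spec.generation.value,
            "nominal_voltage_V": spec.battery.nominal_voltage,
            "capacity_to_eri_Ah": spec.battery.capacity_to_eri,
            "background_current_uA": spec.background_current,
            "reported_background_current_uA": spec.reported_background_current,
            "allowed_multipliers": ";".join(
                repr(m) for m in spec.allowed_multipliers
            ),
        }
        for opt, oc in spec.options.items():
            for level in ("low", "mid", "high"):
                row[f"opt_{opt.value}_uA_{level}"] = getattr(oc, level)
        rows.append(row)
    option_cols = sorted(
        {c for r in rows for c in r} - set(_CSV_BASE_COLUMNS)
    )
    return pd.DataFrame(rows, columns=_CSV_BASE_COLUMNS + option_cols)


def _specs_from_frame(df: pd.DataFrame, where: str) -> list[DeviceSpec]:
    specs = []
    for idx, row in df.iterrows():
        options: dict[str, dict] = {}
        for col in df.columns:
            if col.startswith("opt_") and col.endswith(("_low", "_mid", "_high")):
                stem, level = col.rsplit("_", 1)
                opt = stem[len("opt_"):-len("_uA")]
                value = row[col]
                if pd.notna(value):
                    options.setdefault(opt, {})[level] = float(value)
        reported = row.get("reported_background_current_uA")
        rec = {
            "name": row["name"],
            "manufacturer": row["manufacturer"],
            "category": row["category"],
            "generation": row["generation"],
            "battery": {
                "nominal_voltage_V": float(row["nominal_voltage_V"]),
                "capacity_to_eri_Ah": float(row["capacity_to_eri_Ah"]),
            },
            "background_current_uA": float(row["background_current_uA"]),
            "reported_background_current_uA": (
                float(reported) if pd.notna(reported) else None
            ),
            "options": options,
            "allowed_multipliers": [
                float(x) for x in str(row["allowed_multipliers"]).split(";") if x
            ],
        }
        specs.append(_spec_from_record(rec, f"{where} row {idx}"))
    return specs


def load_device_specs(path: str | Path, format: str = "json") -> list[DeviceSpec]:
    """Read a list of device specs from JSON or flat CSV.

    Order is preserved; every record is validated. Parse failures raise
    :class:`FormatError` naming the offending row/field.
    """
    path = Path(path)
    if format == "json":
        text = path.read_text(encoding="utf-8").strip()
        if not text:
            return []
        try:
            records = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON: {exc}") from exc
        if not isinstance(records, list):
            raise FormatError(f"{path}: expected a JSON array of device records")
        return [
            _spec_from_record(rec, f"{path} record {i}")
            for i, rec in enumerate(records)
        ]
    if format == "csv":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            return []
        except Exception as exc:  # malformed CSV
            raise FormatError(f"{path}: invalid CSV: {exc}") from exc
        return _specs_from_frame(df, str(path))
    raise DomainError(f"unknown device-spec format {format!r}")


def save_device_specs(
    specs: list[DeviceSpec], path: str | Path, format: str = "json"
) -> None:
    """Write device specs so that :func:`load_device_specs` round-trips them."""
    path = Path(path)
    for spec in specs:
        # frozen pydantic models are validated on construction; re-check NaN
        # current explicitly so a corrupted object never reaches disk
        if not math.isfinite(spec.background_current):
            raise DomainError(f"device {spec.name!r}: non-finite background current")
    if format == "json":
        payload = [_spec_to_record(s) for s in specs]
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    elif format == "csv":
        _specs_to_frame(specs).to_csv(path, index=False, float_format="%.17g")
    else:
        raise DomainError(f"unknown device-spec format {format!r}")


# ---------------------------------------------------------------------------
# Built-in registry
# ---------------------------------------------------------------------------

_SENSOR = OptionCurrent.from_range(0.69, 0.77)
_CAPTURE_B2B = OptionCurrent.fixed(1.0)
_CAPTURE_DAILY = OptionCurrent.fixed(0.0)
_REMOTE_RF = OptionCurrent.from_range(1.14, 1.75)
_REMOTE_BT = OptionCurrent.from_range(0.09, 0.59)
_REMOTE_DAILY = OptionCurrent.fixed(1.75)
_IEGM_EMBEDDED = OptionCurrent.fixed(0.0)  # cost already inside background
_IEGM_STD_PREV_MDT = OptionCurrent.from_range(0.11, 0.34)
_IEGM_PRE_PREV_MDT = OptionCurrent.from_range(5.67, 6.16)
_IEGM_STD_CURR_MDT = OptionCurrent.from_range(0.04, 0.11)
_IEGM_PRE_CURR_MDT = OptionCurrent.from_range(1.3, 1.7)
_INTERCAPSULE = OptionCurrent.from_range(0.81, 1.0)

#: Manufacturers whose capture-management algorithm runs beat-to-beat
#: (the others re-measure thresholds daily at no quoted energy cost).
_B2B_CAPTURE = {"Abbott", "Boston Scientific"}
#: Remote-monitoring technology per manufacturer, current generation.
_REMOTE_TECH = {
    "Abbott": {OptionId.REMOTE_RF: _REMOTE_RF},
    "Boston Scientific": {OptionId.REMOTE_RF: _REMOTE_RF},
    "Biotronik": {
        OptionId.REMOTE_RF: _REMOTE_RF,
        OptionId.REMOTE_DAILY_FIXED: _REMOTE_DAILY,
    },
    "Medtronic": {OptionId.REMOTE_BLUETOOTH: _REMOTE_BT},
    "Microport": {OptionId.REMOTE_BLUETOOTH: _REMOTE_BT},
}
#: Manufacturers offering a minute-ventilation sensor.
_MV_SENSOR = {"Boston Scientific", "Microport"}


def _conventional_options(manufacturer: str, generation: Generation) -> OptionCurrentTable:
    opts: OptionCurrentTable = {}
    if manufacturer in _MV_SENSOR:
        opts[OptionId.MV_SENSOR] = _SENSOR
    if manufacturer in _B2B_CAPTURE:
        opts[OptionId.CAPTURE_BEAT_TO_BEAT] = _CAPTURE_B2B
    else:
        opts[OptionId.CAPTURE_DAILY] = _CAPTURE_DAILY
    if manufacturer == "Medtronic":
        if generation is Generation.PREVIOUS:
            opts[OptionId.IEGM_STANDARD] = _IEGM_STD_PREV_MDT
            opts[OptionId.IEGM_PREARRHYTHMIA] = _IEGM_PRE_PREV_MDT
        else:
            opts[OptionId.IEGM_STANDARD] = _IEGM_STD_CURR_MDT
            opts[OptionId.IEGM_PREARRHYTHMIA] = _IEGM_PRE_CURR_MDT
    else:
        opts[OptionId.IEGM_STANDARD] = _IEGM_EMBEDDED
    if generation is Generation.CURRENT:
        opts.update(_REMOTE_TECH.get(manufacturer, {}))
    return opts


# (name, manufacturer, category, generation, voltage V, capacity Ah,
#  modelled background µA, manual-reported background µA or None)
_CONVENTIONAL_ROWS: list[tuple] = [
    # --- SR, previous generation
    ("Identity SR Adx 5180", "Abbott", "SR", "previous", 2.80, 0.55, 5.94, 6.30),
    ("Evia SR", "Biotronik", "SR", "previous", 2.80, 1.20, 7.21, 6.00),
    ("Insignia I Ultra 1190", "Boston Scientific", "SR", "previous", 2.80, 0.97, 10.72, None),
    ("Symphonie SR", "Microport", "SR", "previous", 2.80, 0.93, 5.78, None),
    ("Enpulse E2SR", "Medtronic", "SR", "previous", 2.80, 0.86, 11.10, 11.00),
    ("Adapta SR", "Medtronic", "SR", "previous", 2.80, 0.86, 11.34, 12.93),
    ("G20 SR", "Vitatron", "SR", "previous", 2.80, 0.86, 9.14, 9.80),
    # --- SR, current generation
    ("Assurity MRI SR", "Abbott", "SR", "current", 3.20, 0.91, 5.70, 5.40),
    ("Edora 8 SR", "Biotronik", "SR", "current", 3.10, 0.81, 5.20, 6.00),
    ("Accolade VR", "Boston Scientific", "SR", "current", 2.80, 1.00, 9.70, None),
    ("Alizea SR", "Microport", "SR", "current", 3.10, 1.12, 5.80, 5.73),
    ("Azure XT SR", "Medtronic", "SR", "current", 3.25, 0.97, 6.10, 6.71),
    # --- DR, previous generation
    ("Identity D 5380", "Abbott", "DR", "previous", 2.80, 0.55, 6.19, 6.90),
    ("Identity DR", "Abbott", "DR", "previous", 2.80, 0.95, 5.72, 6.90),
    ("Evia DR-T", "Biotronik", "DR", "previous", 3.10, 1.05, 6.66, 6.00),
    ("Evia DR", "Biotronik", "DR", "previous", 2.80, 1.20, 9.86, 6.00),
    ("Insignia Ultra 1290", "Boston Scientific", "DR", "previous", 2.80, 0.935, 11.62, None),
    ("Insignia Ultra 1291", "Boston Scientific", "DR", "previous", 2.80, 1.44, 13.06, None),
    ("Symphonie DR", "Microport", "DR", "previous", 2.80, 0.93, 6.00, None),
    ("Enpulse E2DR 21", "Medtronic", "DR", "previous", 2.80, 0.82, 13.28, 13.30),
    ("Adapta DR", "Medtronic", "DR", "previous", 2.80, 1.20, 14.67, 13.87),
    ("Enpulse E2DR 33", "Medtronic", "DR", "previous", 2.80, 1.40, 13.70, 13.30),
    ("Enrythm DR", "Medtronic", "DR", "previous", 3.20, 1.10, 9.80, 9.80),
    ("G70 DR", "Vitatron", "DR", "previous", 2.80, 1.22, 11.42, 10.00),
    # --- DR, current generation
    ("Assurity MRI DR", "Abbott", "DR", "current", 3.20, 0.91, 7.50, 7.70),
    ("Edora 8 DR", "Biotronik", "DR", "current", 3.10, 0.81, 6.00, 6.00),
    ("Accolade DR", "Boston Scientific", "DR", "current", 2.80, 1.00, 10.30, None),
    ("Accolade DR EL", "Boston Scientific", "DR", "current", 2.80, 1.60, 10.40, None),
    ("Alizea DR remote", "Microport", "DR", "current", 3.10, 1.04, 6.30, 6.00),
    ("Alizea DR", "Microport", "DR", "current", 3.10, 1.12, 6.30, 6.00),
    ("Azure XT DR", "Medtronic", "DR", "current", 3.25, 0.97, 7.00, 6.71),
    # --- CRT-P, previous generation
    ("Anthem 3112-3212", "Abbott", "CRT-P", "previous", 3.20, 0.80, 7.09, None),
    ("Frontier II", "Abbott", "CRT-P", "previous", 2.80, 0.95, 7.09, None),
    ("Evia HF-T", "Biotronik", "CRT-P", "previous", 3.10, 1.00, 7.26, 7.00),
    ("Eluna HF", "Biotronik", "CRT-P", "previous", 3.10, 1.00, 7.56, 7.00),
    ("Invive CRT-P W173", "Boston Scientific", "CRT-P", "previous", 3.00, 1.36, 11.77, None),
    ("Insync III", "Medtronic", "CRT-P", "previous", 3.25, 1.40, 11.90, 12.00),
    ("Consulta CRT-P", "Medtronic", "CRT-P", "previous", 3.20, 0.97, 7.06, 7.07),
    ("Viva CRT-P", "Medtronic", "CRT-P", "previous", 3.20, 0.97, 7.22, 7.22),
    # --- CRT-P, current generation
    ("Quadra Allure", "Abbott", "CRT-P", "current", 3.20, 0.80, 7.09, None),
    ("Edora HF", "Biotronik", "CRT-P", "current", 3.10, 0.932, 7.10, 7.00),
    ("Visionist", "Boston Scientific", "CRT-P", "current", 2.80, 1.50, 9.63, None),
    ("Reply CRT-P", "Microport", "CRT-P", "current", 2.80, 0.82, 7.50, 7.90),
    ("Percepta CRT-P", "Medtronic", "CRT-P", "current", 3.25, 1.03, 7.19, 7.14),
]

# Leadless capsules. The two-chamber configuration carries a higher background
# per capsule because it includes the inter-capsule communication share; the
# communication range is retained as an option entry for reference.
_LEADLESS_ROWS: list[tuple] = [
    ("Micra", "Medtronic", "leadless-V", 3.20, 0.12, 0.94, 0.80,
     {OptionId.CAPTURE_DAILY: _CAPTURE_DAILY}),
    ("Aveir SR atrial capsule", "Abbott", "leadless-A", 3.00, 0.174, 1.06, 0.94,
     {OptionId.INTERCAPSULE_COMM: _INTERCAPSULE}),
    ("Aveir SR ventricular capsule", "Abbott", "leadless-V", 3.00, 0.241, 1.02, 0.94,
     {OptionId.INTERCAPSULE_COMM: _INTERCAPSULE}),
    ("Aveir DR atrial capsule", "Abbott", "leadless-A", 3.00, 0.174, 2.03, 1.80,
     {OptionId.INTERCAPSULE_COMM: _INTERCAPSULE}),
    ("Aveir DR ventricular capsule", "Abbott", "leadless-V", 3.00, 0.241, 1.94, 1.80,
     {OptionId.INTERCAPSULE_COMM: _INTERCAPSULE}),
]


def builtin_registry() -> list[DeviceSpec]:
    """The packaged device fixture: one entry per published device row.

    Devices published with two battery variants in one row appear as two
    entries (distinct capacities give distinct PCIs).
    """
    specs: list[DeviceSpec] = []
    for name, manu, cat, gen, volts, ah, modelled, reported in _CONVENTIONAL_ROWS:
        generation = Generation(gen)
        specs.append(
            DeviceSpec(
                name=name,
                manufacturer=manu,
                category=DeviceCategory(cat),
                generation=generation,
                battery=BatterySpec(nominal_voltage=volts, capacity_to_eri=ah),
                background_current=modelled,
                reported_background_current=reported,
                options=_conventional_options(manu, generation),
            )
        )
    for name, manu, cat, volts, ah, modelled, reported, opts in _LEADLESS_ROWS:
        specs.append(
            DeviceSpec(
                name=name,
                manufacturer=manu,
                category=DeviceCategory(cat),
                generation=Generation.CURRENT,
                battery=BatterySpec(nominal_voltage=volts, capacity_to_eri=ah),
                background_current=modelled,
                reported_background_current=reported,
                options=opts,
            )
        )
    return specs


def get_device(name: str, specs: Optional[list[DeviceSpec]] = None) -> DeviceSpec:
    """Case-insensitive lookup by device name in a spec list (default: builtin)."""
    if specs is None:
        specs = builtin_registry()
    wanted = name.strip().lower()
    for spec in specs:
        if spec.name.lower() == wanted:
            return spec
    raise KeyError(f"unknown device {name!r}")
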