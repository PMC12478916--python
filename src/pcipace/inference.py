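"""Inferring unreported currents from manual-style longevity tables.

Manufacturers publish projected longevities as a function of programming
(output voltage, pulse width, impedance, pacing percentage, option flags) but
not the underlying currents. Because longevity is the reciprocal of the
capacity-normalised current, each declared longevity row implies a total
current I = 1e6 * C / (L * 8760). Regressing that implied current on the
model's per-channel pacing-current features (charge per pulse x rate x
pacing fraction x pump ratio, which has expected slope 1) recovers the
background current as the intercept; slope deviations from 1 absorb
conversion-efficiency effects. Currents of on/off optional features are
recovered by differencing the reciprocal longevities of otherwise identical
rows.

The regression runs on the current scale rather than the longevity scale:
the physics is additive in currents, so ordinary least squares there is the
natural estimator. Fit quality is nevertheless reported in longevity space
(ratio modelled/declared - 1), matching how manuals are read.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from pydantic import BaseModel, ConfigDict, Field

from .core import (
    DEFAULT_MULTIPLIERS,
    HOURS_PER_YEAR,
    UA_H_PER_AH,
    Chamber,
    PacingChannelSettings,
    ProgrammingProfile,
    channel_pacing_current,
    mpp_adjustment,
)
from .errors import DomainError, FormatError, InferenceError
from .registry import BatterySpec

logger = logging.getLogger(__name__)


class ManualTableRow(BaseModel):
    """One manual row: a programming profile and its declared longevity (years)."""

    model_config = ConfigDict(frozen=True)

    settings: ProgrammingProfile
    declared_longevity: float = Field(gt=0)


class ManualLongevityTable(BaseModel):
    """A manual's (settings -> declared longevity) table for one device."""

    model_config = ConfigDict(frozen=True)

    battery: BatterySpec
    rows: tuple[ManualTableRow, ...]


class RegressionFit(BaseModel):
    """Fitted background current with diagnostics.

    ``residuals_years`` are modelled minus declared longevity per row;
    ``mean_relative_error``/``sd_relative_error`` summarise the ratio
    (modelled longevity / declared longevity) - 1. A negative fitted
    intercept is reported as-is and flagged in ``warnings_``, never clipped.
    """

    model_config = ConfigDict(frozen=True)

    background_current: float
    pacing_coefficients: dict[str, float]
    r_squared: float = Field(ge=0.0, le=1.0)
    residuals_years: tuple[float, ...]
    mean_relative_error: float
    sd_relative_error: float
    n_rows: int
    warnings_: tuple[str, ...] = ()


def implied_total_current(declared_longevity: float, capacity: float) -> float:
    """Total current (µA) a declared longevity implies at a given capacity (Ah)."""
    if declared_longevity <= 0 or capacity <= 0:
        raise DomainError("longevity and capacity must be positive")
    return UA_H_PER_AH * capacity / (declared_longevity * HOURS_PER_YEAR)


def option_current_by_difference(
    longevity_on: float, longevity_off: float, capacity: float
) -> float:
    """Current cost (µA) of an option from longevities with it on and off.

    Delta I = 1e6 * C * (1/L_on - 1/L_off) / 8760. A longer on-longevity than
    off-longevity yields a negative cost, returned with a warning rather than
    clipped.
    """
    if longevity_on <= 0 or longevity_off <= 0 or capacity <= 0:
        raise DomainError("longevities and capacity must be positive")
    delta = (
        UA_H_PER_AH * capacity * (1.0 / longevity_on - 1.0 / longevity_off)
        / HOURS_PER_YEAR
    )
    if delta < 0:
        warnings.warn(
            "longevity with the option on exceeds longevity with it off; "
            "returning a negative option current",
            stacklevel=2,
        )
    return delta


def pacing_features(
    profile: ProgrammingProfile,
    battery_voltage: float,
    chambers: Sequence[Chamber],
    allowed: tuple[float, ...] = DEFAULT_MULTIPLIERS,
) -> np.ndarray:
    """Default regression design: model pacing current (µA) per chamber.

    Each feature equals charge-per-pulse x pulse rate x pacing fraction x
    pump ratio for that chamber (doubled on LV when multipoint pacing is on),
    so the expected regression slope is one.
    """
    feats = []
    for chamber in chambers:
        settings = profile.channels.get(chamber)
        if settings is None:
            feats.append(0.0)
            continue
        current = channel_pacing_current(settings, battery_voltage, allowed)
        if chamber is Chamber.LV:
            current = mpp_adjustment(current, profile.mpp_on)
        feats.append(current)
    return np.asarray(feats)


def fit_background(
    table: ManualLongevityTable,
    allowed: tuple[float, ...] = DEFAULT_MULTIPLIERS,
    design: Optional[Callable[[ProgrammingProfile], np.ndarray]] = None,
    chamber_names: Optional[Sequence[Chamber]] = None,
) -> RegressionFit:
    """Recover the background current from a manual longevity table by OLS.

    The response is the implied total current of each row; the regressors are
    the per-channel pacing-current features (or a caller-supplied ``design``).
    The intercept estimates the background current. An explicitly empty
    design degrades to the mean implied current; a rank-deficient design
    (e.g. no pacing variation across rows) raises :class:`InferenceError`.
    """
    rows = table.rows
    if len(rows) < 2:
        raise InferenceError(
            "at least two rows with varied settings are needed to separate "
            "background from pacing current"
        )
    capacity = table.battery.capacity_to_eri
    y = np.array(
        [implied_total_current(r.declared_longevity, capacity) for r in rows]
    )

    if design is None:
        if chamber_names is None:
            chamber_names = [
                c for c in Chamber
                if any(c in r.settings.channels for r in rows)
            ]
        chamber_names = list(chamber_names)
        voltage = table.battery.nominal_voltage

        def design(profile: ProgrammingProfile) -> np.ndarray:
            return pacing_features(profile, voltage, chamber_names, allowed)
    else:
        chamber_names = list(chamber_names or [])

    X = np.vstack([np.atleast_1d(np.asarray(design(r.settings), float)) for r in rows])
    fit_warnings: list[str] = []

    if X.shape[1] == 0:
        background = float(np.mean(y))
        coeffs: dict[str, float] = {}
        fitted = np.full_like(y, background)
        # intercept-only model: no pacing variance explained
        r2 = 0.0 if np.ptp(y) > 0 else 1.0
    else:
        Xc = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            raise InferenceError(
                "regression design is rank deficient: the table does not vary "
                "the pacing settings enough to identify all coefficients; "
                "add rows with different outputs, fractions or impedances"
            )
        res = sm.OLS(y, Xc).fit()
        background = float(res.params[0])
        slopes = res.params[1:]
        if len(chamber_names) == X.shape[1]:
            names = [c.value for c in chamber_names]
        else:
            names = [f"x{i}" for i in range(X.shape[1])]
        coeffs = {name: float(s) for name, s in zip(names, slopes)}
        fitted = np.asarray(res.fittedvalues)
        r2 = float(min(max(res.rsquared, 0.0), 1.0))

    if background <= 0:
        fit_warnings.append(
            f"fitted background current is non-positive ({background:.3g} µA)"
        )

    declared = np.array([r.declared_longevity for r in rows])
    with np.errstate(divide="ignore"):
        modelled_longevity = UA_H_PER_AH * capacity / (fitted * HOURS_PER_YEAR)
    residuals = modelled_longevity - declared
    rel = modelled_longevity / declared - 1.0
    return RegressionFit(
        background_current=background,
        pacing_coefficients=coeffs,
        r_squared=r2,
        residuals_years=tuple(float(v) for v in residuals),
        mean_relative_error=float(np.mean(rel)),
        sd_relative_error=float(np.std(rel, ddof=1)) if len(rel) > 1 else 0.0,
        n_rows=len(rows),
        warnings_=tuple(fit_warnings),
    )


def fit_report(fit: RegressionFit) -> tuple[str, pd.DataFrame]:
    """Human summary plus a machine-readable per-row residual table."""
    lines = [
        "Manual-table regression fit",
        f"  rows:                    {fit.n_rows}",
        f"  background current:      {fit.background_current:.3f} µA",
    ]
    for name, coef in fit.pacing_coefficients.items():
        lines.append(f"  pacing slope [{name}]:       {coef:.4f} (expected 1)")
    lines += [
        f"  R^2:                     {fit.r_squared:.4f}",
        f"  longevity error:         {100 * fit.mean_relative_error:.2f}% "
        f"± {100 * fit.sd_relative_error:.2f}%",
    ]
    for w in fit.warnings_:
        lines.append(f"  WARNING: {w}")
    text = "\n".join(lines)
    logger.info("%s", text)
    table = pd.DataFrame(
        {
            "row": np.arange(fit.n_rows),
            "residual_years": list(fit.residuals_years),
        }
    )
    return text, table


# ---------------------------------------------------------------------------
# CSV interchange for manual tables
# ---------------------------------------------------------------------------

_CHANNEL_FIELDS = ("rate_bpm", "amplitude_V", "pulse_width_ms", "impedance_ohm",
                   "pacing_fraction")
_FIELD_MAP = dict(zip(_CHANNEL_FIELDS,
                      ("rate", "amplitude", "pulse_width", "impedance",
                       "pacing_fraction")))


def manual_table_to_csv(table: ManualLongevityTable, path: str | Path) -> None:
    """Flatten a manual table to CSV, one row per declared-longevity entry."""
    records = []
    for row in table.rows:
        rec: dict = {}
        for chamber, st in row.settings.channels.items():
            prefix = chamber.value.lower()
            for col, attr in _FIELD_MAP.items():
                rec[f"{prefix}_{col}"] = getattr(st, attr)
        rec["mpp_on"] = int(row.settings.mpp_on)
        rec["declared_longevity_years"] = row.declared_longevity
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False, float_format="%.17g")


def manual_table_from_csv(
    path: str | Path, battery: BatterySpec
) -> ManualLongevityTable:
    """Read a manual table from CSV written by :func:`manual_table_to_csv`."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: invalid manual-table CSV: {exc}") from exc
    if "declared_longevity_years" not in df.columns:
        raise FormatError(f"{path}: missing column declared_longevity_years")
    rows = []
    for idx, rec in df.iterrows():
        channels = {}
        for chamber in Chamber:
            prefix = chamber.value.lower()
            if f"{prefix}_rate_bpm" in df.columns and pd.notna(
                rec[f"{prefix}_rate_bpm"]
            ):
                channels[chamber] = PacingChannelSettings(
                    **{
                        attr: float(rec[f"{prefix}_{col}"])
                        for col, attr in _FIELD_MAP.items()
                    }
                )
        if not channels:
            raise FormatError(f"{path} row {idx}: no pacing channel columns")
        profile = ProgrammingProfile(
            channels=channels, mpp_on=bool(rec.get("mpp_on", 0))
        )
        rows.append(
            ManualTableRow(
                settings=profile,
                declared_longevity=float(rec["declared_longevity_years"]),
            )
        )
    return ManualLongevityTable(battery=battery, rows=tuple(rows))
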