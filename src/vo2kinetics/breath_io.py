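"""Reading, validation and writing of breath-by-breath gas-exchange recordings.

This module is the single source of truth for units and time conventions:

* VO2, VCO2 and VE are litres per minute (``L·min⁻¹``); millilitres appear
  only in derived reports (e.g. the VO2max plateau rule).
* Heart rate is beats per minute.
* Raw files carry time in **seconds from recording start**; alignment to the
  exercise onset is a preprocessing step, not an I/O concern.

The canonical on-disk dialect is a comma-separated table with the header
``t_s,vo2_lmin,vco2_lmin,ve_lmin,hr_bpm`` and empty cells for missing values,
accompanied by a JSON sidecar with the session metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "BreathRecord",
    "SessionMeta",
    "BreathSeries",
    "read_breath_csv",
    "write_breath_csv",
    "read_session_meta",
    "write_session_meta",
    "COLUMNS",
]

#: canonical CSV column order
COLUMNS = ("t_s", "vo2_lmin", "vco2_lmin", "ve_lmin", "hr_bpm")

#: columns that must parse to a finite number in every row
REQUIRED_COLUMNS = ("t_s", "vo2_lmin", "vco2_lmin")

CONDITIONS = ("CON", "IR")
PROTOCOLS = ("square_wave", "ramp")


class FormatError(ValueError):
    """Raised when a file does not follow the canonical breath-CSV dialect."""


class ValidationError(ValueError):
    """Raised when parsed data violate a physiological/structural invariant."""


@dataclass(frozen=True)
class BreathRecord:
    """A single breath: time (s from recording start) and gas-exchange values."""

    t: float
    vo2: float
    vco2: float
    ve: float | None = None
    hr: float | None = None


@dataclass
class SessionMeta:
    """Metadata of one recording session.

    Parameters
    ----------
    subject_id : str
        Free-form participant label.
    condition : {"CON", "IR"}
        Control or ischemia-reperfusion priming.
    protocol : {"square_wave", "ramp"}
        Constant-load transition or incremental ramp test.
    transition_onset : float
        Seconds from recording start at which the work-rate step (square wave)
        or the ramp begins.
    baseline_load : float
        Baseline work rate in W (20 W unloaded-equivalent pedalling).
    work_load : float, optional
        Square-wave target work rate in W.
    ramp_rate : float, optional
        Ramp slope in W·min⁻¹ (ramp protocol only).
    """

    subject_id: str
    condition: str
    protocol: str
    transition_onset: float
    baseline_load: float = 20.0
    work_load: float | None = None
    ramp_rate: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.protocol not in PROTOCOLS:
            raise ValidationError(f"protocol must be one of {PROTOCOLS}, got {self.protocol!r}")
        if self.protocol == "ramp" and self.ramp_rate is not None and self.ramp_rate <= 0:
            raise ValidationError("ramp_rate must be positive")
        if self.transition_onset < 0:
            raise ValidationError("transition_onset must be non-negative")


@dataclass
class BreathSeries:
    """An ordered breath-by-breath recording with its session metadata.

    Channels are stored as equal-length float arrays; missing optional values
    (``ve``, ``hr``) are NaN.
    """

    meta: SessionMeta
    t: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    ve: np.ndarray = field(default=None)  # type: ignore[assignment]
    hr: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        n = self.t.size
        if self.ve is None:
            self.ve = np.full(n, np.nan)
        if self.hr is None:
            self.hr = np.full(n, np.nan)
        self.ve = np.asarray(self.ve, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        self.validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return int(self.t.size)

    def __iter__(self) -> Iterator[BreathRecord]:
        for i in range(len(self)):
            yield BreathRecord(
                t=float(self.t[i]),
                vo2=float(self.vo2[i]),
                vco2=float(self.vco2[i]),
                ve=None if math.isnan(self.ve[i]) else float(self.ve[i]),
                hr=None if math.isnan(self.hr[i]) else float(self.hr[i]),
            )

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self)
        for name in ("vo2", "vco2", "ve", "hr"):
            if getattr(self, name).size != n:
                raise ValidationError(f"channel {name!r} length mismatch")
        if n < 2:
            raise ValidationError("a breath series needs at least 2 breaths")
        if not np.all(np.isfinite(self.t)):
            row = int(np.flatnonzero(~np.isfinite(self.t))[0])
            raise ValidationError(f"non-finite time at row {row + 1}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            row = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise ValidationError(
                f"breath times must be strictly increasing; violation at row {row + 1} "
                f"(t={self.t[row]:g} after t={self.t[row - 1]:g})"
            )
        for name in ("vo2", "vco2"):
            vals = getattr(self, name)
            if not np.all(np.isfinite(vals)):
                row = int(np.flatnonzero(~np.isfinite(vals))[0])
                raise ValidationError(f"missing/unparseable {name} at row {row + 1}")
            if np.any(vals < 0):
                row = int(np.flatnonzero(vals < 0)[0])
                raise ValidationError(f"negative {name} at row {row + 1}")
        finite_ve = self.ve[np.isfinite(self.ve)]
        if np.any(finite_ve < 0):
            raise ValidationError("negative ve value")
        finite_hr = self.hr[np.isfinite(self.hr)]
        if finite_hr.size and (np.any(finite_hr <= 0) or np.any(finite_hr >= 250)):
            raise ValidationError("hr values must lie in (0, 250) bpm or be missing")

    # -- convenience --------------------------------------------------------
    def channel(self, name: str) -> np.ndarray:
        """Return one channel array by short name (vo2, vco2, ve, hr)."""
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"no channel named {name!r}") from None

    def subset(self, keep: np.ndarray) -> "BreathSeries":
        """A new series keeping the breaths selected by a boolean/index mask."""
        return BreathSeries(
            meta=self.meta,
            t=self.t[keep],
            vo2=self.vo2[keep],
            vco2=self.vco2[keep],
            ve=self.ve[keep],
            hr=self.hr[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "vo2_lmin": self.vo2,
                "vco2_lmin": self.vco2,
                "ve_lmin": self.ve,
                "hr_bpm": self.hr,
            }
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_breath_csv(path: str | Path, meta: SessionMeta) -> BreathSeries:
    """Read a canonical breath CSV into a validated :class:`BreathSeries`.

    Raises
    ------
    FormatError
        If a required column is missing from the header.
    ValidationError
        If a required field fails to parse or an invariant is violated; the
        message names the offending (1-based) data row.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns and c not in ("ve_lmin", "hr_bpm")]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for col in ("ve_lmin", "hr_bpm"):
        if col not in df.columns:
            df[col] = np.nan
    # coerce; a required cell that does not parse becomes NaN and is reported
    for col in COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in REQUIRED_COLUMNS:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValidationError(f"{path}: unparseable {col} at row {int(bad[0]) + 1}")
    return BreathSeries(
        meta=meta,
        t=df["t_s"].to_numpy(),
        vo2=df["vo2_lmin"].to_numpy(),
        vco2=df["vco2_lmin"].to_numpy(),
        ve=df["ve_lmin"].to_numpy(),
        hr=df["hr_bpm"].to_numpy(),
    )


def write_breath_csv(series: BreathSeries, path: str | Path) -> Path:
    """Write a series to the canonical CSV dialect with full float precision.

    Missing optional values are written as empty cells; the output round-trips
    through :func:`read_breath_csv` bit-for-bit (``repr`` precision).
    """
    path = Path(path)
    series.validate()
    df = series.to_frame()
    df.to_csv(path, index=False, float_format="%.17g", na_rep="")
    return path


def write_session_meta(meta: SessionMeta, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(asdict(meta), fh, indent=2)
    return path


def read_session_meta(path: str | Path) -> SessionMeta:
    with open(path) as fh:
        payload = json.load(fh)
    return SessionMeta(**payload)
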