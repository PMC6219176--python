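"""Pregnancy record container and the tabular (CSV) schema.

One record describes a single woman/foetus observation close to delivery:
the antenatal measurements taken by a midwife (fundal height, gestational
age, foetal station, recorded estimated foetal weight), the delivery
outcomes (actual birth weight, neonatal head/abdominal circumference) and
the maternal covariates.  Batch work uses a pandas DataFrame with the
column names in :data:`RECORD_COLUMNS`; :func:`records_from_dataframe` and
:func:`records_to_dataframe` convert between the two representations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass, fields
from typing import Iterable, Optional

import pandas as pd

from .errors import ValidationFailure

#: Foetal station categories (position of the head relative to the ischial
#: spines).  These select the Johnson-Toshach subtractor.
STATION_ABOVE = "above_spines"
STATION_AT_OR_BELOW = "at_or_below_spines"
STATION_CATEGORIES = (STATION_ABOVE, STATION_AT_OR_BELOW)

_STATION_SYNONYMS = {
    "above": STATION_ABOVE,
    "above_spines": STATION_ABOVE,
    "floating": STATION_ABOVE,
    "at_or_below": STATION_AT_OR_BELOW,
    "at_or_below_spines": STATION_AT_OR_BELOW,
    "engaged": STATION_AT_OR_BELOW,
}

# Hard bounds: records outside these are rejected outright.
GA_HARD_BOUNDS = (25.0, 43.0)
# Soft bounds: values outside trigger a warning only.
FH_WARN_BOUNDS = (20.0, 45.0)


@dataclass
class PregnancyRecord:
    """A single observation; every field except ``fh_cm``/``ga_weeks`` is
    optional because register rows are frequently incomplete."""

    fh_cm: Optional[float] = None
    ga_weeks: Optional[float] = None
    fs: Optional[str] = None
    efw_recorded_g: Optional[float] = None
    abw_g: Optional[float] = None
    referred: bool = False
    maternal_age_yr: Optional[float] = None
    maternal_height_cm: Optional[float] = None
    maternal_weight_kg: Optional[float] = None
    maternal_bmi: Optional[float] = None
    arm_circumference_cm: Optional[float] = None
    haemoglobin_g_dl: Optional[float] = None
    birth_length_cm: Optional[float] = None
    neonatal_hc_cm: Optional[float] = None
    neonatal_ac_cm: Optional[float] = None
    hc_us_cm: Optional[float] = None
    ac_us_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fs is not None:
            key = str(self.fs).strip().lower()
            if key in ("", "nan", "none"):
                self.fs = None
            elif key in _STATION_SYNONYMS:
                self.fs = _STATION_SYNONYMS[key]
            else:
                raise ValidationFailure(
                    f"unknown foetal station category {self.fs!r}; "
                    f"expected one of {STATION_CATEGORIES}"
                )
        self._validate()

    def _validate(self) -> None:
        if self.ga_weeks is not None and not (
            GA_HARD_BOUNDS[0] <= self.ga_weeks <= GA_HARD_BOUNDS[1]
        ):
            raise ValidationFailure(
                f"gestational age {self.ga_weeks} weeks outside hard bounds "
                f"{GA_HARD_BOUNDS}"
            )
        if self.abw_g is not None and self.abw_g <= 0:
            raise ValidationFailure(f"actual birth weight must be positive, got {self.abw_g}")
        if self.fh_cm is not None and not (
            FH_WARN_BOUNDS[0] <= self.fh_cm <= FH_WARN_BOUNDS[1]
        ):
            warnings.warn(
                f"fundal height {self.fh_cm} cm outside the plausible range "
                f"{FH_WARN_BOUNDS}; keeping the record",
                stacklevel=3,
            )


RECORD_COLUMNS = [f.name for f in fields(PregnancyRecord)]


def _clean(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def record_from_mapping(row) -> PregnancyRecord:
    """Build a record from any mapping, ignoring unknown keys and NaNs."""
    payload = {}
    for name in RECORD_COLUMNS:
        if name in row:
            value = _clean(row[name])
            if name == "referred":
                value = bool(value) if value is not None else False
            payload[name] = value
    return PregnancyRecord(**payload)


def records_from_dataframe(frame: pd.DataFrame) -> list[PregnancyRecord]:
    return [record_from_mapping(row) for row in frame.to_dict("records")]


def records_to_dataframe(records: Iterable[PregnancyRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([asdict(r) for r in records], columns=RECORD_COLUMNS)
    return frame


def read_records_csv(path) -> list[PregnancyRecord]:
    return records_from_dataframe(pd.read_csv(path))


def write_records_csv(records: Iterable[PregnancyRecord], path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)
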