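"""Registry and evaluator for estimated-foetal-weight (EFW) formulas.

The registry holds three families of formulas, all returning grams:

``proposed``
    Four fundal-height regression models developed for ultrasound-free
    primary care: FH alone, FH + GA, and FH combined with a foetal HC or
    AC imputed from GA via a growth standard.
``clinical``
    Published fundal-height comparators (Johnson-Toshach, Risanto,
    Niswander, ...), linear in FH apart from the Johnson-Toshach
    station-dependent subtractor.
``ultrasonic``
    Published comparators driven by foetal HC/AC (Hadlock, Stirnemann, ...)
    or GA alone.  When a record carries no recorded ultrasound values the
    HC/AC inputs are imputed from GA through the growth standards, which is
    how such formulas are deployed in settings without ultrasound.

Formulas live in ``data/weight_formulas.yaml``; see that file for the term
encoding and for which comparator entries are approximate reconstructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import growth_standards
from .errors import LookupFailure, MissingPredictorError, ValidationFailure
from .records import PregnancyRecord, records_from_dataframe

DEFAULT_STANDARD = "australian"

FAMILIES = ("proposed", "clinical", "ultrasonic")


@dataclass(frozen=True)
class WeightModel:
    model_id: str
    family: str
    required_predictors: tuple[str, ...]
    form: str
    spec: dict
    provenance: str = "published"

    def required_inputs(self) -> set[str]:
        """Record-level inputs: imputed biometrics trace back to GA."""
        out: set[str] = set()
        for p in self.required_predictors:
            if p in ("HC_est_mm", "AC_est_mm"):
                out.add("GA_weeks")
            else:
                out.add(p)
        return out


def _load_registry() -> dict[str, WeightModel]:
    text = resources.files("fetalweight.data").joinpath("weight_formulas.yaml").read_text()
    registry = {}
    for entry in yaml.safe_load(text)["models"]:
        registry[entry["model_id"]] = WeightModel(
            model_id=entry["model_id"],
            family=entry["family"],
            required_predictors=tuple(entry["predictors"]),
            form=entry["form"],
            provenance=entry.get("provenance", "published"),
            spec=entry,
        )
    return registry


_REGISTRY = _load_registry()


def get_model(model_id: str) -> WeightModel:
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise LookupFailure(
            f"unknown weight model {model_id!r}; known: {sorted(_REGISTRY)}"
        ) from None


def list_models(family: Optional[str] = None) -> list[WeightModel]:
    models = [_REGISTRY[k] for k in _REGISTRY]
    if family is not None:
        if family not in FAMILIES:
            raise LookupFailure(f"unknown family {family!r}; known: {FAMILIES}")
        models = [m for m in models if m.family == family]
    return models


def required_inputs(model_id: str) -> set[str]:
    return get_model(model_id).required_inputs()


def _missing_predictors(model: WeightModel, record: PregnancyRecord) -> list[str]:
    missing = []
    for p in model.required_predictors:
        if p == "FH_cm" and record.fh_cm is None:
            missing.append(p)
        elif p == "GA_weeks" and record.ga_weeks is None:
            missing.append(p)
        elif p == "FS_category" and record.fs is None:
            missing.append(p)
        elif p in ("HC_est_mm", "AC_est_mm") and record.ga_weeks is None:
            missing.append(p)
        elif p == "HC_us" and record.hc_us_cm is None and record.ga_weeks is None:
            missing.append(p)
        elif p == "AC_us" and record.ac_us_cm is None and record.ga_weeks is None:
            missing.append(p)
    return missing


def _variable(name: str, record: PregnancyRecord, standard_id: str) -> float:
    if name == "FH_cm":
        return record.fh_cm
    if name == "GA_weeks":
        return record.ga_weeks
    if name == "HC_est_mm":
        return growth_standards.estimate_biometric(standard_id, "HC", record.ga_weeks)
    if name == "AC_est_mm":
        return growth_standards.estimate_biometric(standard_id, "AC", record.ga_weeks)
    if name == "HC_cm":
        if record.hc_us_cm is not None:
            return record.hc_us_cm
        return _variable("HC_est_mm", record, standard_id) / 10.0
    if name == "AC_cm":
        if record.ac_us_cm is not None:
            return record.ac_us_cm
        return _variable("AC_est_mm", record, standard_id) / 10.0
    if name == "HC_m":
        return _variable("HC_cm", record, standard_id) / 100.0
    if name == "AC_m":
        return _variable("AC_cm", record, standard_id) / 100.0
    raise LookupFailure(f"unknown formula variable {name!r}")


def predict_efw(
    model_id: str,
    record: PregnancyRecord,
    standard_id: str = DEFAULT_STANDARD,
) -> float:
    """Predicted foetal weight in grams for one record.

    ``standard_id`` selects the growth standard used for any GA-imputed
    biometric input (default Australian).
    """
    model = get_model(model_id)
    missing = _missing_predictors(model, record)
    if missing:
        raise MissingPredictorError(model_id, missing)

    spec = model.spec
    if model.form == "linear":
        value = 0.0
        for term in spec["terms"]:
            if "var" in term:
                value += term["coef"] * _variable(term["var"], record, standard_id)
            else:
                value += term["coef"]
        return float(value)
    if model.form == "fh_offset":
        offset = spec["offsets"][record.fs]
        return float(spec["scale"] * (record.fh_cm - offset))
    if model.form == "logscale":
        exponent = 0.0
        for term in spec["terms"]:
            part = term["coef"]
            for factor in term.get("factors", []):
                v = _variable(factor["var"], record, standard_id)
                part *= math.log(v) ** factor["pow"] if factor.get("log") else v ** factor["pow"]
            exponent += part
        return float(spec["base"] ** exponent)
    raise LookupFailure(f"unknown formula form {model.form!r}")  # pragma: no cover


def predict_batch(
    model_ids: Sequence[str],
    records,
    standard_id: str = DEFAULT_STANDARD,
) -> pd.DataFrame:
    """Record x model table of predictions (grams).

    Cells whose predictors cannot be satisfied are NaN rather than fatal.
    """
    if isinstance(records, pd.DataFrame):
        records = records_from_dataframe(records)
    model_ids = list(model_ids)
    if not model_ids:
        raise ValidationFailure("predict_batch requires at least one model id")
    for mid in model_ids:
        get_model(mid)  # fail fast on unknown ids
    table = np.full((len(records), len(model_ids)), np.nan)
    for i, record in enumerate(records):
        for j, mid in enumerate(model_ids):
            try:
                table[i, j] = predict_efw(mid, record, standard_id)
            except MissingPredictorError:
                pass
    return pd.DataFrame(table, columns=model_ids)
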