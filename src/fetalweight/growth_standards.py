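"""Gestational-age growth standards for foetal HC and AC.

Where ultrasound is unavailable, foetal head circumference (HC) and
abdominal circumference (AC) can be imputed from gestational age alone
using population growth standards.  Three published standards are shipped
(Australian, UK, INTERGROWTH-21st international); each maps decimal weeks
of gestation to a median circumference in millimetres over its validated
gestational-age window.

Curves are stored in ``data/growth_standards.yaml`` as sums of terms
``coef * GA**pow * ln(GA)**logpow``, which covers both plain polynomials
and the INTERGROWTH log-polynomial form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import yaml

from .errors import GARangeError, LookupFailure

STANDARD_IDS = ("australian", "uk", "international")
BIOMETRIES = ("HC", "AC")


@dataclass(frozen=True)
class GrowthStandard:
    """One (standard, biometry) curve: GA weeks -> millimetres."""

    standard_id: str
    biometry: str
    ga_valid_range: tuple[float, float]
    #: term list, each (coef, ga_power, log_ga_power)
    coefficients: tuple[tuple[float, float, float], ...]
    output_unit: str = "mm"
    provenance: str = ""

    def evaluate(self, ga: float) -> float:
        lo, hi = self.ga_valid_range
        if not lo <= ga <= hi:
            raise GARangeError(
                f"GA {ga} weeks outside the {self.standard_id} {self.biometry} "
                f"standard's valid range [{lo}, {hi}] weeks"
            )
        log_ga = math.log(ga)
        return sum(c * ga**p * log_ga**q for c, p, q in self.coefficients)

    def to_dict(self) -> dict:
        return {
            "standard_id": self.standard_id,
            "biometry": self.biometry,
            "ga_valid_range": list(self.ga_valid_range),
            "output_unit": self.output_unit,
            "provenance": self.provenance,
            "terms": [
                {"coef": c, "pow": p, "logpow": q} for c, p, q in self.coefficients
            ],
        }

    @classmethod
    def from_dict(cls, entry: dict) -> "GrowthStandard":
        return cls(
            standard_id=entry["standard_id"],
            biometry=entry["biometry"],
            ga_valid_range=tuple(entry["ga_valid_range"]),
            coefficients=tuple(
                (t["coef"], t.get("pow", 0), t.get("logpow", 0))
                for t in entry["terms"]
            ),
            output_unit=entry.get("output_unit", "mm"),
            provenance=entry.get("provenance", ""),
        )


def _load_registry() -> dict[tuple[str, str], GrowthStandard]:
    text = resources.files("fetalweight.data").joinpath("growth_standards.yaml").read_text()
    registry = {}
    for entry in yaml.safe_load(text)["standards"]:
        std = GrowthStandard.from_dict(entry)
        registry[(std.standard_id, std.biometry)] = std
    return registry


_REGISTRY = _load_registry()


def get_standard(standard_id: str, biometry: str) -> GrowthStandard:
    key = (str(standard_id).lower(), str(biometry).upper())
    if key[0] not in STANDARD_IDS:
        raise LookupFailure(
            f"unknown growth standard {standard_id!r}; known: {STANDARD_IDS}"
        )
    if key[1] not in BIOMETRIES:
        raise LookupFailure(f"unknown biometry {biometry!r}; known: {BIOMETRIES}")
    return _REGISTRY[key]


def estimate_biometric(standard_id: str, biometry: str, ga: float) -> float:
    """Median foetal HC or AC (mm) at gestational age ``ga`` (weeks)."""
    return get_standard(standard_id, biometry).evaluate(float(ga))


def list_standards() -> list[GrowthStandard]:
    """All registered (standard, biometry) curves: 3 standards x 2 biometrics."""
    return [ _REGISTRY[k] for k in sorted(_REGISTRY) ]
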