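"""Synthetic antenatal cohort generator.

Generates pregnancy registers whose marginal statistics, correlation
structure and eligibility flow mirror the primary-care cohort the
estimation toolkit is designed for:

* fundal height (FH) and gestational age (GA) are truncated normals
  (FH 32.2 +/- 2.4 cm on [27, 36]; GA 38.6 +/- 1.5 weeks on [32, 41])
  coupled through a Gaussian copula;
* the recorded estimated foetal weight is generated from the
  one-predictor FH backbone (EFW = -1538.3 + 150.3 FH) plus Gaussian
  noise calibrated so corr(FH, EFW_r) hits its target (0.952);
* actual birth weight adds further independent noise calibrated so
  corr(FH, ABW) hits its target (0.795), recentred to the cohort mean
  (3252.8 g) and redrawn into the normal-delivery band [2600, 4000) g;
* maternal covariates and neonatal HC/AC follow their marginals, with
  BMI derived from height and weight and only weak GA-linked correlation
  for the neonatal circumferences;
* an optional ineligible fraction reproduces the recruitment-flow
  exclusions (missing core fields, GA > 41 weeks, complication referral,
  abnormal birth weight).

Because the birth-weight band truncates the ABW noise, the closed-form
noise calibration is refined by a short deterministic Monte-Carlo loop so
the realized correlation still meets the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ValidationFailure
from .records import (
    STATION_ABOVE,
    STATION_AT_OR_BELOW,
    PregnancyRecord,
)

#: cohort baseline marginals: (mean, sd, min, max)
DEFAULT_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "maternal_age_yr": (27.6, 4.9, 16.0, 44.0),
    "maternal_height_cm": (156.5, 5.0, 148.0, 176.0),
    "maternal_weight_kg": (59.9, 7.5, 44.0, 83.0),
    "arm_circumference_cm": (25.5, 1.7, 22.0, 31.0),
    "haemoglobin_g_dl": (11.6, 0.7, 9.0, 13.2),
    "fh_cm": (32.2, 2.4, 27.0, 36.0),
    "ga_weeks": (38.6, 1.5, 32.0, 41.0),
    "birth_length_cm": (50.2, 2.0, 40.0, 56.0),
    "neonatal_hc_cm": (33.5, 1.3, 29.0, 37.0),
    "neonatal_ac_cm": (34.5, 1.9, 28.0, 37.0),
}

#: exclusion-reason mix of the recruitment flow (missing core fields,
#: GA > 41 weeks, complication referral, abnormal birth weight)
REGISTER_EXCLUSION_MIX = (3, 2, 6, 8)
REGISTER_INELIGIBLE_FRACTION = 19 / 146

REASON_MISSING = "missing_core_fields"
REASON_GA = "ga_gt_41"
REASON_REFERRED = "referred_complication"
REASON_ABW = "abnormal_birth_weight"
EXCLUSION_ORDER = (REASON_MISSING, REASON_GA, REASON_REFERRED, REASON_ABW)


def noise_calibration(target_r: float, predictor_sd: float, slope: float) -> float:
    """Noise SD sigma with corr(x, a + b x + eps) = target_r.

    Closed form: sigma = |b| SD_x sqrt(1 / r^2 - 1).
    """
    if not 0.0 < target_r < 1.0:
        raise ValidationFailure(f"target correlation must be in (0, 1), got {target_r}")
    if predictor_sd <= 0:
        raise ValidationFailure("predictor SD must be positive")
    return abs(slope) * predictor_sd * math.sqrt(1.0 / target_r**2 - 1.0)


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 127
    seed: int = 0
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    #: FH backbone of the recorded EFW (intercept, slope per cm FH)
    model_coefficients: tuple[float, float] = (-1538.3, 150.3)
    corr_fh_efw: float = 0.952
    corr_fh_abw: float = 0.795
    noise_sd_efw: Optional[float] = None  # grams; None -> calibrate
    noise_sd_abw: Optional[float] = None  # grams; None -> calibrate
    fh_ga_rho: float = 0.3
    #: target ABW cohort mean; None keeps ABW centred on the FH backbone
    #: (so the backbone model is exactly unbiased for ABW)
    abw_mean: Optional[float] = 3252.8
    abw_bounds: tuple[float, float] = (2600.0, 4000.0)  # half-open [lo, hi)
    neonatal_hc_ga_rho: float = 0.2
    neonatal_ac_ga_rho: float = 0.08
    fs_engaged_prob: float = 0.7
    ineligible_fraction: float = 0.0
    exclusion_mix: tuple[int, int, int, int] = REGISTER_EXCLUSION_MIX

    def __post_init__(self):
        if self.n < 1:
            raise ValidationFailure("n must be at least 1")
        for name, (mean, sd, lo, hi) in self.marginals.items():
            if sd <= 0:
                raise ValidationFailure(f"{name}: SD must be positive")
            if lo >= hi:
                raise ValidationFailure(f"{name}: min must be below max")
        if not 0.0 <= self.ineligible_fraction < 1.0:
            raise ValidationFailure("ineligible_fraction must be in [0, 1)")
        if not -1.0 < self.fh_ga_rho < 1.0:
            raise ValidationFailure("fh_ga_rho must be in (-1, 1)")

    @classmethod
    def register_mix(cls, **overrides) -> "GeneratorConfig":
        """Config emulating the raw register incl. ineligible records."""
        overrides.setdefault("ineligible_fraction", REGISTER_INELIGIBLE_FRACTION)
        return cls(**overrides)


def _trunc(marginal):
    mean, sd, lo, hi = marginal
    return stats.truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)


def _draw_fh_ga(config: GeneratorConfig, n: int, rng: np.random.Generator):
    rho = config.fh_ga_rho
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    u = stats.norm.cdf(z)
    fh = _trunc(config.marginals["fh_cm"]).ppf(u[:, 0])
    ga = _trunc(config.marginals["ga_weeks"]).ppf(u[:, 1])
    return fh, ga, z[:, 1]


def _abw_noise_sds(config: GeneratorConfig) -> tuple[float, float]:
    """Closed-form EFW/ABW noise SDs before the truncation refinement."""
    b0, b1 = config.model_coefficients
    sd_fh = _trunc(config.marginals["fh_cm"]).std()
    s1 = (
        config.noise_sd_efw
        if config.noise_sd_efw is not None
        else noise_calibration(config.corr_fh_efw, sd_fh, b1)
    )
    if config.noise_sd_abw is not None:
        return s1, config.noise_sd_abw
    signal_var = (b1 * sd_fh) ** 2
    total_noise = signal_var * (1.0 / config.corr_fh_abw**2 - 1.0)
    extra = total_noise - s1**2
    if extra <= 0:
        raise ConfigurationError(
            "corr(FH, ABW) target is infeasible given the corr(FH, EFW) target"
        )
    return s1, math.sqrt(extra)


def _draw_abw(efw, shift, s2, bounds, rng, max_iter: int = 1000):
    lo, hi = bounds
    abw = efw + shift + rng.normal(0.0, s2, efw.size)
    bad = (abw < lo) | (abw >= hi)
    it = 0
    while bad.any():
        abw[bad] = efw[bad] + shift + rng.normal(0.0, s2, int(bad.sum()))
        bad = (abw < lo) | (abw >= hi)
        it += 1
        if it > max_iter:  # pragma: no cover - Gaussian noise always escapes
            raise ConfigurationError("ABW truncation bounds appear infeasible")
    return abw


def _refine_abw_noise(config: GeneratorConfig, s1: float, s2: float, shift: float):
    """Deterministic MC refinement of the ABW noise SD and recentring shift.

    Redrawing ABW into [lo, hi) attenuates both the FH correlation and the
    mean; three fixed-seed iterations adjust s2 and the shift so the
    realized cohort hits the configured targets.
    """
    b0, b1 = config.model_coefficients
    sd_fh = _trunc(config.marginals["fh_cm"]).std()
    signal_var = (b1 * sd_fh) ** 2
    target_extra = signal_var * (1.0 / config.corr_fh_abw**2 - 1.0) - s1**2
    n_cal = 40_000
    for iteration in range(3):
        rng = np.random.default_rng([config.seed % (2**31), 9173, iteration])
        fh, _, _ = _draw_fh_ga(config, n_cal, rng)
        efw = b0 + b1 * fh + rng.normal(0.0, s1, n_cal)
        abw = _draw_abw(efw, shift, s2, config.abw_bounds, rng)
        r_obs = float(np.corrcoef(fh, abw)[0, 1])
        if config.abw_mean is not None:
            shift -= float(abw.mean()) - config.abw_mean
        observed_extra = signal_var * (1.0 / r_obs**2 - 1.0) - s1**2
        if observed_extra > 0 and target_extra > 0:
            s2 *= math.sqrt(target_extra / observed_extra)
    return s2, shift


def generate_cohort(config: GeneratorConfig) -> list[PregnancyRecord]:
    """Draw a cohort of ``config.n`` records; same seed, same cohort."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    b0, b1 = config.model_coefficients

    fh, ga, z_ga = _draw_fh_ga(config, n, rng)
    s1, s2 = _abw_noise_sds(config)
    if config.abw_mean is None:
        shift = 0.0
    else:
        shift = config.abw_mean - (b0 + b1 * _trunc(config.marginals["fh_cm"]).mean())
    s2, shift = _refine_abw_noise(config, s1, s2, shift)

    efw = b0 + b1 * fh + rng.normal(0.0, s1, n)
    abw = _draw_abw(efw, shift, s2, config.abw_bounds, rng)

    covariates = {
        name: _trunc(config.marginals[name]).ppf(rng.random(n))
        for name in (
            "maternal_age_yr",
            "maternal_height_cm",
            "maternal_weight_kg",
            "arm_circumference_cm",
            "haemoglobin_g_dl",
            "birth_length_cm",
        )
    }
    bmi = covariates["maternal_weight_kg"] / (covariates["maternal_height_cm"] / 100.0) ** 2

    neo = {}
    for name, rho in (
        ("neonatal_hc_cm", config.neonatal_hc_ga_rho),
        ("neonatal_ac_cm", config.neonatal_ac_ga_rho),
    ):
        latent = rho * z_ga + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        neo[name] = _trunc(config.marginals[name]).ppf(stats.norm.cdf(latent))

    engaged = rng.random(n) < config.fs_engaged_prob
    fs = np.where(engaged, STATION_AT_OR_BELOW, STATION_ABOVE)

    records = [
        PregnancyRecord(
            fh_cm=float(fh[i]),
            ga_weeks=float(ga[i]),
            fs=str(fs[i]),
            efw_recorded_g=float(efw[i]),
            abw_g=float(abw[i]),
            referred=False,
            maternal_age_yr=float(covariates["maternal_age_yr"][i]),
            maternal_height_cm=float(covariates["maternal_height_cm"][i]),
            maternal_weight_kg=float(covariates["maternal_weight_kg"][i]),
            maternal_bmi=float(bmi[i]),
            arm_circumference_cm=float(covariates["arm_circumference_cm"][i]),
            haemoglobin_g_dl=float(covariates["haemoglobin_g_dl"][i]),
            birth_length_cm=float(covariates["birth_length_cm"][i]),
            neonatal_hc_cm=float(neo["neonatal_hc_cm"][i]),
            neonatal_ac_cm=float(neo["neonatal_ac_cm"][i]),
        )
        for i in range(n)
    ]

    if config.ineligible_fraction > 0:
        records = _inject_ineligible(records, config, rng)
    return records


def _inject_ineligible(records, config: GeneratorConfig, rng: np.random.Generator):
    n = len(records)
    k = int(round(config.ineligible_fraction * n))
    if k == 0:
        return records
    chosen = rng.choice(n, size=k, replace=False)
    mix = np.asarray(config.exclusion_mix, dtype=float)
    reasons = rng.choice(len(mix), size=k, p=mix / mix.sum())
    for idx, reason in zip(chosen, reasons):
        r = records[idx]
        if reason == 0:  # missing core antenatal fields
            records[idx] = replace(r, fh_cm=None, ga_weeks=None, fs=None)
        elif reason == 1:  # delivered past 41 completed weeks
            records[idx] = replace(r, ga_weeks=float(rng.uniform(41.1, 43.0)))
        elif reason == 2:  # referred for a pregnancy complication
            records[idx] = replace(r, referred=True)
        else:  # abnormal birth weight (outside [2500, 4000) g)
            if rng.random() < 0.5:
                records[idx] = replace(r, abw_g=float(rng.uniform(1800.0, 2499.0)))
            else:
                records[idx] = replace(r, abw_g=float(rng.uniform(4000.0, 4600.0)))
    return records


def apply_eligibility(records: Sequence[PregnancyRecord]):
    """Split records into (included, excluded) by the recruitment rules.

    Exclusion reasons, first match wins: missing GA/FH/FS; GA > 41 weeks;
    complication referral; ABW outside [2500, 4000) g (a record with no
    recorded ABW cannot be confirmed normal and is excluded under the same
    reason).  Returns ``(included, excluded)`` where ``excluded`` is a list
    of ``(record, reason)`` pairs.
    """
    included, excluded = [], []
    for record in records:
        if record.ga_weeks is None or record.fh_cm is None or record.fs is None:
            excluded.append((record, REASON_MISSING))
        elif record.ga_weeks > 41.0:
            excluded.append((record, REASON_GA))
        elif record.referred:
            excluded.append((record, REASON_REFERRED))
        elif record.abw_g is None or not 2500.0 <= record.abw_g < 4000.0:
            excluded.append((record, REASON_ABW))
        else:
            included.append(record)
    return included, excluded


def cohort_summary(records: Sequence[PregnancyRecord]) -> dict:
    """Means/SDs and the headline correlations, for audit sidecars."""
    fh = np.array([r.fh_cm for r in records if r.fh_cm is not None], dtype=float)
    complete = [
        r
        for r in records
        if r.fh_cm is not None and r.efw_recorded_g is not None and r.abw_g is not None
    ]
    fh_c = np.array([r.fh_cm for r in complete])
    efw = np.array([r.efw_recorded_g for r in complete])
    abw = np.array([r.abw_g for r in complete])
    summary = {
        "n": len(records),
        "fh_mean_cm": float(fh.mean()) if fh.size else None,
        "fh_sd_cm": float(fh.std(ddof=1)) if fh.size > 1 else None,
        "abw_mean_g": float(abw.mean()) if abw.size else None,
        "abw_sd_g": float(abw.std(ddof=1)) if abw.size > 1 else None,
    }
    if len(complete) > 2:
        summary["corr_fh_efw"] = float(np.corrcoef(fh_c, efw)[0, 1])
        summary["corr_fh_abw"] = float(np.corrcoef(fh_c, abw)[0, 1])
    return summary
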