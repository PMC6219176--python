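"""Train/test protocol and prediction-accuracy metrics.

Records are split into development and assessment sets by independent
Bernoulli draws (train probability 0.7 by default).  Each weight model is
then scored on the test records that satisfy its predictors:

* MPE      mean signed prediction error, ``mean(ABW - EFW)`` in grams —
           positive means the model under-predicts birth weight;
* MAPE     mean of ``|100 (ABW - EFW) / ABW|`` in percent;
* MEDAPE   median of the same absolute percentages (robust to outliers);
* within10 percentage of estimates within 10% of ABW (boundary inclusive);
* error-normality p-value and a two-sample t-test of EFW vs ABW.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import weight_models
from .errors import DegenerateInputError, ValidationFailure
from .records import PregnancyRecord, records_from_dataframe
from .reliability import within_pct

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitConfig:
    train_probability: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_probability < 1.0:
            raise ValidationFailure(
                f"train probability must be in (0, 1), got {self.train_probability}"
            )


def split_bernoulli(records: Sequence, config: SplitConfig):
    """Independent Bernoulli(train_probability) assignment per record."""
    records = list(records)
    if not records:
        raise ValidationFailure("cannot split an empty record collection")
    rng = np.random.default_rng(config.seed)
    train_mask = rng.random(len(records)) < config.train_probability
    train = [r for r, m in zip(records, train_mask) if m]
    test = [r for r, m in zip(records, train_mask) if not m]
    logger.info("Bernoulli split: %d train / %d test", len(train), len(test))
    if not test:
        warnings.warn("Bernoulli split produced an empty test set", stacklevel=2)
    if not train:
        warnings.warn("Bernoulli split produced an empty training set", stacklevel=2)
    return train, test


@dataclass
class AccuracyReport:
    model_id: str
    n: int
    mpe: float  # grams, signed (ABW - EFW)
    mape: float  # percent
    medape: float  # percent
    within10: float  # percent
    error_normality_p: Optional[float] = None
    t_test_p: Optional[float] = None
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "n": self.n,
            "mpe_g": round(self.mpe, 2),
            "mape_pct": round(self.mape, 2),
            "medape_pct": round(self.medape, 2),
            "within10_pct": round(self.within10, 2),
            "error_normality_p": self.error_normality_p,
            "t_test_p": self.t_test_p,
            "note": self.note,
        }


def prediction_errors(abw, efw) -> dict[str, float]:
    """Core accuracy metrics for paired birth weights and predictions."""
    abw = np.asarray(abw, dtype=float)
    efw = np.asarray(efw, dtype=float)
    if abw.shape != efw.shape or abw.size < 1:
        raise ValidationFailure("abw and efw must be equal-length, non-empty")
    if np.any(abw <= 0):
        raise ValidationFailure("actual birth weights must be strictly positive")
    errors = abw - efw
    ape = np.abs(errors / abw) * 100.0
    return {
        "n": int(abw.size),
        "mpe": float(errors.mean()),
        "mape": float(ape.mean()),
        "medape": float(np.median(ape)),
        "within10": 100.0 * within_pct(abw, efw, 10.0),
    }


def two_sample_t(a, b, equal_var: bool = False) -> tuple[float, float]:
    """Two independent sample t-test (Welch by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationFailure("each sample needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise DegenerateInputError("both samples have zero variance")
    result = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(result.statistic), float(result.pvalue)


def compare_models(
    model_ids: Sequence[str],
    test_records,
    standard_id: str = weight_models.DEFAULT_STANDARD,
    sort_by: Optional[str] = "medape",
) -> list[AccuracyReport]:
    """Score each model on the test records it can serve.

    Records lacking a model's predictors are dropped from that model's n
    (complete-case per model); every report carries its own n.  Reports are
    ordered by ``sort_by`` (ascending MEDAPE by default, ``None`` keeps the
    input order).
    """
    if isinstance(test_records, pd.DataFrame):
        test_records = records_from_dataframe(test_records)
    test_records = list(test_records)
    if not test_records:
        raise ValidationFailure("compare_models requires a non-empty test set")
    if any(r.abw_g is None for r in test_records):
        raise ValidationFailure("every test record must carry an actual birth weight")

    abw_all = np.array([r.abw_g for r in test_records], dtype=float)
    predictions = weight_models.predict_batch(model_ids, test_records, standard_id)

    reports = []
    for mid in model_ids:
        efw = predictions[mid].to_numpy()
        mask = np.isfinite(efw)
        n = int(mask.sum())
        if n == 0:
            logger.info("model %s: no test record satisfies its predictors", mid)
            reports.append(
                AccuracyReport(
                    model_id=mid, n=0, mpe=math.nan, mape=math.nan,
                    medape=math.nan, within10=math.nan,
                    note="no record satisfies the model's predictors",
                )
            )
            continue
        if n < len(test_records):
            logger.info(
                "model %s: %d/%d records dropped (missing predictors)",
                mid, len(test_records) - n, len(test_records),
            )
        abw = abw_all[mask]
        core = prediction_errors(abw, efw[mask])
        report = AccuracyReport(
            model_id=mid,
            n=n,
            mpe=core["mpe"],
            mape=core["mape"],
            medape=core["medape"],
            within10=core["within10"],
        )
        errors = abw - efw[mask]
        if n >= 8 and np.ptp(errors) > 0:
            from .model_selection import residual_normality

            report.error_normality_p = residual_normality(errors)
        if n >= 2 and (np.ptp(abw) > 0 or np.ptp(efw[mask]) > 0):
            _, report.t_test_p = two_sample_t(efw[mask], abw)
        reports.append(report)

    if sort_by is not None:
        reports.sort(
            key=lambda r: (
                r.n == 0,
                getattr(r, sort_by) if math.isfinite(getattr(r, sort_by)) else math.inf,
            )
        )
    return reports


def reports_to_dataframe(reports: Sequence[AccuracyReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])


def medape_by_ga(
    test_records,
    predictions: pd.DataFrame,
    weeks: Sequence[int] = range(35, 42),
) -> pd.DataFrame:
    """MEDAPE stratified by completed gestational week (floor of GA).

    ``predictions`` is a record x model table aligned with ``test_records``
    (as produced by :func:`fetalweight.weight_models.predict_batch`).
    Strata with no scoreable record are omitted.
    """
    if isinstance(test_records, pd.DataFrame):
        test_records = records_from_dataframe(test_records)
    test_records = list(test_records)
    if any(r.ga_weeks is None for r in test_records):
        raise ValidationFailure("every record needs GA for stratification")
    ga_week = np.array([math.floor(r.ga_weeks) for r in test_records])
    abw = np.array([r.abw_g for r in test_records], dtype=float)

    rows = []
    for week in weeks:
        in_stratum = ga_week == week
        if not in_stratum.any():
            continue
        for mid in predictions.columns:
            efw = predictions[mid].to_numpy()[in_stratum]
            mask = np.isfinite(efw)
            if not mask.any():
                continue
            ape = np.abs((abw[in_stratum][mask] - efw[mask]) / abw[in_stratum][mask]) * 100
            rows.append(
                {
                    "ga_week": week,
                    "model_id": mid,
                    "n": int(mask.sum()),
                    "medape_pct": float(np.median(ape)),
                }
            )
    return pd.DataFrame(rows, columns=["ga_week", "model_id", "n", "medape_pct"])
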