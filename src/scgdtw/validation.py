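"""Cohort-level validation of the SCG-derived indexes.

Two proof-of-concept analyses over a cohort table of per-subject averaged
indexes and clinical LVEF assessments:

1. univariate ordinary-least-squares models of fractional LVEF against
   (a) PEP/LVET, (b) the Tei index, and (c) their mean, summarized by the
   coefficient of determination R^2;
2. univariate logistic GLMs (logit link, binomial family) scoring each
   subject, with ROC curves, trapezoidal AUC, and the Youden-optimal
   operating point, for distinguishing HFrEF subjects using (a) LVEF
   itself, (b) PEP/LVET, (c) Tei, (d) the mean of the two indexes.

Because the logistic score is monotone in a univariate predictor, the AUC
equals the rank AUC of the raw predictor (with the appropriate sign); this
equivalence is asserted in the test suite.

The module follows the Model/Results idiom: build a
:class:`CohortValidation` from subject records (or a DataFrame), call
``fit()``, and read estimates off the :class:`CohortValidationResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .io import records_to_frame
from .types import Disease, SubjectRecord

__all__ = [
    "LinearFit",
    "RocResult",
    "CohortSummary",
    "CohortValidation",
    "CohortValidationResults",
    "fit_linear",
    "roc_classify",
    "cohort_summary",
    "run_validation",
]


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of fractional LVEF on one predictor."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class RocResult:
    """ROC of a univariate logistic classifier.

    ``optimal_point`` is (fpr, tpr, cutoff) at the Youden-J maximum, with
    the cutoff mapped back to the predictor scale.
    """

    auc: float
    curve: np.ndarray  # (n, 2) columns fpr, tpr
    optimal_point: tuple[float, float, float]
    positive_label: str


@dataclass(frozen=True)
class CohortSummary:
    means: Mapping[str, float]
    sds: Mapping[str, float]
    sex_counts: Mapping[str, int]
    disease_counts: Mapping[str, int]
    cycles_total: int
    n: int


def fit_linear(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares of ``y`` (fractional LVEF) on ``x``.

    Raises on fewer than 3 points, non-finite values, or zero predictor
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need n >= 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression input")
    if np.ptp(x) == 0:
        raise ValueError("zero predictor variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        n=int(x.size),
    )


def roc_classify(
    predictor: Sequence[float],
    labels: Sequence[str | Disease],
    positive: str | Disease = Disease.HFREF,
) -> RocResult:
    """ROC analysis of a univariate logistic GLM.

    Fits ``P(positive) = logistic(b0 + b1 * predictor)``, uses the fitted
    probabilities as scores, sweeps all score thresholds for the ROC curve,
    integrates the AUC by trapezoid, and reports the Youden-optimal
    operating point with the score cutoff inverted back to the predictor
    scale.
    """
    x = np.asarray(predictor, dtype=float)
    positive = Disease(positive) if not isinstance(positive, Disease) else positive
    y = np.array([1 if Disease(l) == positive else 0 for l in labels])
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial())
    res = glm.fit()
    scores = np.asarray(res.fittedvalues, dtype=float)
    fpr, tpr, thresholds = _roc_curve(y, scores)
    roc_auc = float(_trapezoid_auc(fpr, tpr))
    j = tpr - fpr
    k = int(np.argmax(j))
    b0, b1 = float(res.params[0]), float(res.params[1])
    thr = float(thresholds[k])
    if np.isfinite(thr) and 0.0 < thr < 1.0 and b1 != 0.0:
        cutoff = (np.log(thr / (1.0 - thr)) - b0) / b1
    else:
        cutoff = float("nan")
    return RocResult(
        auc=roc_auc,
        curve=np.column_stack([fpr, tpr]),
        optimal_point=(float(fpr[k]), float(tpr[k]), float(cutoff)),
        positive_label=positive.value,
    )


def cohort_summary(records: Sequence[SubjectRecord]) -> CohortSummary:
    """Means, sample SDs, and class counts for a cohort table."""
    if not records:
        raise ValueError("empty cohort")
    frame = records_to_frame(records)
    sd = (lambda v: float(np.std(v, ddof=1))) if len(records) > 1 else (lambda v: 0.0)
    return CohortSummary(
        means={
            "age": float(frame.age.mean()),
            "lvef": float(frame.lvef.mean()),
            "cycles": float(frame.cycles.mean()),
        },
        sds={
            "age": sd(frame.age),
            "lvef": sd(frame.lvef),
            "cycles": sd(frame.cycles),
        },
        sex_counts=frame.sex.value_counts().to_dict(),
        disease_counts=frame.disease.value_counts().to_dict(),
        cycles_total=int(frame.cycles.sum()),
        n=len(records),
    )


#: Predictor label -> column recipe for the three linear models and the last
#: three ROC models.
_INDEX_PREDICTORS = ("pep_lvet", "tei", "mean_index")


def _predictor_values(frame: pd.DataFrame, name: str) -> np.ndarray:
    if name == "pep_lvet":
        return frame.pep_lvet_avg.to_numpy()
    if name == "tei":
        return frame.tei_avg.to_numpy()
    if name == "mean_index":
        return ((frame.pep_lvet_avg + frame.tei_avg) / 2.0).to_numpy()
    if name == "lvef":
        return frame.lvef.to_numpy()
    raise KeyError(name)


class CohortValidation:
    """Validation model over a cohort of subject records.

    Parameters
    ----------
    records : sequence of SubjectRecord
        The cohort; LVEF as fractions.
    positive : Disease
        Class treated as positive in the ROC analyses.
    """

    def __init__(self, records: Sequence[SubjectRecord], positive: Disease = Disease.HFREF):
        self.records = list(records)
        self.positive = Disease(positive)
        self.frame = records_to_frame(self.records)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "CohortValidation":
        """Build from a DataFrame shaped like :func:`scgdtw.io.records_to_frame`."""
        records = [
            SubjectRecord(
                subject_id=row.subject_id,
                sex=row.sex,
                age=float(row.age),
                lvef=float(row.lvef),
                disease=row.disease,
                cycles=int(row.cycles),
                pep_lvet_avg=float(row.pep_lvet_avg),
                pep_lvet_sd=float(row.pep_lvet_sd),
                tei_avg=float(row.tei_avg),
                tei_sd=float(row.tei_sd),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(records, **kwargs)

    def fit(self) -> "CohortValidationResults":
        frame = self.frame
        labels = frame.disease.tolist()
        linear = {
            name: fit_linear(_predictor_values(frame, name), frame.lvef.to_numpy())
            for name in _INDEX_PREDICTORS
        }
        roc = {
            name: roc_classify(_predictor_values(frame, name), labels, self.positive)
            for name in ("lvef", *_INDEX_PREDICTORS)
        }
        return CohortValidationResults(
            model=self,
            linear_fits=linear,
            roc_results=roc,
            summary_stats=cohort_summary(self.records),
        )


@dataclass
class CohortValidationResults:
    """Fitted validation statistics: linear fits, ROC results, cohort summary."""

    model: CohortValidation
    linear_fits: Mapping[str, LinearFit]
    roc_results: Mapping[str, RocResult]
    summary_stats: CohortSummary

    def to_dict(self) -> dict:
        """Machine-readable report."""
        return {
            "n": self.summary_stats.n,
            "cohort": {
                "means": dict(self.summary_stats.means),
                "sds": dict(self.summary_stats.sds),
                "sex_counts": dict(self.summary_stats.sex_counts),
                "disease_counts": dict(self.summary_stats.disease_counts),
                "cycles_total": self.summary_stats.cycles_total,
            },
            "linear": {
                k: {"slope": f.slope, "intercept": f.intercept, "r_squared": f.r_squared, "n": f.n}
                for k, f in self.linear_fits.items()
            },
            "roc": {
                k: {
                    "auc": r.auc,
                    "optimal_fpr": r.optimal_point[0],
                    "optimal_tpr": r.optimal_point[1],
                    "optimal_cutoff": r.optimal_point[2],
                    "positive_label": r.positive_label,
                }
                for k, r in self.roc_results.items()
            },
        }

    def summary(self) -> str:
        """Human-readable summary table."""
        s = self.summary_stats
        lines = [
            "Cohort validation results",
            "=" * 60,
            f"n = {s.n} subjects, {s.cycles_total} heartbeat cycles",
            f"age    {s.means['age']:.1f} +/- {s.sds['age']:.1f} years",
            f"LVEF   {100 * s.means['lvef']:.1f} +/- {100 * s.sds['lvef']:.1f} %",
            f"cycles {s.means['cycles']:.1f} +/- {s.sds['cycles']:.1f} per subject",
            "",
            "Linear models (LVEF fraction vs predictor)",
            f"{'predictor':<12} {'slope':>8} {'intercept':>10} {'R^2':>7}",
        ]
        for name, f in self.linear_fits.items():
            lines.append(f"{name:<12} {f.slope:>8.3f} {f.intercept:>10.3f} {f.r_squared:>7.3f}")
        lines += [
            "",
            f"ROC classification (positive = {next(iter(self.roc_results.values())).positive_label})",
            f"{'predictor':<12} {'AUC':>7} {'opt FPR':>8} {'opt TPR':>8} {'cutoff':>8}",
        ]
        for name, r in self.roc_results.items():
            fpr, tpr, cut = r.optimal_point
            lines.append(f"{name:<12} {r.auc:>7.3f} {fpr:>8.3f} {tpr:>8.3f} {cut:>8.3f}")
        return "\n".join(lines)


def run_validation(records: Sequence[SubjectRecord]) -> CohortValidationResults:
    """Convenience wrapper: build the validation model and fit it."""
    return CohortValidation(records).fit()
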