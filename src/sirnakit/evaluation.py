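"""Evaluation of efficacy predictors.

The evaluation surface has three parts: Pearson correlation between
observed and predicted efficacy; confusion-matrix metrics (Acc, Sn, Sp,
MCC) after calling an siRNA "high-efficacy" at >= 70% inhibition; and a
duplex-stability stratification that reports the correlation separately
for candidates with whole-duplex stacking energy >= -34.6 kcal/mol (the
high-confidence stratum) and below it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .io import Dataset, ValidationError
from .thermo import ThermoParams, whole_dG

EFFICACY_CALL_THRESHOLD = 70.0  # % inhibition defining a high-efficacy siRNA
DG_THRESHOLD = -34.6  # kcal/mol; ">=" stratum is the high-confidence one


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors (rather than returning 0) on
    zero-variance input so silent misuse cannot masquerade as 'no signal'."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("pearson_r needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("pearson_r undefined for zero-variance input")
    return float(stats.pearsonr(x, y)[0])


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def classify_and_count(
    predicted, observed, threshold: float = EFFICACY_CALL_THRESHOLD
) -> ConfusionCounts:
    """Tally the confusion matrix at a shared call threshold.

    A record is positive when its value is >= threshold (inclusive), for
    both the observed truth and the predicted call.
    """
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if len(predicted) != len(observed):
        raise ValidationError("predicted and observed lengths differ")
    truth = observed >= threshold
    call = predicted >= threshold
    return ConfusionCounts(
        TP=int(np.sum(truth & call)),
        FP=int(np.sum(~truth & call)),
        FN=int(np.sum(truth & ~call)),
        TN=int(np.sum(~truth & ~call)),
    )


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Acc, Sn, Sp (percent) and MCC from confusion counts.

    Sn (Sp) is reported as None when there are no actual positives
    (negatives).  An MCC denominator factor of zero yields MCC = 0 with a
    warning, keeping the score a total function.
    """
    if c.total == 0:
        raise ValidationError("empty confusion matrix")
    acc = 100.0 * (c.TP + c.TN) / c.total
    sn = 100.0 * c.TP / (c.TP + c.FN) if (c.TP + c.FN) else None
    sp = 100.0 * c.TN / (c.TN + c.FP) if (c.TN + c.FP) else None
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        warnings.warn("MCC denominator factor is zero; reporting MCC = 0", stacklevel=2)
        mcc = 0.0
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / np.sqrt(denom)
    return {"acc": acc, "sn": sn, "sp": sp, "mcc": float(mcc)}


@dataclass
class StratumReport:
    n: int
    r: float | None


@dataclass
class EvaluationReport:
    """Correlation + classification metrics, optionally dG-stratified."""

    r: float
    acc: float
    sn: float | None
    sp: float | None
    mcc: float
    n: int
    counts: ConfusionCounts
    dG_ge_threshold: StratumReport | None = None
    dG_lt_threshold: StratumReport | None = None
    dG_threshold: float | None = None
    in_sample: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def evaluate_predictions(
    predicted,
    observed,
    call_threshold: float = EFFICACY_CALL_THRESHOLD,
) -> EvaluationReport:
    """Overall report (no stratification) from aligned vectors."""
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    counts = classify_and_count(predicted, observed, call_threshold)
    m = metrics(counts)
    return EvaluationReport(
        r=pearson_r(predicted, observed),
        acc=m["acc"],
        sn=m["sn"],
        sp=m["sp"],
        mcc=m["mcc"],
        n=len(observed),
        counts=counts,
    )


def _stratum_r(pred: np.ndarray, obs: np.ndarray) -> float | None:
    if len(obs) < 3 or np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return None
    return pearson_r(pred, obs)


def stratified_evaluate(
    model,
    test: Dataset,
    dG_threshold: float = DG_THRESHOLD,
    params: ThermoParams | None = None,
    call_threshold: float = EFFICACY_CALL_THRESHOLD,
    in_sample: bool = False,
) -> EvaluationReport:
    """Evaluate a fitted predictor on a labeled dataset with dG strata.

    Records with whole-duplex stacking energy >= ``dG_threshold`` (the
    boundary value inclusive) form the high-confidence stratum; each
    stratum's Pearson r is reported when its n >= 3, else absent.
    """
    if not test.is_labeled:
        raise ValidationError("evaluation requires a labeled dataset")
    obs = np.asarray(test.efficacies, float)
    pred = np.asarray(model.predict(test.sequences), float)
    report = evaluate_predictions(pred, obs, call_threshold)
    dg = np.array([whole_dG(s, params) for s in test.sequences])
    ge = dg >= dG_threshold
    report.dG_ge_threshold = StratumReport(int(ge.sum()), _stratum_r(pred[ge], obs[ge]))
    report.dG_lt_threshold = StratumReport(
        int((~ge).sum()), _stratum_r(pred[~ge], obs[~ge])
    )
    report.dG_threshold = dG_threshold
    report.in_sample = in_sample
    return report
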