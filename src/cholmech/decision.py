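"""QIVIVE reverse dosimetry, rule-based cholestasis call and evaluation.

For each compound the predicted transporter IC50 (µM) is converted to a
plasma concentration in mg/L and divided by the closed-form steady-state
concentration at a unit oral dose rate, giving the daily dose (mg/kg/day)
whose steady-state plasma level equals the IC50 — valid because Css is
linear in dose.  A user correction factor K then divides the extrapolated
dose (K > 1 is conservative: it lowers the threshold and flags more
compounds; set ``invert_k=True`` for the multiplicative convention).

A compound votes "cholestatic" on a transporter when its therapeutic dose
T_D (converted to mg/kg/day) is strictly higher than the corrected in vivo
dose.  The OR rule calls a compound positive on at least one vote, AND on
all votes, MAJORITY on strictly more than half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from . import descriptors, pbtk
from .compound_io import CompoundRecord
from .qsar_panel import TransporterPanel

__all__ = [
    "Rule",
    "RuleConfig",
    "PredictionResult",
    "MetricsReport",
    "qivive_dose",
    "apply_correction",
    "classify",
    "predict_compound",
    "predict_batch",
    "evaluate",
]


class Rule(str, Enum):
    OR = "OR"
    AND = "AND"
    MAJORITY = "MAJORITY"


@dataclass(frozen=True)
class RuleConfig:
    """Decision hyperparameters: correction factor, transporters, logic rule."""

    selected: tuple
    rule: Rule = Rule.OR
    k: float = 1.0
    invert_k: bool = False  # True: K multiplies the in vivo dose instead

    def __post_init__(self):
        if not self.selected:
            raise ValueError("at least one transporter must be selected")
        if not (self.k > 0):
            raise ValueError("correction factor k must be > 0")
        object.__setattr__(self, "rule", Rule(self.rule))
        object.__setattr__(self, "selected", tuple(self.selected))


@dataclass(frozen=True)
class PredictionResult:
    """Per-compound outcome: corrected doses, verdict, score, agreement."""

    compound: CompoundRecord
    in_vivo_dose: Dict[str, float]  # transporter -> mg/kg/day, K-corrected
    td_per_kg: float  # mg/kg/day
    predicted: int
    score: float  # positive-vote fraction in [0, 1]
    rule_used: RuleConfig
    agrees: Optional[bool] = None


@dataclass(frozen=True)
class MetricsReport:
    """Binary-classification metrics with the underlying confusion counts."""

    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: float
    mcc: Optional[float]
    auc: Optional[float]

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "auc": self.auc,
        }


def qivive_dose(ic50_uM: float, mw: float, params: pbtk.PBTKParameters) -> float:
    """Oral dose rate (mg/kg/day) whose steady-state plasma level is the IC50.

    ``ic50`` in µM is converted to mg/L (``ic50 * MW / 1000``) and divided
    by the closed-form Css at 1 mg/kg/day; linearity of Css in dose makes
    this the exact inverse.
    """
    if ic50_uM < 0:
        raise ValueError("ic50 must be >= 0")
    if mw <= 0:
        raise ValueError("molecular weight must be > 0")
    c_mg_l = ic50_uM * mw / 1000.0
    css_unit = pbtk.css_analytic(params, 1.0)  # raises NoClearanceError if CL = 0
    return c_mg_l / css_unit


def apply_correction(dose: float, k: float, invert: bool = False) -> float:
    """Apply the correction factor K to an extrapolated in vivo dose.

    Default convention divides (larger K flags more compounds); ``invert``
    multiplies instead.
    """
    if not (k > 0):
        raise ValueError("correction factor k must be > 0")
    return dose * k if invert else dose / k


def classify(td_per_kg: float, doses: Mapping[str, float], config: RuleConfig) -> int:
    """Combine per-transporter votes into the binary cholestasis call.

    A transporter votes positive when T_D is strictly higher than its
    (already corrected) in vivo dose.
    """
    votes = _votes(td_per_kg, doses, config)
    return _combine(votes, config.rule)


def _votes(td_per_kg: float, doses: Mapping[str, float], config: RuleConfig) -> list[bool]:
    if td_per_kg is None or not math.isfinite(td_per_kg):
        raise ValueError("td_per_kg must be a finite number")
    missing = [t for t in config.selected if t not in doses]
    if missing:
        raise KeyError(f"missing in vivo dose for transporter(s): {missing}")
    return [td_per_kg > doses[t] for t in config.selected]


def _combine(votes: Sequence[bool], rule: Rule) -> int:
    n_pos = sum(votes)
    if rule is Rule.OR:
        return int(n_pos >= 1)
    if rule is Rule.AND:
        return int(n_pos == len(votes))
    return int(n_pos > len(votes) / 2.0)  # MAJORITY: strictly more than half


def predict_compound(
    record: CompoundRecord,
    panel: TransporterPanel,
    config: RuleConfig,
    *,
    params: Optional[pbtk.PBTKParameters] = None,
    expected_dose: Optional[float] = None,
    physiology_overrides: Optional[Mapping] = None,
) -> PredictionResult:
    """Full mechanistic pipeline for one compound.

    features -> per-transporter IC50 -> QIVIVE dose -> K correction ->
    rule vote against T_D.  ``expected_dose`` (mg/day) substitutes for a
    missing ``dose_max``.  The continuous score is the positive-vote
    fraction; ``agrees`` is set when an experimental label is present.
    """
    if params is None:
        params = pbtk.build_parameters(record, overrides=physiology_overrides)
    dose_max = record.dose_max if record.dose_max is not None else expected_dose
    if dose_max is None:
        raise ValueError(
            f"{record.name}: no exposure estimate (dose_max absent and no "
            "expected dose supplied)"
        )
    td_per_kg = dose_max / params.body_weight
    feats = descriptors.featurize(record.smiles).values
    mw = descriptors.molecular_weight(record.smiles)
    doses: Dict[str, float] = {}
    for transporter in config.selected:
        pred = panel.predict_ic50(transporter, feats)
        raw = qivive_dose(pred.ic50_uM, mw, params)
        doses[transporter] = apply_correction(raw, config.k, invert=config.invert_k)
    votes = _votes(td_per_kg, doses, config)
    predicted = _combine(votes, config.rule)
    agrees = None if record.activity is None else bool(predicted == record.activity)
    return PredictionResult(
        compound=record,
        in_vivo_dose=doses,
        td_per_kg=td_per_kg,
        predicted=predicted,
        score=sum(votes) / len(votes),
        rule_used=config,
        agrees=agrees,
    )


def predict_batch(
    records: Iterable[CompoundRecord],
    panel: TransporterPanel,
    config: RuleConfig,
    **kwargs,
) -> list[PredictionResult]:
    """``predict_compound`` over a table, input order preserved."""
    return [predict_compound(r, panel, config, **kwargs) for r in records]


def evaluate(results: Sequence[PredictionResult]) -> MetricsReport:
    """Confusion-matrix metrics of predictions against experimental labels.

    Only results whose compound carries an Activity label are evaluated.
    AUC is the midrank (Mann-Whitney) statistic over the continuous score;
    AUC and MCC are reported as None when only one class is present.
    """
    labelled = [r for r in results if r.compound.activity is not None]
    if not labelled:
        raise ValueError("no results with experimental activity labels")
    y_true = np.array([r.compound.activity for r in labelled], dtype=int)
    y_pred = np.array([r.predicted for r in labelled], dtype=int)
    scores = np.array([r.score for r in labelled], dtype=float)
    return compute_metrics(y_true, y_pred, scores)


def metrics_from_counts(tp, fp, tn, fn):
    """Vectorized sensitivity/specificity/accuracy/MCC from confusion counts.

    Accepts scalars or equal-shape arrays.  Empty margins give NaN for the
    affected rate; a vanishing MCC denominator gives 0 (the usual
    convention, matching sklearn).
    """
    tp, fp, tn, fn = (np.asarray(v, dtype=float) for v in (tp, fp, tn, fn))
    n = tp + fp + tn + fn
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        spec = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
        acc = np.where(n > 0, (tp + tn) / n, np.nan)
        denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = np.where(denom > 0, (tp * tn - fp * fn) / denom, 0.0)
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc, "mcc": mcc}


def compute_metrics(y_true, y_pred, scores=None) -> MetricsReport:
    """Metrics from label/prediction (and optional score) arrays."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    n = y_true.size
    if n == 0:
        raise ValueError("empty evaluation set")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    both_classes = (tp + fn) > 0 and (tn + fp) > 0
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None
    accuracy = (tp + tn) / n
    mcc = float(matthews_corrcoef(y_true, y_pred)) if both_classes else None
    auc = None
    if scores is not None and both_classes:
        auc = float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))
    return MetricsReport(
        n=n,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        mcc=mcc,
        auc=auc,
    )
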