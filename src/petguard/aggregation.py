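"""Patient-level aggregation, identity checking and evaluation metrics.

Per-image class probabilities become one patient-level sex label by majority
rule over hard per-image votes; age and weight estimates aggregate by the
median across views (robust to occasional bad views).  Patient predictions
are compared against claimed demographics and mismatches raised as alerts.

Binned confusion matrices use the clinical reporting convention: 18 age bins
(0-10, 11-15, ..., 86-90, >=91 years) and 14 weight bins (0-30, 31-35, ...,
86-90, >=91 kg).  The boundary between the first two age bins is resolved as
age < 11 -> first bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError
from .model import SEX_CLASSES
from .phantom import Demographics

__all__ = [
    "PatientPrediction",
    "AlertReport",
    "MetricsReport",
    "majority_vote",
    "aggregate_regression",
    "check_identity",
    "evaluate",
    "age_bin",
    "weight_bin",
    "N_AGE_BINS",
    "N_WEIGHT_BINS",
    "DEFAULT_AGE_TOL",
    "DEFAULT_WEIGHT_TOL",
]

N_AGE_BINS = 18
N_WEIGHT_BINS = 14

# Alert tolerances: the regression models are empirically accurate to about
# +-10 years and +-6 kg, so those bands are the default alert thresholds.
DEFAULT_AGE_TOL = 10.0
DEFAULT_WEIGHT_TOL = 6.0


@dataclass
class PatientPrediction:
    patient_id: str
    sex_label: str | None = None
    vote_fraction: float = np.nan
    mean_prob: float = np.nan
    tie_broken: bool = False
    age_estimate: float | None = None
    weight_estimate: float | None = None
    n_images: int = 0
    view_labels: list = field(default_factory=list)  # per-image hard labels


@dataclass
class AlertReport:
    patient_id: str
    sex_mismatch: bool | None
    age_mismatch: bool | None
    weight_mismatch: bool | None
    thresholds: tuple[float, float]
    details: str = ""

    @property
    def any_mismatch(self) -> bool:
        return any(f is True for f in (self.sex_mismatch, self.age_mismatch, self.weight_mismatch))

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "sex_mismatch": self.sex_mismatch,
            "age_mismatch": self.age_mismatch,
            "weight_mismatch": self.weight_mismatch,
            "age_tol": self.thresholds[0],
            "weight_tol": self.thresholds[1],
            "details": self.details,
        }


@dataclass
class MetricsReport:
    image_accuracy: float = np.nan
    patient_accuracy: float = np.nan
    per_sex_accuracy: dict = field(default_factory=dict)
    per_sex_image_accuracy: dict = field(default_factory=dict)
    within_tolerance_fractions: dict = field(default_factory=dict)
    age_confusion: np.ndarray | None = None
    weight_confusion: np.ndarray | None = None
    n_patients: int = 0
    n_images: int = 0

    def to_dict(self) -> dict:
        d = {
            "image_accuracy": self.image_accuracy,
            "patient_accuracy": self.patient_accuracy,
            "per_sex_accuracy": dict(self.per_sex_accuracy),
            "per_sex_image_accuracy": dict(self.per_sex_image_accuracy),
            "within_tolerance_fractions": dict(self.within_tolerance_fractions),
            "n_patients": self.n_patients,
            "n_images": self.n_images,
        }
        if self.age_confusion is not None:
            d["age_confusion"] = self.age_confusion.tolist()
        if self.weight_confusion is not None:
            d["weight_confusion"] = self.weight_confusion.tolist()
        return d


def majority_vote(image_probs) -> tuple[str, float, float, bool]:
    """Aggregate per-image class probabilities to one patient label.

    Each image casts a hard vote for its argmax class; the most frequent
    class wins.  A tie (possible only for even image counts) is broken by
    the larger mean class probability and flagged as low-confidence.

    Returns ``(label, vote_fraction, mean_winner_prob, tie_broken)``.
    """
    probs = np.asarray(image_probs, dtype=float)
    if probs.size == 0:
        raise EmptyInputError("majority_vote requires at least one image prediction")
    if probs.ndim != 2 or probs.shape[1] != len(SEX_CLASSES):
        raise ConfigurationError("expected an (n_images, 2) probability array")
    if np.any(probs < 0) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ConfigurationError("rows must be probability vectors summing to 1")
    votes = probs.argmax(axis=1)
    counts = np.bincount(votes, minlength=len(SEX_CLASSES))
    mean_probs = probs.mean(axis=0)
    tie = counts[0] == counts[1]
    if tie:
        winner = int(np.argmax(mean_probs))
    else:
        winner = int(np.argmax(counts))
    n = len(votes)
    return SEX_CLASSES[winner], counts[winner] / n, float(mean_probs[winner]), bool(tie)


def aggregate_regression(estimates, method: str = "median") -> float:
    """Aggregate per-view scalar estimates to one patient value."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise EmptyInputError("aggregate_regression requires estimates")
    if method == "median":
        return float(np.median(est))
    if method == "mean":
        return float(np.mean(est))
    raise ConfigurationError(f"unknown aggregation method {method!r}")


def check_identity(
    pred: PatientPrediction,
    claimed: Demographics | dict,
    age_tol: float = DEFAULT_AGE_TOL,
    weight_tol: float = DEFAULT_WEIGHT_TOL,
) -> AlertReport:
    """Compare a patient prediction with the claimed demographics.

    A missing claimed field yields flag ``None`` ('unverifiable') rather than
    a silent pass; a missing prediction for a task likewise.
    """
    if isinstance(claimed, Demographics):
        claimed = {"sex": claimed.sex, "age": claimed.age, "weight": claimed.weight}
    details = []

    def _flag(pred_v, claim_v, tol, name):
        if claim_v is None:
            details.append(f"{name}: claimed value missing, unverifiable")
            return None
        if pred_v is None:
            details.append(f"{name}: no prediction, unverifiable")
            return None
        if tol is None:  # categorical
            bad = pred_v != claim_v
        else:
            bad = abs(pred_v - claim_v) > tol
        if bad:
            details.append(f"{name}: predicted {pred_v} vs claimed {claim_v}")
        return bool(bad)

    sex_flag = _flag(pred.sex_label, claimed.get("sex"), None, "sex")
    age_flag = _flag(pred.age_estimate, claimed.get("age"), age_tol, "age")
    weight_flag = _flag(pred.weight_estimate, claimed.get("weight"), weight_tol, "weight")
    return AlertReport(
        patient_id=pred.patient_id,
        sex_mismatch=sex_flag,
        age_mismatch=age_flag,
        weight_mismatch=weight_flag,
        thresholds=(age_tol, weight_tol),
        details="; ".join(details) or "all checks passed",
    )


def age_bin(age: float) -> int:
    """18 bins: 0-10, 11-15, ..., 86-90, >=91."""
    if age < 11:
        return 0
    if age >= 91:
        return N_AGE_BINS - 1
    return 1 + int((age - 11) // 5)


def weight_bin(weight: float) -> int:
    """14 bins: 0-30, 31-35, ..., 86-90, >=91."""
    if weight < 31:
        return 0
    if weight >= 91:
        return N_WEIGHT_BINS - 1
    return 1 + int((weight - 31) // 5)


def evaluate(
    patient_predictions: list[PatientPrediction],
    truths: dict[str, Demographics],
) -> MetricsReport:
    """Image- and patient-level accuracies, tolerance fractions and confusion
    matrices for whichever tasks the predictions carry."""
    ids_pred = {p.patient_id for p in patient_predictions}
    ids_true = set(truths)
    if ids_pred != ids_true:
        missing = sorted(ids_pred ^ ids_true)
        raise ConfigurationError(f"prediction/truth id mismatch: {missing[:10]}")

    rep = MetricsReport(n_patients=len(patient_predictions))
    has_sex = all(p.sex_label is not None for p in patient_predictions)
    if has_sex:
        img_ok = img_tot = 0
        sex_ok: dict[str, list[int]] = {s: [0, 0] for s in SEX_CLASSES}
        sex_img: dict[str, list[int]] = {s: [0, 0] for s in SEX_CLASSES}
        pat_ok = 0
        for p in patient_predictions:
            t = truths[p.patient_id].sex
            pat_ok += p.sex_label == t
            sex_ok[t][0] += p.sex_label == t
            sex_ok[t][1] += 1
            for lbl in p.view_labels:
                img_ok += lbl == t
                sex_img[t][0] += lbl == t
                sex_img[t][1] += 1
                img_tot += 1
        rep.patient_accuracy = pat_ok / len(patient_predictions)
        rep.per_sex_accuracy = {s: (c / n if n else np.nan) for s, (c, n) in sex_ok.items()}
        if img_tot:
            rep.image_accuracy = img_ok / img_tot
            rep.per_sex_image_accuracy = {
                s: (c / n if n else np.nan) for s, (c, n) in sex_img.items()
            }
            rep.n_images = img_tot

    if all(p.age_estimate is not None for p in patient_predictions):
        err = np.array(
            [p.age_estimate - truths[p.patient_id].age for p in patient_predictions]
        )
        rep.within_tolerance_fractions["age_within_5y"] = float(np.mean(np.abs(err) < 5))
        rep.within_tolerance_fractions["age_within_10y"] = float(np.mean(np.abs(err) <= 10))
        conf = np.zeros((N_AGE_BINS, N_AGE_BINS), dtype=int)
        for p in patient_predictions:
            conf[age_bin(truths[p.patient_id].age), age_bin(p.age_estimate)] += 1
        rep.age_confusion = conf

    if all(p.weight_estimate is not None for p in patient_predictions):
        err = np.array(
            [p.weight_estimate - truths[p.patient_id].weight for p in patient_predictions]
        )
        rep.within_tolerance_fractions["weight_within_5kg"] = float(np.mean(np.abs(err) < 5))
        rep.within_tolerance_fractions["weight_within_6kg"] = float(np.mean(np.abs(err) <= 6))
        conf = np.zeros((N_WEIGHT_BINS, N_WEIGHT_BINS), dtype=int)
        for p in patient_predictions:
            conf[weight_bin(truths[p.patient_id].weight), weight_bin(p.weight_estimate)] += 1
        rep.weight_confusion = conf

    return rep


def confusion_to_csv(conf: np.ndarray, path) -> None:
    pd.DataFrame(conf).to_csv(path, index=False)
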