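"""Score-based classifier evaluation: AUC, confusion matrices, Matthews
correlation, and the MCC-maximizing score cutoff used to define the
low-genetic-risk stratum.

Conventions: a sample is predicted a case when its score is strictly above
the cutoff, so "low risk" is the inclusive condition score <= cutoff.
Candidate cutoffs are midpoints between consecutive distinct scores (plus
sentinels below the minimum and above the maximum) so the inclusive rule is
unambiguous under floating-point equality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_cases if self.n_cases else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / self.n_controls if self.n_controls else float("nan")


@dataclass(frozen=True)
class CutoffReport:
    """The selected score cutoff with its operating characteristics."""

    cutoff: float
    mcc: float
    sensitivity: float
    specificity: float
    confusion: ConfusionMatrix
    auc: float

    def to_frame(self) -> pd.DataFrame:
        c = self.confusion
        return pd.DataFrame(
            [
                {
                    "cutoff": self.cutoff,
                    "mcc": self.mcc,
                    "auc": self.auc,
                    "tp": c.tp,
                    "fp": c.fp,
                    "tn": c.tn,
                    "fn": c.fn,
                    "sensitivity": self.sensitivity,
                    "specificity": self.specificity,
                    "pct_low_cases": round(100 * c.fn / c.n_cases, 1),
                    "pct_low_controls": round(100 * c.tn / c.n_controls, 1),
                }
            ]
        )


def _check_two_classes(labels: np.ndarray) -> None:
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("both classes must be present")


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    The fraction of (case, control) pairs where the case scores higher, with
    ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    ranks = rankdata(scores)  # average ranks handle ties
    n1 = int((labels == 1).sum())
    n0 = len(labels) - n1
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n1 * (n1 + 1) / 2) / (n1 * n0)


def mcc(c: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(den)


def confusion_at(scores, labels, cutoff: float) -> ConfusionMatrix:
    """Confusion matrix for the rule: predicted case iff score > cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores > cutoff
    return ConfusionMatrix(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def best_mcc_cutoff(scores, labels) -> CutoffReport:
    """Scan all candidate cutoffs and return the MCC-maximizing report.

    Candidates are midpoints between consecutive distinct scores plus
    sentinels below the minimum and above the maximum; ties in MCC resolve to
    the smallest cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    distinct = np.unique(scores)
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    cases = np.sort(scores[labels == 1])
    ctrls = np.sort(scores[labels == 0])
    n1, n0 = len(cases), len(ctrls)
    tp = n1 - np.searchsorted(cases, candidates, side="right")
    fp = n0 - np.searchsorted(ctrls, candidates, side="right")
    fn = n1 - tp
    tn = n0 - fp
    tpf, fpf, tnf, fnf = (a.astype(float) for a in (tp, fp, tn, fn))
    den = (tpf + fpf) * (tpf + fnf) * (tnf + fpf) * (tnf + fnf)
    with np.errstate(invalid="ignore", divide="ignore"):
        mccs = np.where(den > 0, (tpf * tnf - fpf * fnf) / np.sqrt(den), 0.0)
    best = int(np.argmax(mccs))  # first max -> smallest cutoff
    cut = float(candidates[best])
    conf = ConfusionMatrix(tp=int(tp[best]), fp=int(fp[best]),
                           tn=int(tn[best]), fn=int(fn[best]))
    return CutoffReport(
        cutoff=cut,
        mcc=float(mccs[best]),
        sensitivity=conf.sensitivity,
        specificity=conf.specificity,
        confusion=conf,
        auc=auc(scores, labels),
    )


def stratify(scores, labels, cutoff: float):
    """Split samples at the cutoff: low risk iff score <= cutoff (inclusive).

    Returns (low_mask, high_mask, confusion, proportions) where proportions
    reports the percentage of each class falling in the low stratum, rounded
    to one decimal for reporting.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    low = scores <= cutoff
    conf = confusion_at(scores, labels, cutoff)
    n_cases = max(conf.n_cases, 1)
    n_controls = max(conf.n_controls, 1)
    proportions = {
        "pct_low_cases": round(100.0 * conf.fn / n_cases, 1),
        "pct_low_controls": round(100.0 * conf.tn / n_controls, 1),
    }
    return low, ~low, conf, proportions
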