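"""Turning per-pair confidence scores into interaction calls and evaluating them.

A screening run scores every candidate protein pair (all-against-all over a
monomer set) and calls a pair interacting when its score clears a threshold
(inclusive). Evaluation uses the usual confusion-matrix statistics —

    TPR = Recall = TP / (TP + FN)
    FPR = FP / (TN + FP)
    Precision = TP / (TP + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

— plus ROC / precision-recall curves swept over the distinct score values,
and the normalized AUC_0.1: the area under the ROC curve up to FPR = 0.1
divided by 0.1, so random guessing scores about 0.05 and a perfect
classifier 1.0. The low-FPR regime is what matters when most candidate
pairs are non-interacting.

The C-filter restricts a positive set to pairs whose monomers each appear at
most C times in that set; frequent monomers tend to come from large
assemblies whose members co-purify without touching, so sweeping C separates
direct interactions from assembly-mediated co-membership.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import ParameterError
from .types import CurvePoint, LabeledScore


def all_pairs(monomer_ids: list[str]) -> list[tuple[str, str]]:
    """All n*(n-1)/2 unordered distinct pairs, lexicographically sorted."""
    if len(set(monomer_ids)) != len(monomer_ids):
        raise ParameterError("monomer ids must be unique")
    return list(combinations(sorted(monomer_ids), 2))


@dataclass(frozen=True)
class ConfusionResult:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    recall = tpr

    @property
    def fpr(self) -> float | None:
        neg = self.tn + self.fp
        return self.fp / neg if neg else None

    @property
    def precision(self) -> float | None:
        called = self.tp + self.fp
        return self.tp / called if called else None

    @property
    def mcc(self) -> float | None:
        """Matthews correlation; None (NA) when any marginal is zero."""
        m1, m2 = self.tp + self.fn, self.tp + self.fp
        m3, m4 = self.tn + self.fp, self.tn + self.fn
        if 0 in (m1, m2, m3, m4):
            return None
        return (self.tp * self.tn - self.fp * self.fn) / math.sqrt(
            float(m1) * m2 * m3 * m4
        )


def confusion(scores: list[LabeledScore], threshold: float) -> ConfusionResult:
    """Confusion counts with predicted-positive defined as score >= threshold."""
    tp = fp = tn = fn = 0
    for s in scores:
        called = s.score >= threshold
        if called and s.label:
            tp += 1
        elif called:
            fp += 1
        elif s.label:
            fn += 1
        else:
            tn += 1
    return ConfusionResult(tp=tp, fp=fp, tn=tn, fn=fn)


def roc_pr_curves(scores: list[LabeledScore]) -> list[CurvePoint]:
    """ROC / PR operating points swept over the distinct scores, descending.

    Tied scores are grouped at one threshold. The returned list starts at
    the call-nothing point (FPR = TPR = 0, threshold +inf) and ends at the
    call-everything point (FPR = TPR = 1).
    """
    n_pos = sum(1 for s in scores if s.label)
    n_neg = len(scores) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("both classes must be present to sweep a curve")
    order = sorted(scores, key=lambda s: -s.score)
    points = [CurvePoint(threshold=math.inf, tpr=0.0, fpr=0.0, precision=None)]
    tp = fp = 0
    i = 0
    while i < len(order):
        t = order[i].score
        while i < len(order) and order[i].score == t:
            if order[i].label:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append(
            CurvePoint(
                threshold=t,
                tpr=tp / n_pos,
                fpr=fp / n_neg,
                precision=tp / (tp + fp),
            )
        )
    return points


def auc_fpr_limited(curve: list[CurvePoint], max_fpr: float) -> float:
    """Step-integrate TPR dFPR over [0, max_fpr] (no trapezoids), normalized.

    Between consecutive operating points the step takes the left point's
    TPR, matching threshold-sweep ROC conventions; the curve is right-
    extended at its last TPR if needed.
    """
    if not (0 < max_fpr <= 1):
        raise ParameterError(f"max_fpr must be in (0, 1], got {max_fpr}")
    pts = sorted(curve, key=lambda p: (p.fpr, p.tpr))
    area = 0.0
    for left, right in zip(pts, pts[1:]):
        lo = min(left.fpr, max_fpr)
        hi = min(right.fpr, max_fpr)
        area += left.tpr * (hi - lo)
    last = pts[-1]
    if last.fpr < max_fpr:
        area += last.tpr * (max_fpr - last.fpr)
    return area / max_fpr


def auc_01(curve: list[CurvePoint]) -> float:
    """Normalized AUC_0.1: ROC area on FPR in [0, 0.1], divided by 0.1."""
    return auc_fpr_limited(curve, 0.1)


def c_filter(
    positives: list[LabeledScore], c: int | float | None
) -> list[LabeledScore]:
    """Keep pairs whose monomers each appear <= C times in the positive set.

    Appearance counts are computed on the full positive set before any
    filtering. C = None (or inf) disables filtering entirely.
    """
    if c is None or c == math.inf:
        return list(positives)
    if c < 1:
        raise ParameterError(f"C must be >= 1, got {c}")
    counts: dict[str, int] = {}
    for s in positives:
        for mid in s.pair:
            counts[mid] = counts.get(mid, 0) + 1
    return [
        s for s in positives if counts[s.pair[0]] <= c and counts[s.pair[1]] <= c
    ]


def screen_with_c_filter(
    scores: list[LabeledScore], c: int | float | None
) -> list[LabeledScore]:
    """Apply the C-filter to the positive subset and keep all negatives."""
    positives = [s for s in scores if s.label]
    kept = set(s.pair for s in c_filter(positives, c))
    return [s for s in scores if not s.label or s.pair in kept]


def evaluate_screening(
    scores: list[LabeledScore],
    mcc_threshold: float | None = None,
    c_values: list[int] | None = None,
) -> dict:
    """One-call summary: curve, AUC_0.1, and optional MCC / C-filter sweeps."""
    curve = roc_pr_curves(scores)
    out: dict = {
        "n": len(scores),
        "n_positive": sum(1 for s in scores if s.label),
        "auc_01": auc_01(curve),
    }
    if mcc_threshold is not None:
        cm = confusion(scores, mcc_threshold)
        out["confusion_at_threshold"] = {
            "threshold": mcc_threshold,
            "tp": cm.tp,
            "fp": cm.fp,
            "tn": cm.tn,
            "fn": cm.fn,
            "tpr": cm.tpr,
            "fpr": cm.fpr,
            "precision": cm.precision,
            "mcc": cm.mcc,
        }
    if c_values:
        sweeps = {}
        for c in c_values:
            sub = screen_with_c_filter(scores, c)
            n_pos = sum(1 for s in sub if s.label)
            entry: dict = {"n_positive": n_pos}
            if n_pos > 0:
                entry["auc_01"] = auc_01(roc_pr_curves(sub))
            sweeps[str(c)] = entry
        out["c_filter"] = sweeps
    return out
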