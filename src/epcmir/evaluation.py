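"""ROC construction, operating points and the paired DeLong test.

AUC is the Mann-Whitney probability that an event sample scores above a
non-event sample, ties counted 1/2.  Operating points report sensitivity,
specificity, PPV and NPV at a cutoff chosen by Youden's J (ties broken
toward higher specificity) or supplied explicitly; predicted-positive means
score >= cutoff, with cutoffs taken at observed score values.  The paired
DeLong test compares two correlated AUCs computed on the same samples using
per-sample placement values and a normal reference for the standardized
AUC difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["auc", "roc_analysis", "operating_point", "delong_paired",
           "ROCResult", "DeLongResult"]


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return y


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties counted 1/2."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    ranks = stats.rankdata(s)  # midranks
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class ROCResult:
    """ROC points plus metrics at one operating point."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n_event: int
    n_nonevent: int
    cutoff_rule: str
    degenerate_ppv: bool = False
    degenerate_npv: bool = False

    def metrics_row(self, name: str) -> dict:
        return {"model": name, "AUC": self.auc, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "PPV": self.ppv, "NPV": self.npv,
                "cutoff": self.cutoff, "cutoff_rule": self.cutoff_rule}


def _point_metrics(s: np.ndarray, y: np.ndarray, cutoff: float):
    pred = s >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    deg_ppv = (tp + fp) == 0
    deg_npv = (tn + fn) == 0
    ppv = 1.0 if deg_ppv else tp / (tp + fp)
    npv = 1.0 if deg_npv else tn / (tn + fn)
    return sens, spec, ppv, npv, deg_ppv, deg_npv


def operating_point(scores, labels, rule="youden"):
    """Cutoff and confusion-derived metrics at that cutoff.

    ``rule`` is ``"youden"`` or ``("fixed", c)``.  Youden maximizes
    sensitivity + specificity - 1 over observed score cutoffs; exact ties go
    to the cutoff with higher specificity.  An empty predicted-positive
    (or -negative) set reports PPV (NPV) as 1.0 with a degeneracy warning.
    Returns (cutoff, sens, spec, ppv, npv, degenerate_flags).
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    if isinstance(rule, tuple) and rule[0] == "fixed":
        cutoff = float(rule[1])
    elif rule == "youden":
        best = None
        for c in np.unique(s):
            sens, spec, *_ = _point_metrics(s, y, c)
            j = sens + spec - 1.0
            key = (j, spec)
            if best is None or key > best[0]:
                best = (key, c)
        cutoff = float(best[1])
    else:
        raise ValueError(f"unknown cutoff rule: {rule!r}")
    sens, spec, ppv, npv, deg_ppv, deg_npv = _point_metrics(s, y, cutoff)
    if deg_ppv or deg_npv:
        warnings.warn("degenerate operating point: empty predicted class; PV reported as 1.0")
    return cutoff, sens, spec, ppv, npv, (deg_ppv, deg_npv)


def roc_analysis(scores, labels, rule="youden") -> ROCResult:
    """Full ROC: curve points, AUC, and metrics at the chosen cutoff."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thr = _sk_roc_curve(y, s)
    cutoff, sens, spec, ppv, npv, (dp, dn) = operating_point(s, y, rule)
    rule_name = rule if isinstance(rule, str) else f"fixed({rule[1]:g})"
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc(s, y),
                     cutoff=cutoff, sensitivity=sens, specificity=spec,
                     ppv=ppv, npv=npv, n_event=int(y.sum()),
                     n_nonevent=int((1 - y).sum()), cutoff_rule=rule_name,
                     degenerate_ppv=dp, degenerate_npv=dn)


@dataclass
class DeLongResult:
    """Paired comparison of two correlated AUCs."""

    auc1: float
    auc2: float
    delta: float
    variance: float
    z: float
    p_value: float
    degenerate: bool = False

    def __repr__(self) -> str:
        return (f"<DeLongResult AUC1={self.auc1:.4f} AUC2={self.auc2:.4f} "
                f"z={self.z:.3f} p={self.p_value:.4g}>")


def _placements(s: np.ndarray, y: np.ndarray):
    """DeLong placement values V10 (events) and V01 (non-events)."""
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def delong_paired(scores1, scores2, labels) -> DeLongResult:
    """DeLong test for the difference of two AUCs on the same samples.

    Variance of the AUC difference combines the event- and non-event-side
    covariance of the placement values; z = dAUC / sqrt(var), two-sided
    normal p.  Zero variance with zero difference gives p = 1; zero
    variance with a non-zero difference gives p = 0 with a degeneracy flag.
    """
    y = _check_labels(labels)
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    if s1.shape != s2.shape or s1.shape[0] != y.shape[0]:
        raise ValueError("paired scores must cover the same samples")
    v10_1, v01_1 = _placements(s1, y)
    v10_2, v01_2 = _placements(s2, y)
    a1, a2 = float(v10_1.mean()), float(v10_2.mean())
    m, n = len(v10_1), len(v01_1)
    if m < 2 or n < 2:
        raise ValueError("need at least 2 samples in each class")
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    var = max(float(var), 0.0)
    delta = a1 - a2
    if var == 0.0:
        if delta == 0.0:
            return DeLongResult(a1, a2, 0.0, 0.0, 0.0, 1.0)
        return DeLongResult(a1, a2, delta, 0.0, np.sign(delta) * np.inf, 0.0, degenerate=True)
    z = delta / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongResult(a1, a2, delta, var, float(z), p)
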