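"""Evaluation statistics: ROC AUC, confusion metrics, jackknife CIs, DeLong test.

The AUC is the Mann-Whitney U statistic normalized by n_pos * n_neg with ties
counted as 1/2. Confidence intervals use the leave-one-group-out pseudovalue
jackknife with the patient as the resampling unit (images of one patient are
correlated, so leaving out images would understate the variance). Correlated
AUCs on a shared test set are compared with the DeLong test via per-case
placement values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ScoreSet:
    """Per-image predicted probabilities with labels and patient grouping."""

    scores: np.ndarray
    labels: np.ndarray
    group_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        if self.group_ids is not None:
            object.__setattr__(self, "group_ids", np.asarray(self.group_ids))
            if len(self.group_ids) != len(self.scores):
                raise ValueError("group_ids length mismatch")
        if len(self.scores) != len(self.labels):
            raise ValueError("scores and labels must have equal length")

    def __len__(self) -> int:
        return len(self.scores)

    def subset(self, mask: np.ndarray) -> "ScoreSet":
        g = self.group_ids[mask] if self.group_ids is not None else None
        return ScoreSet(self.scores[mask], self.labels[mask], g)


@dataclass(frozen=True)
class MetricReport:
    auc: float | None = None
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    n_pos: int = 0
    n_neg: int = 0

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    difference: float
    variance: float
    z_statistic: float
    p_value: float


def roc_auc(scoreset: ScoreSet) -> float:
    """Mann-Whitney AUC with ties counted as 1/2."""
    y = scoreset.labels
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scoreset.scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def confusion_metrics(scoreset: ScoreSet, threshold: float = 0.5) -> MetricReport:
    """The five thresholded metrics plus AUC from one 2x2 table.

    Scores >= threshold predict the positive class (S1plus). Ratios with a
    zero denominator are reported as None with a warning, never as 0.
    """
    if len(scoreset) == 0:
        raise ValueError("empty score set")
    y = scoreset.labels
    pred = (scoreset.scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return None
        return num / den

    n_pos, n_neg = tp + fn, tn + fp
    try:
        auc = roc_auc(scoreset)
    except ValueError:
        auc = None
    return MetricReport(
        auc=auc,
        accuracy=(tp + tn) / len(scoreset),
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def jackknife_ci(
    scoreset: ScoreSet, metric, level: float = 0.95
) -> tuple[float, float, float]:
    """Leave-one-group-out pseudovalue jackknife CI for any scalar metric.

    Groups default to patients (``group_ids``) or to single observations.
    Returns (estimate, ci_low, ci_high) with the interval clipped to [0, 1].
    Replicates on which the metric is not computable (e.g. a left-out group
    removes an entire class) are skipped with a warning.
    """
    groups = (
        scoreset.group_ids
        if scoreset.group_ids is not None
        else np.arange(len(scoreset))
    )
    unique = np.unique(groups)
    if len(unique) < 2:
        raise ValueError("jackknife requires at least 2 groups")
    theta_full = metric(scoreset)
    g = len(unique)
    pseudovalues = []
    for u in unique:
        try:
            theta_minus = metric(scoreset.subset(groups != u))
        except ValueError:
            warnings.warn(f"jackknife replicate for group {u!r} skipped", stacklevel=2)
            continue
        pseudovalues.append(g * theta_full - (g - 1) * theta_minus)
    if len(pseudovalues) < 2:
        raise ValueError("fewer than 2 usable jackknife replicates")
    pv = np.asarray(pseudovalues, dtype=float)
    est = float(pv.mean())
    se = float(pv.std(ddof=1) / np.sqrt(len(pv)))
    z = stats.norm.ppf(0.5 + level / 2)
    return est, float(np.clip(est - z * se, 0, 1)), float(np.clip(est + z * se, 0, 1))


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components (placement values) for one classifier."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # V10[i] = P(pos_i > random neg), ties 1/2; V01[j] symmetric
    v10 = ((pos[:, None] > neg[None, :]).sum(axis=1) + 0.5 * (pos[:, None] == neg[None, :]).sum(axis=1)) / len(neg)
    v01 = ((pos[None, :] > neg[:, None]).sum(axis=1) + 0.5 * (pos[None, :] == neg[:, None]).sum(axis=1)) / len(pos)
    return v10, v01, float(v10.mean())


def delong_test(scoreset_a: ScoreSet, scoreset_b: ScoreSet) -> DeLongResult:
    """DeLong test for two correlated AUCs on the same test cases."""
    if not np.array_equal(scoreset_a.labels, scoreset_b.labels):
        raise ValueError("DeLong test requires identical labels (paired scores)")
    labels = scoreset_a.labels
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValueError("DeLong test requires both classes present")
    v10a, v01a, auc_a = _placements(scoreset_a.scores, labels)
    v10b, v01b, auc_b = _placements(scoreset_b.scores, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    diff = auc_a - auc_b
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var <= 0:
        if diff == 0:
            return DeLongResult(auc_a, auc_b, 0.0, max(var, 0.0), 0.0, 1.0)
        raise ValueError("non-positive DeLong variance with nonzero AUC difference")
    z = diff / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, float(diff), var, float(z), p)
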