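"""Clinical evaluation of variant-effect maps.

Utilities for comparing map scores with clinical annotations: diploid
genotype scoring for recessive conditions, the Mann-Whitney U rank test
for group comparisons, precision-recall analysis with low score treated
as disease-predictive, and the reference-bracketing classification used
for blinded variants of uncertain significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import erf, sqrt

import numpy as np
import pandas as pd

__all__ = [
    "diploid_score",
    "mann_whitney_u",
    "MannWhitneyResult",
    "PRCurve",
    "precision_recall",
    "classify_by_references",
    "evaluate_clinical_table",
]

CLINICAL_LABELS = ("pathogenic", "reference", "unknown")


def diploid_score(allele_scores: tuple[float, float]) -> float:
    """Diploid genotype score: the maximum across the two alleles.

    Under recessive inheritance one functional allele suffices, so the
    better-scoring allele determines the subject's expected phenotype.
    """
    a, b = allele_scores
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("allele scores must be finite")
    return max(float(a), float(b))


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p_value: float
    n_a: int
    n_b: int


def mann_whitney_u(group_a, group_b, alternative: str = "two-sided"
                   ) -> MannWhitneyResult:
    """Mann-Whitney U comparing two score groups.

    U counts pairs (a, b) where the first group's score is *lower*
    (ties count one half), i.e. large U means group_a scores below
    group_b.  The p-value uses the normal approximation with tie and
    continuity corrections; ``alternative`` is ``"two-sided"`` or
    ``"less"`` (one-sided: group_a stochastically lower).  U itself is
    the primary statistic.
    """
    if alternative not in ("two-sided", "less"):
        raise ValueError("alternative must be 'two-sided' or 'less'")
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    diff = a[:, None] - b[None, :]
    U = float(np.sum(diff < 0) + 0.5 * np.sum(diff == 0))

    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1.0)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * (n + 1.0 - tie_term)
    if var <= 0:
        return MannWhitneyResult(U, 1.0, n_a, n_b)
    if alternative == "two-sided":
        z = (abs(U - mu) - 0.5) / sqrt(var)
        p = 2.0 * (1.0 - 0.5 * (1.0 + erf(max(z, 0.0) / sqrt(2.0))))
    else:
        z = (U - mu - 0.5) / sqrt(var)
        p = 1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0)))
    return MannWhitneyResult(U, min(p, 1.0), n_a, n_b)


@dataclass
class PRCurve:
    """Precision-recall points (recall non-decreasing) and step AUC."""

    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    auc: float


def precision_recall(scores, labels, low_score_positive: bool = True) -> PRCurve:
    """Precision-recall curve sweeping thresholds over unique scores.

    With ``low_score_positive`` (the default for damage scores) a
    variant is called positive when its score is at or below the
    threshold.  The AUC is a step-wise sum of precision over recall
    increments (no interpolation).
    """
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=bool)
    if y.all() or not y.any():
        raise ValueError("need at least one positive and one negative label")
    thresholds = np.unique(s)
    if not low_score_positive:
        thresholds = thresholds[::-1]
    n_pos = int(y.sum())
    precisions, recalls = [], []
    for t in thresholds:
        called = s <= t if low_score_positive else s >= t
        tp = int((called & y).sum())
        precisions.append(tp / called.sum() if called.any() else 1.0)
        recalls.append(tp / n_pos)
    precision = np.asarray(precisions)
    recall = np.asarray(recalls)
    auc = float(np.sum(np.diff(np.concatenate([[0.0], recall])) * precision))
    return PRCurve(precision, recall, thresholds, auc)


def classify_by_references(
    score: float, max_pathogenic_score: float, min_reference_score: float
) -> str:
    """Bracket a score between known pathogenic and reference variants.

    damaging: below both the highest known-pathogenic score and the
    lowest reference (population) score; benign: above both; otherwise
    uncertain.
    """
    if not (np.isfinite(max_pathogenic_score) and np.isfinite(min_reference_score)):
        raise ValueError("reference anchors must be finite")
    below_path = score < max_pathogenic_score
    below_ref = score < min_reference_score
    if below_path and below_ref:
        return "damaging"
    if not below_path and not below_ref:
        return "benign"
    return "uncertain"


def evaluate_clinical_table(table: pd.DataFrame) -> pd.DataFrame:
    """Classify unknown-label variants against the labelled references.

    ``table`` needs columns variant, score, label (pathogenic /
    reference / unknown).  Returns the unknown rows with a ``call``
    column from :func:`classify_by_references`.
    """
    bad = set(table["label"]) - set(CLINICAL_LABELS)
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}")
    max_path = table.loc[table.label == "pathogenic", "score"].max()
    min_ref = table.loc[table.label == "reference", "score"].min()
    out = table[table.label == "unknown"].copy()
    out["call"] = [
        classify_by_references(s, max_path, min_ref) for s in out["score"]
    ]
    return out.sort_values("score").reset_index(drop=True)
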