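"""Interaction calling under localization-stratified cutoffs, ROC-based
cutoff calibration, screen summaries, and reference-set statistics.

Calls are threshold-based, not p-value-based: a pair is BRET-positive when
its aggregate cBRET is at or above the cutoff for its localization class,
and likewise for cLuC.  The published defaults (cBRET >= 0.01 / cLuC >= 0.03,
raised to 0.03 / 0.05 when *both* proteins of a pair are membrane proteins)
are configuration values; `roc_analysis` reports the full empirical ROC plus
a Youden-index suggestion for users calibrating their own panels, but never
overwrites the configured cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import LocalizationAnnotation
from .scoring import InteractionScore

__all__ = [
    "CutoffScheme",
    "CallResult",
    "RocResult",
    "cutoff_class",
    "call_interaction",
    "call_screen",
    "summarize_screen",
    "roc_analysis",
    "fisher_exact_2x2",
    "replicate_correlation",
]


@dataclass(frozen=True)
class CutoffScheme:
    """Inclusive (>=) cutoffs for the two readouts, by localization class."""

    cbret_default: float = 0.01
    cluc_default: float = 0.03
    cbret_membrane: float = 0.03
    cluc_membrane: float = 0.05

    def __post_init__(self) -> None:
        if self.cbret_membrane < self.cbret_default or self.cluc_membrane < self.cluc_default:
            raise ValueError("membrane cutoffs must be >= default cutoffs")

    def cutoffs(self, cls: str) -> tuple[float, float]:
        if cls == "membrane_pair":
            return self.cbret_membrane, self.cluc_membrane
        return self.cbret_default, self.cluc_default


@dataclass(frozen=True)
class CallResult:
    pair_id: str
    cutoff_class: str
    bret_positive: bool
    luc_positive: bool

    @property
    def double_positive(self) -> bool:
        return self.bret_positive and self.luc_positive

    @property
    def any_positive(self) -> bool:
        return self.bret_positive or self.luc_positive


def cutoff_class(
    protein_a: str, protein_b: str, annotation: LocalizationAnnotation | None
) -> str:
    """``membrane_pair`` iff *both* proteins are membrane class, else
    ``default``.  Unannotated proteins default to non-membrane."""
    if annotation is None:
        return "default"
    if annotation.is_membrane(protein_a) and annotation.is_membrane(protein_b):
        return "membrane_pair"
    return "default"


def call_interaction(
    score: InteractionScore,
    scheme: CutoffScheme = CutoffScheme(),
    cls: str = "default",
) -> CallResult:
    """Flag a scored pair positive/negative per readout (inclusive cutoffs).

    Refuses pairs scored without both controls (``uncorrected``): their
    ratios are not background-corrected and would inflate positives.
    """
    if score.uncorrected:
        raise ValueError(
            f"pair {score.pair_id!r} was scored without both controls; "
            "uncorrected scores cannot be called"
        )
    cbret_cut, cluc_cut = scheme.cutoffs(cls)
    c_bret, c_luc = score.c_bret, score.c_luc
    return CallResult(
        pair_id=score.pair_id,
        cutoff_class=cls,
        bret_positive=bool(np.isfinite(c_bret) and c_bret >= cbret_cut),
        luc_positive=bool(np.isfinite(c_luc) and c_luc >= cluc_cut),
    )


def call_screen(
    scores: Iterable[InteractionScore],
    scheme: CutoffScheme = CutoffScheme(),
    annotation: LocalizationAnnotation | None = None,
    pair_proteins: dict[str, tuple[str, str]] | None = None,
    skip_uncorrected: bool = True,
) -> list[CallResult]:
    """Call every correctable pair of a screen.

    ``pair_proteins`` maps pair_id -> (protein_a, protein_b) for the
    localization lookup; pairs without an entry use the default class.
    """
    calls = []
    for s in scores:
        if s.uncorrected:
            if skip_uncorrected:
                continue
            raise ValueError(f"pair {s.pair_id!r} is uncorrected")
        if pair_proteins and s.pair_id in pair_proteins:
            a, b = pair_proteins[s.pair_id]
            cls = cutoff_class(a, b, annotation)
        else:
            cls = "default"
        calls.append(call_interaction(s, scheme, cls))
    return calls


def summarize_screen(
    calls: Sequence[CallResult], labels: dict[str, object] | None = None
) -> pd.DataFrame:
    """Counts and percentages of positives, overall and (optionally) per label.

    ``labels`` maps pair_id -> group label (e.g. reference-set membership or
    affinity sub-group); per-label recovery rates are appended when given.
    """
    def _row(group: str, subset: Sequence[CallResult]) -> dict:
        n = len(subset)
        counts = {
            "bret_positive": sum(c.bret_positive for c in subset),
            "luc_positive": sum(c.luc_positive for c in subset),
            "double_positive": sum(c.double_positive for c in subset),
            "any_positive": sum(c.any_positive for c in subset),
        }
        row = {"group": group, "n": n, **counts}
        for key, cnt in counts.items():
            row[f"{key}_pct"] = 100.0 * cnt / n if n else 0.0
        return row

    rows = [_row("all", list(calls))]
    if labels:
        by_label: dict[object, list[CallResult]] = {}
        for c in calls:
            if c.pair_id in labels:
                by_label.setdefault(labels[c.pair_id], []).append(c)
        for label in sorted(by_label, key=str):
            rows.append(_row(str(label), by_label[label]))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC over the distinct score values (inclusive thresholds)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_se: float
    youden_threshold: float
    youden_j: float


def roc_analysis(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Empirical ROC of a score against binary labels.

    Thresholds are the distinct observed score values, descending, with a
    leading +inf anchor; a sample is predicted positive when
    ``score >= threshold`` (matching the inclusive cutoff language of the
    calling layer).  AUC is the trapezoid integral; its standard error uses
    the Hanley–McNeil formula.  The Youden-optimal threshold (max TPR−FPR)
    is reported as a suggestion, not applied automatically.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D sequences of equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be represented in labels")

    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = scores >= t
        tpr[i] = np.sum(pred & (labels == 1)) / n_pos
        fpr[i] = np.sum(pred & (labels == 0)) / n_neg

    auc = float(np.trapezoid(tpr, fpr))
    # Hanley & McNeil (1982) analytic SE of the empirical AUC
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    auc_se = float(np.sqrt(max(var, 0.0)))

    j = tpr - fpr
    best = int(np.argmax(j))
    return RocResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        auc_se=auc_se,
        youden_threshold=float(thresholds[best]),
        youden_j=float(j[best]),
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Uses the conventional minimum-likelihood definition: the sum of the
    probabilities of all tables (with the observed margins) no more likely
    than the observed one.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
            raise ValueError("table entries must be nonnegative integers")
        arr = np.round(arr).astype(int)
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def replicate_correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Correlation between paired replicate scores with a two-tailed p.

    ``method`` is ``"pearson"`` or ``"spearman"``; p-values come from the
    usual t-approximation with n−2 degrees of freedom.  Constant input is an
    error (the coefficient is undefined), as is n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)
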